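"""Continuous-time Markov model (CTMM) inference for categorical traits.

Fits a K-state CTMM to tip states on a rooted tree by maximum likelihood
(Felsenstein pruning), selects among nested rate models (ER/SYM/ARD or custom
parameter tyings) by likelihood-ratio test, computes marginal ancestral state
probabilities by two-pass conditioning on all tips, labels every branch with
the ML state of its child node, and counts state transitions along edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import linalg, optimize, stats

from .categories import PhenotypeVector
from .phylo import Phylogeny

__all__ = [
    "RateModel",
    "TransitionRateMatrix",
    "AncestralReconstruction",
    "make_rate_model",
    "transition_probabilities",
    "pruning_loglik",
    "fit_ctmm",
    "lrt_select",
    "marginal_reconstruction",
    "count_transitions",
]

RATE_LOWER, RATE_UPPER = 1e-8, 1e4  # hard positivity bounds on each rate


@dataclass(frozen=True)
class RateModel:
    """Parameter tying for the K x K generator: ER, SYM, ARD, or custom.

    ``index`` is a K x K integer matrix with zero diagonal whose positive
    off-diagonal entries tie generator cells to shared free parameters
    (indices 1..n_params with no gaps).
    """

    k: int
    index: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        m = np.asarray(self.index)
        if m.shape != (self.k, self.k):
            raise ValueError(f"index matrix must be {self.k}x{self.k}")
        if np.any(np.diag(m) != 0):
            raise ValueError("index matrix diagonal must be zero")
        off = m[~np.eye(self.k, dtype=bool)]
        if np.any(off <= 0):
            raise ValueError("off-diagonal indices must be positive integers")
        want = set(range(1, int(off.max()) + 1))
        if set(off.tolist()) != want:
            raise ValueError("parameter indices must form 1..max with no gaps")

    @property
    def n_params(self) -> int:
        return int(self.index.max())

    def build_q(self, params: np.ndarray) -> np.ndarray:
        """Generator from the free-parameter vector (rows sum to zero)."""
        q = np.zeros((self.k, self.k))
        off = ~np.eye(self.k, dtype=bool)
        q[off] = np.asarray(params)[self.index[off] - 1]
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def is_nested_in(self, other: "RateModel") -> bool:
        """True when this model's tying is a coarsening of ``other``'s."""
        if self.k != other.k or self.n_params > other.n_params:
            return False
        off = ~np.eye(self.k, dtype=bool)
        a, b = self.index[off], other.index[off]
        # wherever other ties two cells together, self must too
        mapping: dict[int, int] = {}
        for bi, ai in zip(b, a):
            if mapping.setdefault(int(bi), int(ai)) != int(ai):
                return False
        return True


def make_rate_model(k: int, kind: Literal["ER", "SYM", "ARD"] | np.ndarray = "ER") -> RateModel:
    if k < 2:
        raise ValueError("rate models require K >= 2 categories")
    if isinstance(kind, str):
        kind = kind.upper()
        m = np.zeros((k, k), dtype=int)
        if kind == "ER":
            m[~np.eye(k, dtype=bool)] = 1
        elif kind == "SYM":
            c = 1
            for i in range(k):
                for j in range(i + 1, k):
                    m[i, j] = m[j, i] = c
                    c += 1
        elif kind == "ARD":
            c = 1
            for i in range(k):
                for j in range(k):
                    if i != j:
                        m[i, j] = c
                        c += 1
        else:
            raise ValueError(f"unknown rate model kind {kind!r}")
        return RateModel(k=k, index=m, name=kind)
    return RateModel(k=k, index=np.asarray(kind, dtype=int))


@dataclass
class TransitionRateMatrix:
    """A fitted (or specified) CTMM generator with its log-likelihood."""

    q: np.ndarray
    params: np.ndarray
    loglik: float
    model: RateModel
    root_prior: np.ndarray
    converged: bool = True

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        off = q[~np.eye(q.shape[0], dtype=bool)]
        if np.any(off < 0):
            raise ValueError("generator off-diagonals must be nonnegative")
        if np.max(np.abs(q.sum(axis=1))) > 1e-10:
            raise ValueError("generator rows must sum to zero")
        self.q = q

    @property
    def k(self) -> int:
        return self.q.shape[0]

    def stationary_distribution(self) -> np.ndarray:
        """Left null vector of Q, normalised to a probability vector."""
        w, v = np.linalg.eig(self.q.T)
        i = int(np.argmin(np.abs(w)))
        pi = np.real(v[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


def transition_probabilities(q: np.ndarray | TransitionRateMatrix, t: float) -> np.ndarray:
    """P(t) = expm(Q t); rows are probability vectors."""
    if isinstance(q, TransitionRateMatrix):
        q = q.q
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    k = q.shape[0]
    if t == 0:
        return np.eye(k)
    p = linalg.expm(q * t)
    p = np.clip(p, 0.0, 1.0)
    return p / p.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _tip_states(tree: Phylogeny, tips: PhenotypeVector) -> dict[int, int]:
    idx = tips.state_indices()
    out = {}
    for node in tree.tips:
        label = tree.labels[node]
        if label not in idx:
            raise ValueError(f"tip {label!r} missing from phenotype table")
        out[node] = idx[label]
    return out


def propagator(q: np.ndarray):
    """A fast ``t -> expm(Q t)`` closure.

    Uses the eigendecomposition of Q when it reproduces expm to 1e-10
    (checked once at a reference time); falls back to scipy's expm for
    defective or ill-conditioned generators.
    """
    k = q.shape[0]
    t_ref = 1.0 / max(np.max(np.abs(np.diag(q))), 1e-12)
    try:
        w, v = np.linalg.eig(q)
        vinv = np.linalg.inv(v)

        def eig_p(t: float) -> np.ndarray:
            p = np.real((v * np.exp(w * t)) @ vinv)
            p = np.clip(p, 0.0, 1.0)
            return p / p.sum(axis=1, keepdims=True)

        if np.max(np.abs(eig_p(t_ref) - transition_probabilities(q, t_ref))) < 1e-10:
            return lambda t: np.eye(k) if t == 0 else eig_p(t)
    except np.linalg.LinAlgError:
        pass
    return lambda t: transition_probabilities(q, t)


def _edge_matrices(tree: Phylogeny, q: np.ndarray) -> dict[int, np.ndarray]:
    # cache by branch length: many trees reuse few distinct lengths
    prop = propagator(q)
    cache: dict[float, np.ndarray] = {}
    out = {}
    for node in tree.postorder():
        if node == tree.root:
            continue
        t = float(tree.lengths[node])
        if t not in cache:
            cache[t] = prop(t)
        out[node] = cache[t]
    return out


def _partials(
    tree: Phylogeny, states: dict[int, int], k: int, pmats: dict[int, np.ndarray]
) -> tuple[np.ndarray, np.ndarray, float]:
    """Post-order conditional likelihoods with per-node scaling.

    Returns (down, up_msg, logscale) where ``down[v]`` is the scaled
    likelihood of tips below v given the state at v, and ``up_msg[v]``
    = P_v @ down[v] is the message v passes to its parent.
    """
    n = tree.n_nodes
    down = np.zeros((n, k))
    up_msg = np.zeros((n, k))
    logscale = 0.0
    for node in tree.postorder():
        if tree.is_tip(node):
            down[node, states[node]] = 1.0
        else:
            vec = np.ones(k)
            for c in tree.children[node]:
                vec *= up_msg[c]
            s = vec.sum()
            if s <= 0:
                # impossible data under this Q (numerically zero likelihood)
                return down, up_msg, -np.inf
            vec /= s
            logscale += np.log(s)
            down[node] = vec
        if node != tree.root:
            up_msg[node] = pmats[node] @ down[node]
    return down, up_msg, logscale


def pruning_loglik(
    tree: Phylogeny,
    tips: PhenotypeVector,
    q: np.ndarray | TransitionRateMatrix,
    root_prior: np.ndarray | None = None,
) -> float:
    """Log-likelihood of the observed tip states under the CTMM (Felsenstein pruning)."""
    if isinstance(q, TransitionRateMatrix):
        if root_prior is None:
            root_prior = q.root_prior
        q = q.q
    k = q.shape[0]
    prior = np.full(k, 1.0 / k) if root_prior is None else np.asarray(root_prior, float)
    states = _tip_states(tree, tips)
    pmats = _edge_matrices(tree, q)
    down, _, logscale = _partials(tree, states, k, pmats)
    if not np.isfinite(logscale):
        return -np.inf
    lik = float(prior @ down[tree.root])
    if lik <= 0:
        return -np.inf
    return float(np.log(lik) + logscale)


# ---------------------------------------------------------------------------
# Fitting and model selection
# ---------------------------------------------------------------------------

def _resolve_prior(policy, k: int, q: np.ndarray | None = None) -> np.ndarray:
    if policy is None or policy == "flat":
        return np.full(k, 1.0 / k)
    if policy == "stationary":
        if q is None:
            raise ValueError("stationary prior needs a fitted generator")
        return TransitionRateMatrix(
            q, np.array([]), 0.0, make_rate_model(k, "ER"), np.full(k, 1.0 / k)
        ).stationary_distribution()
    prior = np.asarray(policy, dtype=float)
    if prior.shape != (k,) or abs(prior.sum() - 1) > 1e-8 or np.any(prior < 0):
        raise ValueError("root prior must be a length-K probability vector")
    return prior


def fit_ctmm(
    tree: Phylogeny,
    tips: PhenotypeVector,
    model: RateModel | str = "ARD",
    root_prior: str | np.ndarray = "flat",
    n_starts: int = 5,
    seed: int = 0,
    extra_starts: Sequence[np.ndarray] = (),
) -> TransitionRateMatrix:
    """Maximum-likelihood CTMM fit with seeded multi-start quasi-Newton optimisation.

    Rates are optimised on the log scale for positivity; starts are
    log-uniform on [1e-3, 10] / tree-height.  ``extra_starts`` lets callers
    seed the search with parameter vectors (e.g. a nested model's optimum).
    """
    k = tips.k
    if k < 2:
        raise ValueError("CTMM fitting needs at least two observed categories")
    if isinstance(model, str):
        model = make_rate_model(k, model)
    if model.k != k:
        raise ValueError(f"rate model has K={model.k} but phenotype has K={k}")
    height = tree.height()
    if height <= 0:
        raise ValueError("tree must have positive total height")
    prior = _resolve_prior(root_prior if root_prior != "stationary" else "flat", k)
    states = _tip_states(tree, tips)

    def negloglik(log_rates: np.ndarray) -> float:
        q = model.build_q(np.exp(log_rates))
        pmats = _edge_matrices(tree, q)
        down, _, logscale = _partials(tree, states, k, pmats)
        if not np.isfinite(logscale):
            return 1e300
        lik = float(prior @ down[tree.root])
        if lik <= 0:
            return 1e300
        return -(np.log(lik) + logscale)

    rng = np.random.default_rng(seed)
    lo, hi = np.log(1e-3 / height), np.log(10.0 / height)
    starts = [rng.uniform(lo, hi, size=model.n_params) for _ in range(n_starts)]
    starts.insert(0, np.full(model.n_params, np.log(1.0 / height)))
    starts.extend(np.log(np.clip(s, RATE_LOWER, RATE_UPPER)) for s in extra_starts)

    bounds = [(np.log(RATE_LOWER), np.log(RATE_UPPER))] * model.n_params
    best = None
    any_converged = False
    for x0 in starts:
        res = optimize.minimize(
            negloglik, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    params = np.exp(best.x)
    q = model.build_q(params)
    if root_prior == "stationary":
        prior = _resolve_prior("stationary", k, q)
    return TransitionRateMatrix(
        q=q, params=params, loglik=-float(best.fun), model=model,
        root_prior=prior, converged=any_converged,
    )


@dataclass
class LRTComparison:
    simple: str
    complex: str
    statistic: float
    df: int
    pvalue: float


@dataclass
class ModelSelection:
    fits: dict[str, TransitionRateMatrix]
    comparisons: list[LRTComparison]
    selected: str

    @property
    def best(self) -> TransitionRateMatrix:
        return self.fits[self.selected]


def lrt_select(
    fits: Sequence[TransitionRateMatrix], alpha: float = 0.05
) -> ModelSelection:
    """Select among nested CTMM fits by stepwise likelihood-ratio tests.

    Fits must be ordered simple -> complex and pairwise nested; a more
    complex model is adopted when it rejects the currently held one at
    ``alpha`` (chi-square, df = difference in free parameters).
    """
    if len(fits) < 2:
        raise ValueError("model selection needs at least two fits")
    by_name = {f.model.name: f for f in fits}
    comparisons: list[LRTComparison] = []
    current = fits[0]
    for cand in fits[1:]:
        if not current.model.is_nested_in(cand.model):
            raise ValueError(
                f"{current.model.name} is not nested in {cand.model.name}"
            )
        df = cand.model.n_params - current.model.n_params
        stat = 2.0 * (cand.loglik - current.loglik)
        p = float(stats.chi2.sf(max(stat, 0.0), df)) if df > 0 else 1.0
        comparisons.append(
            LRTComparison(current.model.name, cand.model.name, stat, df, p)
        )
        if p < alpha:
            current = cand
    return ModelSelection(fits=by_name, comparisons=comparisons, selected=current.model.name)


def fit_rate_models(
    tree: Phylogeny,
    tips: PhenotypeVector,
    kinds: Sequence[str] = ("ER", "SYM", "ARD"),
    root_prior="flat",
    seed: int = 0,
) -> ModelSelection:
    """Fit a nested ladder of rate models and run LRT selection.

    Each more complex fit is seeded with the simpler optimum expanded to its
    parameterisation, guaranteeing a nonnegative LRT statistic.
    """
    fits: list[TransitionRateMatrix] = []
    prev: TransitionRateMatrix | None = None
    for kind in kinds:
        model = make_rate_model(tips.k, kind)
        extra = []
        if prev is not None and prev.model.is_nested_in(model):
            off = ~np.eye(tips.k, dtype=bool)
            expanded = np.zeros(model.n_params)
            expanded[model.index[off] - 1] = prev.q[off]
            extra.append(expanded)
        fit = fit_ctmm(tree, tips, model, root_prior=root_prior, seed=seed,
                       extra_starts=extra)
        fits.append(fit)
        prev = fit
    return lrt_select(fits)


# ---------------------------------------------------------------------------
# Ancestral reconstruction
# ---------------------------------------------------------------------------

@dataclass
class AncestralReconstruction:
    """Marginal state probabilities, ML states, and branch category labels."""

    tree: Phylogeny
    categories: list[str]
    probabilities: np.ndarray     # n_nodes x K, each row sums to 1
    ml_states: np.ndarray         # int per node
    root_prior: np.ndarray
    method: str = "marginal"

    def branch_labels(self) -> dict[int, int]:
        """Category index per branch (identified by child node)."""
        return {
            node: int(self.ml_states[node])
            for node in range(self.tree.n_nodes)
            if node != self.tree.root
        }

    def internal_nodes(self) -> list[int]:
        return [n for n in range(self.tree.n_nodes) if not self.tree.is_tip(n)]

    def internal_state_multiset(self) -> list[int]:
        return sorted(int(self.ml_states[n]) for n in self.internal_nodes())


def marginal_reconstruction(
    tree: Phylogeny,
    tips: PhenotypeVector,
    q: TransitionRateMatrix | np.ndarray,
    root_prior: np.ndarray | None = None,
    method: Literal["marginal", "joint"] = "marginal",
) -> AncestralReconstruction:
    """Per-node ancestral state probabilities conditioning on all tips.

    ``marginal`` uses two-pass (inside/outside) conditioning; ``joint``
    returns the single best joint assignment (max-product) with indicator
    probability rows.  ML-state ties break toward the lowest category index.
    """
    if isinstance(q, TransitionRateMatrix):
        if root_prior is None:
            root_prior = q.root_prior
        q = q.q
    k = q.shape[0]
    prior = np.full(k, 1.0 / k) if root_prior is None else np.asarray(root_prior, float)
    states = _tip_states(tree, tips)
    pmats = _edge_matrices(tree, q)
    n = tree.n_nodes

    if method == "joint":
        probs, ml = _joint_reconstruction(tree, states, k, pmats, prior)
    else:
        down, up_msg, logscale = _partials(tree, states, k, pmats)
        if not np.isfinite(logscale):
            raise ValueError("data have zero likelihood under this generator")
        # outside pass: out[v] = likelihood of everything outside v's subtree
        out = np.zeros((n, k))
        out[tree.root] = prior
        for node in tree.postorder()[::-1]:  # pre-order
            for c in tree.children[node]:
                sib = out[node].copy()
                for s in tree.children[node]:
                    if s != c:
                        sib *= up_msg[s]
                vec = sib @ pmats[c]
                tot = vec.sum()
                out[c] = vec / tot if tot > 0 else np.full(k, 1.0 / k)
        probs = out * down
        probs /= probs.sum(axis=1, keepdims=True)
        ml = np.argmax(probs, axis=1)  # argmax takes the lowest index on ties

    # tips are exact indicators of their observed state
    for node, s in states.items():
        ind = np.zeros(k)
        ind[s] = 1.0
        probs[node] = ind
        ml[node] = s
    return AncestralReconstruction(
        tree=tree, categories=list(tips.categories), probabilities=probs,
        ml_states=np.asarray(ml, dtype=int), root_prior=prior, method=method,
    )


def _joint_reconstruction(tree, states, k, pmats, prior):
    n = tree.n_nodes
    logmsg = np.zeros((n, k))   # max-product message from node to parent
    back = {}                   # (node, parent_state) -> best child state
    tiny = -1e300
    for node in tree.postorder():
        if tree.is_tip(node):
            vec = np.full(k, tiny)
            vec[states[node]] = 0.0
        else:
            vec = np.zeros(k)
            for c in tree.children[node]:
                vec += logmsg[c]
        if node == tree.root:
            root_vec = vec + np.log(prior)
            continue
        scores = vec[None, :] + np.log(np.maximum(pmats[node], 1e-300))
        logmsg[node] = scores.max(axis=1)
        back[node] = scores.argmax(axis=1)
    ml = np.zeros(n, dtype=int)
    ml[tree.root] = int(np.argmax(root_vec))
    for node in tree.postorder()[::-1]:
        for c in tree.children[node]:
            ml[c] = int(back[c][ml[node]])
    probs = np.zeros((n, k))
    probs[np.arange(n), ml] = 1.0
    return probs, ml


def count_transitions(
    tree: Phylogeny, reconstruction: AncestralReconstruction
) -> dict[frozenset[int], int]:
    """Per unordered category pair, the number of edges whose endpoint ML states differ."""
    ml = reconstruction.ml_states
    counts: dict[frozenset[int], int] = {}
    for node in tree.postorder():
        if node == tree.root:
            continue
        a, b = int(ml[tree.parent[node]]), int(ml[node])
        if a != b:
            key = frozenset((a, b))
            counts[key] = counts.get(key, 0) + 1
    return counts
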