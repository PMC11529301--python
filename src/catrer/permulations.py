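"""Phylogeny-aware permutation ("permulation") nulls for categorical traits.

A permulation is a null branch labeling built in three steps: (i) tip states
are simulated from the fitted CTMM on the master tree and rejection-sampled
until every category's extant count matches the observed count (optionally
within a relaxation tolerance); (ii) the observed reconstruction's internal
states are randomly permuted onto the internal nodes; (iii) a simulated-
annealing swap search re-organises the internal states to improve the
likelihood of the full labeling while conserving the internal-state multiset.
Gene statistics recomputed under each null labeling yield empirical p-values.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .asr import AncestralReconstruction, TransitionRateMatrix, transition_probabilities
from .phylo import BranchIndex, Phylogeny

__all__ = [
    "PermulationConfig",
    "PermulationSet",
    "EmpiricalPValues",
    "simulate_tip_states",
    "rejection_sample",
    "permute_internal",
    "anneal_internal",
    "permulate",
    "empirical_pvalues",
    "null_gene_stats",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric-cooling schedule: T starts at ``t0`` and is multiplied by
    ``cooling`` after every sweep of ``n_internal`` proposals; total proposals
    = min(100 * n_internal, cap)."""

    t0: float = 1.0
    cooling: float = 0.95
    sweeps: int = 100
    cap: int = 10_000


@dataclass(frozen=True)
class PermulationConfig:
    n: int = 100
    relax: float = 0.0
    max_attempts: int | None = None   # default 100 * n per draw
    schedule: AnnealSchedule = AnnealSchedule()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("need at least one permulation")
        if not 0.0 <= self.relax <= 1.0:
            raise ValueError("relaxation must lie in [0, 1]")
        if self.max_attempts is not None and self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")

    @property
    def attempts_per_draw(self) -> int:
        return self.max_attempts if self.max_attempts is not None else 100 * self.n


@dataclass
class PermulationSet:
    """N null labelings of every tree node, plus per-draw provenance."""

    tree: Phylogeny
    categories: list[str]
    states: np.ndarray            # n_draws x n_nodes, category indices
    attempts: np.ndarray          # rejection attempts used per draw
    logliks: np.ndarray           # full-labeling log-likelihood after annealing
    config: PermulationConfig

    @property
    def n(self) -> int:
        return self.states.shape[0]

    def branch_label_matrix(self, idx: BranchIndex) -> np.ndarray:
        """n_draws x n_branches category indices, child-node rule, index order."""
        nodes = [idx.node_of[c] for c in idx.clade_order]
        return self.states[:, nodes]


@dataclass
class EmpiricalPValues:
    pvalues: pd.Series
    n_nulls: pd.Series
    floored: pd.Series            # True where observed beat every null

    def display(self) -> pd.Series:
        """Render, showing floored entries as '< 1/N'."""
        out = self.pvalues.map(lambda p: f"{p:.6g}")
        for item in self.pvalues.index[self.floored]:
            out.loc[item] = f"< {1.0 / self.n_nulls.loc[item]:.3g}"
        return out


# ---------------------------------------------------------------------------
# Step (i): CTMM simulation with count-matching rejection
# ---------------------------------------------------------------------------

from .asr import _edge_matrices as _sim_matrices  # same propagator caching


def _simulate_batch(
    tree: Phylogeny,
    pmats: dict[int, np.ndarray],
    prior: np.ndarray,
    rng: np.random.Generator,
    batch: int,
) -> np.ndarray:
    """``batch`` independent trait histories; rows are per-node state vectors."""
    k = prior.size
    order = tree.postorder()[::-1]  # parents before children
    states = np.zeros((batch, tree.n_nodes), dtype=int)
    u = rng.random((batch, tree.n_nodes))
    prior_cum = np.cumsum(prior)
    states[:, tree.root] = np.searchsorted(prior_cum, u[:, tree.root], side="right")
    cum = {node: np.cumsum(pm, axis=1) for node, pm in pmats.items()}
    for node in order:
        if node == tree.root:
            continue
        rows = cum[node][states[:, tree.parent[node]]]       # batch x K
        states[:, node] = (rows < u[:, node][:, None]).sum(axis=1)
    return np.minimum(states, k - 1)


def simulate_tip_states(
    tree: Phylogeny,
    q: TransitionRateMatrix | np.ndarray,
    root_prior: np.ndarray | None = None,
    rng: np.random.Generator | int = 0,
    _pmats: dict[int, np.ndarray] | None = None,
) -> np.ndarray:
    """Simulate one trait history down the tree; returns a state per node."""
    if isinstance(q, TransitionRateMatrix):
        if root_prior is None:
            root_prior = q.root_prior
        q = q.q
    k = q.shape[0]
    prior = np.full(k, 1.0 / k) if root_prior is None else np.asarray(root_prior, float)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    pmats = _pmats if _pmats is not None else _sim_matrices(tree, q)
    return _simulate_batch(tree, pmats, prior, rng, 1)[0]


def _tip_counts(tree: Phylogeny, states: np.ndarray, k: int) -> np.ndarray:
    tips = np.fromiter((n for n in range(tree.n_nodes) if tree.is_tip(n)), dtype=int)
    return np.bincount(states[tips], minlength=k)


class RejectionExhausted(RuntimeError):
    """No simulated phenotype matched the observed counts; try a larger relaxation."""


def rejection_sample(
    tree: Phylogeny,
    q: TransitionRateMatrix | np.ndarray,
    root_prior: np.ndarray | None,
    observed_counts: np.ndarray,
    relax: float = 0.0,
    max_attempts: int = 10_000,
    rng: np.random.Generator | int = 0,
    _pmats: dict[int, np.ndarray] | None = None,
) -> tuple[np.ndarray, int]:
    """Simulate until category counts match the observed ones.

    Acceptance: for every category c, |count_c(sim) - count_c(obs)| <=
    ceil(relax * count_c(obs)); relax = 0 demands exact equality and
    relax = 1 accepts any draw.  Returns (node states, attempts used).
    """
    if isinstance(q, TransitionRateMatrix):
        if root_prior is None:
            root_prior = q.root_prior
        q = q.q
    k = q.shape[0]
    observed_counts = np.asarray(observed_counts)
    if relax >= 1.0:
        tol = np.full_like(observed_counts, observed_counts.sum())
    else:
        tol = np.ceil(relax * observed_counts).astype(int)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    pmats = _pmats if _pmats is not None else _sim_matrices(tree, q)
    prior = np.full(k, 1.0 / k) if root_prior is None else np.asarray(root_prior, float)
    tips = np.fromiter((n for n in range(tree.n_nodes) if tree.is_tip(n)), dtype=int)
    used = 0
    batch_size = 16  # grow geometrically: cheap when acceptance is easy
    while used < max_attempts:
        batch = int(min(batch_size, max_attempts - used))
        batch_size = min(batch_size * 2, 512)
        states = _simulate_batch(tree, pmats, prior, rng, batch)
        counts = np.stack([
            np.bincount(states[b, tips], minlength=k) for b in range(batch)
        ])
        ok = np.all(np.abs(counts - observed_counts[None, :]) <= tol[None, :], axis=1)
        hit = np.flatnonzero(ok)
        if hit.size:
            return states[hit[0]], used + int(hit[0]) + 1
        used += batch
    raise RejectionExhausted(
        f"no accepted draw in {max_attempts} attempts at relaxation {relax}; "
        "increase the relaxation fraction or the attempt budget"
    )


# ---------------------------------------------------------------------------
# Steps (ii)-(iii): permute and re-organise internal states
# ---------------------------------------------------------------------------

def permute_internal(
    observed_internal: np.ndarray, rng: np.random.Generator | int = 0
) -> np.ndarray:
    """A uniform random permutation of the observed internal-state multiset."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    arr = np.asarray(observed_internal)
    return arr[rng.permutation(arr.size)]


def _labeling_loglik(
    tree: Phylogeny, states: np.ndarray, logp: dict[int, np.ndarray], log_prior: np.ndarray
) -> float:
    ll = float(log_prior[states[tree.root]])
    for node, lp in logp.items():
        ll += lp[states[tree.parent[node]], states[node]]
    return ll


def anneal_internal(
    tree: Phylogeny,
    states: np.ndarray,
    q: TransitionRateMatrix | np.ndarray,
    root_prior: np.ndarray | None = None,
    schedule: AnnealSchedule = AnnealSchedule(),
    rng: np.random.Generator | int = 0,
    _logp: dict[int, np.ndarray] | None = None,
    _log_prior: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Swap-based annealing over internal states, conserving their multiset.

    Proposals swap the states of two internal nodes with differing states;
    improvements are always accepted, worsenings with probability
    exp(delta/T) under geometric cooling.  Returns the best labeling visited
    and its log-likelihood (never worse than the input's).
    """
    if isinstance(q, TransitionRateMatrix):
        if root_prior is None:
            root_prior = q.root_prior
        q = q.q
    k = q.shape[0]
    prior = np.full(k, 1.0 / k) if root_prior is None else np.asarray(root_prior, float)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if _logp is None:
        _logp = {
            node: np.log(np.maximum(pm, 1e-300))
            for node, pm in _sim_matrices(tree, q).items()
        }
    log_prior = _log_prior if _log_prior is not None else np.log(np.maximum(prior, 1e-300))

    internal = [n for n in range(tree.n_nodes) if not tree.is_tip(n)]
    states = np.asarray(states).copy()
    if len(set(int(states[n]) for n in internal)) < 2:
        ll = _labeling_loglik(tree, states, _logp, log_prior)
        return states, ll

    def local_ll(nodes: set[int], st: np.ndarray) -> float:
        total = 0.0
        edges: set[int] = set()
        for u in nodes:
            if u != tree.root:
                edges.add(u)
            edges.update(tree.children[u])
        for e in edges:
            total += _logp[e][st[tree.parent[e]], st[e]]
        if tree.root in nodes:
            total += log_prior[st[tree.root]]
        return total

    current_ll = _labeling_loglik(tree, states, _logp, log_prior)
    best_states, best_ll = states.copy(), current_ll
    n_int = len(internal)
    total_steps = min(schedule.sweeps * n_int, schedule.cap)
    temp = schedule.t0
    internal_arr = np.asarray(internal)
    for step in range(total_steps):
        if step > 0 and step % n_int == 0:
            temp *= schedule.cooling
        u = v = -1
        for _ in range(20):
            u, v = internal_arr[rng.integers(0, n_int)], internal_arr[rng.integers(0, n_int)]
            if states[u] != states[v]:
                break
        else:
            break
        nodes = {int(u), int(v)}
        before = local_ll(nodes, states)
        states[u], states[v] = states[v], states[u]
        after = local_ll(nodes, states)
        delta = after - before
        if delta >= 0 or rng.random() < math.exp(delta / max(temp, 1e-12)):
            current_ll += delta
            if current_ll > best_ll:
                best_ll = current_ll
                best_states = states.copy()
        else:
            states[u], states[v] = states[v], states[u]
    return best_states, best_ll


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def permulate(
    master: Phylogeny,
    q: TransitionRateMatrix,
    reconstruction: AncestralReconstruction,
    observed_counts: np.ndarray,
    cfg: PermulationConfig,
) -> PermulationSet:
    """Draw N independent permulations (rejection -> permute -> anneal).

    Each draw uses an independent child RNG spawned from ``cfg.seed``, so the
    whole set is reproducible bit-for-bit from the config.
    """
    k = q.k
    pmats = _sim_matrices(master, q.q)
    logp = {node: np.log(np.maximum(pm, 1e-300)) for node, pm in pmats.items()}
    log_prior = np.log(np.maximum(q.root_prior, 1e-300))
    internal = reconstruction.internal_nodes()
    obs_internal = reconstruction.ml_states[internal]

    n_nodes = master.n_nodes
    states = np.zeros((cfg.n, n_nodes), dtype=int)
    attempts = np.zeros(cfg.n, dtype=int)
    logliks = np.zeros(cfg.n)
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n)
    for i in range(cfg.n):
        rng = np.random.default_rng(seeds[i])
        sim, used = rejection_sample(
            master, q.q, q.root_prior, observed_counts,
            relax=cfg.relax, max_attempts=cfg.attempts_per_draw, rng=rng,
            _pmats=pmats,
        )
        sim[internal] = permute_internal(obs_internal, rng)
        final, ll = anneal_internal(
            master, sim, q.q, q.root_prior, schedule=cfg.schedule, rng=rng,
            _logp=logp, _log_prior=log_prior,
        )
        states[i] = final
        attempts[i] = used
        logliks[i] = ll
        if (i + 1) % 50 == 0:
            log.info("permulation %d/%d", i + 1, cfg.n)
    return PermulationSet(
        tree=master, categories=list(reconstruction.categories),
        states=states, attempts=attempts, logliks=logliks, config=cfg,
    )


# ---------------------------------------------------------------------------
# Null gene statistics and empirical p-values
# ---------------------------------------------------------------------------

def null_gene_stats(
    rers: pd.DataFrame,
    perms: PermulationSet,
    idx: BranchIndex,
    min_per_category: int = 2,
    posthoc: bool = False,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Kruskal-Wallis effect sizes (and optionally Dunn Z) under every null labeling.

    Returns ``eff`` of shape (n_draws, n_genes) with nan where a labeling
    leaves some category short of ``min_per_category`` usable branches for
    the gene, and ``z`` of shape (n_draws, n_pairs, n_genes) when
    ``posthoc`` is requested.  Ranks are computed once per gene: only the
    group memberships change across draws.
    """
    label_mat = perms.branch_label_matrix(idx)      # n_draws x n_branches
    k = len(perms.categories)
    x = rers.to_numpy(dtype=float)
    n_branches, n_genes = x.shape
    n_draws = label_mat.shape[0]
    pairs = list(itertools.combinations(range(k), 2))

    # per-gene fixed quantities
    ranks = np.full_like(x, np.nan)
    tie_terms = np.zeros(n_genes)
    ns = np.zeros(n_genes, dtype=int)
    masks = np.isfinite(x)
    for g in range(n_genes):
        m = masks[:, g]
        vals = x[m, g]
        ns[g] = vals.size
        ranks[m, g] = stats.rankdata(vals)
        _, cnt = np.unique(vals, return_counts=True)
        tie_terms[g] = float(np.sum(cnt**3 - cnt))

    eff = np.full((n_draws, n_genes), np.nan)
    zmat = np.full((n_draws, len(pairs), n_genes), np.nan) if posthoc else None
    rk = np.nan_to_num(ranks)
    complete = masks.all(axis=0)

    for d in range(n_draws):
        lab = label_mat[d]
        onehot = np.zeros((n_branches, k))
        onehot[np.arange(n_branches), lab] = 1.0
        # group sizes and rank sums per gene (masked)
        sizes = masks.T.astype(float) @ onehot        # n_genes x k
        rsums = (rk.T @ onehot)                       # n_genes x k
        valid = (sizes >= min_per_category).all(axis=1)
        n = ns.astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            h = 12.0 / (n * (n + 1)) * np.sum(rsums**2 / np.where(sizes > 0, sizes, np.nan), axis=1) - 3 * (n + 1)
            correction = 1.0 - tie_terms / (n**3 - n)
            h = h / np.where(correction > 0, correction, np.nan)
            e2 = h / (n - 1)
        e2[~valid] = np.nan
        eff[d] = e2
        if posthoc:
            with np.errstate(divide="ignore", invalid="ignore"):
                mean_ranks = rsums / sizes            # n_genes x k
                var_base = n * (n + 1) / 12.0 - tie_terms / (12.0 * (n - 1))
                for pi, (a, b) in enumerate(pairs):
                    se = np.sqrt(var_base * (1.0 / sizes[:, a] + 1.0 / sizes[:, b]))
                    z = (mean_ranks[:, a] - mean_ranks[:, b]) / se
                    z[~valid] = np.nan
                    zmat[d, pi] = z
    return eff, zmat


def empirical_pvalues(
    observed: pd.Series,
    nulls: np.ndarray,
    sidedness: str = "greater",
) -> EmpiricalPValues:
    """Empirical p per item: proportion of nulls at least as extreme as observed.

    ``greater`` counts null >= observed (one-sided, for effect sizes);
    ``two-sided`` compares absolute values (for signed post hoc statistics).
    p = 0 is flagged as floored (reportable as "< 1/N"); no add-one
    correction is applied by default.
    """
    obs = observed.to_numpy(dtype=float)
    nulls = np.asarray(nulls, dtype=float)
    if nulls.ndim != 2 or nulls.shape[1] != obs.size:
        raise ValueError("nulls must be (n_draws, n_items)")
    valid = np.isfinite(nulls)
    n_valid = valid.sum(axis=0)
    if np.any(n_valid == 0):
        bad = observed.index[n_valid == 0].tolist()
        raise ValueError(f"items with no valid nulls: {bad}")
    if sidedness == "two-sided":
        hits = (np.abs(nulls) >= np.abs(obs)[None, :]) & valid
    elif sidedness == "greater":
        hits = (nulls >= obs[None, :]) & valid
    else:
        raise ValueError("sidedness must be 'greater' or 'two-sided'")
    p = hits.sum(axis=0) / n_valid
    return EmpiricalPValues(
        pvalues=pd.Series(p, index=observed.index, name="perm_p"),
        n_nulls=pd.Series(n_valid, index=observed.index, name="n_nulls"),
        floored=pd.Series(p == 0, index=observed.index, name="floored"),
    )
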