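"""Pathway-level rank enrichment of gene scan results.

Genes are ranked by their association scores (-log10 p for the omnibus test,
signed -log10 p for a category-pair post hoc test); a Wilcoxon rank-sum test
asks whether a pathway's members sit coherently toward one end of the
ranking.  Fold-enrichment curves visualise the same signal, and permulation
nulls supply rank-clustering-robust empirical p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catstats import GeneTestResult, signed_logp

__all__ = [
    "PathwayDB",
    "PathwayEnrichment",
    "read_gmt",
    "rank_genes",
    "wilcoxon_enrichment",
    "fold_curve",
    "bh_adjust",
    "permulation_enrichment",
    "enrich",
]


@dataclass
class PathwayDB:
    """Pathway id -> gene set, with size bounds applied after intersection."""

    sets: dict[str, set[str]]
    min_size: int = 10
    max_size: int = 500

    def usable(self, scanned_genes: Iterable[str]) -> dict[str, set[str]]:
        """Pathways intersected with the scanned genes and size-filtered."""
        universe = set(scanned_genes)
        out = {}
        for pid, genes in self.sets.items():
            inter = genes & universe
            if self.min_size <= len(inter) <= self.max_size:
                out[pid] = inter
        return out


def read_gmt(source: str, min_size: int = 10, max_size: int = 500) -> PathwayDB:
    """Parse GMT text: ``pathway<TAB>description<TAB>gene1<TAB>gene2...`` per line."""
    sets: dict[str, set[str]] = {}
    for line in source.splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = {g for g in parts[2:] if g}
    return PathwayDB(sets=sets, min_size=min_size, max_size=max_size)


def write_gmt(db: PathwayDB) -> str:
    return "".join(
        f"{pid}\tna\t" + "\t".join(sorted(genes)) + "\n" for pid, genes in db.sets.items()
    )


def rank_genes(
    results: Sequence[GeneTestResult],
    mode: str = "omnibus",
    pair: tuple[str, str] | None = None,
) -> pd.Series:
    """Gene scores sorted for enrichment.

    ``omnibus``: -log10 omnibus p, descending.  ``pair``: signed -log10
    adjusted post hoc p for the given category pair, most positive first.
    Ties break deterministically by gene id.
    """
    if not results:
        raise ValueError("no gene results to rank")
    if mode == "omnibus":
        scores = {r.gene: -np.log10(max(r.pvalue, 1e-300)) for r in results}
    elif mode == "pair":
        if pair is None:
            raise ValueError("pair mode needs a category pair")
        scores = {r.gene: signed_logp(r, pair) for r in results}
    else:
        raise ValueError("mode must be 'omnibus' or 'pair'")
    # mergesort on a pre-sorted-by-id frame gives stable gene-id tie-breaks
    df = (
        pd.DataFrame({"score": pd.Series(scores)})
        .sort_index()
        .sort_values("score", ascending=False, kind="mergesort")
    )
    return df["score"]


def _wilcoxon_on_scores(
    scores: pd.Series, members: set[str], alternative: str, method: str = "auto"
) -> tuple[float, float]:
    in_set = scores.index.isin(members)
    a, b = scores[in_set].to_numpy(), scores[~in_set].to_numpy()
    if a.size == 0 or b.size == 0:
        return np.nan, 1.0
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_enrichment(
    scores: pd.Series,
    pathway_genes: set[str],
    min_size: int = 10,
    alternative: str = "greater",
    method: str = "auto",
) -> tuple[float, float]:
    """Rank-sum test of pathway members' scores against non-members'.

    ``greater`` (omnibus mode) asks whether members are shifted toward high
    scores; ``two-sided`` fits the signed pair-mode scores.  ``method`` is
    passed to the rank-sum backend: exact enumeration for small tie-free
    samples under "auto", or "asymptotic" to force the normal approximation.
    """
    members = pathway_genes & set(scores.index)
    if len(members) < min_size:
        raise ValueError(f"pathway has {len(members)} scanned genes < {min_size}")
    return _wilcoxon_on_scores(scores, members, alternative, method)


def fold_curve(ranked: pd.Series, pathway_genes: set[str]) -> pd.DataFrame:
    """Cumulative observed/expected pathway-gene fraction by rank, plus barcode.

    At rank k the curve is (members in top k / k) / (pathway size / total);
    it equals exactly 1 at k = total.
    """
    order = ranked.index.to_numpy()
    total = order.size
    member = np.isin(order, list(pathway_genes))
    size = int(member.sum())
    if size == 0:
        raise ValueError("pathway has no scanned genes")
    k = np.arange(1, total + 1)
    cum = np.cumsum(member)
    curve = (cum / k) / (size / total)
    return pd.DataFrame({"rank": k, "fold_enrichment": curve, "is_member": member})


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


@dataclass
class PathwayEnrichment:
    pathway: str
    statistic: float
    pvalue: float
    bh_pvalue: float
    size: int
    perm_pvalue: float | None = None
    perm_floored: bool = False


def enrich(
    results: Sequence[GeneTestResult],
    db: PathwayDB,
    mode: str = "omnibus",
    pair: tuple[str, str] | None = None,
) -> list[PathwayEnrichment]:
    """Parametric enrichment of every usable pathway, BH-corrected across pathways."""
    scores = rank_genes(results, mode=mode, pair=pair)
    usable = db.usable(scores.index)
    if not usable:
        raise ValueError("no pathway passes the size bounds after intersection")
    alternative = "greater" if mode == "omnibus" else "two-sided"
    rows = []
    for pid in sorted(usable):
        stat, p = _wilcoxon_on_scores(scores, usable[pid], alternative)
        rows.append((pid, stat, p, len(usable[pid])))
    adj = bh_adjust([r[2] for r in rows])
    return [
        PathwayEnrichment(pathway=pid, statistic=stat, pvalue=p, bh_pvalue=float(a), size=sz)
        for (pid, stat, p, sz), a in zip(rows, adj)
    ]


def _rank_and_tie(vals: np.ndarray) -> tuple[np.ndarray, float]:
    ranks = stats.rankdata(vals)
    _, cnt = np.unique(vals, return_counts=True)
    return ranks, float(np.sum(cnt**3 - cnt))


def _z_from_ranks(ranks: np.ndarray, tie: float, members: np.ndarray) -> float:
    """Tie-corrected z of the members' rank sum (positive = members rank high)."""
    n = ranks.size
    m = int(members.sum())
    r = float(ranks[members].sum())
    mu = m * (n + 1) / 2.0
    tie_term = tie / (n * (n - 1)) if n > 1 else 0.0
    var = m * (n - m) / 12.0 * ((n + 1) - tie_term)
    return (r - mu) / np.sqrt(var) if var > 0 else 0.0


def _standardised_rank_sum(scores: pd.Series, members: np.ndarray) -> float:
    ranks, tie = _rank_and_tie(scores.to_numpy(dtype=float))
    return _z_from_ranks(ranks, tie, members)


def permulation_enrichment(
    observed_scores: pd.Series,
    null_scores: np.ndarray | Sequence[pd.Series],
    db: PathwayDB,
    mode: str = "omnibus",
) -> dict[str, tuple[float, bool]]:
    """Empirical pathway p-values from permulated gene scores.

    Every permulation's gene scores go through the same standardised
    rank-sum statistic as the observed scores; the empirical p matches the
    parametric sidedness (one-sided toward high scores for omnibus mode,
    two-sided for pair mode).  ``null_scores`` rows must align with
    ``observed_scores``'s gene index.  Returns pathway -> (p, floored).
    """
    if isinstance(null_scores, np.ndarray):
        nulls = null_scores
    else:
        nulls = np.vstack([s.reindex(observed_scores.index).to_numpy() for s in null_scores])
    if nulls.ndim != 2 or nulls.shape[1] != observed_scores.size:
        raise ValueError("null scores must be (n_draws, n_genes) aligned to observed")
    usable = db.usable(observed_scores.index)
    if not usable:
        raise ValueError("no pathway passes the size bounds after intersection")
    gene_index = observed_scores.index
    finite = np.all(np.isfinite(nulls), axis=1)
    if not finite.any():
        raise ValueError("no permulation produced a complete gene-score vector")
    # rank each permulation's score vector once; pathways reuse the ranks
    null_ranks = [_rank_and_tie(row) for row in nulls[finite]]
    obs_ranks, obs_tie = _rank_and_tie(observed_scores.to_numpy(dtype=float))
    out: dict[str, tuple[float, bool]] = {}
    for pid, genes in sorted(usable.items()):
        member = gene_index.isin(genes)
        obs_z = _z_from_ranks(obs_ranks, obs_tie, member)
        null_z = np.array([_z_from_ranks(r, t, member) for r, t in null_ranks])
        if mode == "omnibus":
            p = float(np.mean(null_z >= obs_z))
        else:
            p = float(np.mean(np.abs(null_z) >= abs(obs_z)))
        out[pid] = (p, p == 0.0)
    return out


def attach_permulation_pvalues(
    observed: list[PathwayEnrichment], perm_p: dict[str, tuple[float, bool]]
) -> list[PathwayEnrichment]:
    for e in observed:
        if e.pathway in perm_p:
            e.perm_pvalue, e.perm_floored = perm_p[e.pathway]
    return observed


def plot_fold_curve(curve: pd.DataFrame, ax=None, title: str | None = None):
    """Fold-enrichment curve with the member barcode underneath."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    ax.plot(curve["rank"], curve["fold_enrichment"], lw=1.5)
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    member_ranks = curve.loc[curve["is_member"], "rank"]
    ymin = min(0.0, float(curve["fold_enrichment"].min()))
    ax.vlines(member_ranks, ymin - 0.4, ymin - 0.1, color="black", lw=0.5)
    ax.set_xlabel("gene rank")
    ax.set_ylabel("fold enrichment")
    if title:
        ax.set_title(title)
    return ax


def enrichment_frame(entries: list[PathwayEnrichment]) -> pd.DataFrame:
    rows = [
        {
            "pathway": e.pathway, "size": e.size, "statistic": e.statistic,
            "p": e.pvalue, "bh_p": e.bh_pvalue, "perm_p": e.perm_pvalue,
            "perm_floored": e.perm_floored,
        }
        for e in entries
    ]
    return pd.DataFrame(rows).set_index("pathway")
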