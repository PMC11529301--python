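"""Per-gene association of RERs with branch categories.

Omnibus tests (Kruskal-Wallis with the epsilon-squared effect size H/(n-1),
or one-way ANOVA with eta squared) compare RER distributions across all
categories at once; post hoc tests (Dunn Z with multiplicity adjustment, or
Tukey HSD) identify the category pairs driving an omnibus signal.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneTestResult",
    "kruskal_omnibus",
    "dunn_posthoc",
    "anova_omnibus",
    "tukey_posthoc",
    "gene_scan",
    "signed_logp",
]


@dataclass
class PosthocEntry:
    pair: tuple[str, str]
    statistic: float      # Dunn Z or Tukey mean difference; >0 = first category higher
    pvalue: float         # multiplicity-adjusted


@dataclass
class GeneTestResult:
    gene: str
    method: str                         # "KW" or "ANOVA"
    statistic: float                    # H or F
    effect_size: float                  # epsilon^2 or eta^2
    pvalue: float
    n: int
    category_counts: dict[str, int]
    posthoc: list[PosthocEntry] = field(default_factory=list)

    def posthoc_for(self, pair: tuple[str, str]) -> PosthocEntry:
        for entry in self.posthoc:
            if entry.pair == pair:
                return entry
            if entry.pair == (pair[1], pair[0]):
                return PosthocEntry(pair, -entry.statistic, entry.pvalue)
        raise KeyError(f"pair {pair} not tested for gene {self.gene}")


def _check_groups(groups) -> list[np.ndarray]:
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    if any(a.size == 0 for a in arrs):
        raise ValueError("empty group")
    return arrs


def kruskal_omnibus(groups) -> tuple[float, float, float]:
    """Tie-corrected Kruskal-Wallis H, chi-square p, and epsilon^2 = H/(n-1)."""
    arrs = _check_groups(groups)
    n = sum(a.size for a in arrs)
    if n < len(arrs) + 1:
        raise ValueError("too few observations for an omnibus test")
    if all(np.array_equal(a, arrs[0]) for a in arrs[1:]) or len(
        np.unique(np.concatenate(arrs))
    ) == 1:
        # degenerate: scipy raises when all values are identical
        return 0.0, 1.0, 0.0
    h, p = stats.kruskal(*arrs)
    return float(h), float(p), float(h / (n - 1))


def _rank_all(arrs: list[np.ndarray]) -> tuple[np.ndarray, list[np.ndarray], float]:
    pooled = np.concatenate(arrs)
    ranks = stats.rankdata(pooled)
    split = np.split(ranks, np.cumsum([a.size for a in arrs])[:-1])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    return ranks, split, tie_term


def dunn_posthoc(
    groups,
    labels: list[str] | None = None,
    adjust: str = "fdr_bh",
) -> list[PosthocEntry]:
    """Dunn's pairwise Z tests on mean ranks with tie-corrected variance.

    Z > 0 when the first category of the pair (registry order) has the larger
    mean rank; two-sided p-values are adjusted across the K(K-1)/2 pairs
    within the gene (Benjamini-Hochberg by default, ``holm`` available).
    """
    arrs = _check_groups(groups)
    k = len(arrs)
    if labels is None:
        labels = [f"g{i}" for i in range(k)]
    n = sum(a.size for a in arrs)
    _, split, tie_term = _rank_all(arrs)
    mean_ranks = [float(r.mean()) for r in split]
    var_base = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    pairs = list(itertools.combinations(range(k), 2))
    zs, ps = [], []
    for i, j in pairs:
        se = math.sqrt(var_base * (1.0 / arrs[i].size + 1.0 / arrs[j].size))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        zs.append(z)
        ps.append(2.0 * stats.norm.sf(abs(z)))
    adj = multipletests(ps, method=adjust)[1] if ps else []
    return [
        PosthocEntry((labels[i], labels[j]), float(z), float(p))
        for (i, j), z, p in zip(pairs, zs, adj)
    ]


def anova_omnibus(groups) -> tuple[float, float, float]:
    """One-way ANOVA F, p, and eta^2 = SS_between / (SS_between + SS_within)."""
    arrs = _check_groups(groups)
    n = sum(a.size for a in arrs)
    if n < len(arrs) + 1:
        raise ValueError("too few observations for an omnibus test")
    grand = np.concatenate(arrs).mean()
    ss_b = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ss_w = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrs)
    if ss_b + ss_w == 0:
        return 0.0, 1.0, 0.0
    eta2 = ss_b / (ss_b + ss_w)
    if ss_w == 0:
        return float("inf"), 0.0, 1.0
    f, p = stats.f_oneway(*arrs)
    return float(f), float(p), float(eta2)


def tukey_posthoc(groups, labels: list[str] | None = None) -> list[PosthocEntry]:
    """Tukey HSD pairwise mean differences with family-wise adjusted p-values.

    The statistic is mean(first) - mean(second) in registry pair order.
    """
    arrs = _check_groups(groups)
    k = len(arrs)
    if labels is None:
        labels = [f"g{i}" for i in range(k)]
    if all(np.all(a == arrs[0][0]) for a in arrs):
        return [
            PosthocEntry((labels[i], labels[j]), 0.0, 1.0)
            for i, j in itertools.combinations(range(k), 2)
        ]
    res = stats.tukey_hsd(*arrs)
    out = []
    for i, j in itertools.combinations(range(k), 2):
        out.append(
            PosthocEntry(
                (labels[i], labels[j]),
                float(res.statistic[i, j]),
                float(res.pvalue[i, j]),
            )
        )
    return out


def signed_logp(result: GeneTestResult, pair: tuple[str, str], floor: float = 1e-300) -> float:
    """Signed -log10 adjusted p for a category pair: sign follows the pair statistic."""
    entry = result.posthoc_for(pair)
    p = max(entry.pvalue, floor)
    return float(-np.log10(p) * np.sign(entry.statistic))


def gene_scan(
    rers: pd.DataFrame,
    branch_labels: pd.Series,
    categories: list[str],
    method: str = "kw",
    min_per_category: int = 2,
    posthoc: bool = True,
    dunn_adjust: str = "fdr_bh",
) -> tuple[list[GeneTestResult], dict[str, str]]:
    """Associate every gene's RERs with branch categories.

    ``branch_labels`` maps branch id (RER row index) to a category label;
    both terminal and internal branches participate.  Genes missing RERs on
    some branches use the remaining ones; genes with fewer than
    ``min_per_category`` usable branches in any category are skipped.
    Returns (results, skipped gene -> reason).
    """
    if method not in {"kw", "anova"}:
        raise ValueError("method must be 'kw' or 'anova'")
    labels = branch_labels.reindex(rers.index)
    if labels.isna().any():
        raise ValueError("branch labels must cover every RER branch")
    results: list[GeneTestResult] = []
    skipped: dict[str, str] = {}
    for gene in rers.columns:
        col = rers[gene]
        ok = col.notna()
        groups, counts = [], {}
        too_small = None
        for cat in categories:
            vals = col[ok & (labels == cat)].to_numpy()
            counts[cat] = int(vals.size)
            if vals.size < min_per_category:
                too_small = cat
            groups.append(vals)
        if too_small is not None:
            skipped[gene] = f"category {too_small!r} has < {min_per_category} branches"
            continue
        n = int(sum(counts.values()))
        if method == "kw":
            stat, p, eff = kruskal_omnibus(groups)
            ph = dunn_posthoc(groups, categories, adjust=dunn_adjust) if posthoc else []
            name = "KW"
        else:
            stat, p, eff = anova_omnibus(groups)
            ph = tukey_posthoc(groups, categories) if posthoc else []
            name = "ANOVA"
        results.append(
            GeneTestResult(
                gene=gene, method=name, statistic=stat, effect_size=eff,
                pvalue=p, n=n, category_counts=counts, posthoc=ph,
            )
        )
    if not results:
        raise ValueError(f"all genes skipped: {skipped}")
    return results, skipped


def results_frame(results: list[GeneTestResult]) -> pd.DataFrame:
    """Flatten scan results to a table: one row per gene, pair columns appended."""
    rows = []
    for r in results:
        row = {
            "gene": r.gene, "method": r.method, "N": r.n,
            "statistic": r.statistic, "effect_size": r.effect_size, "p": r.pvalue,
        }
        for entry in r.posthoc:
            tag = f"{entry.pair[0]}_vs_{entry.pair[1]}"
            row[f"stat[{tag}]"] = entry.statistic
            row[f"p[{tag}]"] = entry.pvalue
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")
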