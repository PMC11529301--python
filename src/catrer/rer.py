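"""Relative evolutionary rates: per-branch, per-gene deviations from the genome-wide trend.

A gene's branch lengths are regressed (after scale normalisation and an
optional square-root transform) on the genome-wide expected lengths; the
residuals are the gene's relative evolutionary rates (RERs).  Positive RER =
the gene evolved faster than expected on that branch, negative = slower.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylo import BranchIndex, GeneTreeSet, Phylogeny, map_gene_branches

__all__ = ["RERConfig", "build_branch_matrix", "expected_lengths", "compute_rers"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RERConfig:
    """Parameters of the RER computation.

    sqrt_transform
        Square-root both gene lengths and expectations before regressing;
        stabilises the variance of length-like quantities.
    weighted
        Weight the regression by inverse per-branch residual variance
        estimated from the cross-gene residual spread.
    winsorize
        Clip each gene's ``winsorize`` most extreme values per tail (applied
        to the transformed lengths and expectations) before regressing.
    min_species
        Genes whose trees have fewer tips are dropped.
    """

    sqrt_transform: bool = True
    weighted: bool = True
    winsorize: int = 3
    min_species: int = 10

    def __post_init__(self) -> None:
        if self.winsorize < 0:
            raise ValueError("winsorize count must be >= 0")
        if self.min_species < 3:
            raise ValueError("min_species must be >= 3")


def build_branch_matrix(
    genes: GeneTreeSet,
    master: Phylogeny,
    idx: BranchIndex,
    min_species: int = 10,
) -> pd.DataFrame:
    """Branch-length matrix: rows = master branches (index order), columns = genes.

    Entries are ``nan`` where a gene lacks the branch.  Genes with fewer than
    ``min_species`` tips are dropped (logged).
    """
    if len(genes) == 0:
        raise ValueError("empty gene tree set")
    cols: dict[str, np.ndarray] = {}
    for gene_id, tree in genes:
        if len(tree.tips) < min_species:
            log.info("dropping gene %s: %d species < %d", gene_id, len(tree.tips), min_species)
            continue
        cols[gene_id] = map_gene_branches(tree, master, idx)
    if not cols:
        raise ValueError(f"no gene has >= {min_species} species")
    return pd.DataFrame(cols, index=idx.branch_ids())


def expected_lengths(matrix: pd.DataFrame, max_iter: int = 20, tol: float = 1e-6) -> pd.Series:
    """Per-branch genome-wide expected length.

    Each gene column is scale-normalised by its least-squares projection onto
    the current expectation, the expectation is re-estimated as the
    per-branch mean of the normalised columns, and the two steps are iterated
    to a fixed point (max relative change < ``tol``, at most ``max_iter``
    rounds).  Branches present in no gene have missing expectation.
    """
    x = matrix.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("expectation needs at least 2 genes")
    mask = np.isfinite(x)
    with np.errstate(invalid="ignore"):
        e = np.nanmean(x, axis=1)
    for _ in range(max_iter):
        scales = _projection_scales(x, e, mask)
        norm = x / scales[None, :]
        new_e = np.nanmean(norm, axis=1)
        denom = np.where(np.abs(e) > 0, np.abs(e), 1.0)
        delta = np.nanmax(np.abs(new_e - e) / denom)
        e = new_e
        if delta < tol:
            break
    return pd.Series(e, index=matrix.index, name="expected_length")


def _projection_scales(x: np.ndarray, e: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-gene least-squares scale of each column onto the expectation."""
    e2 = np.where(mask, e[:, None] ** 2, 0.0)
    xe = np.where(mask, x * e[:, None], 0.0)
    denom = e2.sum(axis=0)
    scales = np.where(denom > 0, xe.sum(axis=0) / denom, 1.0)
    return np.where(scales > 0, scales, 1.0)


def _winsorize_tails(v: np.ndarray, count: int) -> np.ndarray:
    """Clip the ``count`` most extreme values per tail to the next inner value."""
    if count <= 0 or v.size <= 2 * count + 1:
        return v
    srt = np.sort(v)
    lo, hi = srt[count], srt[-count - 1]
    return np.clip(v, lo, hi)


def compute_rers(
    matrix: pd.DataFrame,
    expectation: pd.Series,
    cfg: RERConfig = RERConfig(),
) -> pd.DataFrame:
    """Relative evolutionary rates for every gene.

    Per gene: scale-normalise the column (so RERs are invariant to overall
    gene rate), optionally square-root transform lengths and expectations,
    winsorize both tails, and take residuals from a (optionally
    variance-weighted) linear regression of gene lengths on the expectation.
    Missing branch lengths stay missing.
    """
    x = matrix.to_numpy(dtype=float)
    e = expectation.to_numpy(dtype=float)
    mask = np.isfinite(x) & np.isfinite(e)[:, None]
    scales = _projection_scales(np.where(mask, x, np.nan), e, mask)
    xn = x / scales[None, :]

    def transformed(col: np.ndarray, m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        xv, ev = col[m], e[m]
        if cfg.sqrt_transform:
            xv, ev = np.sqrt(np.maximum(xv, 0.0)), np.sqrt(np.maximum(ev, 0.0))
        xv = _winsorize_tails(xv, cfg.winsorize)
        ev = _winsorize_tails(ev, cfg.winsorize)
        return xv, ev

    n_branches, n_genes = x.shape
    resid = np.full_like(x, np.nan)

    # pass 1: unweighted residuals, used to estimate per-branch variances
    for j in range(n_genes):
        m = mask[:, j]
        if m.sum() < 3:
            continue
        xv, ev = transformed(xn[:, j], m)
        resid[m, j] = _ols_residuals(xv, ev)

    if not cfg.weighted:
        return pd.DataFrame(resid, index=matrix.index, columns=matrix.columns)

    with np.errstate(invalid="ignore"):
        var = np.nanvar(resid, axis=1)
    ok = np.isfinite(var) & (var > 0)
    if ok.sum() >= 2:
        floor = np.percentile(var[ok], 5)
        var = np.where(ok, np.maximum(var, floor), np.nan)
        default = np.nanmedian(var)
        var = np.where(np.isfinite(var), var, default)
        weights = 1.0 / var
        weights = weights / weights.mean()  # unit mean: equal variances leave residuals untouched
    else:
        weights = np.ones(n_branches)

    # residuals are standardised by the estimated per-branch sd so RERs are
    # comparable across branches (rank tests need homoskedastic values)
    out = np.full_like(x, np.nan)
    for j in range(n_genes):
        m = mask[:, j]
        if m.sum() < 3:
            continue
        xv, ev = transformed(xn[:, j], m)
        out[m, j] = _wls_residuals(xv, ev, weights[m]) * np.sqrt(weights[m])
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _ols_residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    a = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(a, y, rcond=None)
    return y - a @ beta


def _wls_residuals(y: np.ndarray, x: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    a = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(a * sw[:, None], y * sw, rcond=None)
    return y - a @ beta
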