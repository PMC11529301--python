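"""Model/results interface tying the pipeline together.

``CategoricalRERScan`` is built from the three data objects (master tree,
gene trees, phenotypes); ``fit()`` computes RERs, fits and selects the CTMM,
reconstructs ancestral states, and scans every gene, returning a
``RERScanResults`` carrying the estimates and a ``summary()`` table.
Permulation p-values and pathway enrichment hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import asr, catstats, enrichment, permulations, rer
from .categories import PhenotypeVector, read_phenotypes
from .phylo import BranchIndex, GeneTreeSet, Phylogeny, read_gene_trees, read_newick

__all__ = ["CategoricalRERScan", "RERScanResults"]


class CategoricalRERScan:
    """Associate per-gene relative evolutionary rates with a categorical trait.

    Parameters
    ----------
    master
        Species tree whose branch lengths are average genome-wide rates.
    gene_trees
        Per-gene trees on the master topology (validated on construction).
    phenotype
        Species -> category assignments covering every master tip.
    rate_model
        "ER", "SYM", "ARD", or "auto" (likelihood-ratio ladder ER->SYM->ARD).
    """

    def __init__(
        self,
        master: Phylogeny,
        gene_trees: GeneTreeSet,
        phenotype: PhenotypeVector,
        rate_model: str = "auto",
        rer_config: rer.RERConfig = rer.RERConfig(),
        root_prior="flat",
        seed: int = 0,
    ):
        missing = master.tip_labels - set(phenotype.assignments)
        if missing:
            raise ValueError(f"master tips missing from phenotype table: {sorted(missing)}")
        self.master = master
        self.gene_trees = gene_trees
        self.phenotype = phenotype.restrict(master.tip_labels)
        if self.phenotype.k < 2:
            raise ValueError("analysis needs at least two categories among master tips")
        self.rate_model = rate_model
        self.rer_config = rer_config
        self.root_prior = root_prior
        self.seed = seed
        self.branch_index = BranchIndex.from_tree(master)

    @classmethod
    def from_files(
        cls, master_path, genes_path, pheno_path, **kwargs
    ) -> "CategoricalRERScan":
        master = read_newick(Path(master_path).read_text())
        genes = read_gene_trees(Path(genes_path).read_text(), master)
        pheno = read_phenotypes(Path(pheno_path).read_text())
        return cls(master, genes, pheno, **kwargs)

    def fit(
        self,
        method: str = "kw",
        min_per_category: int = 2,
        dunn_adjust: str = "fdr_bh",
    ) -> "RERScanResults":
        idx = self.branch_index
        lengths = rer.build_branch_matrix(
            self.gene_trees, self.master, idx, min_species=self.rer_config.min_species
        )
        expectation = rer.expected_lengths(lengths)
        rers = rer.compute_rers(lengths, expectation, self.rer_config)

        if self.rate_model == "auto":
            selection = asr.fit_rate_models(
                self.master, self.phenotype, root_prior=self.root_prior, seed=self.seed
            )
            q = selection.best
        else:
            selection = None
            q = asr.fit_ctmm(
                self.master, self.phenotype, self.rate_model,
                root_prior=self.root_prior, seed=self.seed,
            )
        recon = asr.marginal_reconstruction(self.master, self.phenotype, q)

        labels = recon.branch_labels()
        cats = self.phenotype.categories
        branch_cats = pd.Series(
            {bid: cats[labels[idx.node_of[clade]]]
             for bid, clade in zip(idx.branch_ids(), idx.clade_order)},
            name="category",
        )
        results, skipped = catstats.gene_scan(
            rers, branch_cats, cats, method=method,
            min_per_category=min_per_category, dunn_adjust=dunn_adjust,
        )
        return RERScanResults(
            model=self, rers=rers, expectation=expectation, q=q,
            selection=selection, reconstruction=recon, branch_categories=branch_cats,
            gene_results=results, skipped=skipped, method=method,
            min_per_category=min_per_category,
        )


@dataclass
class RERScanResults:
    """Fitted estimates: RER matrix, CTMM, reconstruction, and gene tests."""

    model: CategoricalRERScan
    rers: pd.DataFrame
    expectation: pd.Series
    q: asr.TransitionRateMatrix
    selection: asr.ModelSelection | None
    reconstruction: asr.AncestralReconstruction
    branch_categories: pd.Series
    gene_results: list[catstats.GeneTestResult]
    skipped: dict[str, str]
    method: str
    min_per_category: int
    permulation_set: permulations.PermulationSet | None = None
    null_effect_sizes: np.ndarray | None = None
    perm_pvalues: permulations.EmpiricalPValues | None = None

    @property
    def gene_table(self) -> pd.DataFrame:
        table = catstats.results_frame(self.gene_results)
        if self.perm_pvalues is not None:
            table = table.join(self.perm_pvalues.pvalues)
        return table

    def transition_counts(self) -> dict[tuple[str, str], int]:
        cats = self.model.phenotype.categories
        raw = asr.count_transitions(self.model.master, self.reconstruction)
        out: dict[tuple[str, str], int] = {}
        for key, v in raw.items():
            a, b = sorted(key)
            out[(cats[a], cats[b])] = v
        return out

    # -- permulations --------------------------------------------------------

    def permulate(
        self,
        n: int = 100,
        relax: float = 0.0,
        seed: int | None = None,
        max_attempts: int | None = None,
    ) -> "RERScanResults":
        """Attach permulation empirical p-values to every scanned gene.

        Null labelings are drawn on the master tree from the fitted CTMM with
        the observed category counts conserved (within ``relax``); each gene's
        observed effect size is compared one-sided against its null effect
        sizes.
        """
        cfg = permulations.PermulationConfig(
            n=n, relax=relax, max_attempts=max_attempts,
            seed=self.model.seed if seed is None else seed,
        )
        counts = self.model.phenotype.counts()
        observed_counts = np.array([counts[c] for c in self.model.phenotype.categories])
        self.permulation_set = permulations.permulate(
            self.model.master, self.q, self.reconstruction, observed_counts, cfg
        )
        eff, _ = permulations.null_gene_stats(
            self.rers, self.permulation_set, self.model.branch_index,
            min_per_category=self.min_per_category,
        )
        scanned = [r.gene for r in self.gene_results]
        cols = [self.rers.columns.get_loc(g) for g in scanned]
        self.null_effect_sizes = eff[:, cols]
        observed = pd.Series(
            [r.effect_size for r in self.gene_results], index=scanned, name="effect_size"
        )
        self.perm_pvalues = permulations.empirical_pvalues(
            observed, self.null_effect_sizes, sidedness="greater"
        )
        return self

    # -- enrichment ------------------------------------------------------------

    def null_gene_scores(self) -> pd.DataFrame:
        """Permulated -log10 omnibus p per gene (rows = draws), for enrichment."""
        if self.null_effect_sizes is None:
            raise ValueError("run .permulate() first")
        scanned = [r.gene for r in self.gene_results]
        k = self.model.phenotype.k
        ns = np.array([r.n for r in self.gene_results], dtype=float)
        h = self.null_effect_sizes * (ns - 1)[None, :]
        p = sstats.chi2.sf(h, k - 1)
        scores = -np.log10(np.maximum(p, 1e-300))
        return pd.DataFrame(scores, columns=scanned)

    def enrich(
        self,
        db: enrichment.PathwayDB,
        mode: str = "omnibus",
        pair: tuple[str, str] | None = None,
        permuted: bool = False,
    ) -> pd.DataFrame:
        """Pathway enrichment table; adds permulation p-values when available."""
        entries = enrichment.enrich(self.gene_results, db, mode=mode, pair=pair)
        if permuted:
            if mode != "omnibus":
                raise ValueError("permulated enrichment is implemented for omnibus mode")
            scores = enrichment.rank_genes(self.gene_results, mode="omnibus")
            nulls = self.null_gene_scores().reindex(columns=scores.index).to_numpy()
            perm = enrichment.permulation_enrichment(scores, nulls, db, mode="omnibus")
            enrichment.attach_permulation_pvalues(entries, perm)
        return enrichment.enrichment_frame(entries)

    # -- reporting ---------------------------------------------------------------

    def summary(self, top: int = 10) -> str:
        ph = self.model.phenotype
        lines = [
            "Categorical RER scan",
            "====================",
            f"species: {len(ph.species)}   categories: {ph.k} {ph.categories}",
            f"genes scanned: {len(self.gene_results)}   skipped: {len(self.skipped)}",
            f"branches: {len(self.model.branch_index)}",
            "",
            f"CTMM rate model: {self.q.model.name}"
            + (f" (selected by LRT from {list(self.selection.fits)})" if self.selection else ""),
            f"log-likelihood: {self.q.loglik:.4f}",
            "Q (generator):",
        ]
        with np.printoptions(precision=4, suppress=True):
            lines.append(str(self.q.q))
        trans = self.transition_counts()
        if trans:
            lines.append("inferred transitions: " + ", ".join(
                f"{a}-{b}: {v}" for (a, b), v in sorted(trans.items())
            ))
        table = self.gene_table.sort_values("p")
        n_sig = int((table["p"] < 0.05).sum())
        lines += [
            "",
            f"omnibus method: {self.method.upper()}   genes with p < 0.05: {n_sig}",
        ]
        if self.perm_pvalues is not None:
            n_perm_sig = int((self.perm_pvalues.pvalues < 0.05).sum())
            lines.append(
                f"permulations: N={self.permulation_set.n} "
                f"(relax={self.permulation_set.config.relax}); perm p < 0.05: {n_perm_sig}"
            )
        lines += ["", f"top {min(top, len(table))} genes:",
                  table.head(top).to_string(float_format=lambda v: f"{v:.4g}")]
        return "\n".join(lines)
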