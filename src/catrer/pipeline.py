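"""Stage-wise pipeline orchestration with a manifest and up-to-date skipping.

Stages run in dependency order (rer -> asr -> scan -> permulate -> enrich ->
sites); each stage's outputs carry a hash of its parameters and input files,
so re-running an unchanged configuration skips completed work and changing,
say, the permulation seed regenerates only the permulation-dependent stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, asr, catstats, enrichment, permulations, rer, site_screen
from .categories import PhenotypeVector, read_phenotypes
from .model import CategoricalRERScan
from .phylo import BranchIndex, read_gene_trees, read_newick

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Declarative description of a full run (paths + per-stage parameters)."""

    master: str
    genes: str
    phenotypes: str
    out_dir: str
    pathways: str | None = None
    alignment: str | None = None
    seed: int = 0
    model_seed: int = 0
    rate_model: str = "auto"
    method: str = "kw"
    min_per_category: int = 2
    rer_params: dict = field(default_factory=dict)
    permulation_params: dict = field(default_factory=lambda: {"n": 100, "relax": 0.0})
    enrichment_params: dict = field(default_factory=lambda: {"min_size": 10, "max_size": 500})
    site_params: dict = field(default_factory=lambda: {"threshold": 0.2, "reference": None})
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def validate(self) -> None:
        for label, p in [("master", self.master), ("genes", self.genes),
                         ("phenotypes", self.phenotypes), ("pathways", self.pathways),
                         ("alignment", self.alignment)]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label} file not found: {p}")


def _file_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _stage_hash(params: dict, inputs: list[str | Path]) -> str:
    payload = {
        "params": params,
        "inputs": [_file_hash(p) for p in inputs],
        "version": __version__,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def _up_to_date(manifest: dict, stage: str, h: str, outputs: list[Path]) -> bool:
    rec = manifest.get("stages", {}).get(stage)
    return (
        rec is not None
        and rec.get("hash") == h
        and all(Path(o).exists() for o in outputs)
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all applicable stages; returns (and writes) the run manifest."""
    cfg.validate()
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    )
    manifest.setdefault("stages", {})
    manifest["version"] = __version__
    manifest["config"] = cfg.__dict__.copy()

    master = read_newick(Path(cfg.master).read_text())
    idx = BranchIndex.from_tree(master)
    pheno = read_phenotypes(Path(cfg.phenotypes).read_text()).restrict(master.tip_labels)
    cats = pheno.categories
    rer_cfg = rer.RERConfig(**cfg.rer_params)

    def finish(stage: str, h: str, outputs: list[Path], started: float) -> None:
        manifest["stages"][stage] = {
            "hash": h,
            "outputs": {str(o): _file_hash(o) for o in outputs},
            "seconds": round(time.time() - started, 3),
        }
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
        log.info("stage %s: done (%.1fs)", stage, time.time() - started)

    # -- stage: rer ---------------------------------------------------------
    rers_path = out / "rers.tsv"
    h = _stage_hash({"rer": cfg.rer_params}, [cfg.master, cfg.genes])
    if not _up_to_date(manifest, "rer", h, [rers_path]):
        t0 = time.time()
        genes = read_gene_trees(Path(cfg.genes).read_text(), master)
        lengths = rer.build_branch_matrix(genes, master, idx, min_species=rer_cfg.min_species)
        expectation = rer.expected_lengths(lengths)
        rers_df = rer.compute_rers(lengths, expectation, rer_cfg)
        rers_df.to_csv(rers_path, sep="\t", na_rep="NA")
        finish("rer", h, [rers_path], t0)
    else:
        log.info("stage rer: up to date, skipped")

    # -- stage: asr ---------------------------------------------------------
    asr_path = out / "asr.json"
    h = _stage_hash(
        {"rate_model": cfg.rate_model, "model_seed": cfg.model_seed},
        [cfg.master, cfg.phenotypes],
    )
    if not _up_to_date(manifest, "asr", h, [asr_path]):
        t0 = time.time()
        if cfg.rate_model == "auto":
            selection = asr.fit_rate_models(master, pheno, seed=cfg.model_seed)
            q = selection.best
            lrt = [c.__dict__ for c in selection.comparisons]
        else:
            q = asr.fit_ctmm(master, pheno, cfg.rate_model, seed=cfg.model_seed)
            lrt = []
        recon = asr.marginal_reconstruction(master, pheno, q)
        payload = {
            "categories": cats,
            "model": q.model.name,
            "loglik": q.loglik,
            "q": q.q.tolist(),
            "root_prior": q.root_prior.tolist(),
            "model_seed": cfg.model_seed,
            "lrt": lrt,
            "ml_states": recon.ml_states.tolist(),
            "probabilities": recon.probabilities.tolist(),
            "branch_labels": {
                bid: cats[recon.ml_states[idx.node_of[clade]]]
                for bid, clade in zip(idx.branch_ids(), idx.clade_order)
            },
        }
        asr_path.write_text(json.dumps(payload, indent=1))
        finish("asr", h, [asr_path], t0)
    else:
        log.info("stage asr: up to date, skipped")

    # -- stage: scan --------------------------------------------------------
    scan_path = out / "genes.tsv"
    h = _stage_hash(
        {"method": cfg.method, "min_per_category": cfg.min_per_category},
        [rers_path, asr_path],
    )
    if not _up_to_date(manifest, "scan", h, [scan_path]):
        t0 = time.time()
        rers_df = pd.read_csv(rers_path, sep="\t", index_col=0, na_values="NA")
        asr_data = json.loads(asr_path.read_text())
        branch_cats = pd.Series(asr_data["branch_labels"])
        results, skipped = catstats.gene_scan(
            rers_df, branch_cats, asr_data["categories"],
            method=cfg.method, min_per_category=cfg.min_per_category,
        )
        catstats.results_frame(results).to_csv(scan_path, sep="\t")
        (out / "genes_skipped.tsv").write_text(
            "".join(f"{g}\t{r}\n" for g, r in skipped.items())
        )
        finish("scan", h, [scan_path], t0)
    else:
        log.info("stage scan: up to date, skipped")

    # -- stage: permulate ---------------------------------------------------
    perm_cfg = dict(cfg.permulation_params)
    n_perm = int(perm_cfg.get("n", 0))
    null_path = out / "null_effect_sizes.tsv"
    permp_path = out / "perm_pvalues.tsv"
    if n_perm > 0:
        h = _stage_hash(
            {"perm": perm_cfg, "seed": cfg.seed,
             "min_per_category": cfg.min_per_category},
            [rers_path, asr_path, scan_path],
        )
        if not _up_to_date(manifest, "permulate", h, [null_path, permp_path]):
            t0 = time.time()
            rers_df = pd.read_csv(rers_path, sep="\t", index_col=0, na_values="NA")
            asr_data = json.loads(asr_path.read_text())
            q = asr.TransitionRateMatrix(
                q=np.array(asr_data["q"]), params=np.array([]),
                loglik=asr_data["loglik"],
                model=asr.make_rate_model(len(cats), asr_data["model"] if asr_data["model"] in ("ER", "SYM", "ARD") else "ARD"),
                root_prior=np.array(asr_data["root_prior"]),
            )
            recon = asr.AncestralReconstruction(
                tree=master, categories=cats,
                probabilities=np.array(asr_data["probabilities"]),
                ml_states=np.array(asr_data["ml_states"]),
                root_prior=np.array(asr_data["root_prior"]),
            )
            counts = pheno.counts()
            observed_counts = np.array([counts[c] for c in cats])
            pcfg = permulations.PermulationConfig(
                n=n_perm, relax=float(perm_cfg.get("relax", 0.0)),
                max_attempts=perm_cfg.get("max_attempts"), seed=cfg.seed,
            )
            perms = permulations.permulate(master, q, recon, observed_counts, pcfg)
            eff, _ = permulations.null_gene_stats(
                rers_df, perms, idx, min_per_category=cfg.min_per_category
            )
            scan_df = pd.read_csv(scan_path, sep="\t", index_col=0)
            cols = [rers_df.columns.get_loc(g) for g in scan_df.index]
            nulls = eff[:, cols]
            pd.DataFrame(nulls, columns=scan_df.index).to_csv(null_path, sep="\t", index=False)
            emp = permulations.empirical_pvalues(scan_df["effect_size"], nulls, "greater")
            pd.DataFrame(
                {"perm_p": emp.pvalues, "n_nulls": emp.n_nulls, "floored": emp.floored}
            ).to_csv(permp_path, sep="\t")
            finish("permulate", h, [null_path, permp_path], t0)
        else:
            log.info("stage permulate: up to date, skipped")

    # -- stage: enrich ------------------------------------------------------
    if cfg.pathways is not None:
        enrich_path = out / "pathways.tsv"
        inputs = [scan_path, cfg.pathways] + ([null_path] if n_perm > 0 and null_path.exists() else [])
        h = _stage_hash({"enrich": cfg.enrichment_params}, inputs)
        if not _up_to_date(manifest, "enrich", h, [enrich_path]):
            t0 = time.time()
            scan_df = pd.read_csv(scan_path, sep="\t", index_col=0)
            db = enrichment.read_gmt(Path(cfg.pathways).read_text(), **cfg.enrichment_params)
            scores = (-np.log10(scan_df["p"].clip(lower=1e-300))).sort_values(ascending=False)
            usable = db.usable(scores.index)
            rows = []
            for pid in sorted(usable):
                stat, p = enrichment.wilcoxon_enrichment(
                    scores, usable[pid], min_size=db.min_size
                )
                rows.append({"pathway": pid, "size": len(usable[pid]), "statistic": stat, "p": p})
            tab = pd.DataFrame(rows).set_index("pathway")
            tab["bh_p"] = enrichment.bh_adjust(tab["p"])
            if n_perm > 0 and null_path.exists():
                k = len(cats)
                nulls = pd.read_csv(null_path, sep="\t")
                ns = scan_df["N"].reindex(nulls.columns)
                from scipy import stats as sstats

                hh = nulls.to_numpy() * (ns.to_numpy() - 1)[None, :]
                null_scores = -np.log10(np.maximum(sstats.chi2.sf(hh, k - 1), 1e-300))
                perm = enrichment.permulation_enrichment(
                    scores,
                    pd.DataFrame(null_scores, columns=nulls.columns)
                    .reindex(columns=scores.index).to_numpy(),
                    db, mode="omnibus",
                )
                tab["perm_p"] = [perm.get(pid, (np.nan, False))[0] for pid in tab.index]
            tab.to_csv(enrich_path, sep="\t")
            finish("enrich", h, [enrich_path], t0)
        else:
            log.info("stage enrich: up to date, skipped")

    # -- stage: sites -------------------------------------------------------
    if cfg.alignment is not None:
        sites_path = out / "sites.tsv"
        h = _stage_hash({"sites": cfg.site_params}, [cfg.alignment, cfg.master, cfg.phenotypes])
        if not _up_to_date(manifest, "sites", h, [sites_path]):
            t0 = time.time()
            aln = site_screen.read_alignment(Path(cfg.alignment).read_text())
            cands = site_screen.screen_sites(
                aln, pheno, master,
                threshold=float(cfg.site_params.get("threshold", 0.2)),
                reference=cfg.site_params.get("reference"),
            )
            rows = [
                {
                    "site": c.site, "similarity": c.similarity,
                    "focal_category": c.focal_category,
                    "focal_residues": "".join(sorted(c.focal_residues)),
                    "origins": c.origins, "clade_confounded": c.clade_confounded,
                }
                for c in cands
            ]
            pd.DataFrame(rows).to_csv(sites_path, sep="\t", index=False)
            finish("sites", h, [sites_path], t0)
        else:
            log.info("stage sites: up to date, skipped")

    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
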