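"""Synthetic master trees, phenotypes, and gene trees with category-linked rate shifts.

The generator provides full ground truth for every pipeline stage: a random
rooted topology with exponential branch lengths (average genome-wide rates),
a categorical trait history simulated from a CTMM (true internal states
included), and per-gene trees whose branch lengths are the master lengths
scaled by a gene factor, multiplicative lognormal noise, and - for affected
genes - a rate multiplier on branches of one target category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .asr import TransitionRateMatrix, make_rate_model
from .categories import PhenotypeVector
from .permulations import simulate_tip_states
from .phylo import BranchIndex, GeneTreeSet, Phylogeny

__all__ = [
    "ShiftSpec",
    "random_tree",
    "simulate_phenotype_on_tree",
    "simulate_gene_trees",
    "simulate_correlated_blocks",
]


@dataclass(frozen=True)
class ShiftSpec:
    """A planted association: genes in ``fraction`` of the genome evolve
    ``multiplier``-fold faster (or slower) on branches of ``target_category``;
    every gene carries per-branch lognormal noise of scale ``noise_sd``."""

    target_category: int | str = 0
    multiplier: float = 3.0
    fraction: float = 0.1
    noise_sd: float = 0.3
    gene_scale_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise ValueError("rate multiplier must be positive")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("affected fraction must lie in [0, 1]")
        if self.noise_sd < 0 or self.gene_scale_sd < 0:
            raise ValueError("noise scales must be nonnegative")


def random_tree(
    n_tips: int,
    mean_branch_length: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> Phylogeny:
    """Random pure-birth (uniform-split) rooted topology with i.i.d.
    exponential branch lengths of the given mean."""
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    width = len(str(n_tips))
    # grow a binary topology by splitting a uniformly chosen active lineage
    parent = [-1, 0, 0]
    active = [1, 2]
    while len(active) < n_tips:
        i = int(rng.integers(0, len(active)))
        node = active.pop(i)
        for _ in range(2):
            parent.append(node)
            active.append(len(parent) - 1)
    n = len(parent)
    lengths = np.full(n, np.nan)
    lengths[1:] = rng.exponential(mean_branch_length, size=n - 1)
    labels = {node: f"t{j + 1:0{width}d}" for j, node in enumerate(sorted(active))}
    return Phylogeny(
        parent=np.asarray(parent), lengths=lengths, labels=labels, root=0
    )


def default_generator(k: int, rate: float = 1.0) -> TransitionRateMatrix:
    """An equal-rates CTMM generator, convenient for simulating trait histories."""
    model = make_rate_model(k, "ER")
    q = model.build_q(np.array([rate]))
    return TransitionRateMatrix(
        q=q, params=np.array([rate]), loglik=np.nan, model=model,
        root_prior=np.full(k, 1.0 / k),
    )


def simulate_phenotype_on_tree(
    tree: Phylogeny,
    q: TransitionRateMatrix | np.ndarray,
    root_prior: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
    categories: list[str] | None = None,
    require_all_categories: bool = True,
    max_tries: int = 1000,
) -> tuple[PhenotypeVector, np.ndarray]:
    """Simulate a trait history; returns (tip phenotypes, true per-node states).

    With ``require_all_categories`` the simulation redraws until every
    category appears in at least two tips, so downstream K-group tests are
    well posed on the realised data.
    """
    if isinstance(q, TransitionRateMatrix):
        k = q.k
    else:
        k = np.asarray(q).shape[0]
    if categories is None:
        categories = [chr(ord("A") + i) for i in range(k)]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(max_tries):
        states = simulate_tip_states(tree, q, root_prior, rng)
        tip_states = {tree.labels[t]: int(states[t]) for t in tree.tips}
        counts = np.bincount(list(tip_states.values()), minlength=k)
        if not require_all_categories or np.all(counts >= 2):
            pheno = PhenotypeVector(
                {sp: categories[s] for sp, s in tip_states.items()}, list(categories)
            )
            return pheno, states
    raise RuntimeError(
        f"no simulation produced >=2 tips per category in {max_tries} tries; "
        "use a faster generator or a larger tree"
    )


def simulate_gene_trees(
    master: Phylogeny,
    branch_states: np.ndarray,
    n_genes: int,
    spec: ShiftSpec = ShiftSpec(),
    seed: int | np.random.Generator = 0,
    categories: list[str] | None = None,
) -> tuple[GeneTreeSet, pd.DataFrame]:
    """Gene trees on the master topology with a planted categorical rate shift.

    Gene g's length on branch b is ``master_b * scale_g * noise_gb``, times
    ``spec.multiplier`` when g is affected and b's true state is the target
    category.  Returns the gene set and a truth table (gene, affected).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    target = spec.target_category
    if isinstance(target, str):
        if categories is None:
            raise ValueError("category labels needed to resolve a string target")
        target = categories.index(target)
    n_nodes = master.n_nodes
    nonroot = np.array([n for n in range(n_nodes) if n != master.root])
    on_target = branch_states[nonroot] == target

    n_affected = int(round(spec.fraction * n_genes))
    affected = np.zeros(n_genes, dtype=bool)
    affected[rng.choice(n_genes, size=n_affected, replace=False)] = True

    width = len(str(n_genes))
    trees: dict[str, Phylogeny] = {}
    rows = []
    base = master.lengths[nonroot]
    for g in range(n_genes):
        scale = float(rng.lognormal(0.0, spec.gene_scale_sd)) if spec.gene_scale_sd > 0 else 1.0
        noise = (
            rng.lognormal(0.0, spec.noise_sd, size=nonroot.size)
            if spec.noise_sd > 0
            else np.ones(nonroot.size)
        )
        lengths = base * scale * noise
        if affected[g]:
            lengths = np.where(on_target, lengths * spec.multiplier, lengths)
        new_lengths = np.full(n_nodes, np.nan)
        new_lengths[nonroot] = lengths
        gid = f"g{g + 1:0{width}d}"
        trees[gid] = Phylogeny(
            parent=master.parent.copy(), lengths=new_lengths,
            labels=dict(master.labels), root=master.root,
        )
        rows.append({"gene": gid, "affected": bool(affected[g])})
    truth = pd.DataFrame(rows).set_index("gene")
    return GeneTreeSet(trees=trees), truth


def simulate_correlated_blocks(
    master: Phylogeny,
    n_independent: int,
    block_sizes: list[int],
    shared_sd: float = 0.4,
    noise_sd: float = 0.15,
    gene_scale_sd: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> tuple[GeneTreeSet, dict[str, set[str]]]:
    """Null gene trees where blocks of genes share per-branch rate noise.

    No gene depends on the trait; genes within a block share one lognormal
    per-branch noise vector (scale ``shared_sd``) on top of individual noise
    (``noise_sd``), so their association statistics - and hence their ranks -
    cluster together, emulating co-regulated families such as olfactory
    receptors.  Returns the gene set and one pathway per block.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_nodes = master.n_nodes
    nonroot = np.array([n for n in range(n_nodes) if n != master.root])
    base = master.lengths[nonroot]
    trees: dict[str, Phylogeny] = {}
    pathways: dict[str, set[str]] = {}

    def add_gene(gid: str, shared: np.ndarray | None) -> None:
        scale = float(rng.lognormal(0.0, gene_scale_sd)) if gene_scale_sd > 0 else 1.0
        noise = (
            rng.lognormal(0.0, noise_sd, size=nonroot.size)
            if noise_sd > 0
            else np.ones(nonroot.size)
        )
        lengths = base * scale * noise
        if shared is not None:
            lengths = lengths * shared
        new_lengths = np.full(n_nodes, np.nan)
        new_lengths[nonroot] = lengths
        trees[gid] = Phylogeny(
            parent=master.parent.copy(), lengths=new_lengths,
            labels=dict(master.labels), root=master.root,
        )

    for b, size in enumerate(block_sizes):
        shared = rng.lognormal(0.0, shared_sd, size=nonroot.size) if shared_sd > 0 else None
        members = set()
        for i in range(size):
            gid = f"blk{b + 1:03d}_{i + 1:03d}"
            add_gene(gid, shared)
            members.add(gid)
        pathways[f"block_{b + 1:03d}"] = members
    for i in range(n_independent):
        add_gene(f"ind{i + 1:04d}", None)
    return GeneTreeSet(trees=trees), pathways
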