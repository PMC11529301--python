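import numpy as np
import pytest

from catrer import CategoricalRERScan, random_tree, simulate_gene_trees, simulate_phenotype_on_tree
from catrer.synth import ShiftSpec, default_generator


@pytest.fixture(scope="session")
def null_scan():
    """Fitted scan of a no-association simulation (60 species, 500 genes),
    with 200 permulations attached; shared by calibration tests."""
    master = random_tree(60, seed=11)
    q = default_generator(3, rate=0.6 / master.height())
    pheno, states = simulate_phenotype_on_tree(master, q, seed=12)
    genes, truth = simulate_gene_trees(
        master, states, 500, ShiftSpec(0, multiplier=1.0, fraction=0.0, noise_sd=0.3), seed=13
    )
    res = CategoricalRERScan(master, genes, pheno, rate_model="ER").fit()
    res.permulate(n=200, seed=14, max_attempts=500_000)
    return res


@pytest.fixture(scope="session")
def planted_scan():
    """Fitted scan of a planted-shift simulation (100 species, 500 genes,
    3x multiplier on one category, 10% of genes affected) plus its truth table."""
    master = random_tree(100, seed=21)
    q = default_generator(3, rate=0.6 / master.height())
    pheno, states = simulate_phenotype_on_tree(master, q, seed=22)
    genes, truth = simulate_gene_trees(
        master, states, 500, ShiftSpec(0, multiplier=3.0, fraction=0.1, noise_sd=0.3), seed=23
    )
    res = CategoricalRERScan(master, genes, pheno, rate_model="ER").fit()
    return res, truth
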