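import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from catrer import random_tree, simulate_phenotype_on_tree
from catrer.asr import make_rate_model, marginal_reconstruction
from catrer.permulations import (
    AnnealSchedule,
    PermulationConfig,
    RejectionExhausted,
    anneal_internal,
    empirical_pvalues,
    permulate,
    permute_internal,
    rejection_sample,
    simulate_tip_states,
    _labeling_loglik,
    _sim_matrices,
)
from catrer.phylo import read_newick
from catrer.synth import default_generator


@pytest.fixture(scope="module")
def perm_setup():
    """A 20-tip tree with a fitted-style generator and reconstruction."""
    master = random_tree(20, seed=51)
    q = default_generator(2, rate=0.8 / master.height())
    pheno, states = simulate_phenotype_on_tree(master, q, seed=52)
    recon = marginal_reconstruction(master, pheno, q)
    counts = pheno.counts()
    observed = np.array([counts[c] for c in pheno.categories])
    return master, q, pheno, recon, observed


class TestSimulateTipStates:
    def test_zero_rates_inherit_root(self):
        master = random_tree(10, seed=1)
        q = make_rate_model(3, "ER").build_q(np.array([1e-12]))
        states = simulate_tip_states(master, q, np.array([0.0, 1.0, 0.0]), rng=3)
        assert np.all(states == 1)

    def test_single_branch_change_frequency(self):
        """Two-state ER on one branch: P(change) = 1/2 - exp(-2 a t)/2."""
        tree = read_newick("(A:0.6,B:0.0001);")
        alpha = 0.9
        q = make_rate_model(2, "ER").build_q(np.array([alpha]))
        rng = np.random.default_rng(7)
        pm = _sim_matrices(tree, q)
        n = 10_000
        changes = 0
        from catrer.permulations import _simulate_batch

        batch = _simulate_batch(tree, pm, np.array([0.5, 0.5]), rng, n)
        a_node = [t for t in tree.tips if tree.labels[t] == "A"][0]
        changes = np.sum(batch[:, a_node] != batch[:, tree.root])
        p = 0.5 - 0.5 * np.exp(-2 * alpha * 0.6)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(changes / n - p) < 3 * se

    def test_seed_determinism(self, perm_setup):
        master, q, *_ = perm_setup
        s1 = simulate_tip_states(master, q, rng=123)
        s2 = simulate_tip_states(master, q, rng=123)
        assert np.array_equal(s1, s2)


class TestRejectionSample:
    def test_exact_match_at_zero_relaxation(self, perm_setup):
        master, q, pheno, recon, observed = perm_setup
        tips = [n for n in range(master.n_nodes) if master.is_tip(n)]
        rng = np.random.default_rng(8)
        for _ in range(100):
            states, _ = rejection_sample(
                master, q, None, observed, relax=0.0, max_attempts=100_000, rng=rng
            )
            counts = np.bincount(states[tips], minlength=2)
            assert np.array_equal(counts, observed)

    def test_relaxation_window(self, perm_setup):
        """Relaxed acceptance: |count - observed| <= ceil(r * observed)."""
        master, q, pheno, recon, observed = perm_setup
        tips = [n for n in range(master.n_nodes) if master.is_tip(n)]
        tol = np.ceil(0.1 * observed).astype(int)
        rng = np.random.default_rng(9)
        for _ in range(50):
            states, _ = rejection_sample(
                master, q, None, observed, relax=0.1, max_attempts=100_000, rng=rng
            )
            counts = np.bincount(states[tips], minlength=2)
            assert np.all(np.abs(counts - observed) <= tol)

    def test_full_relaxation_accepts_first_draw(self, perm_setup):
        master, q, pheno, recon, observed = perm_setup
        _, attempts = rejection_sample(
            master, q, None, observed, relax=1.0, max_attempts=10, rng=0
        )
        assert attempts == 1

    def test_exhaustion_raises(self, perm_setup):
        master, q, pheno, recon, observed = perm_setup
        impossible = observed.copy()
        impossible[0] += 100  # more tips than exist in the category
        with pytest.raises(RejectionExhausted):
            rejection_sample(master, q, None, impossible, max_attempts=50, rng=0)

    def test_relaxed_needs_no_more_attempts(self, perm_setup):
        master, q, pheno, recon, observed = perm_setup
        exact, relaxed = [], []
        for i in range(20):
            _, a = rejection_sample(
                master, q, None, observed, relax=0.0, max_attempts=100_000, rng=1000 + i
            )
            exact.append(a)
            _, a = rejection_sample(
                master, q, None, observed, relax=0.25, max_attempts=100_000, rng=1000 + i
            )
            relaxed.append(a)
        assert np.mean(relaxed) <= np.mean(exact)


class TestPermuteInternal:
    def test_multiset_conserved(self):
        rng = np.random.default_rng(0)
        obs = np.array([0, 0, 1, 2, 1])
        for _ in range(20):
            got = permute_internal(obs, rng)
            assert sorted(got) == sorted(obs)

    def test_single_element_identity(self):
        assert permute_internal(np.array([2]), 0).tolist() == [2]

    def test_arrangements_uniform(self):
        """3 slots with states {A,A,B}: each arrangement ~ 1/3 of draws."""
        rng = np.random.default_rng(11)
        counts = {}
        n = 10_000
        for _ in range(n):
            key = tuple(permute_internal(np.array([0, 0, 1]), rng))
            counts[key] = counts.get(key, 0) + 1
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        assert len(counts) == 3
        for v in counts.values():
            assert abs(v / n - 1 / 3) < 4 * se


class TestAnnealInternal:
    def test_never_worse_than_input(self, perm_setup):
        master, q, pheno, recon, observed = perm_setup
        rng = np.random.default_rng(12)
        from catrer.permulations import _sim_matrices

        logp = {n: np.log(np.maximum(p, 1e-300)) for n, p in _sim_matrices(master, q.q).items()}
        log_prior = np.log(q.root_prior)
        internal = recon.internal_nodes()
        for i in range(10):
            states = recon.ml_states.copy()
            states[internal] = permute_internal(states[internal], rng)
            ll0 = _labeling_loglik(master, states, logp, log_prior)
            _, ll = anneal_internal(master, states, q, rng=rng)
            assert ll >= ll0 - 1e-12

    def test_uniform_internal_states_returned_unchanged(self, perm_setup):
        master, q, *_ = perm_setup
        states = np.zeros(master.n_nodes, dtype=int)
        got, _ = anneal_internal(master, states, q, rng=0)
        assert np.array_equal(got, states)

    def test_reaches_brute_force_optimum(self):
        """Small tree: annealing finds the best multiset arrangement >=95/100 runs."""
        master = read_newick(
            "(((A:0.2,B:0.2):0.2,(C:0.2,D:0.2):0.2):0.2,(E:0.2,F:0.2):0.2);"
        )
        q = default_generator(2, rate=1.0)
        internal = [n for n in range(master.n_nodes) if not master.is_tip(n)]
        tipstates = {"A": 0, "B": 0, "C": 1, "D": 1, "E": 0, "F": 1}
        base = np.zeros(master.n_nodes, dtype=int)
        for t in master.tips:
            base[t] = tipstates[master.labels[t]]
        multiset = [0, 0, 1, 1, 0]  # five internal nodes
        logp = {n: np.log(np.maximum(p, 1e-300)) for n, p in _sim_matrices(master, q.q).items()}
        log_prior = np.log(q.root_prior)

        best = -np.inf
        for arrangement in set(itertools.permutations(multiset)):
            s = base.copy()
            s[internal] = arrangement
            best = max(best, _labeling_loglik(master, s, logp, log_prior))

        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            s = base.copy()
            s[internal] = permute_internal(np.array(multiset), rng)
            _, ll = anneal_internal(master, s, q, rng=rng)
            wins += ll >= best - 1e-9
        assert wins >= 95


class TestPermulate:
    def test_invariants_and_determinism(self, perm_setup):
        master, q, pheno, recon, observed = perm_setup
        cfg = PermulationConfig(n=50, relax=0.0, seed=99, max_attempts=100_000)
        ps1 = permulate(master, q, recon, observed, cfg)
        ps2 = permulate(master, q, recon, observed, cfg)
        assert np.array_equal(ps1.states, ps2.states)  # bit-identical given seed
        tips = [n for n in range(master.n_nodes) if master.is_tip(n)]
        internal = recon.internal_nodes()
        obs_multiset = sorted(recon.ml_states[internal])
        for d in range(ps1.n):
            counts = np.bincount(ps1.states[d, tips], minlength=2)
            assert np.array_equal(counts, observed)
            assert sorted(ps1.states[d, internal]) == obs_multiset

    def test_draws_differ(self, perm_setup):
        master, q, pheno, recon, observed = perm_setup
        cfg = PermulationConfig(n=50, relax=0.0, seed=7, max_attempts=100_000)
        ps = permulate(master, q, recon, observed, cfg)
        unique = {tuple(row) for row in ps.states}
        # the skewed 3/17 phenotype leaves few distinct labelings, so allow a
        # handful of birthday collisions while requiring real variety
        assert len(unique) > 35


class TestEmpiricalPvalues:
    def test_midpoint(self):
        obs = pd.Series({"g": 5.5})
        nulls = np.arange(1.0, 11.0).reshape(-1, 1)
        out = empirical_pvalues(obs, nulls, "greater")
        assert out.pvalues["g"] == pytest.approx(0.5)
        assert not out.floored["g"]

    def test_floor_flagged(self):
        obs = pd.Series({"g": 100.0})
        nulls = np.arange(1.0, 11.0).reshape(-1, 1)
        out = empirical_pvalues(obs, nulls, "greater")
        assert out.pvalues["g"] == 0.0 and bool(out.floored["g"])
        assert out.display()["g"] == "< 0.1"

    def test_observed_below_all_nulls(self):
        obs = pd.Series({"g": -1.0})
        nulls = np.arange(1.0, 11.0).reshape(-1, 1)
        out = empirical_pvalues(obs, nulls, "greater")
        assert out.pvalues["g"] == 1.0

    def test_two_sided_uses_magnitude(self):
        obs = pd.Series({"g": -3.0})
        nulls = np.array([[-4.0], [2.0], [3.5], [-1.0]])
        out = empirical_pvalues(obs, nulls, "two-sided")
        assert out.pvalues["g"] == pytest.approx(0.5)

    def test_missing_nulls_rejected(self):
        obs = pd.Series({"g": 1.0})
        with pytest.raises(ValueError):
            empirical_pvalues(obs, np.array([[np.nan]]), "greater")


def test_null_calibration_is_uniform(null_scan):
    """Permulation p-values on no-association data are uniform."""
    pvals = null_scan.perm_pvalues.pvalues
    assert stats.kstest(pvals, "uniform").pvalue > 0.01
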