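"""Plug-in entropy/MI estimation against independent oracles."""

import numpy as np
import pytest

from alinfo.circuit import CircuitParams, SpikeCountTable
from alinfo.info_exact import (
    ConditionalDistribution,
    entropy_bits,
    entropy_decomposition_curve,
    estimate_conditional,
    mutual_information_exact,
)


def make_table(counts, odor_index, cap=5):
    return SpikeCountTable(
        counts=np.atleast_2d(counts), odor_index=np.asarray(odor_index),
        cap=cap, t_bin=0.01, n_pn=1,
    )


def brute_force_mi(conditionals, prior):
    """Independent exhaustive double sum over all patterns.

    ``conditionals[s]`` is a list of per-unit marginals; the joint is their
    product (pattern probabilities enumerated with explicit loops).
    """
    import itertools

    n_units = len(conditionals[0])
    levels = len(conditionals[0][0])
    p_r = {}
    per_odor = []
    for s, margs in enumerate(conditionals):
        table = {}
        for pattern in itertools.product(range(levels), repeat=n_units):
            p = 1.0
            for u, k in enumerate(pattern):
                p *= margs[u][k]
            table[pattern] = p
            p_r[pattern] = p_r.get(pattern, 0.0) + prior[s] * p
        per_odor.append(table)
    mi = 0.0
    for s, table in enumerate(per_odor):
        for pattern, p in table.items():
            if p > 0 and p_r[pattern] > 0:
                mi += prior[s] * p * np.log2(p / p_r[pattern])
    return mi


class TestEstimateConditional:
    def test_single_pn_marginal(self):
        tab = make_table(np.array([[0], [0], [1], [1]]), [0, 0, 0, 0])
        cond = estimate_conditional(tab)
        np.testing.assert_allclose(cond.tables[0, 0], [0.5, 0.5, 0, 0, 0, 0])

    def test_degenerate_distribution_zero_entropy(self):
        tab = make_table(np.array([[2, 3]] * 10), [0] * 10)
        cond = estimate_conditional(tab)
        res = mutual_information_exact(cond, prior=[1.0])
        assert res.entropy == pytest.approx(0.0, abs=1e-12)

    def test_missing_odor_rejected(self):
        tab = make_table(np.array([[1], [2]]), [1, 1])
        with pytest.raises(ValueError, match="odor 0 has no trials"):
            estimate_conditional(tab)

    def test_marginals_match_binomial_generator(self):
        # product-Bernoulli responses: empirical marginals within 3 SE
        rng = np.random.default_rng(0)
        p0, p1, n = 0.3, 0.7, 400
        counts = np.column_stack(
            [rng.binomial(1, p0, n), rng.binomial(1, p1, n)]
        )
        cond = estimate_conditional(make_table(counts, [0] * n, cap=1))
        for u, p in enumerate([p0, p1]):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(cond.tables[0, u, 1] - p) < 3 * se

    def test_joint_mode_counts_patterns(self):
        tab = make_table(np.array([[0, 1], [0, 1], [1, 0], [1, 1]]), [0] * 4, cap=1)
        cond = estimate_conditional(tab, factorized=False)
        # mixed radix, unit 0 most significant: patterns 01,01,10,11
        np.testing.assert_allclose(cond.tables[0], [0, 0.5, 0.25, 0.25])

    def test_joint_ceiling_refers_to_decoder(self):
        tab = make_table(np.zeros((2, 12), dtype=int), [0, 1])
        with pytest.raises(ValueError, match="decod"):
            estimate_conditional(tab, factorized=False)


class TestMutualInformation:
    def test_identical_conditionals_zero_information(self):
        marg = np.tile([0.25, 0.5, 0.25], (3, 2, 1))  # 3 odors, 2 units
        cond = ConditionalDistribution(marg, cap=2, n_units=2, factorized=True,
                                       n_trials=np.full(3, 100))
        res = mutual_information_exact(cond)
        assert res.mutual_information == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_code_gives_log2_s(self):
        # 8 odors mapped to 8 distinct deterministic 3-bit patterns
        marg = np.zeros((8, 3, 2))
        for s in range(8):
            for u in range(3):
                marg[s, u, (s >> u) & 1] = 1.0
        cond = ConditionalDistribution(marg, cap=1, n_units=3, factorized=True,
                                       n_trials=np.full(8, 10))
        res = mutual_information_exact(cond)
        assert res.mutual_information == pytest.approx(3.0, abs=1e-12)
        assert res.noise_entropy == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_brute_force_sum(self):
        # 2 glomeruli, 2 odors, cap 2: exhaustive 9-pattern oracle
        margs = [
            [[0.7, 0.2, 0.1], [0.6, 0.3, 0.1]],
            [[0.2, 0.5, 0.3], [0.1, 0.4, 0.5]],
        ]
        prior = [0.5, 0.5]
        cond = ConditionalDistribution(
            np.array(margs), cap=2, n_units=2, factorized=True,
            n_trials=np.full(2, 100),
        )
        res = mutual_information_exact(cond, prior=prior)
        assert res.mutual_information == pytest.approx(
            brute_force_mi(margs, prior), abs=1e-9
        )

    def test_factorized_and_joint_agree_for_independent_units(self):
        rng = np.random.default_rng(1)
        n = 10_000
        probs = [(0.2, 0.6), (0.5, 0.3)]  # per-odor Bernoulli p per unit
        counts, odors = [], []
        for s, (pa, pb) in enumerate(probs):
            counts.append(
                np.column_stack([rng.binomial(2, pa, n), rng.binomial(2, pb, n)])
            )
            odors.extend([s] * n)
        tab = make_table(np.vstack(counts), odors, cap=2)
        fact = mutual_information_exact(estimate_conditional(tab, factorized=True))
        joint = mutual_information_exact(estimate_conditional(tab, factorized=False))
        assert fact.mutual_information == pytest.approx(
            joint.mutual_information, abs=0.01
        )

    def test_plugin_bias_shrinks_with_trials(self):
        # plug-in MI decreases in expectation toward the large-sample value
        rng = np.random.default_rng(2)
        probs = [(0.2, 0.6), (0.5, 0.3), (0.8, 0.8), (0.4, 0.1)]

        def draw_mi(n, reps):
            vals = []
            for _ in range(reps):
                counts, odors = [], []
                for s, (pa, pb) in enumerate(probs):
                    counts.append(np.column_stack(
                        [rng.binomial(2, pa, n), rng.binomial(2, pb, n)]
                    ))
                    odors.extend([s] * n)
                tab = make_table(np.vstack(counts), odors, cap=2)
                vals.append(
                    mutual_information_exact(
                        estimate_conditional(tab)
                    ).mutual_information
                )
            return float(np.mean(vals))

        reference = draw_mi(100_000, 1)
        means = [draw_mi(n, 50) for n in (50, 100, 200, 400)]
        assert all(a >= b - 1e-3 for a, b in zip(means, means[1:]))
        assert means[-1] >= reference - 0.01

    def test_bounds_on_simulated_instance(self, small_matrix):
        from alinfo.circuit import run_ensemble

        tab = run_ensemble(small_matrix, CircuitParams(beta=0.5), 200, seed=0)
        res = mutual_information_exact(estimate_conditional(tab))
        upper = min(np.log2(small_matrix.n_odors), tab.n_units * np.log2(6))
        assert -1e-9 <= res.mutual_information <= upper + 1e-9
        assert res.mutual_information == pytest.approx(
            res.entropy - res.noise_entropy, abs=1e-9
        )

    def test_bad_prior_rejected(self):
        marg = np.tile([0.5, 0.5], (2, 1, 1))
        cond = ConditionalDistribution(marg, cap=1, n_units=1, factorized=True,
                                       n_trials=np.full(2, 10))
        with pytest.raises(ValueError, match="prior"):
            mutual_information_exact(cond, prior=[0.9, 0.2])


class TestEntropyDecompositionCurve:
    def test_single_point_equals_direct_call(self, small_matrix):
        from alinfo.circuit import run_ensemble

        p = CircuitParams()
        (res,) = entropy_decomposition_curve(
            small_matrix, p, "beta", [0.5], n_trials=100, seed=3
        )
        tab = run_ensemble(small_matrix, p.with_(beta=0.5), 100, seed=3)
        direct = mutual_information_exact(estimate_conditional(tab))
        assert res.mutual_information == pytest.approx(direct.mutual_information)

    def test_unknown_parameter_rejected(self, small_matrix):
        with pytest.raises(ValueError, match="vary"):
            entropy_decomposition_curve(small_matrix, CircuitParams(), "tau", [1])

    def test_empty_grid_rejected(self, small_matrix):
        with pytest.raises(ValueError, match="non-empty"):
            entropy_decomposition_curve(small_matrix, CircuitParams(), "beta", [])


def test_entropy_bits_of_uniform():
    assert entropy_bits(np.full(8, 0.125)) == pytest.approx(3.0)
    assert entropy_bits(np.array([1.0, 0.0])) == pytest.approx(0.0)
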