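"""Pruning-algorithm likelihoods on quartet trees, constant and gamma rates."""

import numpy as np
import pytest

from quartetstar import (
    QuartetTree,
    RateModel,
    class_likelihood,
    class_site_probs,
    counts_from_spec,
    enumerate_classes,
    expected_class_probs,
    gamma_class_probs,
    lnL_constant,
    lnL_gamma,
)
from quartetstar.patterns import MULTIPLICITIES

from conftest import brute_force_column_prob


class TestClassLikelihood:
    def test_monomorphic_class_zero_tree(self):
        tree = QuartetTree("star", (0.0, 0.0, 0.0, 0.0))
        g5 = enumerate_classes()[14]
        assert class_likelihood(g5, tree) == pytest.approx(0.25, abs=1e-15)

    def test_all_distinct_impossible_without_change(self):
        tree = QuartetTree("star", (0.0, 0.0, 0.0, 0.0))
        g1 = enumerate_classes()[0]
        assert class_likelihood(g1, tree) == 0.0

    def test_pruning_equals_brute_force_enumeration(self, random_trees):
        # oracle: explicit summation over internal-node states
        for tree in random_trees:
            for r in (1.0, 0.35):
                probs = class_site_probs(tree, r)
                for cls in enumerate_classes():
                    oracle = brute_force_column_prob(cls.representative, tree, r)
                    assert probs[cls.class_id - 1] == pytest.approx(
                        oracle, abs=1e-12
                    )

    def test_normalization_over_all_patterns(self, random_trees):
        # multiplicity-weighted class probabilities sum to 1 for any tree/rate
        for tree in random_trees:
            for r in (0.2, 1.0, 4.0):
                total = float(MULTIPLICITIES @ class_site_probs(tree, r))
                assert total == pytest.approx(1.0, abs=1e-10)
            total = float(MULTIPLICITIES @ gamma_class_probs(tree, 0.7))
            assert total == pytest.approx(1.0, abs=1e-8)


class TestLnLConstant:
    def test_star_value_at_reported_branch_lengths(self):
        counts = counts_from_spec(0, 14, 43, 4, 40)
        tree = QuartetTree("star", (0.426784,) * 4)
        assert lnL_constant(counts, tree) == pytest.approx(-1537.68, abs=0.005)

    def test_monomorphic_closed_form(self):
        counts = counts_from_spec(0, 0, 0, 0, 400)
        tree = QuartetTree("star", (0.0,) * 4)
        assert lnL_constant(counts, tree) == pytest.approx(400 * np.log(0.25))

    def test_resolved_with_zero_internal_equals_star(self):
        rng = np.random.default_rng(3)
        counts = counts_from_spec(*rng.integers(1, 30, size=5))
        b = tuple(rng.uniform(0.1, 2.0, size=4))
        star = lnL_constant(counts, QuartetTree("star", b))
        for topo in ("T12|34", "T13|24", "T14|23"):
            resolved = lnL_constant(counts, QuartetTree(topo, b, 0.0))
            assert resolved == pytest.approx(star, abs=1e-10)

    def test_zero_probability_class_gives_neg_inf(self):
        counts = counts_from_spec(5, 0, 0, 0, 5)
        tree = QuartetTree("star", (0.0,) * 4)
        assert lnL_constant(counts, tree) == -np.inf

    def test_monotone_approach_to_saturation_bound(self):
        # the all-patterns dataset's lnL rises monotonically in a common
        # branch length toward the equal-frequency bound 256 ln(1/256)
        counts = counts_from_spec(24, 24, 12, 12, 4)
        values = [
            lnL_constant(counts, QuartetTree("star", (b,) * 4))
            for b in (0.5, 1, 2, 4, 8, 16, 32)
        ]
        # strictly increasing until the curve flattens onto the bound
        assert all(v2 > v1 for v1, v2 in zip(values[:4], values[1:5]))
        assert all(v2 >= v1 - 1e-9 for v1, v2 in zip(values, values[1:]))
        assert values[-1] == pytest.approx(256 * np.log(1 / 256), abs=1e-6)


class TestLnLGamma:
    def test_large_alpha_recovers_constant_rate(self):
        tree = QuartetTree("star", (1.0, 0.8, 1.2, 0.9))
        for spec in [(24, 24, 12, 96, 32), (0, 14, 43, 4, 40)]:
            counts = counts_from_spec(*spec)
            assert lnL_gamma(counts, tree, 1e6) == pytest.approx(
                lnL_constant(counts, tree), abs=1e-3
            )

    def test_reported_star_gamma_value(self):
        counts = counts_from_spec(24, 24, 12, 96, 32)
        tree = QuartetTree("star", (1.020429,) * 4)
        assert lnL_gamma(counts, tree, 10000.0) == pytest.approx(-2947.797, abs=0.005)

    def test_single_site_integral_bounded_by_rate_extremes(self):
        from quartetstar import PatternCounts

        tree = QuartetTree("T13|24", (0.4, 0.6, 0.3, 0.8), 0.5)
        counts = PatternCounts(np.eye(15, dtype=int)[4])
        lo = min(class_site_probs(tree, r)[4] for r in (0.01, 100.0))
        hi = max(class_site_probs(tree, r)[4] for r in (0.01, 100.0))
        val = np.exp(lnL_gamma(counts, tree, 2.0))
        assert lo <= val <= hi

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            gamma_class_probs(QuartetTree("star", (1,) * 4), -1.0)


class TestExpectedClassProbs:
    def test_zero_tree_concentrates_on_monomorphic(self):
        probs = expected_class_probs(
            QuartetTree("star", (0.0,) * 4), RateModel.constant()
        )
        assert probs[14] == pytest.approx(1.0)
        assert probs[:14].sum() == pytest.approx(0.0, abs=1e-15)

    def test_saturation_proportional_to_multiplicities(self):
        probs = expected_class_probs(
            QuartetTree("star", (50.0,) * 4), RateModel.constant()
        )
        np.testing.assert_allclose(probs, MULTIPLICITIES / 256, atol=1e-8)

    def test_sums_to_one(self, random_trees):
        for tree in random_trees[:4]:
            for model in (RateModel.constant(), RateModel.gamma(0.5)):
                assert expected_class_probs(tree, model).sum() == pytest.approx(
                    1.0, abs=1e-8
                )


class TestTopologySymmetry:
    def test_resolved_topologies_agree_on_symmetric_counts(self):
        # within-group-equal counts cannot prefer any resolved pairing
        counts = counts_from_spec(10, 7, 9, 11, 20)
        values = [
            lnL_constant(counts, QuartetTree(t, (0.9,) * 4, 0.4))
            for t in ("T12|34", "T13|24", "T14|23")
        ]
        assert max(values) - min(values) < 1e-10


class TestQuartetTreeValidation:
    def test_star_rejects_internal_branch(self):
        with pytest.raises(ValueError):
            QuartetTree("star", (1, 1, 1, 1), 0.5)

    def test_negative_branch_rejected(self):
        with pytest.raises(ValueError):
            QuartetTree("T12|34", (1, -1, 1, 1), 0.5)
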