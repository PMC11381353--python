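import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from wormsrna.io import CountMatrix
from wormsrna.quant import (
    MIR35_FAMILY,
    NormalizerSpec,
    class_sum,
    normalize_by,
    rpm_normalize,
    summarize_class,
    two_sample_test,
)


def matrix(genes, samples, counts, totals=None):
    counts = np.asarray(counts, dtype=float)
    if totals is None:
        totals = counts.sum(axis=0)
    return CountMatrix(genes, samples, counts, np.asarray(totals, float))


class TestRpm:
    def test_arithmetic(self):
        cm = matrix(["g1", "g2"], ["s"], [[5], [5]], totals=[10])
        rpm = rpm_normalize(cm)
        assert rpm.counts[:, 0].tolist() == [5e5, 5e5]

    def test_seven_reads_in_two_million(self):
        cm = matrix(["g"], ["s"], [[7]], totals=[2e6])
        assert rpm_normalize(cm).counts[0, 0] == pytest.approx(3.5)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            CountMatrix(["g"], ["s"], np.array([[0.0]]), np.array([0.0]))

    def test_rpm_conservation(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 500, (50, 3)).astype(float)
        cm = matrix([f"g{i}" for i in range(50)], list("abc"), counts)
        rpm = rpm_normalize(cm)
        # totals equal column sums here, so each column sums to 1e6
        assert np.allclose(rpm.counts.sum(axis=0), 1e6, rtol=1e-9)


class TestNormalizeBy:
    def test_family_ratio(self):
        genes = ["cls"] + sorted(MIR35_FAMILY)
        counts = np.vstack([[50.0], np.full((8, 1), 100.0 / 8)])
        cm = matrix(genes, ["s"], counts, totals=[1e6])
        spec = NormalizerSpec("feature_family", MIR35_FAMILY)
        out = normalize_by(cm, spec)
        assert out.counts[0, 0] == pytest.approx(0.5)

    def test_depth_scaling_invariance(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 300, (10, 4)).astype(float)
        genes = [f"g{i}" for i in range(9)] + ["rpl-32"]
        cm = matrix(genes, list("abcd"), counts)
        spec = NormalizerSpec("reference_gene", frozenset({"rpl-32"}))
        base = normalize_by(rpm_normalize(cm), spec)
        scaled = matrix(genes, list("abcd"), counts * 10)
        out = normalize_by(rpm_normalize(scaled), spec)
        assert np.allclose(base.counts, out.counts, rtol=1e-9)

    def test_missing_reference_gene_rejected(self):
        cm = matrix(["g1"], ["s"], [[5.0]])
        spec = NormalizerSpec("reference_gene", frozenset({"rpl-32"}))
        with pytest.raises(ValueError, match="rpl-32"):
            normalize_by(cm, spec)

    def test_zero_normalizer_names_sample(self):
        cm = matrix(["g1", "rpl-32"], ["s1", "s2"], [[5.0, 5.0], [1.0, 0.0]])
        spec = NormalizerSpec("reference_gene", frozenset({"rpl-32"}))
        with pytest.raises(ValueError, match="s2"):
            normalize_by(cm, spec)


class TestClassSum:
    def test_sum(self):
        cm = matrix(["g1", "g2", "g3"], ["s"], [[2.0], [3.0], [9.0]])
        assert class_sum(cm, {"g1", "g2"})["s"] == 5.0

    def test_empty_intersection_is_zero(self):
        cm = matrix(["g1"], ["s"], [[2.0]])
        assert class_sum(cm, {"x"}, allow_missing=True)["s"] == 0.0

    def test_missing_gene_rejected_when_strict(self):
        cm = matrix(["g1"], ["s"], [[2.0]])
        with pytest.raises(ValueError, match="g2"):
            class_sum(cm, {"g1", "g2"}, allow_missing=False)

    def test_summary_replicates_kept_separate(self):
        genes = ["a", "b", "rpl-32"]
        cm = matrix(genes, ["r1", "r2"], [[10.0, 20.0], [30.0, 40.0], [10.0, 20.0]],
                    totals=[1e6, 1e6])
        spec = NormalizerSpec("reference_gene", frozenset({"rpl-32"}))
        out = summarize_class(rpm_normalize(cm), {"a", "b"}, "cls", spec)
        assert [s.sample_id for s in out] == ["r1", "r2"]
        assert [s.value for s in out] == pytest.approx([4.0, 3.0])


def wilcoxon_enumeration_p(a, b):
    """Independent exhaustive two-sided rank-sum oracle (tie-free inputs)."""
    n1 = len(a)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w_obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            hits += 1
    return hits / total


class TestTwoSampleTests:
    def test_identical_groups_welch(self):
        r = two_sample_test([1, 2, 3], [1, 2, 3], "welch_t", "two")
        assert r.statistic == 0
        assert r.p == 1

    def test_welch_derived_example(self):
        r = two_sample_test([1, 2, 3], [4, 5, 6], "welch_t", "two")
        assert r.statistic == pytest.approx(-3.674234, abs=1e-5)
        assert r.df == pytest.approx(4.0)
        assert r.p == pytest.approx(0.021312, abs=1e-5)

    def test_wilcoxon_fully_separated_exact(self):
        r = two_sample_test([1, 2, 3], [101, 102, 103], "wilcoxon_ranksum", "two")
        assert r.p == pytest.approx(0.1)

    def test_one_tailed_student_is_half_two_tailed_in_matching_direction(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.5]
        two = two_sample_test(a, b, "student_t", "two")
        one = two_sample_test(a, b, "student_t", "one", direction="a_less")
        assert one.p == pytest.approx(two.p / 2)

    def test_degenerate_zero_variance(self):
        equal = two_sample_test([2, 2], [2, 2], "welch_t", "two")
        assert (equal.statistic, equal.p) == (0.0, 1.0)
        diff = two_sample_test([2, 2], [3, 3], "welch_t", "two")
        assert diff.p == 0.0
        assert diff.degenerate

    def test_direction_required_for_one_tailed(self):
        with pytest.raises(ValueError):
            two_sample_test([1, 2], [3, 4], "welch_t", "one")

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            two_sample_test([1], [2, 3], "welch_t", "two")

    @pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 4), (2, 8), (5, 5)])
    def test_exact_wilcoxon_matches_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(20):
            a = rng.normal(size=n1)
            b = rng.normal(size=n2)
            r = two_sample_test(a, b, "wilcoxon_ranksum", "two")
            assert r.p == pytest.approx(wilcoxon_enumeration_p(a, b), abs=1e-12)

    def test_exact_wilcoxon_matches_scipy_exact(self):
        # independent library oracle on tie-free samples
        rng = np.random.default_rng(0)
        for n1, n2 in [(3, 3), (4, 5), (2, 6)]:
            a = rng.normal(size=n1)
            b = rng.normal(size=n2)
            ours = two_sample_test(a, b, "wilcoxon_ranksum", "two").p
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_large_sample_normal_approximation_close_to_exact_tail(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 30)
        b = rng.normal(1.2, 1, 30)
        ours = two_sample_test(a, b, "wilcoxon_ranksum", "two").p
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert ours == pytest.approx(ref, rel=0.05)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_one_sided_halves_sum_to_at_most_one_plus_point_mass(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=3)
        b = rng.normal(size=4)
        lo = two_sample_test(a, b, "wilcoxon_ranksum", "one", direction="a_less").p
        hi = two_sample_test(a, b, "wilcoxon_ranksum", "one", direction="a_greater").p
        assert lo + hi >= 1.0 - 1e-12  # exact one-sided tails overlap on the point mass
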