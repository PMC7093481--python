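"""RM classification, ratios with Wilson intervals, deltas, correlations, tests."""

import itertools
import math

import numpy as np
import pytest

from epishore.stats import (
    CorrelationResult,
    DeltaRecord,
    IncompleteSRegionError,
    RMSummary,
    StatsError,
    classify_rm,
    correlate,
    direction_concordance,
    methylation_level,
    passage_delta,
    rm_allele_ratio,
    rm_threshold_count,
    ttest_two_sample,
    variance_by_allele,
)


class TestThresholdCount:
    @pytest.mark.parametrize("n,f,expected", [(9, 0.75, 7), (9, 1.0, 9), (4, 0.75, 3)])
    def test_examples(self, n, f, expected):
        assert rm_threshold_count(n, f) == expected

    @pytest.mark.parametrize("n", range(4, 17))
    @pytest.mark.parametrize("f", [0.5, 0.6, 0.75, 0.8, 1.0])
    def test_matches_smallest_k_oracle(self, n, f):
        oracle = min(k for k in range(1, n + 1) if k / n >= f)
        assert rm_threshold_count(n, f) == oracle

    def test_invalid_inputs(self):
        with pytest.raises(StatsError):
            rm_threshold_count(0, 0.75)
        with pytest.raises(StatsError):
            rm_threshold_count(9, 0.0)


class TestClassifyRM:
    @pytest.mark.parametrize(
        "n_unmeth,expected", [(9, True), (7, True), (6, False), (0, False)]
    )
    def test_unmethylated_count_rule(self, n_unmeth, expected):
        calls = ["U"] * n_unmeth + ["M"] * (9 - n_unmeth)
        assert classify_rm(calls) is expected

    def test_missing_call_is_an_error(self):
        with pytest.raises(IncompleteSRegionError, match="incomplete_s_region"):
            classify_rm(["U"] * 8 + ["."])

    def test_agrees_with_brute_force_on_all_512_vectors(self):
        for bits in itertools.product("MU", repeat=9):
            expected = sum(1 for b in bits if b == "U") >= 7
            assert classify_rm(list(bits)) is expected


class TestRMRatio:
    def test_ratio_arithmetic(self):
        s = rm_allele_ratio([True] * 12 + [False] * 18)
        assert s.n_reads == 30 and s.n_rm == 12 and s.ratio == pytest.approx(0.4)
        assert s.ci_low <= s.ratio <= s.ci_high

    def test_zero_rm_reads(self):
        s = rm_allele_ratio([False] * 30)
        assert s.ratio == 0.0 and s.ci_low == 0.0

    def test_empty_summary_is_flagged(self):
        s = rm_allele_ratio([])
        assert s.n_reads == 0 and math.isnan(s.ratio)

    def test_adding_one_rm_read_weakly_increases_ratio(self, rng):
        flags = list(rng.integers(2, size=25).astype(bool))
        assert rm_allele_ratio(flags + [True]).ratio >= rm_allele_ratio(flags).ratio

    def test_ratio_invariant_under_relabeling(self, rng):
        flags = list(rng.integers(2, size=30).astype(bool))
        shuffled = list(rng.permutation(flags))
        assert rm_allele_ratio(flags).ratio == rm_allele_ratio(shuffled).ratio


def _summary(sample, passage, allele, ratio, n=30):
    n_rm = round(ratio * n)
    return RMSummary(sample, passage, allele, n, n_rm, n_rm / n, 0.0, 1.0)


class TestPassageDelta:
    def test_signed_difference(self):
        early = [_summary("L1", "P6", "WT", 0.5)]
        late = [_summary("L1", "P20", "WT", 0.3)]
        (rec,) = passage_delta(early, late, {"L1": -0.4})
        assert rec.delta_rm == pytest.approx(-0.2)
        assert rec.delta_expr == pytest.approx(-0.4)

    def test_identical_passages_give_zero(self):
        early = [_summary("L1", "P6", "WT", 0.5)]
        late = [_summary("L1", "P20", "WT", 0.5)]
        assert passage_delta(early, late)[0].delta_rm == 0.0

    def test_six_lines_two_alleles(self):
        early = [
            _summary(f"L{i}", "P6", a, 0.5) for i in range(6) for a in ("WT", "KO")
        ]
        late = [
            _summary(f"L{i}", "P20", a, 0.4) for i in range(6) for a in ("WT", "KO")
        ]
        recs = passage_delta(early, late)
        assert len(recs) == 12
        assert sum(1 for r in recs if r.allele == "WT") == 6

    def test_duplicate_summary_rejected(self):
        early = [_summary("L1", "P6", "WT", 0.5), _summary("L1", "P6", "WT", 0.6)]
        with pytest.raises(StatsError, match="duplicate"):
            passage_delta(early, [_summary("L1", "P20", "WT", 0.3)])

    def test_missing_passage_omitted(self):
        early = [_summary("L1", "P6", "WT", 0.5), _summary("L2", "P6", "WT", 0.5)]
        late = [_summary("L1", "P20", "WT", 0.3)]
        recs = passage_delta(early, late)
        assert [r.sample_id for r in recs] == ["L1"]


class TestConcordance:
    def test_signs(self):
        deltas = [
            DeltaRecord("a", "WT", +0.2, +0.1),
            DeltaRecord("b", "WT", -0.2, +0.1),
            DeltaRecord("c", "WT", 0.0, +0.1),
        ]
        frame = direction_concordance(deltas)
        assert list(frame["concordant"]) == [True, False, False]
        assert list(frame["sign_rm"]) == ["+", "-", "0"]

    def test_concordance_count_matches_generator_truth(self):
        signs = [+1, +1, -1, -1, +1, -1]
        deltas = [
            DeltaRecord(f"L{i}", "WT", 0.1 * s, 0.2 * s) for i, s in enumerate(signs)
        ]
        frame = direction_concordance(deltas)
        assert int(frame["concordant"].sum()) == 6


class TestCorrelate:
    def test_exact_linear_relations(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert correlate(x, [2 * v + 1 for v in x]).r == pytest.approx(1.0)
        assert correlate(x, [-v for v in x]).r == pytest.approx(-1.0)

    def test_sign_equals_slope_sign(self, rng):
        x = rng.normal(size=10)
        for a in (-3.0, 0.5, 7.0):
            res = correlate(x, a * x + 2.0)
            assert res.r == pytest.approx(math.copysign(1.0, a))

    def test_matches_hand_rolled_covariance_formula(self, rng):
        x = rng.normal(size=12)
        y = -0.8 * x + rng.normal(scale=0.3, size=12)
        res = correlate(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        manual = float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))
        assert res.r == pytest.approx(manual, abs=1e-12)
        assert res.r < 0

    def test_zero_variance_flagged_undefined(self):
        res = correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert not res.defined and math.isnan(res.r)

    def test_too_few_pairs(self):
        with pytest.raises(StatsError):
            correlate([1.0, 2.0], [1.0, 2.0])

    def test_spearman_flag(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = correlate(x, [math.exp(v) for v in x], method="spearman")
        assert res.r == pytest.approx(1.0)


class TestMethylationLevel:
    def test_all_methylated(self):
        calls = [{0: "M", 5: "M"}] * 4
        assert methylation_level(calls, [0, 5]) == 1.0

    def test_constructed_matrix_fraction(self):
        """10 reads x 9 S CpGs = 90 observations; 18 methylated -> 0.2."""
        positions = list(range(9))
        calls = []
        for i in range(10):
            row = {p: "U" for p in positions}
            if i < 9:
                row[0] = row[1] = "M"  # 9 reads x 2 = 18 methylated calls
            calls.append(row)
        assert methylation_level(calls, positions) == pytest.approx(18 / 90)

    def test_missing_excluded_and_order_invariance(self, rng):
        positions = [0, 1, 2]
        calls = [{0: "M", 1: ".", 2: "U"}, {0: ".", 1: "U", 2: "M"}]
        level = methylation_level(calls, positions)
        assert level == pytest.approx(0.5)
        assert methylation_level(calls[::-1], positions) == level

    def test_no_observations_is_nan(self):
        assert math.isnan(methylation_level([{0: "."}], [0]))


class TestVarianceByAllele:
    def test_hand_computed_variance(self):
        comp = variance_by_allele({"WT": [0.2, 0.4, 0.6], "KO": [0.1, 0.5, 0.9]})
        assert comp.variances["WT"] == pytest.approx(0.04)
        assert comp.f_ratio == pytest.approx(comp.variances["KO"] / 0.04)

    def test_identical_ratios_zero_variance(self):
        comp = variance_by_allele({"WT": [0.3, 0.3, 0.3], "KO": [0.2, 0.4, 0.6]})
        assert comp.variances["WT"] == 0.0

    def test_single_line_rejected(self):
        with pytest.raises(StatsError):
            variance_by_allele({"WT": [0.3], "KO": [0.2, 0.4]})


class TestTTest:
    def test_identical_groups(self):
        res = ttest_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0) and res.p_value == pytest.approx(1.0)

    def test_closed_form_example(self):
        res = ttest_two_sample([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.t == pytest.approx(-3.674, abs=5e-4)
        assert res.df == 4

    def test_zero_variance_conventions(self):
        same = ttest_two_sample([2.0, 2.0], [2.0, 2.0])
        assert (same.t, same.p_value) == (0.0, 1.0) and not same.degenerate
        diff = ttest_two_sample([2.0, 2.0], [3.0, 3.0])
        assert diff.degenerate and math.isinf(diff.t) and diff.t < 0

    def test_matches_permutation_oracle(self, rng):
        a = rng.normal(0.0, 1.0, size=8)
        b = rng.normal(0.9, 1.0, size=8)
        res = ttest_two_sample(a, b)
        pooled = np.concatenate([a, b])
        observed = abs(np.mean(a) - np.mean(b))
        hits = 0
        n_perm = 10_000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if abs(np.mean(perm[:8]) - np.mean(perm[8:])) >= observed - 1e-12:
                hits += 1
        p_perm = hits / n_perm
        assert res.p_value == pytest.approx(p_perm, abs=0.05)
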