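"""Validity and Bland-Altman agreement statistics."""

import numpy as np
import pytest

from footkin import (
    bland_altman,
    classify_bias,
    compare_peaks,
    pearson_validity,
    validity_report,
)
from footkin.agreement import BlandAltmanResult


class TestPearson:
    def test_perfect_agreement(self):
        truth = np.array([-90.0, -45.0, 0.0, 45.0, 90.0])
        res = pearson_validity(truth, truth)
        assert res.r == pytest.approx(1.0)
        assert res.n == 5

    def test_affine_reversal(self):
        truth = np.array([-90.0, -45.0, 0.0, 45.0, 90.0])
        res = pearson_validity(-truth + 7.0, truth)
        assert res.r == pytest.approx(-1.0)

    def test_hand_formula_oracle(self):
        truth = np.array([-90.0, -45.0, 0.0, 45.0, 90.0])
        measured = np.array([-80.0, -50.0, 5.0, 40.0, 95.0])
        # textbook formula computed independently
        mx, my = measured.mean(), truth.mean()
        r_hand = np.sum((measured - mx) * (truth - my)) / np.sqrt(
            np.sum((measured - mx) ** 2) * np.sum((truth - my) ** 2)
        )
        res = pearson_validity(measured, truth)
        assert res.r == pytest.approx(r_hand, abs=1e-12)

    def test_affine_rescaling_invariance(self, rng):
        truth = rng.normal(size=40)
        measured = truth + rng.normal(scale=0.3, size=40)
        r0 = pearson_validity(measured, truth).r
        r1 = pearson_validity(3.2 * measured + 11.0, truth).r
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_validity(np.ones(5), np.arange(5.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            pearson_validity([1.0, 2.0], [1.0, 2.0])


class TestBlandAltman:
    def test_exact_constant_offset(self):
        truth = np.linspace(-30, 30, 20)
        res = bland_altman(truth + 5.0, truth)
        assert res.bias == pytest.approx(5.0)
        assert res.sd == 0.0
        assert res.loa == (pytest.approx(5.0), pytest.approx(5.0))
        assert res.fixed_bias and not res.proportional_bias
        assert classify_bias(res) == "fixed"

    def test_identical_methods_have_no_bias(self):
        truth = np.linspace(-30, 30, 20)
        res = bland_altman(truth, truth)
        assert res.bias == 0.0
        assert classify_bias(res) == "none"

    def test_monte_carlo_parameter_recovery(self, rng):
        # differences generated as N(bias=2, sd=1), n=200
        truth = np.linspace(-45, 45, 200)
        d = rng.normal(2.0, 1.0, 200)
        res = bland_altman(truth + d, truth)
        se = res.sd / np.sqrt(res.n)
        assert abs(res.bias - 2.0) < 2 * se
        width = res.loa[1] - res.loa[0]
        assert abs(width - 2 * 1.96 * 1.0) < 0.15 * 2 * 1.96
        assert res.fixed_bias and not res.proportional_bias

    def test_loa_coverage_is_nominal(self, rng):
        # ~95% of Gaussian differences fall inside the limits (binomial band)
        truth = np.zeros(2000) + np.arange(2000.0)
        res = bland_altman(truth + rng.normal(0.0, 1.0, 2000), truth)
        p = 0.95
        band = 3 * np.sqrt(p * (1 - p) / 2000)
        assert abs(res.inside_loa - p) < band + 0.005

    def test_proportional_bias_detected(self, rng):
        truth = np.linspace(-45, 45, 100)
        measured = truth + 0.1 * truth + rng.normal(0.0, 0.5, 100)
        res = bland_altman(measured, truth)
        assert res.proportional_bias
        assert res.slope == pytest.approx(0.1, abs=0.05)

    def test_bias_estimator_unbiased_over_replicates(self):
        # 500 seeded replicates (n=37, sd=1): mean recovered bias within 3 SE
        rng = np.random.default_rng(4415)
        truth = np.linspace(-90, 90, 37)
        biases = [
            bland_altman(truth + rng.normal(2.0, 1.0, 37), truth).bias
            for _ in range(500)
        ]
        se_mean = 1.0 / np.sqrt(37 * 500)
        assert abs(np.mean(biases) - 2.0) < 3 * se_mean


class TestClassify:
    @pytest.mark.parametrize(
        "fixed,proportional,label",
        [
            (False, False, "none"),
            (True, False, "fixed"),
            (False, True, "proportional"),
            (True, True, "fixed+proportional"),
        ],
    )
    def test_exhaustive_flag_mapping(self, fixed, proportional, label):
        res = BlandAltmanResult(
            bias=1.0, sd=1.0, loa=(-1.0, 3.0), fixed_bias=fixed,
            proportional_bias=proportional, slope=0.0, slope_p=1.0,
            inside_loa=0.95, n=10,
        )
        assert classify_bias(res) == label


class TestTTest:
    def test_identical_groups_not_significant(self):
        a = np.array([1.0, 2.0, 3.0])
        res = compare_peaks(a, a)
        assert res.t == pytest.approx(0.0)
        assert not res.significant
        assert res.df == 4

    def test_large_shift_significant(self):
        a = np.array([1.0, 2.0, 3.0])
        res = compare_peaks(a, a + 10.0)
        assert res.significant and res.p < 0.01

    def test_hand_computed_t_statistic(self):
        # worked pooled-variance example, computed by the textbook formula
        a = np.array([19.0, 22.0, 24.0, 27.0, 28.0])
        b = np.array([15.0, 18.0, 19.0, 22.0, 24.0])
        sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
            a.size + b.size - 2
        )
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
        res = compare_peaks(a, b)
        assert res.t == pytest.approx(t_hand, abs=1e-10)
        assert res.df == 8

    def test_degenerate_zero_variance(self):
        res = compare_peaks([5.0, 5.0], [5.0, 5.0])
        assert (res.t, res.p) == (0.0, 1.0)
        res2 = compare_peaks([5.0, 5.0], [7.0, 7.0])
        assert res2.p == 0.0 and np.isinf(res2.t)


class TestValidityReport:
    def test_row_bookkeeping(self, rng):
        truth = np.linspace(-90, 90, 37)
        cells = [
            (m, j, p, truth + rng.normal(0, 0.5, 37), truth)
            for m in ("new", "rizzoli")
            for j in ("Met_Hal", "Cal_Met")
            for p in ("frontal", "sagittal")
        ]
        table = validity_report(iter(cells))
        assert len(table) == 8
        assert set(table.columns) >= {"model", "joint", "plane", "r", "p", "bias",
                                      "loa_lower", "loa_upper", "bias_class"}
        assert (table["n"] == 37).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no validation cells"):
            validity_report(iter([]))
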