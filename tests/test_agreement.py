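"""Eight-variable summaries, Bland-Altman, phase bias, slice regression."""

import numpy as np
import pandas as pd
import pytest

from dectlung import (
    VARIABLES,
    CtVolume,
    bland_altman,
    classify_aeration,
    correlate_means,
    phase_bias,
    slice_position_regression,
    summarize_variables,
)
from dectlung.agreement import agreement_report
from dectlung.decomposition import FractionMaps


def make_fractions(f_gas, f_blood=None, spacing=(1.0, 1.0, 1.0)):
    f_gas = np.asarray(f_gas, dtype=float)
    f_blood = np.zeros_like(f_gas) if f_blood is None else np.asarray(f_blood, dtype=float)
    return FractionMaps(
        f_gas=f_gas,
        f_tissue=1.0 - f_gas - f_blood,
        f_blood=f_blood,
        mask=np.ones(f_gas.shape, bool),
        spacing=spacing,
    )


class TestSummarizeVariables:
    def test_uniform_phantom(self):
        shape = (4, 4, 2)
        f = make_fractions(np.full(shape, 0.6))
        merge = CtVolume(np.full(shape, -600.0), (1, 1, 1))
        labels = classify_aeration(f.f_gas, f.mask)
        v = summarize_variables(merge, f, labels, f.mask)
        assert v["ct_density_hu"] == pytest.approx(-600.0)
        assert v["fv_gas_pct"] == pytest.approx(60.0)
        assert v["fv_normally_aerated_pct"] == pytest.approx(100.0)

    def test_two_region_weighted_means(self):
        """30 voxels at 0.2 gas and 10 at 0.8: hand volume-weighted means."""
        f_gas = np.concatenate([np.full(30, 0.2), np.full(10, 0.8)]).reshape(40, 1, 1)
        f = make_fractions(f_gas)
        merge = CtVolume(np.where(f_gas < 0.5, -200.0, -800.0), (1, 1, 1))
        labels = classify_aeration(f.f_gas, f.mask)
        v = summarize_variables(merge, f, labels, f.mask)
        assert v["fv_gas_pct"] == pytest.approx((30 * 0.2 + 10 * 0.8) / 40 * 100)
        assert v["ct_density_hu"] == pytest.approx((30 * -200 + 10 * -800) / 40)
        assert v["fv_poorly_aerated_pct"] == pytest.approx(75.0)
        assert v["fv_normally_aerated_pct"] == pytest.approx(25.0)

    def test_material_fractions_sum_to_100(self):
        rng = np.random.default_rng(0)
        g = rng.uniform(0, 0.8, (5, 5, 2))
        b = rng.uniform(0, 0.2, (5, 5, 2))
        f = make_fractions(g, b)
        merge = CtVolume(np.zeros(g.shape), (1, 1, 1))
        labels = classify_aeration(f.f_gas, f.mask)
        v = summarize_variables(merge, f, labels, f.mask)
        total = v["fv_gas_pct"] + v["fv_soft_tissue_pct"] + v["fv_iodinated_blood_pct"]
        assert total == pytest.approx(100.0, abs=1e-6)


class TestBlandAltman:
    def test_identical_pairs(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        ba = bland_altman(x, x)
        assert ba.mean_diff == 0.0
        assert ba.loa_lower == 0.0 and ba.loa_upper == 0.0

    def test_hand_differences(self):
        """Differences {-1, 0, 1}: mean 0, SD 1, LoA +/- 1.96."""
        whole = np.array([10.0, 10.0, 10.0])
        dct = whole + np.array([-1.0, 0.0, 1.0])
        ba = bland_altman(dct, whole)
        assert ba.mean_diff == pytest.approx(0.0)
        assert ba.loa_lower == pytest.approx(-1.96)
        assert ba.loa_upper == pytest.approx(1.96)

    def test_ci_shrinks_with_n(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0, 1, 100)
        small = bland_altman(d[:10], np.zeros(10))
        # same empirical SD scale, larger n
        big = bland_altman(np.tile(d[:10], 10), np.zeros(100))
        width = lambda ci: ci[1] - ci[0]
        assert width(big.mean_diff_ci) < width(small.mean_diff_ci)
        assert width(big.loa_upper_ci) < width(small.loa_upper_ci)

    def test_ordering_invariant(self):
        rng = np.random.default_rng(2)
        ba = bland_altman(rng.normal(5, 2, 40), rng.normal(0, 2, 40))
        assert ba.loa_lower <= ba.mean_diff <= ba.loa_upper

    def test_loa_ci_uses_root_3_over_n(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0, 2, 25)
        ba = bland_altman(d, np.zeros(25))
        from scipy import stats

        half = stats.t.ppf(0.975, 24) * d.std(ddof=1) * np.sqrt(3 / 25)
        assert ba.loa_upper_ci[1] - ba.loa_upper == pytest.approx(half)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestCorrelateMeans:
    def test_perfect_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert correlate_means(2 * x + 1, x) == pytest.approx(1.0)

    def test_hand_pairs(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 5.0])
        # explicit product-moment formula as the oracle
        r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert correlate_means(x, y) == pytest.approx(r**2)

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=(2, 30))
        assert correlate_means(3 * x - 7, y) == pytest.approx(correlate_means(x, y))
        assert correlate_means(x, -2 * y + 1) == pytest.approx(correlate_means(x, y))


class TestPhaseBias:
    def _frame(self, exp_vals, insp_vals):
        rows = []
        for i, v in enumerate(exp_vals):
            rows.append({"condition": i, "phase": "expiratory", "ct_density_hu": v})
        for i, v in enumerate(insp_vals):
            rows.append({"condition": i, "phase": "inspiratory", "ct_density_hu": v})
        return pd.DataFrame(rows)

    def test_equal_biases_give_zero_difference(self):
        rep = phase_bias(self._frame([-3.0, -3.0], [-3.0, -3.0]))
        row = rep.loc["ct_density_hu"]
        assert row["difference_mean"] == 0.0
        assert row["difference_limit_low"] == 0.0 == row["difference_limit_high"]

    def test_hand_arithmetic(self):
        """Expiratory {-2,-2}, inspiratory {1,1}: difference mean 3, SD 0."""
        rep = phase_bias(self._frame([-2.0, -2.0], [1.0, 1.0]))
        row = rep.loc["ct_density_hu"]
        assert row["difference_mean"] == pytest.approx(3.0)
        assert row["expiratory_mean"] == pytest.approx(-2.0)
        assert row["inspiratory_sd"] == 0.0
        assert row["difference_limit_low"] == pytest.approx(3.0)

    def test_limits_widen_with_sd(self):
        narrow = phase_bias(self._frame([0.0, 0.0, 0.0], [1.0, 1.1, 0.9])).loc["ct_density_hu"]
        wide = phase_bias(self._frame([0.0, 0.0, 0.0], [1.0, 3.0, -1.0])).loc["ct_density_hu"]
        assert (wide["difference_limit_high"] - wide["difference_limit_low"]) > (
            narrow["difference_limit_high"] - narrow["difference_limit_low"]
        )

    def test_mismatched_phases_rejected(self):
        df = pd.DataFrame(
            [
                {"phase": "expiratory", "ct_density_hu": 1.0},
            ]
        )
        with pytest.raises(ValueError):
            phase_bias(df)


class TestSlicePositionRegression:
    def test_exact_linear_fit(self):
        """3 HU per mm of cranial distance across three 5-mm slices."""
        df = pd.DataFrame(
            {
                "offset_mm": [0.0, 5.0, 10.0] * 4,
                "ct_density_hu": [3.0 * o for o in [0.0, 5.0, 10.0] * 4],
            }
        )
        fit = slice_position_regression(df)
        assert fit.loc["ct_density_hu", "slope_per_mm"] == pytest.approx(3.0)
        assert fit.loc["ct_density_hu", "r2"] == pytest.approx(1.0)

    def test_constant_values_zero_slope(self):
        df = pd.DataFrame({"offset_mm": [0.0, 5.0, 10.0], "fv_gas_pct": [4.0, 4.0, 4.0]})
        fit = slice_position_regression(df)
        assert fit.loc["fv_gas_pct", "slope_per_mm"] == 0.0

    def test_matches_closed_form_least_squares(self):
        rng = np.random.default_rng(5)
        x = np.array([0.0, 5.0, 10.0] * 6)
        y = 0.4 * x + rng.normal(0, 1, x.size)
        df = pd.DataFrame({"offset_mm": x, "fv_gas_pct": y})
        fit = slice_position_regression(df)
        # closed-form OLS oracle
        b = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        ss_res = ((y - (y.mean() + b * (x - x.mean()))) ** 2).sum()
        r2 = 1 - ss_res / ((y - y.mean()) ** 2).sum()
        assert fit.loc["fv_gas_pct", "slope_per_mm"] == pytest.approx(b)
        assert fit.loc["fv_gas_pct", "r2"] == pytest.approx(r2)

    def test_single_offset_rejected(self):
        df = pd.DataFrame({"offset_mm": [0.0, 0.0], "fv_gas_pct": [1.0, 2.0]})
        with pytest.raises(ValueError):
            slice_position_regression(df)


class TestAgreementReport:
    def test_report_shape_and_ordering(self):
        rng = np.random.default_rng(6)
        whole = pd.DataFrame({v: rng.normal(50, 5, 12) for v in VARIABLES})
        dct = whole + rng.normal(0, 1, whole.shape)
        rep = agreement_report(dct, whole)
        assert list(rep.index) == list(VARIABLES)
        assert (rep["loa_lower"] <= rep["mean_diff"]).all()
        assert (rep["mean_diff"] <= rep["loa_upper"]).all()
        assert (rep["n"] == 12).all()
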