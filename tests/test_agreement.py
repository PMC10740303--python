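"""ICC(2,1), power, Bland–Altman, descriptive differences and calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sasmorph as sm
from sasmorph.phantom import RaterSimSpec


def anova_ms_oracle(x):
    """Hand-computed two-way mean squares via explicit sums (independent of
    the package's vectorized path)."""
    n, k = x.shape
    grand = sum(x.ravel()) / (n * k)
    msr = sum(k * (row.mean() - grand) ** 2 for row in x) / (n - 1)
    msc = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    return msr, msc, sse / ((n - 1) * (k - 1))


class TestAverageRepetitions:
    def test_arithmetic_mean(self):
        table = pd.DataFrame(
            {
                "subject_id": ["s1"] * 3,
                "rater": ["novice"] * 3,
                "position": ["seated"] * 3,
                "repetition": [1, 2, 3],
                "sas_mm": [11.0, 12.0, 13.0],
            }
        )
        out = sm.average_repetitions(table)
        assert len(out) == 1
        assert out["sas_mm"].iloc[0] == pytest.approx(12.0)

    def test_single_repetition_unchanged(self):
        table = pd.DataFrame(
            [("s1", "r1", "seated", 1, 9.7)],
            columns=["subject_id", "rater", "position", "repetition", "sas_mm"],
        )
        assert sm.average_repetitions(table)["sas_mm"].iloc[0] == 9.7

    def test_matches_groupby_oracle(self):
        table, _ = sm.simulate_measurements(RaterSimSpec(seed=5))
        out = sm.average_repetitions(table)
        for _, row in out.iterrows():
            cell = table[
                (table.subject_id == row.subject_id) & (table.rater == row.rater)
            ]["sas_mm"]
            assert row.sas_mm == pytest.approx(cell.mean(), abs=1e-12)

    def test_missing_value_reported(self):
        table = pd.DataFrame(
            [("s1", "r1", "seated", 1, np.nan)],
            columns=["subject_id", "rater", "position", "repetition", "sas_mm"],
        )
        with pytest.raises(ValueError, match="missing"):
            sm.average_repetitions(table)


class TestICC21:
    def test_identical_columns_perfect_agreement(self):
        x = np.column_stack([np.arange(8.0) + 10, np.arange(8.0) + 10])
        assert sm.icc_2_1(x).icc == pytest.approx(1.0)

    def test_offset_column_penalized_below_pearson(self):
        """Absolute agreement penalizes a constant bias; consistency
        (Pearson) does not."""
        a = np.array([10.0, 11.5, 9.0, 12.0, 10.5, 13.0])
        x = np.column_stack([a, a + 2.0])
        r = sm.icc_2_1(x)
        pearson = np.corrcoef(x[:, 0], x[:, 1])[0, 1]
        assert r.icc < 1.0
        assert r.icc < pearson

    def test_mean_squares_match_hand_oracle(self):
        rng = np.random.default_rng(2)
        for shape in [(6, 2), (18, 2), (7, 3)]:
            x = rng.normal(12, 2, shape)
            r = sm.icc_2_1(x)
            msr, msc, mse = anova_ms_oracle(x)
            assert r.ms_rows == pytest.approx(msr, abs=1e-10)
            assert r.ms_cols == pytest.approx(msc, abs=1e-10)
            assert r.ms_error == pytest.approx(mse, abs=1e-10)

    def test_matches_pingouin_point_and_ci(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        for n in (6, 18):
            x = rng.normal(11, 2, (n, 1)) + rng.normal(0, 1, (n, 2))
            df = pd.DataFrame(
                {
                    "subj": np.repeat(np.arange(n), 2),
                    "rater": np.tile(["a", "b"], n),
                    "y": x.ravel(),
                }
            )
            ref = pg.intraclass_corr(df, targets="subj", raters="rater", ratings="y")
            ref = ref.set_index("Type").loc["ICC(A,1)"]  # absolute-agreement single
            mine = sm.icc_2_1(x)
            assert mine.icc == pytest.approx(ref["ICC"], abs=1e-10)
            # pingouin rounds its CI bounds to two decimals
            assert mine.ci_low == pytest.approx(ref["CI95"][0], abs=6e-3)
            assert mine.ci_high == pytest.approx(ref["CI95"][1], abs=6e-3)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((10_000, 2))
        assert abs(sm.icc_2_1(x).icc) < 0.05

    def test_constant_matrix_rejected(self):
        with pytest.raises(ZeroDivisionError, match="constant"):
            sm.icc_2_1(np.full((6, 2), 7.0))

    def test_incomplete_matrix_rejected(self):
        x = np.random.default_rng(1).normal(size=(5, 2))
        x[2, 1] = np.nan
        with pytest.raises(ValueError, match="incomplete"):
            sm.icc_2_1(x)

    def test_ci_brackets_estimate_and_display_truncates(self):
        rng = np.random.default_rng(9)
        x = rng.normal(11, 0.3, (8, 1)) + rng.normal(0, 1.5, (8, 2))
        r = sm.icc_2_1(x)
        assert r.ci_low <= r.icc <= r.ci_high
        lo, hi = r.ci_display
        assert 0.0 <= lo <= hi <= 1.0

    def test_estimator_recovery_simulation(self):
        """Mean estimate within 0.03 of the implied ICC (500 tables each,
        n=18, k=2, true ICC 0.2/0.5/0.8)."""
        for target in (0.2, 0.5, 0.8):
            ests = []
            for i in range(500):
                spec = RaterSimSpec.for_population_icc(target, seed=i)
                table, implied = sm.simulate_measurements(spec)
                wide = sm.pivot_sources(sm.average_repetitions(table))
                ests.append(sm.icc_2_1(wide.to_numpy()).icc)
            assert abs(np.mean(ests) - target) < 0.03


class TestICCPower:
    @pytest.mark.parametrize(
        "rho,expected",
        [(0.74, 0.97), (0.63, 0.86), (0.21, 0.14), (0.23, 0.16),
         (0.27, 0.21), (0.34, 0.31), (0.25, 0.18), (0.36, 0.34),
         (0.45, 0.52), (0.49, 0.60)],
    )
    def test_two_rater_cohort_powers(self, rho, expected):
        """Post-hoc power at n=18, k=2, alpha=0.05 over the observed ICC
        range, to two decimals."""
        assert round(sm.icc_power(rho, n=18, k=2), 2) == pytest.approx(expected)

    def test_null_limit_equals_alpha(self):
        assert sm.icc_power(1e-12, n=18) == pytest.approx(0.05, abs=1e-3)
        assert sm.icc_power(0.0, n=18) == 0.05

    def test_strictly_increasing_in_effect_and_n(self):
        rhos = np.linspace(0.05, 0.95, 10)
        powers = [sm.icc_power(r, n=18) for r in rhos]
        assert np.all(np.diff(powers) > 0)
        ns = [6, 10, 18, 40, 100]
        powers_n = [sm.icc_power(0.5, n=n) for n in ns]
        assert np.all(np.diff(powers_n) > 0)

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            sm.icc_power(1.0, n=18)
        with pytest.raises(ValueError):
            sm.icc_power(0.5, n=3)

    def test_alternative_se_methods_available(self):
        p_default = sm.icc_power(0.5, n=18)
        p_classic = sm.icc_power(0.5, n=18, se_method="n_minus_3_2")
        p_genk = sm.icc_power(0.5, n=18, se_method="general_k")
        assert p_default != p_classic != p_genk
        for p in (p_default, p_classic, p_genk):
            assert 0 < p < 1


class TestBlandAltman:
    def test_identical_pairs(self):
        a = np.array([10.0, 11.0, 12.0, 13.0])
        r = sm.bland_altman(a, a)
        assert r.bias == 0 and r.loa_low == 0 and r.loa_high == 0

    def test_constant_offset(self):
        a = np.array([10.0, 11.0, 12.0])
        r = sm.bland_altman(a, a - 1.3)
        assert r.bias == pytest.approx(1.3)
        assert r.sd_diff == pytest.approx(0.0, abs=1e-12)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(4)
        a = rng.normal(12.4, 2.0, 18)
        b = rng.normal(11.0, 1.8, 18)
        r = sm.bland_altman(a, b)
        d = a - b
        assert r.bias == pytest.approx(d.mean(), abs=1e-12)
        assert r.sd_diff == pytest.approx(d.std(ddof=1), abs=1e-12)
        assert r.loa_low == pytest.approx(d.mean() - 1.96 * d.std(ddof=1), abs=1e-12)
        assert r.loa_high == pytest.approx(d.mean() + 1.96 * d.std(ddof=1), abs=1e-12)

    def test_orientation_antisymmetry(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(12, 2, 10), rng.normal(11, 2, 10)
        ab, ba = sm.bland_altman(a, b), sm.bland_altman(b, a)
        assert ab.bias == pytest.approx(-ba.bias)
        assert ab.loa_low == pytest.approx(-ba.loa_high)
        assert ab.loa_high == pytest.approx(-ba.loa_low)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="3 pairs"):
            sm.bland_altman([1.0, 2.0], [1.0, 2.0])


class TestDescribeDifferences:
    def test_extrema(self):
        a = np.array([10.3, 8.0, 13.6])
        b = np.array([10.0, 11.0, 12.0])  # |diffs| = 0.3, 3.0, 1.6
        r = sm.describe_differences(a, b)
        assert r.min_abs == pytest.approx(0.3)
        assert r.max_abs == pytest.approx(3.0)

    def test_identical_pairs_all_zero(self):
        a = np.array([9.0, 10.0, 11.0])
        r = sm.describe_differences(a, a)
        assert r.mean_abs == 0 and r.max_abs == 0 and r.mean_signed == 0

    def test_matches_brute_oracle(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(12, 2, 18), rng.normal(11, 2, 18)
        r = sm.describe_differences(a, b)
        assert r.mean_abs == pytest.approx(np.abs(a - b).mean(), abs=1e-12)
        assert r.sd_abs == pytest.approx(np.abs(a - b).std(ddof=1), abs=1e-12)
        assert r.mean_signed == pytest.approx((a - b).mean(), abs=1e-12)


class TestCalibrateRegression:
    def test_exact_linear_relation(self):
        x = np.array([8.0, 10.0, 12.0, 14.0])
        r = sm.calibrate_regression(x, 2 * x)
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(0.0, abs=1e-10)
        assert r.r2 == pytest.approx(1.0)
        assert r.rmse == pytest.approx(0.0, abs=1e-10)

    def test_constant_response(self):
        x = np.array([8.0, 10.0, 12.0, 14.0])
        r = sm.calibrate_regression(x, np.full(4, 9.5))
        assert r.slope == pytest.approx(0.0, abs=1e-12)
        assert r.r2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        us = rng.normal(12.4, 2.0, 18)
        mri = 4.86 + 0.37 * us + rng.normal(0, 1.0, 18)
        r = sm.calibrate_regression(us, mri)
        X = np.column_stack([np.ones(18), us])
        beta = np.linalg.solve(X.T @ X, X.T @ mri)
        assert r.intercept == pytest.approx(beta[0], abs=1e-10)
        assert r.slope == pytest.approx(beta[1], abs=1e-10)
        resid = mri - X @ beta
        assert r.rmse == pytest.approx(np.sqrt(resid @ resid / 16), abs=1e-10)
        ss_tot = np.sum((mri - mri.mean()) ** 2)
        assert r.r2 == pytest.approx(1 - resid @ resid / ss_tot, abs=1e-10)

    def test_zero_predictor_variance_rejected(self):
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            sm.calibrate_regression(np.full(5, 12.0), np.arange(5.0))


class TestClassifyICC:
    @pytest.mark.parametrize(
        "icc,label",
        [
            (0.74, "moderate"),
            (0.63, "moderate"),
            (0.21, "poor"),
            (0.49, "poor"),
            (0.94, "excellent"),
            (0.98, "excellent"),
            (0.83, "good"),
            (0.50, "moderate"),
            (0.75, "good"),
            (0.90, "good"),
            (0.91, "excellent"),
            (-0.2, "poor"),
        ],
    )
    def test_bands(self, icc, label):
        assert sm.classify_icc(icc) == label

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            sm.classify_icc(1.2)


class TestScaleEquivariance:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=0.1, max_value=50.0))
    def test_scaling_measurements(self, scale):
        """Multiplying all measurements by c leaves ICC, R^2 and the label
        unchanged; bias, LoA, RMSE and intercept scale by c."""
        rng = np.random.default_rng(12)
        x = rng.normal(12, 2, (10, 2))
        base_icc = sm.icc_2_1(x)
        base_ba = sm.bland_altman(x[:, 0], x[:, 1])
        base_reg = sm.calibrate_regression(x[:, 0], x[:, 1])
        s_icc = sm.icc_2_1(scale * x)
        s_ba = sm.bland_altman(scale * x[:, 0], scale * x[:, 1])
        s_reg = sm.calibrate_regression(scale * x[:, 0], scale * x[:, 1])
        assert s_icc.icc == pytest.approx(base_icc.icc, rel=1e-9)
        assert s_icc.classification == base_icc.classification
        assert s_ba.bias == pytest.approx(scale * base_ba.bias, rel=1e-9)
        assert s_ba.loa_high == pytest.approx(scale * base_ba.loa_high, rel=1e-9)
        assert s_reg.r2 == pytest.approx(base_reg.r2, rel=1e-9)
        assert s_reg.rmse == pytest.approx(scale * base_reg.rmse, rel=1e-9, abs=1e-12)
        assert s_reg.intercept == pytest.approx(
            scale * base_reg.intercept, rel=1e-9, abs=1e-12
        )
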