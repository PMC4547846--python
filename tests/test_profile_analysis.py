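"""Quantification stage: smoothing, pole fits, batching, regressions."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pom1grad.model_core import GradientProfile, InvalidParameterError, ModelParams
from pom1grad.profile_analysis import (
    AnalysisSettings,
    InsufficientDataError,
    analyze_table,
    bartlett_compare,
    bin_by_tea4,
    compare_exponential_powerlaw,
    cv_vs_distance,
    extract_pole_fit,
    fit_poles,
    power_law_summary,
    ratio_regression,
    smooth_profile,
    weighted_loglog_regression,
)
from pom1grad.synthetic_profiles import PopulationSpec, ProfileTable, sample_population


def _profile(fn, x=None):
    if x is None:
        x = np.arange(0.0, 4.001, 0.01)
    return GradientProfile(x, fn(x))


class TestSmoothProfile:
    def test_constant_unchanged(self):
        prof = _profile(lambda x: np.full_like(x, 2.0))
        out = smooth_profile(prof, 0.3)
        np.testing.assert_allclose(out.values, 2.0, rtol=1e-12)

    def test_pixel_window_is_identity(self):
        prof = _profile(lambda x: 1.0 / (1.0 + x) ** 2)
        out = smooth_profile(prof, 0.01)
        np.testing.assert_array_equal(out.values, prof.values)

    def test_linear_ramp_interior_unchanged(self):
        prof = _profile(lambda x: 5.0 - x)
        out = smooth_profile(prof, 0.3)
        np.testing.assert_allclose(out.values[20:-20], prof.values[20:-20],
                                   rtol=1e-12)

    def test_integral_preserved(self):
        prof = _profile(lambda x: 1.0 / (1.0 + x) ** 2)
        out = smooth_profile(prof, 0.3)
        assert out.total() == pytest.approx(prof.total(), rel=0.02)

    def test_window_errors(self):
        prof = _profile(lambda x: np.exp(-x))
        with pytest.raises(InvalidParameterError):
            smooth_profile(prof, 0.001)
        with pytest.raises(InvalidParameterError):
            smooth_profile(prof, 10.0)


class TestExtractPoleFit:
    def test_power_law_profile(self):
        """P = 1/(1+x)^2: amplitude ~ 1 at the pole, half-max crossing at
        x0 (sqrt 2 - 1) ~ 0.41421."""
        prof = _profile(lambda x: 1.0 / (1.0 + x) ** 2)
        fit = extract_pole_fit(prof, fraction=0.5, background=0.0,
                               amplitude_band=0.01)
        assert fit.amplitude == pytest.approx(1.0, abs=0.02)
        assert fit.decay_length == pytest.approx(np.sqrt(2) - 1, abs=0.02)
        assert not fit.censored

    def test_exponential_profile_1_over_e(self):
        prof = _profile(lambda x: np.exp(-x))
        fit = extract_pole_fit(prof, fraction=np.exp(-1), background=0.0,
                               amplitude_band=0.01)
        assert fit.decay_length == pytest.approx(1.0, abs=0.02)

    def test_all_background_censored(self):
        prof = _profile(lambda x: np.full_like(x, 0.2))
        fit = extract_pole_fit(prof, background=0.2)
        assert fit.amplitude == 0.0
        assert fit.censored and fit.decay_length is None

    def test_no_crossing_in_range_censored(self):
        prof = _profile(lambda x: 1.0 - 0.01 * x)  # barely decays
        fit = extract_pole_fit(prof, fraction=0.5, background=0.0)
        assert fit.censored

    def test_cortical_total_is_trapezoid(self):
        prof = _profile(lambda x: np.exp(-x))
        fit = extract_pole_fit(prof, background=0.0)
        assert fit.cortical_total == pytest.approx(
            np.trapezoid(prof.values, prof.positions), rel=1e-12
        )


def _fits_frame(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "cell_id": np.arange(n) // 4,
        "pole_id": np.arange(n) % 4,
        "amplitude": rng.lognormal(0, 0.3, n),
        "tea4_amplitude": rng.lognormal(0, 0.4, n),
        "decay_length": rng.lognormal(-0.5, 0.2, n),
        "cortical_total": rng.lognormal(0.2, 0.2, n),
        "censored": np.zeros(n, dtype=bool),
    })


class TestBinByTea4:
    def test_388_poles_in_20_batches_of_19_or_20(self):
        batches = bin_by_tea4(_fits_frame(388), 0.05)
        sizes = [b.member_count for b in batches]
        assert len(batches) == 20
        assert set(sizes) == {19, 20}
        assert sizes == sorted(sizes, reverse=True)  # larger batches first
        assert sum(sizes) == 388

    def test_100_poles_exactly_5_per_batch(self):
        batches = bin_by_tea4(_fits_frame(100), 0.05)
        assert [b.member_count for b in batches] == [5] * 20

    def test_batches_ordered_by_tea4(self):
        batches = bin_by_tea4(_fits_frame(388), 0.05)
        means = [b.tea4_mean for b in batches]
        assert means == sorted(means)

    def test_singleton_batches_flag_sem(self):
        batches = bin_by_tea4(_fits_frame(20), 0.05)
        assert all(b.member_count == 1 for b in batches)
        assert all(b.amplitude_sem == 0.0 for b in batches)

    def test_empty_table_rejected(self):
        with pytest.raises(InsufficientDataError):
            bin_by_tea4(_fits_frame(0), 0.05)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(n=st.integers(min_value=1, max_value=500))
    def test_partition_conserves_poles(self, n):
        batches = bin_by_tea4(_fits_frame(n), 0.05)
        sizes = [b.member_count for b in batches]
        assert sum(sizes) == n
        assert max(sizes) - min(sizes) <= 1


class TestWeightedLogLogRegression:
    def test_exact_power_law(self):
        x = np.geomspace(0.1, 10, 20)
        res = weighted_loglog_regression(x, 3.0 * x**-0.5)
        assert res.slope == pytest.approx(-0.5, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0)
        assert res.ci_2se[0] <= res.slope <= res.ci_2se[1]

    def test_matches_manual_wls(self):
        """Cross-check against the closed-form weighted normal equations."""
        rng = np.random.default_rng(7)
        x = np.geomspace(0.5, 20, 15)
        y = 2.0 * x**0.7 * np.exp(rng.normal(0, 0.05, x.size))
        sem = 0.05 * y
        res = weighted_loglog_regression(x, y, sem)
        w = (y * np.log(10) / sem) ** 2
        lx, ly = np.log10(x), np.log10(y)
        xb = np.sum(w * lx) / np.sum(w)
        yb = np.sum(w * ly) / np.sum(w)
        slope = np.sum(w * (lx - xb) * (ly - yb)) / np.sum(w * (lx - xb) ** 2)
        assert res.slope == pytest.approx(slope, rel=1e-10)
        se = np.sqrt(
            (np.sum(w * (ly - yb - slope * (lx - xb))**2) / (x.size - 2))
            / np.sum(w * (lx - xb) ** 2)
        )
        assert res.slope_se == pytest.approx(se, rel=1e-8)

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidParameterError, match="indices"):
            weighted_loglog_regression([1.0, -1.0, 2.0], [1.0, 1.0, 1.0])

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            weighted_loglog_regression([1.0, 2.0], [1.0, 2.0])

    def test_zero_sem_falls_back_to_equal_weights(self):
        x = np.geomspace(1, 10, 8)
        y = x**2.0
        with pytest.warns(UserWarning, match="equal weights"):
            res = weighted_loglog_regression(x, y, np.zeros_like(y))
        assert res.slope == pytest.approx(2.0, abs=1e-10)


class TestRatioRegression:
    def test_identity_with_amplitude_slope(self):
        """slope(log(P/T) vs log T) = slope(log P vs log T) - 1 exactly
        for equal-weight fits."""
        rng = np.random.default_rng(8)
        tea4 = rng.lognormal(0, 0.4, 50)
        pom1 = tea4**0.66 * np.exp(rng.normal(0, 0.1, 50))
        amp = weighted_loglog_regression(tea4, pom1)
        ratio = ratio_regression(pom1, tea4)
        assert ratio.slope == pytest.approx(amp.slope - 1.0, abs=1e-10)

    def test_proportional_data_zero_slope(self):
        tea4 = np.geomspace(0.5, 5, 12)
        res = ratio_regression(3.0 * tea4, tea4)
        assert res.slope == pytest.approx(0.0, abs=1e-10)


class TestCvVsDistance:
    def _table_from_profiles(self, profiles, x):
        rows = []
        for i, prof in enumerate(profiles):
            rows.append(pd.DataFrame({
                "cell_id": i, "pole_id": 0, "position_um": x,
                "pom1": prof, "tea4": np.exp(-0.5 * (x / 0.3) ** 2),
            }))
        return ProfileTable(pd.concat(rows, ignore_index=True),
                            pd.DataFrame({"cell_id": range(len(profiles))}))

    def test_identical_profiles_zero_cv(self):
        x = np.arange(0.0, 4.05, 0.1)
        table = self._table_from_profiles([1.0 / (1.0 + x) ** 2] * 12, x)
        cv = cv_vs_distance(table, background=0.0)
        np.testing.assert_allclose(cv["cv"].to_numpy(), 0.0, atol=1e-12)

    def test_exponential_family_constant_cv(self):
        """Common decay length, variable amplitude: SD/mean is x-independent."""
        x = np.arange(0.0, 4.05, 0.1)
        rng = np.random.default_rng(9)
        amps = rng.lognormal(0, 0.3, 15)
        table = self._table_from_profiles([a * np.exp(-x) for a in amps], x)
        cv = cv_vs_distance(table, background=0.0)["cv"].to_numpy()
        np.testing.assert_allclose(cv, cv[0], rtol=1e-8)

    def test_trans_family_cv_decreases(self):
        """Power-law steady states share the source-independent tail
        C/x^2, so pole variability fades with distance."""
        x = np.arange(0.0, 4.05, 0.1)
        rng = np.random.default_rng(10)
        profiles = []
        for S in rng.lognormal(np.log(2.0), 0.35, 20):
            p = ModelParams(D=1.0, alpha=0.45, source_strength=S)
            from pom1grad.model_core import analytic_steady_state
            profiles.append(analytic_steady_state(p, _Grid(x)).values)
        table = self._table_from_profiles(profiles, x)
        cv = cv_vs_distance(table, background=0.0)
        c = cv.set_index("position_um")["cv"]
        assert c.loc[2.0] < c.loc[0.0]

    def test_too_few_poles(self):
        x = np.arange(0.0, 4.05, 0.1)
        table = self._table_from_profiles([np.exp(-x)] * 3, x)
        with pytest.raises(InsufficientDataError):
            cv_vs_distance(table, background=0.0)


class TestCompareExponentialPowerLaw:
    def test_self_fit_power_law(self):
        prof = _profile(lambda x: 2.0 / (x + 0.8) ** 2)
        cmp = compare_exponential_powerlaw(prof)
        assert cmp.power_rms == pytest.approx(0.0, abs=1e-8)
        assert cmp.power_params[0] == pytest.approx(2.0, rel=1e-6)
        assert cmp.power_params[1] == pytest.approx(0.8, rel=1e-6)

    def test_self_fit_exponential(self):
        prof = _profile(lambda x: 1.5 * np.exp(-x / 0.7))
        cmp = compare_exponential_powerlaw(prof)
        assert cmp.exp_rms == pytest.approx(0.0, abs=1e-8)
        assert cmp.exp_params[1] == pytest.approx(0.7, rel=1e-6)

    def test_noisy_trans_profile_fits_equally_well(self):
        """Individual profiles constrain the functional form only weakly:
        over 0-2 um with 10% noise the residual ratio stays within 2x."""
        rng = np.random.default_rng(12)
        x = np.arange(0.0, 4.05, 0.1)
        y = 13.3 / (x + 2.37) ** 2 * rng.lognormal(0, 0.1, x.size)
        cmp = compare_exponential_powerlaw(GradientProfile(x, y))
        assert 0.5 < cmp.residual_ratio < 2.0


class TestPowerLawSummary:
    def test_recovers_known_parameters(self):
        prof = _profile(lambda x: 1.0 / (x + 1.0) ** 2)
        fit = power_law_summary(prof)
        assert fit.amplitude == pytest.approx(1.0, rel=1e-6)
        assert fit.decay_length == pytest.approx(np.sqrt(2) - 1, rel=1e-6)
        assert fit.cortical_total == pytest.approx(1.0, rel=1e-6)


class TestBartlettCompare:
    def test_sample_against_itself(self):
        rng = np.random.default_rng(13)
        a = rng.normal(0, 1, 50)
        stat, p = bartlett_compare(a, a)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_fourfold_variance_detected(self):
        """n = 100 per group, exact variance ratio 4: closed-form Bartlett
        statistic agrees and the chi-square tail is < 0.05."""
        rng = np.random.default_rng(14)
        a = rng.normal(0, 1, 100)
        b = 2.0 * (a - a.mean()) + a.mean()  # variance exactly 4x
        stat, p = bartlett_compare(a, b)
        # independent closed form: k groups, pooled variance, correction C
        n, va, vb = 100, np.var(a, ddof=1), np.var(b, ddof=1)
        sp2 = (va + vb) / 2
        num = (2 * n - 2) * np.log(sp2) - (n - 1) * (np.log(va) + np.log(vb))
        corr = 1 + (2 / (n - 1) - 1 / (2 * n - 2)) / (3 * 1)
        assert stat == pytest.approx(num / corr, rel=1e-10)
        from scipy.stats import chi2
        assert p == pytest.approx(chi2.sf(stat, 1), rel=1e-10)
        assert p < 0.05

    def test_sample_size_guard(self):
        with pytest.raises(InsufficientDataError):
            bartlett_compare([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_degenerate_variances(self):
        with pytest.raises(InvalidParameterError):
            bartlett_compare([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])


@pytest.fixture(scope="module")
def analysis():
    table = sample_population(PopulationSpec(seed=21))
    return analyze_table(table)


class TestAnalyzeTable:

    def test_ratio_identity_on_batches(self, analysis):
        """The ratio regression differs from the amplitude regression by
        exactly 1 in slope when both use equal weights."""
        ok = [b for b in analysis.batches if np.isfinite(b.decay_length_mean)]
        pom1 = [b.amplitude_mean for b in ok]
        tea4 = [b.tea4_mean for b in ok]
        amp = weighted_loglog_regression(tea4, pom1)
        ratio = ratio_regression(pom1, tea4)
        assert ratio.slope == pytest.approx(amp.slope - 1.0, abs=1e-10)

    def test_batch_partition_conserves_poles(self, analysis):
        assert sum(b.member_count for b in analysis.batches) == 388

    def test_regression_keys_present(self, analysis):
        assert set(analysis.regressions) == {
            "decay_length_vs_amplitude", "pom1_vs_tea4",
            "cortical_total_vs_amplitude", "ratio_vs_tea4",
        }

    def test_sublinear_pom1_vs_tea4(self, analysis):
        res = analysis.regressions["pom1_vs_tea4"]
        assert res.slope < 1.0
        assert res.p_value < 1e-6

    def test_misaligned_positions_rejected(self):
        from pom1grad.profile_analysis import AlignmentError

        x1 = np.arange(0.0, 4.05, 0.1)
        x2 = x1 + 0.05
        x2[0] = 0.0
        df = pd.concat([
            pd.DataFrame({"cell_id": 0, "pole_id": 0, "position_um": x1,
                          "pom1": np.exp(-x1), "tea4": np.exp(-x1)}),
            pd.DataFrame({"cell_id": 0, "pole_id": 1, "position_um": x2,
                          "pom1": np.exp(-x2), "tea4": np.exp(-x2)}),
        ], ignore_index=True)
        with pytest.raises(AlignmentError):
            fit_poles(ProfileTable(df, pd.DataFrame({"cell_id": [0]})))


class _Grid:
    def __init__(self, positions):
        self.positions = positions
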