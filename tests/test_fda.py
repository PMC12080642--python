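import warnings

import numpy as np
import pandas as pd
import pytest

from cptspect.fda import (
    BandTestResult,
    common_grid,
    freq_period_convert,
    pairwise_pointwise_ttest,
    pointwise_group_ftest,
    primary_band,
    smooth_spectrum,
    summarize_band,
)
from cptspect.spectral import Periodogram


def make_pg(x, y, pid="p"):
    return Periodogram(pid, np.asarray(x, float), np.asarray(y, float),
                       float(x[0]), float(x[-1]), 1.0)


def synthetic_cohort_spectra(rng, n_per_group, bump_groups=(), f0=0.063,
                             bump=5.0, groups=("HC", "PT"), n_points=120):
    """Smoothed spectra + covariates with an optional power bump at f0."""
    x = np.linspace(0.002, 0.106, n_points)
    spectra, rows = [], []
    for g in groups:
        for i in range(n_per_group):
            pid = f"{g}{i}"
            y = rng.chisquare(2, n_points) / 2  # white-noise-like power
            if g in bump_groups:
                y = y + bump * np.exp(-((x - f0) ** 2) / (2 * 0.004**2))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                spectra.append(smooth_spectrum(make_pg(x, y, pid), 30))
            rows.append(
                {
                    "participant_id": pid,
                    "group": g,
                    "age": float(rng.uniform(20, 60)),
                    "sex": "F" if rng.random() < 0.5 else "M",
                }
            )
    return spectra, pd.DataFrame(rows)


class TestSmoothing:
    def test_cubic_polynomial_reproduced_exactly(self):
        x = np.linspace(0.002, 0.106, 80)
        y = 4 * x**3 - 2 * x**2 + 0.5 * x + 1.0
        sm = smooth_spectrum(make_pg(x, y), 44)
        assert np.abs(sm.evaluate(x) - y).max() < 1e-8
        assert sm.n_basis == 48
        assert sm.n_interior_knots == 44

    def test_all_zero_power_gives_zero_smooth(self):
        x = np.linspace(0.002, 0.106, 80)
        sm = smooth_spectrum(make_pg(x, np.zeros_like(x)), 44)
        assert np.allclose(sm.evaluate(x), 0.0, atol=1e-12)

    def test_peak_location_preserved(self):
        x = np.linspace(0.002, 0.106, 120)
        y = np.exp(-((x - 0.06) ** 2) / (2 * 0.003**2))
        sm = smooth_spectrum(make_pg(x, y), 44)
        grid = np.linspace(x[0], x[-1], 500)
        peak = grid[np.argmax(sm.evaluate(grid))]
        assert abs(peak - 0.06) <= x[1] - x[0]

    def test_basis_reduced_when_points_scarce(self):
        x = np.linspace(0.002, 0.106, 30)
        y = np.ones_like(x)
        with pytest.warns(UserWarning):
            sm = smooth_spectrum(make_pg(x, y), 44)
        assert sm.reduced
        assert sm.n_basis <= 30

    def test_common_grid_is_intersection(self):
        a = make_pg(np.linspace(0.002, 0.10, 50), np.ones(50), "a")
        b = make_pg(np.linspace(0.004, 0.12, 50), np.ones(50), "b")
        g = common_grid([a, b], 100)
        assert g[0] == pytest.approx(0.004)
        assert g[-1] == pytest.approx(0.10)


class TestGroupFTest:
    def test_injected_band_detected(self):
        rng = np.random.default_rng(21)
        spectra, cov = synthetic_cohort_spectra(rng, 30, bump_groups=("PT",))
        res = pointwise_group_ftest(spectra, cov)
        assert any(lo <= 0.063 <= hi for lo, hi in res.bands)
        band = primary_band(res)
        assert band[0] <= 0.063 <= band[1]

    def test_null_flag_fraction_near_alpha(self):
        rng = np.random.default_rng(22)
        fractions = []
        for _ in range(60):
            spectra, cov = synthetic_cohort_spectra(rng, 15)
            res = pointwise_group_ftest(spectra, cov)
            fractions.append(res.significant.mean())
        assert np.mean(fractions) == pytest.approx(0.05, abs=0.025)

    def test_permuted_labels_lose_signal(self):
        rng = np.random.default_rng(23)
        spectra, cov = synthetic_cohort_spectra(rng, 25, bump_groups=("PT",))
        res_true = pointwise_group_ftest(spectra, cov)
        perm = cov.copy()
        perm["group"] = rng.permutation(perm["group"].to_numpy())
        res_perm = pointwise_group_ftest(spectra, perm)
        assert res_perm.significant.mean() < res_true.significant.mean()

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(24)
        spectra, cov = synthetic_cohort_spectra(rng, 10)
        cov["sex"] = "F"
        cov["age"] = 40.0  # age constant -> collinear with intercept
        with pytest.raises(ValueError):
            pointwise_group_ftest(spectra, cov)

    def test_single_group_rejected(self):
        rng = np.random.default_rng(25)
        spectra, cov = synthetic_cohort_spectra(rng, 10, groups=("HC",))
        with pytest.raises(ValueError):
            pointwise_group_ftest(spectra, cov)


class TestPairwiseTTest:
    def test_bonferroni_critical_never_below_uncorrected(self):
        rng = np.random.default_rng(31)
        spectra, cov = synthetic_cohort_spectra(rng, 12)
        tt = pairwise_pointwise_ttest(spectra, cov, ("HC", "PT"))
        assert tt["crit_bonferroni"] >= tt["crit_uncorrected"]

    def test_null_exceedance_near_alpha(self):
        rng = np.random.default_rng(32)
        rates = []
        for _ in range(60):
            spectra, cov = synthetic_cohort_spectra(rng, 15)
            tt = pairwise_pointwise_ttest(spectra, cov, ("HC", "PT"))
            rates.append(np.mean(np.abs(tt["t"]) > tt["crit_uncorrected"]))
        assert np.mean(rates) == pytest.approx(0.05, abs=0.03)

    def test_injected_group_separates_inside_band(self):
        rng = np.random.default_rng(33)
        spectra, cov = synthetic_cohort_spectra(rng, 30, bump_groups=("PT",))
        res = pointwise_group_ftest(spectra, cov)
        band = primary_band(res)
        tt = pairwise_pointwise_ttest(spectra, cov, ("PT", "HC"), band=band)
        assert np.max(tt["t"]) > tt["crit_bonferroni"]

    def test_band_restriction(self):
        rng = np.random.default_rng(34)
        spectra, cov = synthetic_cohort_spectra(rng, 10)
        tt = pairwise_pointwise_ttest(spectra, cov, ("HC", "PT"), band=(0.05, 0.07))
        assert tt["frequencies"][0] >= 0.05
        assert tt["frequencies"][-1] <= 0.07

    def test_missing_pair_rejected(self):
        rng = np.random.default_rng(35)
        spectra, cov = synthetic_cohort_spectra(rng, 10)
        with pytest.raises(ValueError):
            pairwise_pointwise_ttest(spectra, cov, ("HC", "ZZ"))


class TestBandSummary:
    def test_period_bounds_are_reciprocals(self):
        res = BandTestResult(
            frequencies=np.linspace(0.01, 0.1, 10),
            f_stat=np.zeros(10),
            f_crit=1.0,
            df_num=1,
            df_den=10,
            alpha=0.05,
            bands=[(0.049, 0.077)],
        )
        (slow, fast), = res.band_periods()
        assert slow == pytest.approx(1 / 0.049, abs=1e-9)
        assert fast == pytest.approx(1 / 0.077, abs=1e-9)
        assert slow == pytest.approx(20.41, abs=0.01)
        assert fast == pytest.approx(12.99, abs=0.01)

    def test_no_band_empty_summary(self):
        rng = np.random.default_rng(41)
        spectra, cov = synthetic_cohort_spectra(rng, 8)
        res = BandTestResult(
            frequencies=np.linspace(0.01, 0.1, 10),
            f_stat=np.zeros(10),
            f_crit=1.0,
            df_num=1,
            df_den=10,
            alpha=0.05,
            bands=[],
        )
        assert summarize_band(res, spectra, cov).empty

    def test_symmetric_null_groups_similar_means(self):
        rng = np.random.default_rng(42)
        spectra, cov = synthetic_cohort_spectra(rng, 40)
        res = pointwise_group_ftest(spectra, cov)
        res.bands = [(0.02, 0.09)]
        summary = summarize_band(res, spectra, cov)
        means = summary.set_index("group")["mean_power"]
        # power curves are iid across groups: means should be close
        assert abs(means["HC"] - means["PT"]) < 0.15

    def test_single_participant_groups_degenerate_mean(self):
        rng = np.random.default_rng(43)
        spectra, cov = synthetic_cohort_spectra(rng, 1)
        res = BandTestResult(
            frequencies=np.linspace(0.01, 0.1, 50),
            f_stat=np.zeros(50),
            f_crit=1.0,
            df_num=1,
            df_den=1,
            alpha=0.05,
            bands=[(0.02, 0.09)],
        )
        summary = summarize_band(res, spectra, cov)
        sel = (res.frequencies >= 0.02) & (res.frequencies <= 0.09)
        for _, row in summary.iterrows():
            s = next(x for x in spectra if x.participant_id.startswith(row["group"]))
            assert row["mean_power"] == pytest.approx(
                s.evaluate(res.frequencies[sel]).mean()
            )


class TestFreqPeriodConvert:
    def test_reference_band_equivalences(self):
        assert round(freq_period_convert(15.77), 3) == pytest.approx(0.063)
        assert round(freq_period_convert(20.24), 3) == pytest.approx(0.049)
        assert round(freq_period_convert(12.90), 3) == pytest.approx(0.078)

    def test_fixed_point(self):
        assert freq_period_convert(1.0) == 1.0

    def test_involution(self):
        for x in (0.049, 0.063, 0.077, 12.9, 20.24):
            assert freq_period_convert(freq_period_convert(x)) == pytest.approx(x)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            freq_period_convert(0.0)
        with pytest.raises(ValueError):
            freq_period_convert(-2.0)
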