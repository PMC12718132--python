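"""Log-normal brightness fitting, density correction and classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import smstoich as sm
from smstoich.exceptions import (
    DegenerateVarianceError,
    InsufficientDataError,
    InvalidParameterError,
)

from conftest import make_mixture_values


class TestHistogram:
    def test_unit_bins_aligned_to_integers(self):
        centers, counts = sm.brightness_histogram([2.2, 2.7, 3.1], bin_width=1)
        assert np.allclose(centers - 0.5, [2, 3])  # bins [2,3) and [3,4)
        assert counts.tolist() == [2, 1]

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.1, 1e4), min_size=1, max_size=200),
           st.floats(0.1, 10))
    def test_counts_are_conserved(self, values, bin_width):
        _, counts = sm.brightness_histogram(values, bin_width)
        assert counts.sum() == len(values)

    def test_sampling_consistency_with_density(self, rng):
        v = rng.lognormal(np.log(200), 0.35, 100_000)
        centers, counts = sm.brightness_histogram(v, bin_width=5.0)
        expected = v.size * 5.0 * stats.lognorm.pdf(centers, 0.35, scale=200.0)
        keep = expected > 10
        chi2 = (((counts - expected) ** 2) / expected)[keep].sum()
        assert stats.chi2.sf(chi2, df=int(keep.sum()) - 1) > 0.01

    def test_bad_bin_width(self):
        with pytest.raises(InvalidParameterError):
            sm.brightness_histogram([1.0, 2.0], bin_width=0.0)


class TestSingleLogNormal:
    def test_degenerate_sample_reports_geometric_mean(self):
        with pytest.raises(DegenerateVarianceError) as err:
            sm.fit_lognormal_single([150.0] * 20)
        assert err.value.geometric_mean == pytest.approx(150.0)

    def test_geometric_mean_recovery(self, rng):
        v = rng.lognormal(np.log(200), 0.35, 100_000)
        fit = sm.fit_lognormal_single(v)
        assert abs(fit.geometric_mean - 200) / 200 < 0.01

    def test_mle_matches_closed_form_log_moments(self, rng):
        """MLE of a log-normal is exactly the log-domain sample moments."""
        v = rng.lognormal(5.0, 0.5, 5000) + rng.random(5000)
        fit = sm.fit_lognormal_single(v)
        logs = np.log(v)
        assert fit.mu_log == pytest.approx(np.mean(logs), rel=1e-9)
        assert fit.sigma_log == pytest.approx(np.std(logs), rel=1e-9)
        assert fit.geometric_mean == pytest.approx(np.exp(np.mean(logs)),
                                                   rel=1e-9)

    def test_histogram_ls_agrees_with_mle(self, rng):
        v = rng.lognormal(np.log(300), 0.35, 10_000)
        mle = sm.fit_lognormal_single(v, fit_method="mle")
        hls = sm.fit_lognormal_single(v, fit_method="histogram_ls")
        assert abs(hls.geometric_mean - mle.geometric_mean) / mle.geometric_mean < 0.03

    def test_zeros_are_dropped_and_counted(self, rng):
        v = np.concatenate([rng.lognormal(5, 0.3, 500), np.zeros(7)])
        fit = sm.fit_lognormal_single(v)
        assert fit.n_dropped == 7 and fit.n == 500

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            sm.fit_lognormal_single([1.0, 2.0, 3.0])


class TestMixture:
    def test_pure_monomer_hits_boundary(self, rng):
        v = rng.lognormal(np.log(200), 0.35, 10_000)
        fit = sm.fit_lognormal_mixture(v)
        assert fit.monomer_fraction >= 0.95

    @pytest.mark.parametrize("f_true", [0.1, 0.5, 0.9])
    def test_fraction_recovery(self, f_true):
        rng = np.random.default_rng(100 + int(10 * f_true))
        v = make_mixture_values(rng, f_true, 10_000)
        fit = sm.fit_lognormal_mixture(v)
        assert abs(fit.monomer_fraction - f_true) <= 0.05
        assert fit.g2 == pytest.approx(2 * fit.g1)

    def test_unconstrained_recovers_component_ratio(self, rng):
        v = make_mixture_values(rng, 0.5, 20_000)
        fit = sm.fit_lognormal_mixture(v, constrain_ratio=False)
        assert fit.g2 / fit.g1 == pytest.approx(2.0, rel=0.1)

    def test_labeling_correction_recovers_fraction(self):
        """Incomplete labeling (p = 0.7) makes visible dimers a binomial mix
        of 1- and 2-fluorophore states; the corrected model recovers f."""
        rng = np.random.default_rng(55)
        p, f_true, n = 0.7, 0.5, 20_000
        is_mono = rng.random(n) < f_true
        active = np.where(
            is_mono, 1,
            1 + (rng.random(n) < (p * p) / (1 - (1 - p) ** 2)),
        )
        v = active * rng.lognormal(np.log(200), 0.35, n)
        fit = sm.fit_lognormal_mixture(v, labeling_efficiency=p)
        assert abs(fit.monomer_fraction - f_true) <= 0.1

    def test_needs_enough_values(self, rng):
        with pytest.raises(InsufficientDataError):
            sm.fit_lognormal_mixture(rng.lognormal(5, 0.3, 50))


class TestDensityRegression:
    def test_flat_data_returns_common_mean_exactly(self):
        res = sm.density_corrected_brightness(
            [(0.02, 300.0), (0.05, 300.0), (0.09, 300.0), (0.12, 300.0)]
        )
        assert res.slope == pytest.approx(0.0, abs=1e-9)
        assert res.intercept == pytest.approx(300.0, abs=1e-9)

    def test_interval_coverage(self):
        covered = 0
        for i in range(100):
            r = np.random.default_rng(i)
            rho = r.uniform(0.01, 0.12, 30)
            g = 250.0 + 500.0 * rho + r.normal(0, 10, 30)
            res = sm.DensityRegression().fit(rho, g).result_()
            lo, hi = res.intercept_ci
            covered += lo <= 250.0 <= hi
        assert covered >= 93

    def test_two_points_insufficient(self):
        with pytest.raises(InsufficientDataError):
            sm.density_corrected_brightness([(0.02, 300.0), (0.05, 310.0)])

    def test_identical_densities_rank_deficient(self):
        with pytest.raises(InvalidParameterError):
            sm.density_corrected_brightness(
                [(0.05, 300.0), (0.05, 310.0), (0.05, 320.0)]
            )

    def test_per_trial_grouping(self, rng):
        import pandas as pd
        rows = []
        for trial in ("a", "b"):
            rho = rng.uniform(0.01, 0.12, 10)
            rows.append(pd.DataFrame({
                "trial_id": trial, "density_per_um2": rho,
                "g_mean": 200 + 400 * rho + rng.normal(0, 5, 10),
            }))
        res = sm.density_corrected_brightness(pd.concat(rows),
                                              group_by_trial=True)
        assert {r.trial_id for r in res} == {"a", "b"}


class TestAssumptionChecks:
    def test_gaussian_equal_variance_goes_parametric(self):
        hits = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            groups = [r.normal(10, 2, 30), r.normal(12, 2, 30)]
            rep = sm.assumption_checks(groups)
            hits += rep["recommendation"] == "parametric"
        assert hits >= 45

    def test_heavy_skew_goes_rank(self):
        r = np.random.default_rng(1)
        groups = [np.exp(r.normal(0, 1.5, 60)), r.normal(5, 1, 60)]
        assert sm.assumption_checks(groups)["recommendation"] == "rank"

    def test_single_group_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            sm.assumption_checks([rng.normal(0, 1, 20)])

    def test_small_group_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            sm.assumption_checks([rng.normal(0, 1, 5), rng.normal(0, 1, 20)])


def _cohort(rng, gm, n_cells, sd=0.05):
    return np.exp(np.log(gm) + rng.normal(0, sd, n_cells))


class TestCompareStoichiometry:
    def test_monomer_sample_classified_monomer(self, rng):
        controls = {"monomer": _cohort(rng, 200, 73),
                    "dimer": _cohort(rng, 400, 75),
                    "trimer": _cohort(rng, 600, 68)}
        rep = sm.compare_stoichiometry(_cohort(rng, 200, 47), controls)
        assert rep["classification"] == "monomer"
        assert rep["posthoc_p"]["dimer"] < 0.05
        assert rep["posthoc_p"]["trimer"] < 0.05

    def test_dimer_sample_classified_dimer(self, rng):
        controls = {"monomer": _cohort(rng, 200, 73),
                    "dimer": _cohort(rng, 400, 75),
                    "trimer": _cohort(rng, 600, 68)}
        rep = sm.compare_stoichiometry(_cohort(rng, 400, 40), controls)
        assert rep["classification"] == "dimer"

    def test_identical_groups_are_indistinguishable(self, rng):
        controls = {k: _cohort(rng, 200, 25) for k in ("a", "b", "c")}
        rep = sm.compare_stoichiometry(_cohort(rng, 200, 25), controls)
        assert rep["classification"] == "indistinguishable-from-all"

    def test_rank_path_used_when_assumptions_fail(self):
        r = np.random.default_rng(7)
        controls = {"monomer": np.exp(r.normal(np.log(200), 0.05, 40)) ** 3,
                    "dimer": np.exp(r.normal(np.log(400), 0.05, 40)) ** 3}
        rep = sm.compare_stoichiometry(
            np.exp(r.normal(np.log(200), 0.05, 30)) ** 3, controls,
            log_transform=False,
        )
        assert rep["method"] == "kruskal+dunn"
        assert rep["classification"] == "monomer"

    def test_empty_group_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            sm.compare_stoichiometry(
                _cohort(rng, 200, 10),
                {"monomer": np.array([]), "dimer": _cohort(rng, 400, 10)},
            )


class TestBrightnessAdditivity:
    def test_nmer_geometric_mean_ratios(self):
        """Pure n-mer cohorts from the generator satisfy g_n / g_1 = n
        (full labeling, no bleaching)."""
        gms = {}
        for n_sub in (1, 2, 3):
            cfg = sm.SimConfig(
                oligomer_fractions={n_sub: 1.0}, labeling_efficiency=1.0,
                bleach_rate_per_s=0.0, cell_log_jitter_sd=0.0,
                frame_count=200, seed=40 + n_sub,
            )
            values, _ = sm.sample_cell_brightness(cfg)
            gms[n_sub] = sm.fit_lognormal_single(values).geometric_mean
        assert gms[2] / gms[1] == pytest.approx(2.0, rel=0.05)
        assert gms[3] / gms[1] == pytest.approx(3.0, rel=0.05)
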