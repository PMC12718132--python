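"""Ground-truth properties of the synthetic TIRF generator."""

import numpy as np
import pytest
from scipy import stats

import smstoich as sm
from smstoich.exceptions import InvalidParameterError
from smstoich.simulate import _draw_emitters


class TestFluorophoreIntensity:
    def test_zero_variance_is_degenerate_at_geometric_mean(self):
        out = sm.sample_fluorophore_intensity(np.log(100), 0.0, 5, seed=1)
        assert np.allclose(out, 100.0)

    def test_geometric_mean_converges(self):
        out = sm.sample_fluorophore_intensity(np.log(200), 0.3, 100_000, seed=2)
        gm = np.exp(np.mean(np.log(out)))
        assert abs(gm - 200) / 200 < 0.01

    def test_empty_request(self):
        assert sm.sample_fluorophore_intensity(np.log(100), 0.3, 0).size == 0

    def test_negative_sigma_rejected(self):
        with pytest.raises(InvalidParameterError):
            sm.sample_fluorophore_intensity(np.log(100), -0.1, 5)


class TestCellMovie:
    def test_no_emitters_gives_pure_background(self):
        cfg = sm.SimConfig(frame_count=3, height_px=32, width_px=32,
                           density_per_um2=0.0, background_photons=12.0,
                           read_noise_adu=0.0, shot_noise=False, seed=3)
        movie, truth = sm.simulate_cell_movie(cfg)
        expected_adu = 12.0 / cfg.gain_photons_per_adu
        assert np.allclose(movie.data, expected_adu)
        assert truth.n_emitters == 0

    def test_photon_conservation_single_spot(self, noiseless_config):
        """Noiseless rendering conserves emitted photons: the full frame
        recovers >= 99% and a 3-sigma disc matches the closed-form Gaussian
        disc integral 1 - exp(-r^2 / 2 sigma^2)."""
        cfg = noiseless_config.replace(density_per_um2=0.02, sigma_log=0.0,
                                       frame_count=2, seed=11)
        movie, truth = sm.simulate_cell_movie(cfg)
        vis = truth.visible()
        assert len(vis) > 0
        ps = cfg.pixel_size_um
        disc_mass = 1.0 - np.exp(-(3.0**2) / 2.0)  # analytic, ~0.9889
        for _, r in vis.iterrows():
            frame_ph = movie.to_photons(movie.data[int(r.frame)])
            assert frame_ph.sum() >= 0.99 * r.photons
            yy, xx = np.mgrid[0:frame_ph.shape[0], 0:frame_ph.shape[1]]
            d2 = ((xx + 0.5) * ps - r.x_um) ** 2 + ((yy + 0.5) * ps - r.y_um) ** 2
            in_disc = d2 <= (3 * cfg.psf_sigma_um) ** 2
            observed = frame_ph[in_disc].sum() / r.photons
            assert observed == pytest.approx(disc_mass, abs=0.01)

    def test_emitter_count_expectation(self):
        counts = []
        for seed in range(40):
            cfg = sm.SimConfig(frame_count=1, height_px=250, width_px=250,
                               pixel_size_um=0.084, density_per_um2=0.06,
                               seed=seed)
            _, _, labeled = _draw_emitters(cfg, np.random.default_rng(seed))
            counts.append(labeled.size)
        expected = 0.06 * (250 * 0.084) ** 2
        se = np.sqrt(expected / len(counts))
        assert abs(np.mean(counts) - expected) < 4 * se

    def test_seed_reproducibility(self):
        cfg = sm.SimConfig(frame_count=3, height_px=48, width_px=48, seed=9)
        m1, t1 = sm.simulate_cell_movie(cfg)
        m2, t2 = sm.simulate_cell_movie(cfg)
        assert np.array_equal(m1.data, m2.data)
        assert t1.table.equals(t2.table)

    def test_active_fluorophores_non_increasing(self):
        cfg = sm.SimConfig(frame_count=50, height_px=64, width_px=64,
                           density_per_um2=0.1, bleach_rate_per_s=1.0,
                           oligomer_fractions={3: 1.0}, seed=4)
        _, truth = sm.simulate_cell_movie(cfg)
        for _, tab in truth.table.groupby("emitter_id"):
            active = tab.sort_values("frame")["active_fluors"].to_numpy()
            assert (np.diff(active) <= 0).all()
            assert active.max() <= 3

    def test_labeling_is_binomial(self):
        """Labeled-fluorophore counts of trimers follow Binomial(3, p)."""
        cfg = sm.SimConfig(height_px=1000, width_px=1000, density_per_um2=1.5,
                           oligomer_fractions={3: 1.0},
                           labeling_efficiency=0.8, seed=5)
        _, _, labeled = _draw_emitters(cfg, np.random.default_rng(5))
        assert labeled.size > 8000
        observed = np.bincount(labeled, minlength=4)
        expected = labeled.size * stats.binom.pmf(np.arange(4), 3, 0.8)
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=3) > 0.01

    def test_zero_area_rejected(self):
        with pytest.raises(InvalidParameterError):
            sm.SimConfig(height_px=0, width_px=10)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(InvalidParameterError):
            sm.SimConfig(oligomer_fractions={1: 0.6, 2: 0.6})


class TestFastBrightnessSampler:
    def test_matches_movie_generative_law(self):
        """The detection-level sampler reproduces the n-mer brightness law:
        geometric mean n * exp(mu_log) for a pure n-mer population."""
        for n_sub, expect in ((1, 200.0), (2, 400.0)):
            cfg = sm.SimConfig(oligomer_fractions={n_sub: 1.0},
                               labeling_efficiency=1.0, bleach_rate_per_s=0.0,
                               cell_log_jitter_sd=0.0, seed=21 + n_sub)
            values, density = sm.sample_cell_brightness(cfg)
            gm = np.exp(np.mean(np.log(values)))
            assert abs(gm - expect) / expect < 0.03
            assert density == pytest.approx(
                len(values) / (cfg.frame_count * cfg.area_um2)
            )


class TestMixtureDataset:
    def test_pure_monomer_ratio(self):
        cfg = sm.SimConfig(frame_count=2, height_px=48, width_px=48,
                           density_per_um2=0.2)
        ds = sm.simulate_mixture_dataset([(1.0, 0.0)], 2, cfg, seed=1)
        for _, truth in ds[(1.0, 0.0)]:
            assert (truth.table["n_subunits"] == 1).all()

    def test_four_cohorts_with_labels(self):
        cfg = sm.SimConfig(frame_count=1, height_px=32, width_px=32)
        ratios = [(0.9, 0.1), (0.8, 0.2), (0.6, 0.4), (0.5, 0.5)]
        ds = sm.simulate_mixture_dataset(ratios, 1, cfg, seed=1,
                                         render_movies=False)
        assert set(ds) == set(ratios)

    def test_mean_brightness_scales_with_dimer_fraction(self):
        """With full labeling and no bleaching, the arithmetic-mean
        brightness scales as (1 + dimer_fraction)."""
        cfg = sm.SimConfig(frame_count=100, density_per_um2=0.12,
                           labeling_efficiency=1.0, bleach_rate_per_s=0.0,
                           cell_log_jitter_sd=0.0)
        means = {}
        for ratio in [(1.0, 0.0), (0.5, 0.5)]:
            ds = sm.simulate_mixture_dataset([ratio], 6, cfg, seed=3,
                                             render_movies=False)
            means[ratio] = np.mean(np.concatenate(
                [vals for vals, _, _ in ds[ratio]]
            ))
        observed = means[(0.5, 0.5)] / means[(1.0, 0.0)]
        assert abs(observed - 1.5) < 0.08

    def test_invalid_ratio_rejected(self):
        cfg = sm.SimConfig(frame_count=1, height_px=16, width_px=16)
        with pytest.raises(InvalidParameterError):
            sm.simulate_mixture_dataset([(1.2, -0.2)], 1, cfg)


class TestBleachTrace:
    def test_noiseless_staircase_levels(self):
        t, y, steps = sm.simulate_bleach_trace(3, 150.0, 0.5, 0.05, 40.0,
                                               noise_sd=0.0, seed=8)
        levels = np.unique(y)
        assert set(levels).issubset({0.0, 150.0, 300.0, 450.0})
        assert y[0] == 450.0 and y[-1] == 0.0

    def test_single_fluor_single_step(self):
        t, y, steps = sm.simulate_bleach_trace(1, 100.0, 0.5, 0.05, 40.0,
                                               noise_sd=0.0, seed=2)
        drops = np.flatnonzero(np.diff(y) < 0)
        assert drops.size == 1 and steps.size == 1

    def test_first_bleach_time_is_min_of_exponentials(self):
        """Mean first-bleach time of a trimer is 1/(3*rate)."""
        rate = 1.0
        firsts = [
            sm.simulate_bleach_trace(3, 100.0, rate, 0.1, 20.0, seed=s)[2][0]
            for s in range(3000)
        ]
        expected = 1.0 / (3 * rate)
        se = expected / np.sqrt(len(firsts))
        assert abs(np.mean(firsts) - expected) < 4 * se

    def test_bad_dt_rejected(self):
        with pytest.raises(InvalidParameterError):
            sm.simulate_bleach_trace(2, 100.0, 0.5, 10.0, 5.0)


class TestMovieIO:
    def test_tiff_roundtrip(self, tmp_path):
        cfg = sm.SimConfig(frame_count=2, height_px=24, width_px=24, seed=6)
        movie, _ = sm.simulate_cell_movie(cfg)
        path = movie.write_tiff(tmp_path / "m.tif")
        back = sm.Movie.read_tiff(path)
        assert back.data.shape == movie.data.shape
        assert back.pixel_size_um == movie.pixel_size_um
        assert np.allclose(back.data, np.clip(np.round(movie.data), 0, 65535))
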