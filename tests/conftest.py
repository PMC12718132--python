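import numpy as np
import pytest

import smstoich as sm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_config():
    """Small noiseless movie configuration with well-separated immobile spots."""
    return sm.SimConfig(
        frame_count=4, height_px=128, width_px=128,
        density_per_um2=0.05, background_photons=0.0, read_noise_adu=0.0,
        shot_noise=False, bleach_rate_per_s=0.0, diffusion_um2_per_s=0.0,
        labeling_efficiency=1.0, cell_log_jitter_sd=0.0,
        min_separation_um=1.0, seed=7,
    )


def make_mixture_values(rng, f_monomer, n, g1=200.0, sigma=0.35):
    """Draw brightness values from a monomer/dimer log-normal mixture with
    the dimer geometric mean at twice the monomer one."""
    is_mono = rng.random(n) < f_monomer
    mono = rng.lognormal(np.log(g1), sigma, n)
    dim = rng.lognormal(np.log(2 * g1), sigma, n)
    return np.where(is_mono, mono, dim)


def match_localizations(truth_frame, locs_frame, pixel_size_um, radius_px=1.0):
    """Greedy nearest matching of ground-truth emitters to localizations.

    Returns (matches, n_unmatched_truth, n_unmatched_locs); each match is
    (truth_row, localization, distance_px).
    """
    remaining = list(locs_frame)
    matches = []
    unmatched = 0
    for _, r in truth_frame.iterrows():
        if not remaining:
            unmatched += 1
            continue
        d2 = [(l.x_um - r.x_um) ** 2 + (l.y_um - r.y_um) ** 2 for l in remaining]
        i = int(np.argmin(d2))
        d_px = np.sqrt(d2[i]) / pixel_size_um
        if d_px <= radius_px:
            matches.append((r, remaining.pop(i), d_px))
        else:
            unmatched += 1
    return matches, unmatched, len(remaining)
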