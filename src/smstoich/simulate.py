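"""Synthetic TIRF data generator with full ground truth.

Emulates the statistical structure single-molecule brightness stoichiometry
analysis relies on: sparse diffraction-limited emitters on a membrane,
oligomer-dependent log-normal brightness, incomplete fluorophore labeling,
stepwise photobleaching, Brownian lateral diffusion, and camera noise with an
ADU/photon gain.

Model
-----
Each emitter is an n-mer whose subunits independently carry a matured
fluorophore with probability ``labeling_efficiency``. Labeled fluorophores
bleach independently with exponential lifetimes. The per-frame intensity
fluctuation (motion of the complex through the evanescent field) is a single
log-normal factor drawn per emitter per frame and shared by all fluorophores
of that complex, so an emitter with m active fluorophores emits
``m * LogNormal(mu_log, sigma_log)`` photons in a frame. The brightness of a
pure n-mer population is therefore exactly log-normal with geometric mean
``n * exp(mu_log)`` — the model the downstream one- and two-component
log-normal fits assume.

The PSF is a symmetric 2-D Gaussian integrated over pixel areas and truncated
at 5 sigma. Continuous positions are in micrometres with the origin at the
outer corner of pixel (0, 0); a spot at the centre of pixel i has coordinate
``(i + 0.5) * pixel_size_um``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import erf

from .exceptions import InvalidParameterError
from .movie import ADU_CONVENTIONS, Movie

__all__ = [
    "SimConfig",
    "GroundTruth",
    "sample_fluorophore_intensity",
    "simulate_cell_movie",
    "sample_cell_brightness",
    "simulate_mixture_dataset",
    "simulate_bleach_trace",
]


@dataclass
class SimConfig:
    """Acquisition and sample parameters for one synthetic cell movie.

    Defaults reproduce the imaging conditions of the brightness assay:
    250x250 px frames, 84 nm pixels, 50 ms exposure, a 20 s analysis window
    (400 frames), ~0.06 emitters/um^2, and a 0.22 photons/ADU camera gain.
    """

    frame_count: int = 400
    height_px: int = 250
    width_px: int = 250
    pixel_size_um: float = 0.084
    exposure_s: float = 0.05
    psf_sigma_um: float = 0.125
    density_per_um2: float = 0.06
    oligomer_fractions: dict[int, float] = field(default_factory=lambda: {1: 1.0})
    labeling_efficiency: float = 0.8
    mu_log: float = float(np.log(200.0))  # GM of single-fluorophore photons/frame
    sigma_log: float = 0.35
    bleach_rate_per_s: float = 0.01  # lifetime >> 20 s analysis window
    diffusion_um2_per_s: float = 0.1
    background_photons: float = 10.0
    read_noise_adu: float = 7.0
    gain_photons_per_adu: float = 0.22
    adu_convention: str = "photons_per_adu"
    shot_noise: bool = True
    cell_log_jitter_sd: float = 0.05  # cell-to-cell illumination/expression spread
    min_separation_um: float = 0.0  # hard-core distance between initial positions
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_count < 1:
            raise InvalidParameterError("frame_count must be >= 1")
        if self.height_px < 1 or self.width_px < 1:
            raise InvalidParameterError("frame must have a positive area")
        for name in ("pixel_size_um", "exposure_s", "psf_sigma_um",
                     "gain_photons_per_adu"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        for name in ("density_per_um2", "bleach_rate_per_s",
                     "diffusion_um2_per_s", "background_photons",
                     "read_noise_adu", "sigma_log", "cell_log_jitter_sd",
                     "min_separation_um"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be nonnegative")
        if not 0.0 <= self.labeling_efficiency <= 1.0:
            raise InvalidParameterError("labeling_efficiency must be in [0, 1]")
        total = sum(self.oligomer_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidParameterError(
                f"oligomer_fractions must sum to 1 (got {total})"
            )
        if any(n < 1 or f < 0 for n, f in self.oligomer_fractions.items()):
            raise InvalidParameterError("oligomer_fractions keys >= 1, values >= 0")
        if self.adu_convention not in ADU_CONVENTIONS:
            raise InvalidParameterError(
                f"adu_convention must be one of {ADU_CONVENTIONS}"
            )

    @property
    def area_um2(self) -> float:
        return self.height_px * self.width_px * self.pixel_size_um**2

    def replace(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["oligomer_fractions"] = {str(k): v for k, v in d["oligomer_fractions"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "oligomer_fractions" in d:
            d["oligomer_fractions"] = {
                int(k): float(v) for k, v in d["oligomer_fractions"].items()
            }
        return cls(**d)


@dataclass
class GroundTruth:
    """Per-emitter, per-frame truth table for one simulated movie.

    ``table`` columns: emitter_id, frame, x_um, y_um, n_subunits,
    active_fluors, photons. Only frames where the emitter has at least one
    labeled fluorophore at frame 0 appear; ``active_fluors`` may reach 0 as
    fluorophores bleach and is non-increasing per emitter.
    """

    table: pd.DataFrame
    config: SimConfig

    COLUMNS = ("emitter_id", "frame", "x_um", "y_um",
               "n_subunits", "active_fluors", "photons")

    @property
    def n_emitters(self) -> int:
        return self.table["emitter_id"].nunique() if len(self.table) else 0

    def frame_table(self, frame: int) -> pd.DataFrame:
        return self.table[self.table["frame"] == frame]

    def visible(self) -> pd.DataFrame:
        """Rows where at least one fluorophore is emitting."""
        return self.table[self.table["active_fluors"] > 0]

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path

    @classmethod
    def read_csv(cls, path: str | Path, config: SimConfig | None = None) -> "GroundTruth":
        return cls(pd.read_csv(path), config or SimConfig())


# --------------------------------------------------------------------------
def sample_fluorophore_intensity(
    mu_log: float, sigma_log: float, n: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw ``n`` single-fluorophore photon rates from a log-normal law.

    The population geometric mean converges to ``exp(mu_log)``;
    ``sigma_log = 0`` is the degenerate law concentrated at ``exp(mu_log)``.
    """
    if sigma_log < 0:
        raise InvalidParameterError("sigma_log must be nonnegative")
    if n < 0:
        raise InvalidParameterError("n must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n == 0:
        return np.empty(0)
    return rng.lognormal(mean=mu_log, sigma=sigma_log, size=n)


def _render_integrated_gaussian(
    image: np.ndarray, x_um: np.ndarray, y_um: np.ndarray,
    photons: np.ndarray, sigma_um: float, pixel_size_um: float,
) -> None:
    """Add pixel-integrated 2-D Gaussian spots to ``image`` (photons), in place.

    Truncated at 5 sigma; the integral over the full plane equals ``photons``.
    """
    h, w = image.shape
    ps = pixel_size_um
    half = int(np.ceil(5.0 * sigma_um / ps))
    s = sigma_um * np.sqrt(2.0)
    for x0, y0, nph in zip(x_um, y_um, photons):
        cx = int(x0 / ps)
        cy = int(y0 / ps)
        x_lo, x_hi = max(0, cx - half), min(w, cx + half + 1)
        y_lo, y_hi = max(0, cy - half), min(h, cy + half + 1)
        if x_lo >= x_hi or y_lo >= y_hi:
            continue
        xe = np.arange(x_lo, x_hi + 1) * ps
        ye = np.arange(y_lo, y_hi + 1) * ps
        fx = 0.5 * erf((xe - x0) / s)
        fy = 0.5 * erf((ye - y0) / s)
        image[y_lo:y_hi, x_lo:x_hi] += nph * np.outer(np.diff(fy), np.diff(fx))


def _draw_emitters(config: SimConfig, rng: np.random.Generator):
    """Sample emitter count, oligomer sizes, labeled-fluorophore counts and
    per-fluorophore bleach times."""
    n_emitters = rng.poisson(config.density_per_um2 * config.area_um2)
    sizes = np.array(sorted(config.oligomer_fractions), dtype=int)
    probs = np.array([config.oligomer_fractions[s] for s in sizes], dtype=float)
    probs = probs / probs.sum()
    n_subunits = rng.choice(sizes, size=n_emitters, p=probs) if n_emitters else np.empty(0, int)
    labeled = rng.binomial(n_subunits, config.labeling_efficiency) if n_emitters else np.empty(0, int)
    return n_emitters, n_subunits, labeled


def _bleach_times(labeled: np.ndarray, rate: float, rng: np.random.Generator):
    """List of sorted bleach-time arrays, one per emitter (inf if no bleaching)."""
    out = []
    for m in labeled:
        if m == 0:
            out.append(np.empty(0))
        elif rate > 0:
            out.append(np.sort(rng.exponential(1.0 / rate, size=m)))
        else:
            out.append(np.full(m, np.inf))
    return out


def simulate_cell_movie(config: SimConfig) -> tuple[Movie, GroundTruth]:
    """Render one synthetic cell movie and its ground-truth table.

    Pixel values are ``Poisson(background + rendered PSFs)`` photons converted
    to ADU by the camera gain, plus Gaussian read noise; fully reproducible
    from ``config.seed``. With ``shot_noise=False`` and zero read noise the
    frames are the noiseless expectations (useful for oracle tests).
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.height_px, config.width_px
    n_frames = config.frame_count
    dt = config.exposure_s
    lx = w * config.pixel_size_um
    ly = h * config.pixel_size_um

    n_emitters, n_subunits, labeled = _draw_emitters(config, rng)
    bleach = _bleach_times(labeled, config.bleach_rate_per_s, rng)
    mu_cell = config.mu_log + (
        rng.normal(0.0, config.cell_log_jitter_sd) if config.cell_log_jitter_sd else 0.0
    )

    # trajectories: free 2-D Brownian motion, reflecting boundaries
    x, y = _initial_positions(n_emitters, lx, ly,
                              config.min_separation_um, rng)
    step_sd = np.sqrt(2.0 * config.diffusion_um2_per_s * dt)

    records: list[tuple] = []
    frames = np.zeros((n_frames, h, w))
    for k in range(n_frames):
        if k > 0 and step_sd > 0 and n_emitters:
            x = _reflect(x + rng.normal(0.0, step_sd, n_emitters), lx)
            y = _reflect(y + rng.normal(0.0, step_sd, n_emitters), ly)
        t_mid = (k + 0.5) * dt
        active = np.array(
            [int(np.searchsorted(b, t_mid)) for b in bleach], dtype=int
        )
        active = labeled - active if n_emitters else active
        lum = rng.lognormal(mu_cell, config.sigma_log, size=n_emitters) if n_emitters else np.empty(0)
        photons = active * lum
        emitting = photons > 0
        if emitting.any():
            _render_integrated_gaussian(
                frames[k], x[emitting], y[emitting], photons[emitting],
                config.psf_sigma_um, config.pixel_size_um,
            )
        for i in np.flatnonzero(labeled > 0):
            records.append((i, k, x[i], y[i], int(n_subunits[i]),
                            int(active[i]), float(photons[i])))

    expected = frames + config.background_photons
    if config.shot_noise:
        counts = rng.poisson(expected).astype(float)
    else:
        counts = expected
    if config.adu_convention == "photons_per_adu":
        adu = counts / config.gain_photons_per_adu
    else:
        adu = counts * config.gain_photons_per_adu
    if config.read_noise_adu > 0:
        adu = adu + rng.normal(0.0, config.read_noise_adu, size=adu.shape)

    movie = Movie(
        data=adu,
        pixel_size_um=config.pixel_size_um,
        exposure_s=config.exposure_s,
        gain_photons_per_adu=config.gain_photons_per_adu,
        adu_convention=config.adu_convention,
        metadata={"simulated": True, "seed": config.seed},
    )
    table = pd.DataFrame(records, columns=list(GroundTruth.COLUMNS))
    return movie, GroundTruth(table=table, config=config)


def _initial_positions(n: int, lx: float, ly: float, min_sep: float,
                       rng: np.random.Generator):
    """Uniform positions; with ``min_sep`` > 0, a hard-core (dart-throwing)
    layout useful for well-separated control spots."""
    if min_sep <= 0 or n == 0:
        return rng.uniform(0.0, lx, size=n), rng.uniform(0.0, ly, size=n)
    # keep a half-separation margin from the frame edges so every control
    # spot has a full fitting window
    m = min(min_sep / 2.0, lx / 4.0, ly / 4.0)
    xs: list[float] = []
    ys: list[float] = []
    for _ in range(n):
        for _attempt in range(1000):
            cx, cy = rng.uniform(m, lx - m), rng.uniform(m, ly - m)
            if all((cx - px) ** 2 + (cy - py) ** 2 >= min_sep**2
                   for px, py in zip(xs, ys)):
                xs.append(cx)
                ys.append(cy)
                break
        else:
            raise InvalidParameterError(
                "cannot place emitters with the requested min_separation_um"
            )
    return np.asarray(xs), np.asarray(ys)


def _reflect(v: np.ndarray, upper: float) -> np.ndarray:
    """Reflect coordinates into [0, upper] (handles multiple bounces)."""
    period = 2.0 * upper
    v = np.mod(v, period)
    return np.where(v > upper, period - v, v)


def sample_cell_brightness(
    config: SimConfig, rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, float]:
    """Draw the detection-level brightness sample of one cell without
    rendering frames.

    Returns ``(values, density)`` where ``values`` are per-detection photon
    counts (one per visible emitter per frame, the quantity spot integration
    estimates) and ``density`` is visible detections per um^2 per frame.
    This is the generative model of :func:`simulate_cell_movie` with the
    optics and camera stripped away; it is the fast path for replicate-level
    statistical experiments.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    n_emitters, n_subunits, labeled = _draw_emitters(config, rng)
    bleach = _bleach_times(labeled, config.bleach_rate_per_s, rng)
    mu_cell = config.mu_log + (
        rng.normal(0.0, config.cell_log_jitter_sd) if config.cell_log_jitter_sd else 0.0
    )
    dt = config.exposure_s
    t_mid = (np.arange(config.frame_count) + 0.5) * dt
    values = []
    n_visible = 0
    for i in range(n_emitters):
        if labeled[i] == 0:
            continue
        active = labeled[i] - np.searchsorted(bleach[i], t_mid)
        vis = active > 0
        m = int(vis.sum())
        if m == 0:
            continue
        n_visible += m
        lum = rng.lognormal(mu_cell, config.sigma_log, size=m)
        values.append(active[vis] * lum)
    vals = np.concatenate(values) if values else np.empty(0)
    density = n_visible / (config.frame_count * config.area_um2)
    return vals, density


def simulate_mixture_dataset(
    ratios: list[tuple[float, float]],
    cells_per_ratio: int,
    base_config: SimConfig,
    seed: int = 0,
    render_movies: bool = True,
):
    """Generate monomer:dimer mixture cohorts (e.g. 9:1, 8:2, 6:4, 5:5).

    Returns ``{ratio: [(Movie, GroundTruth), ...]}`` keyed by the
    (monomer_fraction, dimer_fraction) tuple; with ``render_movies=False``
    each cell is ``(values, density, GroundTruth=None)`` from the fast
    brightness sampler.
    """
    if cells_per_ratio < 1:
        raise InvalidParameterError("cells_per_ratio must be >= 1")
    for mono, di in ratios:
        if not (0 <= mono <= 1 and 0 <= di <= 1):
            raise InvalidParameterError("ratio fractions must be in [0, 1]")
        if abs(mono + di - 1.0) > 1e-9:
            raise InvalidParameterError("each ratio pair must sum to 1")
    ss = np.random.SeedSequence(seed)
    dataset: dict[tuple[float, float], list] = {}
    for (mono, di), child in zip(ratios, ss.spawn(len(ratios))):
        fractions = {n: f for n, f in ((1, mono), (2, di)) if f > 0}
        cell_seeds = child.generate_state(cells_per_ratio) % np.uint32(2**31)
        cohort = []
        for cs in cell_seeds:
            cfg = base_config.replace(oligomer_fractions=fractions, seed=int(cs))
            if render_movies:
                cohort.append(simulate_cell_movie(cfg))
            else:
                vals, dens = sample_cell_brightness(cfg)
                cohort.append((vals, dens, None))
        dataset[(mono, di)] = cohort
    return dataset


def simulate_bleach_trace(
    n_fluors: int,
    photons_per_fluor: float,
    bleach_rate_per_s: float,
    dt_s: float,
    duration_s: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate a stepwise photobleaching intensity trace.

    Returns ``(t, intensity, true_step_times)``: a piecewise-constant,
    decreasing staircase (level = number of unbleached fluorophores times
    ``photons_per_fluor``) with independent exponential waiting times per
    fluorophore, plus additive Gaussian noise. Step times beyond the record
    are omitted.
    """
    if n_fluors < 1:
        raise InvalidParameterError("n_fluors must be >= 1")
    if photons_per_fluor <= 0 or bleach_rate_per_s <= 0:
        raise InvalidParameterError("photons_per_fluor and bleach_rate must be > 0")
    if dt_s <= 0 or dt_s >= duration_s:
        raise InvalidParameterError("need 0 < dt_s < duration_s")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    bleach_times = np.sort(rng.exponential(1.0 / bleach_rate_per_s, size=n_fluors))
    t = np.arange(0.0, duration_s, dt_s)
    active = n_fluors - np.searchsorted(bleach_times, t, side="right")
    intensity = active * photons_per_fluor
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, size=t.size)
    return t, intensity, bleach_times[bleach_times < duration_s]


# ------------------------------------------------------------------ disk I/O
def write_simulated_cell(
    movie: Movie, truth: GroundTruth, out_dir: str | Path, stem: str
) -> dict:
    """Write movie TIFF + config sidecar + ground-truth CSV; return paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tif = movie.write_tiff(out_dir / f"{stem}.tif")
    cfg_path = out_dir / f"{stem}.config.json"
    cfg_path.write_text(json.dumps(truth.config.to_dict(), indent=1, sort_keys=True))
    csv = truth.write_csv(out_dir / f"{stem}.truth.csv")
    return {"movie": str(tif), "config": str(cfg_path), "truth": str(csv)}
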