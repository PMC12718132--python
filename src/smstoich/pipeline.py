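"""End-to-end orchestration: simulate -> detect -> fit -> classify.

A single global seed is expanded into independent per-stage / per-cell
substreams with :func:`derive_seed` (a documented splitting rule based on
``numpy.random.SeedSequence``), so any stage can be rerun in isolation yet
reproducibly. Every run writes a manifest recording parameters, seeds and
SHA-256 hashes of all outputs; reruns with the same seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .brightness import compare_stoichiometry, fit_lognormal_single
from .detect import SpotDetector, locs_to_dataframe
from .exceptions import InvalidParameterError, ValidationError
from .movie import Movie
from .simulate import SimConfig, sample_cell_brightness, simulate_cell_movie

__all__ = [
    "derive_seed",
    "make_stoichiometry_dataset",
    "run_pipeline",
    "PRESETS",
]

# cohort name -> (number of cells, oligomer fractions); sizes follow the
# published cohort sizes of the calibration-ladder experiment
PRESETS: dict[str, dict[str, tuple[int, dict[int, float]]]] = {
    "controls": {
        "monomer": (73, {1: 1.0}),
        "mixed": (24, {1: 0.5, 2: 0.5}),
        "dimer": (75, {2: 1.0}),
        "trimer": (68, {3: 1.0}),
    },
    "receptor": {
        "receptor_basal": (47, {1: 1.0}),
        "receptor_pth": (52, {1: 1.0}),
    },
    "mixing-ratios": {
        "10:0": (24, {1: 1.0}),
        "9:1": (24, {1: 0.9, 2: 0.1}),
        "8:2": (24, {1: 0.8, 2: 0.2}),
        "6:4": (24, {1: 0.6, 2: 0.4}),
        "5:5": (24, {1: 0.5, 2: 0.5}),
    },
}
PRESETS["full"] = {**PRESETS["controls"], **PRESETS["receptor"]}


def derive_seed(seed: int, *labels: str | int) -> int:
    """Derive a reproducible sub-seed (< 2**31) from a global seed and a
    label path, e.g. ``derive_seed(s, "simulate", "monomer", 3)``."""
    keys = [int(seed)] + [
        zlib.crc32(str(label).encode()) for label in labels
    ]
    return int(np.random.SeedSequence(keys).generate_state(1)[0] % 2**31)


def _scaled(n: int, scale: float) -> int:
    # round half up, never below one cell
    return max(1, int(np.floor(n * scale + 0.5)))


def make_stoichiometry_dataset(
    preset: str,
    seed: int = 0,
    scale: float = 1.0,
    base_config: SimConfig | None = None,
    render_movies: bool = False,
    out_dir: str | Path | None = None,
):
    """Generate a calibration-ladder-style cohort dataset with ground truth.

    ``preset`` is one of ``controls`` (monomer/mixed/dimer/trimer cohorts at
    the published cell counts 73/24/75/68), ``receptor`` (two
    monomer-generated receptor cohorts, 47/52 cells), ``full`` (both) or
    ``mixing-ratios`` (monomer:dimer 10:0 ... 5:5). ``scale`` shrinks cohort
    sizes (round half up, minimum one cell). By default cells are generated
    with the fast detection-level brightness sampler; ``render_movies=True``
    renders full movies with ground-truth tables instead.

    Returns ``{condition: [cell, ...]}`` where each cell is a dict with
    ``values`` (photon brightness per detection) and ``density_per_um2``, or
    ``movie``/``truth`` objects when rendering.
    """
    if preset not in PRESETS:
        raise InvalidParameterError(
            f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
        )
    if scale <= 0:
        raise InvalidParameterError("scale must be positive")
    base = base_config or SimConfig()
    dataset: dict[str, list] = {}
    for condition, (n_cells, fractions) in PRESETS[preset].items():
        cells = []
        for i in range(_scaled(n_cells, scale)):
            cfg = base.replace(
                oligomer_fractions=dict(fractions),
                seed=derive_seed(seed, "simulate", condition, i),
            )
            if render_movies:
                movie, truth = simulate_cell_movie(cfg)
                cells.append({"cell_id": f"{condition}_{i:03d}",
                              "movie": movie, "truth": truth, "config": cfg})
            else:
                values, density = sample_cell_brightness(cfg)
                cells.append({"cell_id": f"{condition}_{i:03d}",
                              "values": values, "density_per_um2": density,
                              "config": cfg})
        dataset[condition] = cells
    if out_dir is not None:
        _write_dataset(dataset, Path(out_dir), preset, seed)
    return dataset


def _write_dataset(dataset, out_dir: Path, preset: str, seed: int) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for condition, cells in dataset.items():
        for cell in cells:
            if "movie" in cell:
                from .simulate import write_simulated_cell
                write_simulated_cell(cell["movie"], cell["truth"], out_dir,
                                     cell["cell_id"])
            else:
                for v in cell["values"]:
                    rows.append((cell["cell_id"], condition, v))
    if rows:
        pd.DataFrame(rows, columns=["cell_id", "condition", "intensity"]).to_csv(
            out_dir / "brightness_samples.csv", index=False
        )
    (out_dir / "dataset.json").write_text(json.dumps(
        {"preset": preset, "seed": seed,
         "conditions": {c: len(cells) for c, cells in dataset.items()}},
        indent=1, sort_keys=True,
    ))


# ----------------------------------------------------------------- pipeline
def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _validate_config(config: dict) -> None:
    if "seed" not in config:
        raise ValidationError("run config must set a global 'seed'")
    if "out_dir" not in config:
        raise ValidationError("run config must set 'out_dir'")
    sim = config.get("simulate")
    detect = config.get("detect", {})
    if sim is None and "movies" not in detect and "samples" not in config.get(
            "fit", {}):
        raise ValidationError(
            "config needs a 'simulate' block, detect.movies paths, or "
            "fit.samples tables"
        )
    for path in detect.get("movies", []):
        if not Path(path).exists():
            raise ValidationError(f"movie path does not exist: {path}")
    if sim is not None and sim.get("preset") not in (None, *PRESETS):
        raise ValidationError(f"unknown preset {sim.get('preset')!r}")


def run_pipeline(config: dict | str | Path) -> dict:
    """Execute a synthetic stoichiometry run from a config dict or YAML path.

    Config keys: ``seed``, ``out_dir``; ``simulate`` (``preset``, ``scale``,
    ``render_movies``, optional ``sim_config`` overrides); optional
    ``detect`` (detector parameters, or explicit ``movies`` paths);
    ``classify`` (``sample`` condition and ``controls`` conditions). The run
    fails pre-flight (nothing executed) on invalid configuration. Writes
    per-cell fits, the classification report and a manifest; returns the run
    report.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    _validate_config(config)
    seed = int(config["seed"])
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)

    sim_block = config.get("simulate") or {}
    overrides = sim_block.get("sim_config", {})
    base = SimConfig(**overrides) if overrides else SimConfig()
    render = bool(sim_block.get("render_movies", False)) or "detect" in config
    dataset = make_stoichiometry_dataset(
        preset=sim_block.get("preset", "full"),
        seed=seed,
        scale=float(sim_block.get("scale", 1.0)),
        base_config=base,
        render_movies=render,
    )

    det_cfg = config.get("detect", {})
    fit_rows = []
    for condition, cells in dataset.items():
        for cell in cells:
            if "movie" in cell:
                detector = SpotDetector(
                    method=det_cfg.get("method", "dog"),
                    est_diameter_um=det_cfg.get("est_diameter_um", 0.5),
                    threshold=det_cfg.get("threshold"),
                )
                movie: Movie = cell["movie"]
                locs = detector.detect(movie)
                values = np.array([l.intensity for l in locs])
                density = len(locs) / (movie.n_frames * movie.frame_area_um2)
            else:
                values, density = cell["values"], cell["density_per_um2"]
            if len(values) < 10:
                continue
            fit = fit_lognormal_single(values)
            fit_rows.append({
                "cell_id": cell["cell_id"], "condition": condition,
                "n_detections": fit.n, "geometric_mean": fit.geometric_mean,
                "mu_log": fit.mu_log, "sigma_log": fit.sigma_log,
                "density_per_um2": density,
            })
    fits = pd.DataFrame(fit_rows)
    fits_path = out_dir / "percell_fits.csv"
    fits.to_csv(fits_path, index=False, float_format="%.10g")

    cls_cfg = config.get("classify", {})
    sample_cond = cls_cfg.get("sample", "receptor_basal")
    control_conds = cls_cfg.get("controls", ["monomer", "dimer", "trimer"])
    report: dict = {"seed": seed, "version": __version__,
                    "n_cells": int(len(fits))}
    if sample_cond in set(fits["condition"]):
        sample_g = fits.loc[fits["condition"] == sample_cond, "geometric_mean"]
        controls = {
            c: fits.loc[fits["condition"] == c, "geometric_mean"].to_numpy()
            for c in control_conds if c in set(fits["condition"])
        }
        if len(controls) >= 2:
            report["classification"] = compare_stoichiometry(
                sample_g.to_numpy(), controls,
                alpha=float(cls_cfg.get("alpha", 0.05)),
            )
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=1, sort_keys=True))

    manifest = {
        "seed": seed,
        "version": __version__,
        "config": _jsonable(config),
        "outputs": {
            p.name: {"path": str(p), "sha256": _sha256(p)}
            for p in (fits_path, report_path)
        },
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    report["outputs"] = manifest["outputs"]
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj
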