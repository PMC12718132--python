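"""Movie container: a calibrated single-channel TIRF image stack.

Intensities are stored in camera units (ADU). Conversion to photons uses the
camera gain; both vendor conventions for quoting the gain are supported,
selected by ``adu_convention``:

* ``"photons_per_adu"`` (default): photons = ADU * gain
* ``"adu_per_photon"``:            photons = ADU / gain
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .exceptions import InvalidParameterError

ADU_CONVENTIONS = ("photons_per_adu", "adu_per_photon")


@dataclass
class Movie:
    """A frame-major intensity stack with physical calibration.

    Parameters
    ----------
    data : ndarray, shape (n_frames, height, width)
        Pixel intensities in ADU. Float internally; quantised to uint16 only
        on TIFF export.
    pixel_size_um : float
        Physical pixel pitch in micrometres.
    exposure_s : float
        Exposure per frame in seconds.
    gain_photons_per_adu : float
        Camera gain constant (interpretation set by ``adu_convention``).
    """

    data: np.ndarray
    pixel_size_um: float
    exposure_s: float
    gain_photons_per_adu: float = 0.22
    adu_convention: str = "photons_per_adu"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise InvalidParameterError(
                f"movie data must be 3-D (frames, y, x); got shape {self.data.shape}"
            )
        if self.pixel_size_um <= 0:
            raise InvalidParameterError("pixel_size_um must be positive")
        if self.exposure_s <= 0:
            raise InvalidParameterError("exposure_s must be positive")
        if self.gain_photons_per_adu <= 0:
            raise InvalidParameterError("gain must be positive")
        if self.adu_convention not in ADU_CONVENTIONS:
            raise InvalidParameterError(
                f"adu_convention must be one of {ADU_CONVENTIONS}"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def frame_area_um2(self) -> float:
        h, w = self.shape
        return h * w * self.pixel_size_um**2

    def to_photons(self, frame: np.ndarray | None = None) -> np.ndarray:
        """Convert ADU to photons for one frame (or the whole stack)."""
        x = self.data if frame is None else np.asarray(frame)
        if self.adu_convention == "photons_per_adu":
            return x * self.gain_photons_per_adu
        return x / self.gain_photons_per_adu

    def photons_to_adu(self, photons: np.ndarray) -> np.ndarray:
        if self.adu_convention == "photons_per_adu":
            return np.asarray(photons) / self.gain_photons_per_adu
        return np.asarray(photons) * self.gain_photons_per_adu

    # ------------------------------------------------------------------ I/O
    def write_tiff(self, path: str | Path) -> Path:
        """Write a 16-bit multi-page TIFF plus a JSON calibration sidecar."""
        path = Path(path)
        quantised = np.clip(np.round(self.data), 0, np.iinfo(np.uint16).max)
        tifffile.imwrite(path, quantised.astype("<u2"),
                         photometric="minisblack")
        sidecar = {
            "pixel_size_um": self.pixel_size_um,
            "exposure_s": self.exposure_s,
            "gain_photons_per_adu": self.gain_photons_per_adu,
            "adu_convention": self.adu_convention,
            "metadata": self.metadata,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1, sort_keys=True, default=str)
        )
        return path

    @classmethod
    def read_tiff(
        cls,
        path: str | Path,
        pixel_size_um: float | None = None,
        exposure_s: float | None = None,
        gain_photons_per_adu: float | None = None,
        adu_convention: str | None = None,
    ) -> "Movie":
        """Read a multi-page TIFF; calibration from the sidecar unless given."""
        path = Path(path)
        data = tifffile.imread(path).astype(float)
        if data.ndim == 2:
            data = data[None]
        side = {}
        sidecar_path = path.with_suffix(path.suffix + ".json")
        if sidecar_path.exists():
            side = json.loads(sidecar_path.read_text())
        return cls(
            data=data,
            pixel_size_um=pixel_size_um or side.get("pixel_size_um", 0.084),
            exposure_s=exposure_s or side.get("exposure_s", 0.05),
            gain_photons_per_adu=gain_photons_per_adu
            or side.get("gain_photons_per_adu", 0.22),
            adu_convention=adu_convention
            or side.get("adu_convention", "photons_per_adu"),
            metadata=side.get("metadata", {}),
        )
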