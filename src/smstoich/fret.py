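"""FRET photometry: bleed-through-corrected ratios, acceptor-photobleaching
efficiency, and one-exponential activation/deactivation kinetics.

Dual-emission photometry with donor-line excitation records a donor channel
(480 nm, CFP) and an acceptor channel (535 nm, YFP). The acceptor channel is
contaminated by donor spillover (alpha) and by direct acceptor excitation
(gamma); the donor channel by acceptor spillover (beta). With known
coefficients the two channels form a linear system in the true donor and
sensitized-acceptor signals and are inverted exactly:

    F480 = F_D + beta * F_A
    F535 = alpha * F_D + F_A + (direct excitation term)

The direct-excitation term is ``gamma * A_ref`` when an acceptor-only
reference trace is supplied, else ``gamma * F_A`` (proportional to the
acceptor signal itself). FRET efficiency from acceptor photobleaching is the
donor-dequenching form ``E = 1 - CFP_before / CFP_after``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

from .exceptions import (
    FitFailureError,
    InsufficientDataError,
    InvalidParameterError,
    UncorrectableTrendError,
)

__all__ = [
    "PhotometryTrace",
    "FretKinetics",
    "FretEfficiency",
    "MonoExponential",
    "corrected_fret_ratio",
    "photobleach_detrend",
    "fret_efficiency_apb",
    "fit_monoexponential",
]


@dataclass
class PhotometryTrace:
    """Two-channel photometry time series with correction coefficients.

    ``alpha``: donor spillover into the 535 nm channel; ``beta``: acceptor
    spillover into the 480 nm channel; ``gamma``: direct acceptor excitation
    fraction. ``stimulus`` is a boolean mask (True while ligand is applied);
    ``acceptor_ref`` an optional acceptor-only reference trace for the direct
    excitation term.
    """

    t: np.ndarray
    f480: np.ndarray
    f535: np.ndarray
    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0
    stimulus: np.ndarray | None = None
    acceptor_ref: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f480 = np.asarray(self.f480, dtype=float)
        self.f535 = np.asarray(self.f535, dtype=float)
        if not (self.t.size == self.f480.size == self.f535.size):
            raise InvalidParameterError("t, F480 and F535 must have equal length")
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise InvalidParameterError(f"{name} must be in [0, 1)")
        if self.stimulus is not None:
            self.stimulus = np.asarray(self.stimulus, dtype=bool)
            if self.stimulus.size != self.t.size:
                raise InvalidParameterError("stimulus mask length mismatch")
        if self.acceptor_ref is not None:
            self.acceptor_ref = np.asarray(self.acceptor_ref, dtype=float)
            if self.acceptor_ref.size != self.t.size:
                raise InvalidParameterError("acceptor_ref length mismatch")

    @classmethod
    def read_csv(cls, path, **coeffs) -> "PhotometryTrace":
        """Read a trace CSV with columns ``t_s, F480, F535[, stimulus]``."""
        df = pd.read_csv(path)
        stim = df["stimulus"].to_numpy(dtype=bool) if "stimulus" in df else None
        return cls(t=df["t_s"].to_numpy(), f480=df["F480"].to_numpy(),
                   f535=df["F535"].to_numpy(), stimulus=stim, **coeffs)

    def write_csv(self, path):
        df = pd.DataFrame({"t_s": self.t, "F480": self.f480, "F535": self.f535})
        if self.stimulus is not None:
            df["stimulus"] = self.stimulus.astype(int)
        df.to_csv(path, index=False)
        return path


@dataclass
class FretKinetics:
    amplitude: float
    tau_s: float
    baseline: float
    rms: float

    def __post_init__(self) -> None:
        if self.tau_s <= 0:
            raise InvalidParameterError("tau_s must be positive")


@dataclass
class FretEfficiency:
    value: float
    flagged: bool  # True for negative E (no FRET / bleaching artifact)

    def __float__(self) -> float:
        return self.value


def corrected_fret_ratio(trace: PhotometryTrace) -> pd.DataFrame:
    """Spillover- and direct-excitation-corrected FRET emission ratio.

    Solves the two-channel linear system exactly at every time point and
    reports both orientations: ``ratio_DA = F_D / F_A`` (the methods'
    F_CFP/F_YFP) and ``ratio_AD = F_A / F_D``. Points where a corrected
    channel is non-positive are masked (NaN) with a warning.
    """
    a, b, g = trace.alpha, trace.beta, trace.gamma
    if trace.acceptor_ref is not None:
        # F535 = a*F_D + F_A + g*A_ref ; F480 = F_D + b*F_A
        f_a = (trace.f535 - g * trace.acceptor_ref - a * trace.f480) / (1.0 - a * b)
    else:
        # F535 = a*F_D + (1+g)*F_A ; F480 = F_D + b*F_A
        # => F535 - a*F480 = ((1+g) - a*b) * F_A
        f_a = (trace.f535 - a * trace.f480) / ((1.0 + g) - a * b)
    f_d = trace.f480 - b * f_a
    bad = (f_a <= 0) | (f_d <= 0)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} time points with non-positive corrected "
            "channel masked", stacklevel=2,
        )
        f_a = np.where(bad, np.nan, f_a)
        f_d = np.where(bad, np.nan, f_d)
    with np.errstate(invalid="ignore", divide="ignore"):
        return pd.DataFrame({
            "t_s": trace.t,
            "F_D": f_d,
            "F_A": f_a,
            "ratio_DA": f_d / f_a,
            "ratio_AD": f_a / f_d,
        })


def _monoexp_decay(t, a, tau, c):
    return a * np.exp(-t / tau) + c


def photobleach_detrend(t, y, stimulus_free: np.ndarray,
                        mode: str = "subtract") -> np.ndarray:
    """Remove the slow photobleaching baseline from one channel.

    The baseline is a mono-exponential (linear fallback) fitted on the
    stimulus-free samples only, then subtracted (default) or divided out,
    anchored at the first sample so a flat trace passes through unchanged.
    Requires stimulus-free samples both before and after the stimulus window;
    a level change confined to the stimulus window cannot be attributed to
    bleaching and raises :class:`UncorrectableTrendError`.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    free = np.asarray(stimulus_free, dtype=bool)
    if mode not in ("subtract", "divide"):
        raise InvalidParameterError("mode must be 'subtract' or 'divide'")
    if free.sum() < 4:
        raise InsufficientDataError("need >= 4 stimulus-free samples")
    # split free samples into contiguous intervals
    idx = np.flatnonzero(free)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    intervals = np.split(idx, breaks + 1)
    if len(intervals) < 2:
        raise InsufficientDataError(
            "need stimulus-free intervals on both sides of the stimulus"
        )
    # uncorrectable: flat free intervals at clearly different levels
    first, last = intervals[0], intervals[-1]
    lvl1, lvl2 = y[first].mean(), y[last].mean()
    noise = np.sqrt((y[first].var(ddof=1) + y[last].var(ddof=1)) / 2.0)
    se = max(noise, 1e-12) * np.sqrt(1.0 / first.size + 1.0 / last.size)
    slope1 = np.polyfit(t[first], y[first], 1)[0] if first.size > 2 else 0.0
    slope2 = np.polyfit(t[last], y[last], 1)[0] if last.size > 2 else 0.0
    span = t[last].mean() - t[first].mean()
    predicted_drift = 0.5 * (slope1 + slope2) * span
    if abs(lvl2 - lvl1) > max(5.0 * se, 1e-12) and \
            abs(predicted_drift) < 0.2 * abs(lvl2 - lvl1):
        raise UncorrectableTrendError(
            "baseline change confined to the stimulus window; cannot be "
            "attributed to photobleaching"
        )
    tf, yf = t[free], y[free]
    if np.ptp(yf) == 0:
        baseline = np.full_like(y, yf[0])
    else:
        a0 = yf[0] - yf[-1]
        c0 = yf[-1]
        tau0 = max(tf[-1] - tf[0], 1e-6)
        try:
            popt, _ = optimize.curve_fit(
                _monoexp_decay, tf - tf[0], yf, p0=[a0, tau0, c0],
                maxfev=2000,
            )
            if popt[1] <= 0:
                raise RuntimeError
            baseline = _monoexp_decay(t - tf[0], *popt)
        except (RuntimeError, optimize.OptimizeWarning):
            coeff = np.polyfit(tf, yf, 1)
            baseline = np.polyval(coeff, t)
    if mode == "subtract":
        return y - baseline + baseline[0]
    return y * baseline[0] / baseline


def fret_efficiency_apb(cfp_before: float, cfp_after: float) -> FretEfficiency:
    """Acceptor-photobleaching FRET efficiency by donor dequenching.

    ``E = 1 - CFP_before / CFP_after``. Negative values (donor dimmer after
    bleaching: no FRET, or a bleaching artifact) are allowed but flagged.
    """
    if cfp_after <= 0:
        raise InvalidParameterError("cfp_after must be positive")
    if cfp_before < 0:
        raise InvalidParameterError("cfp_before must be nonnegative")
    e = 1.0 - cfp_before / cfp_after
    return FretEfficiency(value=float(e), flagged=bool(e < 0))


class MonoExponential(BaseEstimator):
    """One-exponential response fit ``y = baseline + A * (1 - e^{-(t-t0)/tau})``.

    Initial values are data-driven: baseline from the pre-onset mean,
    amplitude from the late plateau, tau from the time to 63% of the
    amplitude. Fitted attributes: ``amplitude_``, ``tau_s_``, ``baseline_``,
    ``rms_``.
    """

    def __init__(self, stimulus_onset: float = 0.0):
        self.stimulus_onset = stimulus_onset

    def fit(self, t, y) -> "MonoExponential":
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        t0 = self.stimulus_onset
        after = t >= t0
        if after.sum() < 10:
            raise InsufficientDataError("need >= 10 points after stimulus onset")
        if np.ptp(y[after]) == 0:
            raise FitFailureError(
                "constant response: tau is unidentifiable",
                details={"level": float(y[after][0])},
            )
        pre = t < t0
        baseline0 = float(y[pre].mean()) if pre.any() else float(y[after][0])
        ta, ya = t[after], y[after]
        n_tail = max(3, ya.size // 5)
        plateau = float(ya[-n_tail:].mean())
        amp0 = plateau - baseline0
        if amp0 == 0:
            amp0 = float(ya.max() - baseline0) or 1.0
        target = baseline0 + 0.63 * amp0
        crossing = np.flatnonzero(
            (ya - target) * np.sign(amp0) >= 0
        )
        tau0 = float(ta[crossing[0]] - t0) if crossing.size else float(
            (ta[-1] - t0) / 3.0
        )
        tau0 = max(tau0, (ta[1] - ta[0]) if ta.size > 1 else 1e-3)

        def model(tt, baseline, amp, tau):
            return baseline + amp * (1.0 - np.exp(-(tt - t0) / tau))

        # standardise y so the fit (and hence tau) is invariant under affine
        # rescaling of the response
        shift = float(ya.mean())
        scale = float(np.ptp(ya))
        za = (ya - shift) / scale
        p0 = [(baseline0 - shift) / scale, amp0 / scale, tau0]
        try:
            popt, _ = optimize.curve_fit(
                model, ta, za, p0=p0,
                bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=20000,
            )
        except RuntimeError as err:
            raise FitFailureError(
                "mono-exponential fit did not converge",
                details={"p0": [baseline0, amp0, tau0]},
            ) from err
        self.baseline_ = float(shift + scale * popt[0])
        self.amplitude_ = float(scale * popt[1])
        self.tau_s_ = float(popt[2])
        resid = ya - model(ta, self.baseline_, self.amplitude_, self.tau_s_)
        self.rms_ = float(np.sqrt(np.mean(resid**2)))
        self._t0 = t0
        return self

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.baseline_ + self.amplitude_ * (
            1.0 - np.exp(-(t - self._t0) / self.tau_s_)
        )

    def result_(self) -> FretKinetics:
        return FretKinetics(amplitude=self.amplitude_, tau_s=self.tau_s_,
                            baseline=self.baseline_, rms=self.rms_)


def fit_monoexponential(t, y, stimulus_onset: float = 0.0) -> FretKinetics:
    """Fit the one-exponential response model; see :class:`MonoExponential`."""
    return MonoExponential(stimulus_onset=stimulus_onset).fit(t, y).result_()
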