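"""Brightness-distribution fitting and stoichiometry classification.

Single-molecule spot brightness under TIRF follows a skewed log-normal law;
its geometric mean ``exp(mean(log v))`` is the central-tendency statistic
used throughout. An n-mer population has geometric mean ``n * g1`` relative
to the single-fluorophore value ``g1``, which is what the calibration ladder
(1x/2x/3x concatemer controls), the two-component mixture model (dimer
component pinned at twice the monomer brightness) and the density-correction
regression ``G_mean = rho * k + G_i`` all exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .exceptions import (
    DegenerateVarianceError,
    FitFailureError,
    InsufficientDataError,
    InvalidParameterError,
)

__all__ = [
    "BrightnessSample",
    "LogNormalFit",
    "MixtureFit",
    "DensityRegressionResult",
    "LogNormalBrightness",
    "BrightnessMixture",
    "DensityRegression",
    "StoichiometryClassifier",
    "brightness_histogram",
    "fit_lognormal_single",
    "fit_lognormal_mixture",
    "density_corrected_brightness",
    "assumption_checks",
    "compare_stoichiometry",
    "dunn_test",
]

LN2 = float(np.log(2.0))


@dataclass
class BrightnessSample:
    """Per-detection brightness values of one cell under one condition."""

    cell_id: str
    condition: str
    values: np.ndarray
    density_per_um2: float = np.nan

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise InvalidParameterError("brightness values must be nonnegative")


@dataclass
class LogNormalFit:
    mu_log: float
    sigma_log: float
    geometric_mean: float
    fit_method: str
    goodness: float
    n: int
    n_dropped: int = 0


@dataclass
class MixtureFit:
    monomer_fraction: float
    g1: float
    g2: float
    sigma_log: float
    log_likelihood: float
    constrained: bool
    boundary: bool
    n: int
    converged: bool = True


@dataclass
class DensityRegressionResult:
    slope: float  # photons per (molecules/um^2)
    intercept: float  # G_i, density-corrected intrinsic brightness (photons)
    intercept_ci: tuple[float, float]  # 95% CI
    points: pd.DataFrame = field(repr=False)
    trial_id: str | None = None
    slope_se: float = np.nan
    r_squared: float = np.nan


# --------------------------------------------------------------- histograms
def brightness_histogram(values, bin_width: float = 1.0):
    """Frequency histogram with contiguous bins aligned to multiples of
    ``bin_width`` (bin [k*w, (k+1)*w) labelled by its centre).

    Returns ``(centers, counts)`` with ``counts.sum() == len(values)``.
    """
    if bin_width <= 0:
        raise InvalidParameterError("bin_width must be positive")
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InsufficientDataError("empty sample")
    lo = np.floor(v.min() / bin_width) * bin_width
    hi = np.floor(v.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(v, bins=edges)
    centers = edges[:-1] + bin_width / 2.0
    return centers, counts


# ------------------------------------------------------- single log-normal
class LogNormalBrightness(BaseEstimator):
    """Single-component log-normal brightness fit.

    ``fit_method="mle"`` (default) uses the closed-form log-domain moments:
    ``mu = mean(log v)``, ``sigma = sd(log v)``. ``fit_method="histogram_ls"``
    reproduces the literal histogram procedure: a bin-width-1 frequency
    histogram least-squares-fitted with a scaled log-normal density. Zeros
    and negatives (possible after background subtraction) are dropped and
    counted in ``n_dropped_``.
    """

    def __init__(self, fit_method: str = "mle", bin_width: float = 1.0):
        self.fit_method = fit_method
        self.bin_width = bin_width

    def fit(self, values, y=None) -> "LogNormalBrightness":
        if self.fit_method not in ("mle", "histogram_ls"):
            raise InvalidParameterError("fit_method must be 'mle' or 'histogram_ls'")
        v = np.asarray(values, dtype=float).ravel()
        pos = v[v > 0]
        self.n_dropped_ = int(v.size - pos.size)
        if pos.size < 10:
            raise InsufficientDataError(
                f"need >= 10 positive values, got {pos.size}"
            )
        logs = np.log(pos)
        if np.ptp(logs) == 0:
            raise DegenerateVarianceError(
                "all values identical; sigma_log would be 0",
                geometric_mean=float(pos[0]),
            )
        if self.fit_method == "mle":
            self.mu_log_ = float(np.mean(logs))
            self.sigma_log_ = float(np.std(logs))
            # log-likelihood per point as the goodness figure
            self.goodness_ = float(
                np.mean(stats.lognorm.logpdf(pos, self.sigma_log_,
                                             scale=np.exp(self.mu_log_)))
            )
        else:
            self.mu_log_, self.sigma_log_, self.goodness_ = _fit_lognormal_histogram(
                pos, self.bin_width
            )
        self.geometric_mean_ = float(np.exp(self.mu_log_))
        self.n_ = int(pos.size)
        return self

    def result_(self) -> LogNormalFit:
        return LogNormalFit(
            mu_log=self.mu_log_, sigma_log=self.sigma_log_,
            geometric_mean=self.geometric_mean_, fit_method=self.fit_method,
            goodness=self.goodness_, n=self.n_, n_dropped=self.n_dropped_,
        )


def _fit_lognormal_histogram(pos: np.ndarray, bin_width: float):
    """Least squares of a scaled log-normal density against bin counts."""
    centers, counts = brightness_histogram(pos, bin_width)
    n = pos.size
    logs = np.log(pos)
    p0 = [float(np.mean(logs)), float(max(np.std(logs), 1e-3)), float(n * bin_width)]

    def model(p):
        mu, sig, amp = p
        return amp * stats.lognorm.pdf(centers, max(sig, 1e-6), scale=np.exp(mu))

    def resid(p):
        return model(p) - counts

    res = optimize.least_squares(resid, p0, max_nfev=500)
    if not res.success and res.status <= 0:
        raise FitFailureError("histogram least-squares fit did not converge",
                              details={"status": res.status})
    mu, sig, _ = res.x
    ss_res = float(np.sum(res.fun**2))
    ss_tot = float(np.sum((counts - counts.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return float(mu), float(abs(sig)), r2


def fit_lognormal_single(values, fit_method: str = "mle",
                         bin_width: float = 1.0) -> LogNormalFit:
    """Fit a single log-normal; see :class:`LogNormalBrightness`."""
    return LogNormalBrightness(fit_method=fit_method, bin_width=bin_width)\
        .fit(values).result_()


# --------------------------------------------------------------- mixture
class BrightnessMixture(BaseEstimator):
    """Two-component log-normal mixture for monomer/dimer brightness.

    Components share ``sigma_log``; with ``constrain_ratio=True`` (default)
    the dimer geometric mean is pinned at twice the monomer one, which is the
    identifiable parameterisation for one-channel brightness data. Optional
    incomplete-labeling correction (``labeling_efficiency``): a dimer is then
    itself a binomial mixture of one- and two-fluorophore states conditioned
    on being visible. Fitted by EM with multi-start over the monomer
    fraction.

    With a ``monomer_calibration`` and ``anchor_calibration=True`` (default),
    the monomer position and sigma are fixed from the same-day monomer
    control and only the mixing weight is estimated — single-channel
    brightness cannot otherwise distinguish "all monomers at g" from "all
    dimers at 2g". Without a calibration that ambiguity is resolved by a
    tie-break: among (near-)equal-likelihood solutions the one assigning
    more weight to the monomer component is reported, so a one-component
    sample reads as pure monomer rather than pure dimer.
    """

    def __init__(self, constrain_ratio: bool = True,
                 monomer_calibration: LogNormalFit | None = None,
                 anchor_calibration: bool = True,
                 labeling_efficiency: float | None = None,
                 n_starts: int = 9, max_iter: int = 500, tol: float = 1e-8):
        self.constrain_ratio = constrain_ratio
        self.monomer_calibration = monomer_calibration
        self.anchor_calibration = anchor_calibration
        self.labeling_efficiency = labeling_efficiency
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.tol = tol

    # latent states: (component, log-offset, within-component weight)
    def _states(self, f: float, mu2_offset: float):
        p = self.labeling_efficiency
        if p is None or p >= 1.0:
            return [(0, 0.0, f), (1, mu2_offset, 1.0 - f)]
        # visible dimer: active fluorophores k ~ Binomial(2, p) | k >= 1
        w1 = 2 * p * (1 - p)
        w2 = p * p
        z = w1 + w2
        return [
            (0, 0.0, f),
            (1, 0.0, (1.0 - f) * w1 / z),
            (1, mu2_offset, (1.0 - f) * w2 / z),
        ]

    def fit(self, values, y=None) -> "BrightnessMixture":
        v = np.asarray(values, dtype=float).ravel()
        x = np.log(v[v > 0])
        if x.size < 100:
            raise InsufficientDataError("mixture fit needs >= 100 positive values")
        calib = self.monomer_calibration
        mu0 = calib.mu_log if calib is not None else float(np.mean(x)) - LN2 / 2
        sig0 = calib.sigma_log if calib is not None else float(np.std(x)) * 0.8
        sig0 = max(sig0, 1e-3)
        anchored = (calib is not None and self.anchor_calibration
                    and self.constrain_ratio)

        best = None
        starts = np.linspace(0.1, 0.9, self.n_starts)
        for f0 in starts:
            out = self._em(x, f0, mu0, sig0, anchored=anchored)
            if best is None:
                best = out
                continue
            # near-ties (one-component degeneracy) resolve toward the
            # monomer labelling
            tol = 1e-5 * max(1.0, abs(best["ll"]))
            if out["ll"] > best["ll"] + tol or (
                    abs(out["ll"] - best["ll"]) <= tol
                    and out["f"] > best["f"]):
                best = out
        if best is None or not np.isfinite(best["ll"]):
            raise FitFailureError("mixture EM failed from all starts")
        self.monomer_fraction_ = best["f"]
        self.g1_ = float(np.exp(best["mu"]))
        self.g2_ = float(np.exp(best["mu"] + best["off"]))
        self.sigma_log_ = best["sigma"]
        self.log_likelihood_ = best["ll"]
        self.converged_ = best["converged"]
        self.boundary_ = bool(best["f"] < 1e-3 or best["f"] > 1 - 1e-3)
        self.n_ = int(x.size)
        return self

    def _em(self, x: np.ndarray, f0: float, mu0: float, sig0: float,
            anchored: bool = False) -> dict:
        f, mu, sig = f0, mu0, sig0
        off = LN2  # constrained offset; re-estimated when unconstrained
        ll_old = -np.inf
        converged = False
        for _ in range(self.max_iter):
            states = self._states(f, off)
            # responsibilities (inline normal log-density for speed)
            log_norm = -np.log(sig) - 0.5 * np.log(2.0 * np.pi)
            logp = np.stack([
                np.log(max(w, 1e-300)) + log_norm
                - 0.5 * ((x - mu - o) / sig) ** 2
                for (_c, o, w) in states
            ])
            m = logp.max(axis=0)
            lse = m + np.log(np.exp(logp - m).sum(axis=0))
            r = np.exp(logp - lse)
            ll = float(lse.sum())
            # M-step
            w_states = r.sum(axis=1)
            f = float(sum(w_states[i] for i, s in enumerate(states) if s[0] == 0)
                      / x.size)
            f = min(max(f, 0.0), 1.0)
            offsets = np.array([s[1] for s in states])
            if anchored:
                pass  # mu and sigma stay at the same-day calibration values
            elif self.constrain_ratio:
                mu = float((r * (x[None, :] - offsets[:, None])).sum() / x.size)
            else:
                # free second-component location: solve jointly
                is2 = np.array([s[0] == 1 and s[1] > 0 for s in states])
                n2 = r[is2].sum()
                n_other = x.size - n2
                mu = float((r[~is2] * (x[None, :] - offsets[~is2, None])).sum()
                           / max(n_other, 1e-12))
                if n2 > 1e-12:
                    mu2 = float((r[is2] * x[None, :]).sum() / n2)
                    off = max(mu2 - mu, 1e-6)
            if not anchored:
                sig = float(np.sqrt(
                    (r * (x[None, :] - mu - offsets[:, None]) ** 2).sum()
                    / x.size
                ))
                sig = max(sig, 1e-4)
            if abs(ll - ll_old) < self.tol * max(1.0, abs(ll)):
                converged = True
                break
            ll_old = ll
        return {"f": f, "mu": mu, "sigma": sig, "off": off, "ll": ll,
                "converged": converged}

    def result_(self) -> MixtureFit:
        return MixtureFit(
            monomer_fraction=self.monomer_fraction_, g1=self.g1_, g2=self.g2_,
            sigma_log=self.sigma_log_, log_likelihood=self.log_likelihood_,
            constrained=self.constrain_ratio, boundary=self.boundary_,
            n=self.n_, converged=self.converged_,
        )


def fit_lognormal_mixture(values, monomer_calibration: LogNormalFit | None = None,
                          constrain_ratio: bool = True,
                          anchor_calibration: bool = True,
                          labeling_efficiency: float | None = None) -> MixtureFit:
    """Fit the two-component mixture; see :class:`BrightnessMixture`."""
    return BrightnessMixture(
        constrain_ratio=constrain_ratio,
        monomer_calibration=monomer_calibration,
        anchor_calibration=anchor_calibration,
        labeling_efficiency=labeling_efficiency,
    ).fit(values).result_()


# -------------------------------------------------------- density regression
class DensityRegression(BaseEstimator):
    """OLS of per-cell geometric-mean brightness against molecule density.

    ``G_mean = rho * k + G_i``; the intercept ``G_i`` is the density-corrected
    intrinsic brightness, reported with its 95% confidence interval.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, density, g_mean=None) -> "DensityRegression":
        if g_mean is None:
            density = np.asarray(density, dtype=float)
            density, g_mean = density[:, 0], density[:, 1]
        rho = np.asarray(density, dtype=float).ravel()
        g = np.asarray(g_mean, dtype=float).ravel()
        if rho.size != g.size:
            raise InvalidParameterError("density and G_mean lengths differ")
        if rho.size < 3:
            raise InsufficientDataError("need >= 3 (density, G_mean) points")
        if np.ptp(rho) == 0:
            raise InvalidParameterError(
                "all densities identical: regression is rank-deficient"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            model = sm.OLS(g, sm.add_constant(rho)).fit()
            self.intercept_ = float(model.params[0])
            self.slope_ = float(model.params[1])
            ci = model.conf_int(alpha=self.alpha)
            self.intercept_ci_ = (float(ci[0][0]), float(ci[0][1]))
            self.slope_se_ = float(model.bse[1])
            self.r_squared_ = float(model.rsquared)
        self._points = pd.DataFrame({"density_per_um2": rho, "g_mean": g})
        return self

    def predict(self, density) -> np.ndarray:
        rho = np.asarray(density, dtype=float).ravel()
        return self.intercept_ + self.slope_ * rho

    def result_(self, trial_id: str | None = None) -> DensityRegressionResult:
        return DensityRegressionResult(
            slope=self.slope_, intercept=self.intercept_,
            intercept_ci=self.intercept_ci_, points=self._points,
            trial_id=trial_id, slope_se=self.slope_se_,
            r_squared=self.r_squared_,
        )


def density_corrected_brightness(points, group_by_trial: bool = False):
    """Per-trial density-correction regressions.

    ``points``: DataFrame with columns ``density_per_um2, g_mean`` (plus
    ``trial_id`` when ``group_by_trial``) or a sequence of (rho, G_mean)
    pairs. Returns one :class:`DensityRegressionResult` (or a list, one per
    trial).
    """
    if not isinstance(points, pd.DataFrame):
        points = pd.DataFrame(points, columns=["density_per_um2", "g_mean"])
    if group_by_trial:
        if "trial_id" not in points.columns:
            raise InvalidParameterError("group_by_trial requires a trial_id column")
        return [
            DensityRegression().fit(sub["density_per_um2"], sub["g_mean"])
            .result_(trial_id=str(tid))
            for tid, sub in points.groupby("trial_id")
        ]
    return DensityRegression().fit(
        points["density_per_um2"], points["g_mean"]
    ).result_()


# ------------------------------------------------------------- group stats
def assumption_checks(groups: dict[str, np.ndarray] | list[np.ndarray],
                      alpha: float = 0.05) -> dict:
    """Normality (D'Agostino-Pearson) and homoscedasticity (Bartlett) gates.

    Returns per-group normality statistics, the cross-group Bartlett test and
    the recommended downstream path: ``"parametric"`` when every group passes
    normality and variances are homogeneous, else ``"rank"``.
    """
    if isinstance(groups, dict):
        names = list(groups)
        arrays = [np.asarray(groups[k], dtype=float) for k in names]
    else:
        arrays = [np.asarray(g, dtype=float) for g in groups]
        names = [f"group{i}" for i in range(len(arrays))]
    if len(arrays) < 2:
        raise InsufficientDataError("need >= 2 groups")
    for name, a in zip(names, arrays):
        if a.size < 8:
            raise InsufficientDataError(
                f"group '{name}' has n={a.size} < 8 (normality test undefined)"
            )
    normality = {}
    all_normal = True
    for name, a in zip(names, arrays):
        stat, p = stats.normaltest(a)
        normality[name] = {"statistic": float(stat), "p": float(p)}
        all_normal &= p > alpha
    bstat, bp = stats.bartlett(*arrays)
    homoscedastic = bp > alpha
    return {
        "normality": normality,
        "bartlett": {"statistic": float(bstat), "p": float(bp)},
        "recommendation": "parametric" if (all_normal and homoscedastic) else "rank",
    }


def dunn_test(sample: np.ndarray, controls: dict[str, np.ndarray],
              adjust: str = "bonferroni") -> dict[str, float]:
    """Dunn's rank post hoc: the sample against each control on pooled ranks.

    z-statistics use the Kruskal-Wallis pooled-rank variance with tie
    correction; p-values are two-sided and Bonferroni-adjusted by default.
    """
    arrays = [np.asarray(sample, dtype=float)] + [
        np.asarray(v, dtype=float) for v in controls.values()
    ]
    pooled = np.concatenate(arrays)
    ranks = stats.rankdata(pooled)
    n = pooled.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    splits = np.cumsum([a.size for a in arrays])[:-1]
    group_ranks = np.split(ranks, splits)
    mean_ranks = [r.mean() for r in group_ranks]
    sizes = [r.size for r in group_ranks]
    m = len(controls)
    out = {}
    for j, name in enumerate(controls, start=1):
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term)
                     * (1.0 / sizes[0] + 1.0 / sizes[j]))
        z = (mean_ranks[0] - mean_ranks[j]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        if adjust == "bonferroni":
            p = min(1.0, p * m)
        out[name] = float(p)
    return out


class StoichiometryClassifier(BaseEstimator):
    """Classify a test condition against monomer/dimer/trimer calibrations.

    ``fit`` stores the control cohorts (per-cell geometric means);
    ``classify`` runs the omnibus test (one-way ANOVA or Kruskal-Wallis,
    chosen by the assumption gates), then a post hoc of the sample against
    each control (Dunnett when parametric, Bonferroni-adjusted Dunn
    otherwise). The classification is the single control the sample is *not*
    significantly different from; "ambiguous" when none or several, and
    "indistinguishable-from-all" when the omnibus test is not significant.

    With ``log_transform=True`` (default) all tests run on log geometric
    means: per-cell geometric means of log-normal brightness are themselves
    log-normal across cells, so the log scale is where the normality and
    equal-variance assumptions can actually hold; the classification is
    unchanged by the monotone transform.
    """

    def __init__(self, alpha: float = 0.05, min_cells: int = 5,
                 log_transform: bool = True):
        self.alpha = alpha
        self.min_cells = min_cells
        self.log_transform = log_transform

    def _prepare(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float).ravel()
        if self.log_transform:
            if (v <= 0).any():
                raise InvalidParameterError(
                    "log_transform requires positive geometric means"
                )
            return np.log(v)
        return v

    def fit(self, controls: dict[str, np.ndarray], y=None) -> "StoichiometryClassifier":
        if len(controls) < 2:
            raise InsufficientDataError("need >= 2 control groups")
        for name, vals in controls.items():
            if len(np.asarray(vals)) < self.min_cells:
                raise InsufficientDataError(
                    f"control '{name}' has fewer than {self.min_cells} cells"
                )
        self.controls_ = {k: self._prepare(v) for k, v in controls.items()}
        return self

    def classify(self, sample) -> dict:
        sample = self._prepare(sample)
        if sample.size < self.min_cells:
            raise InsufficientDataError("sample has too few cells")
        groups = [sample] + list(self.controls_.values())
        try:
            checks = assumption_checks(
                {"sample": sample, **self.controls_}, alpha=self.alpha
            )
            parametric = checks["recommendation"] == "parametric"
        except InsufficientDataError:
            checks = None
            parametric = False
        if parametric:
            omnibus_stat, omnibus_p = stats.f_oneway(*groups)
            res = stats.dunnett(*self.controls_.values(), control=sample)
            posthoc = {name: float(p)
                       for name, p in zip(self.controls_, res.pvalue)}
            method = "anova+dunnett"
        else:
            omnibus_stat, omnibus_p = stats.kruskal(*groups)
            posthoc = dunn_test(sample, self.controls_)
            method = "kruskal+dunn"
        if omnibus_p >= self.alpha:
            classification = "indistinguishable-from-all"
        else:
            matches = [name for name, p in posthoc.items() if p >= self.alpha]
            classification = matches[0] if len(matches) == 1 else "ambiguous"
        return {
            "classification": classification,
            "method": method,
            "omnibus": {"statistic": float(omnibus_stat), "p": float(omnibus_p)},
            "posthoc_p": posthoc,
            "assumption_checks": checks,
            "alpha": self.alpha,
        }

    def predict(self, sample) -> str:
        return self.classify(sample)["classification"]


def compare_stoichiometry(sample, controls: dict[str, np.ndarray],
                          alpha: float = 0.05,
                          log_transform: bool = True) -> dict:
    """Functional facade over :class:`StoichiometryClassifier`."""
    clf = StoichiometryClassifier(alpha=alpha, log_transform=log_transform)
    return clf.fit(controls).classify(sample)
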