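"""Dose-response curve fitting and calibration-curve (CC) dose inversion.

Two response forms are fitted to the per-sample endpoint means:

* MFI is linear in dose, ``MFI = alpha * D + beta`` — alpha is the
  fluorescence gain per Gy, beta the background at 0 Gy;
* spot count and spot area saturate, ``Y = v * (1 - exp(-xi * D))`` — v is
  the plateau and xi the steepness (1/Gy), the empirical signature of focus
  merging at high dose.

Both are unweighted least squares with parameter covariance and 95%
confidence bands.  CC dose estimation inverts the linear MFI fit at an
observed value; its interval comes from intersecting the horizontal line at
the observation with the fit's 95% prediction band (Fieller-style band
inversion), which stays honest when the slope is poorly determined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "LinearFit",
    "SaturatingFit",
    "DoseEstimate",
    "fit_linear",
    "fit_saturating",
    "invert_linear",
    "save_fit",
    "load_fit",
]


@dataclass(frozen=True)
class DoseEstimate:
    """A dose estimate with its 95% confidence interval.

    ``method`` is ``"CC"`` (calibration-curve inversion) or ``"KNN"``.
    ``diagnostics`` carries method detail: inversion branch flags for CC,
    neighbor row indices for K-NN.
    """

    dose_hat: float
    ci_low: float
    ci_high: float
    method: str
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dose_hat < 0:
            raise ValueError("dose_hat must be >= 0")
        if not (self.ci_low <= self.dose_hat <= self.ci_high):
            raise ValueError(
                f"interval must bracket the estimate: {self.ci_low} <= {self.dose_hat} <= {self.ci_high} violated"
            )


@dataclass(frozen=True)
class LinearFit:
    """Ordinary-least-squares fit of the linear MFI response."""

    alpha: float
    beta: float
    cov: np.ndarray  # 2x2 covariance of (alpha, beta)
    resid_var: float
    n: int
    dose_mean: float
    dose_ss: float  # sum of squared dose deviations

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("LinearFit needs n >= 3")
        c = np.asarray(self.cov)
        if c.shape != (2, 2) or not np.allclose(c, c.T):
            raise ValueError("covariance must be a symmetric 2x2 matrix")
        if np.linalg.eigvalsh(c).min() < -1e-8 * max(1.0, abs(c).max()):
            raise ValueError("covariance must be positive semi-definite")

    def predict(self, dose):
        return self.alpha * np.asarray(dose, dtype=float) + self.beta

    def _t(self, level: float) -> float:
        return float(stats.t.ppf(0.5 + level / 2.0, self.n - 2))

    def confidence_band(self, dose, level: float = 0.95):
        """Mean-response band: predicted value +/- half-width at each dose."""
        dose = np.asarray(dose, dtype=float)
        se = np.sqrt(self.resid_var * (1.0 / self.n + (dose - self.dose_mean) ** 2 / self.dose_ss))
        h = self._t(level) * se
        y = self.predict(dose)
        return y - h, y + h

    def prediction_band(self, dose, level: float = 0.95):
        """Band for one new observation (adds the single-sample variance)."""
        dose = np.asarray(dose, dtype=float)
        se = np.sqrt(self.resid_var * (1.0 + 1.0 / self.n + (dose - self.dose_mean) ** 2 / self.dose_ss))
        h = self._t(level) * se
        y = self.predict(dose)
        return y - h, y + h


@dataclass(frozen=True)
class SaturatingFit:
    """Nonlinear least-squares fit of the saturating spot-feature response."""

    v: float
    xi: float
    cov: np.ndarray  # 2x2 covariance of (v, xi)
    n: int

    def __post_init__(self) -> None:
        if not (self.v > 0 and self.xi > 0):
            raise ValueError("SaturatingFit requires v > 0 and xi > 0")

    def predict(self, dose):
        return self.v * (1.0 - np.exp(-self.xi * np.asarray(dose, dtype=float)))

    def confidence_band(self, dose, level: float = 0.95):
        """Delta-method band on the mean response."""
        dose = np.asarray(dose, dtype=float)
        e = np.exp(-self.xi * dose)
        grad = np.stack([1.0 - e, self.v * dose * e], axis=-1)  # d/dv, d/dxi
        var = np.einsum("...i,ij,...j->...", grad, self.cov, grad)
        h = stats.norm.ppf(0.5 + level / 2.0) * np.sqrt(np.clip(var, 0.0, None))
        y = self.predict(dose)
        return y - h, y + h


def fit_linear(doses: Sequence[float], y: Sequence[float]) -> LinearFit:
    """OLS fit of ``y = alpha * D + beta``."""
    d = np.asarray(doses, dtype=float)
    yv = np.asarray(y, dtype=float)
    if d.shape != yv.shape or d.ndim != 1:
        raise ValueError("doses and y must be equal-length 1-D sequences")
    n = d.size
    if n < 3:
        raise ValueError("fit_linear needs at least 3 points")
    if np.unique(d).size < 2:
        raise ValueError("degenerate design: all doses are equal")
    X = np.column_stack([d, np.ones(n)])
    coef, _, _, _ = np.linalg.lstsq(X, yv, rcond=None)
    alpha, beta = float(coef[0]), float(coef[1])
    resid = yv - X @ coef
    dof = n - 2
    resid_var = float(resid @ resid / dof)
    xtx_inv = np.linalg.inv(X.T @ X)
    return LinearFit(
        alpha=alpha,
        beta=beta,
        cov=resid_var * xtx_inv,
        resid_var=resid_var,
        n=n,
        dose_mean=float(d.mean()),
        dose_ss=float(((d - d.mean()) ** 2).sum()),
    )


def fit_saturating(doses: Sequence[float], y: Sequence[float]) -> SaturatingFit:
    """Bounded nonlinear least squares for ``Y = v (1 - exp(-xi D))``.

    Initialised at v0 = max(y), xi0 = 1/mean(dose) — robust for plateauing
    data.  Raises on non-convergence with the solver message attached.
    """
    d = np.asarray(doses, dtype=float)
    yv = np.asarray(y, dtype=float)
    if d.shape != yv.shape or d.ndim != 1:
        raise ValueError("doses and y must be equal-length 1-D sequences")
    if d.size < 4:
        raise ValueError("fit_saturating needs at least 4 points")
    if d.max() <= 0:
        raise ValueError("doses must span low and high values (all zero)")
    v0 = max(float(yv.max()), 1e-6)
    xi0 = 1.0 / max(float(d.mean()), 1e-6)
    try:
        popt, pcov = optimize.curve_fit(
            lambda x, v, xi: v * (1.0 - np.exp(-xi * x)),
            d,
            yv,
            p0=(v0, xi0),
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as err:  # pragma: no cover - solver-dependent message
        raise RuntimeError(f"saturating fit did not converge: {err}") from err
    return SaturatingFit(v=float(popt[0]), xi=float(popt[1]), cov=np.asarray(pcov), n=d.size)


def invert_linear(
    mfi_obs: float,
    fit: LinearFit,
    level: float = 0.95,
    max_dose: Optional[float] = None,
) -> DoseEstimate:
    """Calibration-curve dose estimate from one observed MFI.

    Point estimate ``(mfi_obs - beta) / alpha``, truncated below at 0 Gy.
    The interval inverts the 95% prediction band: it is the dose range where
    the band straddles the observed value, found by solving the Fieller
    quadratic analytically.  A non-positive discriminant or degenerate
    leading coefficient (slope indistinguishable from the band growth) gives
    an unbounded interval, flagged in diagnostics.
    """
    if fit.alpha <= 0:
        raise ValueError("non-informative calibration: alpha must be > 0 to invert")
    raw = (mfi_obs - fit.beta) / fit.alpha
    dose_hat = max(0.0, raw)
    diagnostics: dict = {"truncated_at_zero": raw < 0, "raw_estimate": raw}

    # Solve (mfi_obs - alpha D - beta)^2 = t^2 s^2 (1 + 1/n + (D - Dbar)^2 / Sxx)
    t = fit._t(level)
    s2 = fit.resid_var
    g = mfi_obs - fit.beta
    c0 = t**2 * s2 * (1.0 + 1.0 / fit.n)
    c1 = t**2 * s2 / fit.dose_ss
    A = fit.alpha**2 - c1
    B = -2.0 * fit.alpha * g + 2.0 * c1 * fit.dose_mean
    C = g**2 - c0 - c1 * fit.dose_mean**2
    disc = B**2 - 4.0 * A * C
    if A <= 0 or disc < 0:
        diagnostics["unbounded_interval"] = True
        lo, hi = 0.0, np.inf
    else:
        r = np.sqrt(disc)
        lo = (-B - r) / (2.0 * A)
        hi = (-B + r) / (2.0 * A)
        lo, hi = min(lo, hi), max(lo, hi)
        lo = max(0.0, lo)
    if max_dose is not None:
        hi = min(hi, max_dose)
    # physical truncation can push the estimate to an interval edge
    lo = min(lo, dose_hat)
    hi = max(hi, dose_hat)
    return DoseEstimate(dose_hat=dose_hat, ci_low=float(lo), ci_high=float(hi), method="CC", diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# fit serialization
# ---------------------------------------------------------------------------


def save_fit(fit, path) -> None:
    """Write a fit to portable JSON, reloadable for estimation-only runs."""
    if isinstance(fit, LinearFit):
        payload = {
            "kind": "linear",
            "alpha": fit.alpha,
            "beta": fit.beta,
            "cov": np.asarray(fit.cov).tolist(),
            "resid_var": fit.resid_var,
            "n": fit.n,
            "dose_mean": fit.dose_mean,
            "dose_ss": fit.dose_ss,
        }
    elif isinstance(fit, SaturatingFit):
        payload = {"kind": "saturating", "v": fit.v, "xi": fit.xi, "cov": np.asarray(fit.cov).tolist(), "n": fit.n}
    else:
        raise TypeError(f"unsupported fit type: {type(fit).__name__}")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def load_fit(path):
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    kind = payload.pop("kind")
    if kind == "linear":
        payload["cov"] = np.asarray(payload["cov"])
        return LinearFit(**payload)
    if kind == "saturating":
        payload["cov"] = np.asarray(payload["cov"])
        return SaturatingFit(**payload)
    raise ValueError(f"unknown fit kind: {kind!r}")
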