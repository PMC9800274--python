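"""Dose-response curves, the minimal dose (ED50) and E-values.

The fitted spline model yields an adjusted hazard-ratio curve
``HR(x) = exp(basis(x)'beta - basis(0)'beta)`` with exposure 0 (no VILPA)
as the referent and pointwise delta-method 95% confidence bands. From the
curve this module extracts:

* the **minimal dose** (ED50): the smallest exposure achieving half of the
  optimal risk reduction, where "optimal" is the largest reduction
  ``1 - min HR`` observed over the capped exposure range;
* hazard ratios (with CIs) at arbitrary exposures such as the sample median
  and maximum, by log-scale interpolation;
* **E-values** quantifying the minimum strength of unmeasured confounding
  (on the risk-ratio scale, with both exposure and outcome) that could
  explain an estimate away: for a protective HR the transform is
  ``RR = 1/HR`` and ``E = RR + sqrt(RR (RR - 1))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, NoBenefitError

Z95 = 1.959963984540054


@dataclass
class DoseResponseCurve:
    """Hazard-ratio curve on an exposure grid, referent at exposure 0."""

    grid: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    exposure_name: str = "exposure"

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.hr = np.asarray(self.hr, dtype=float)
        self.ci_low = np.asarray(self.ci_low, dtype=float)
        self.ci_high = np.asarray(self.ci_high, dtype=float)
        if not (len(self.grid) == len(self.hr) == len(self.ci_low) == len(self.ci_high)):
            raise InputError("curve arrays must share a length")
        if np.any(np.diff(self.grid) <= 0):
            raise InputError("exposure grid must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "exposure": self.grid,
                "hr": self.hr,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


@dataclass
class MinimalDose:
    """ED50: exposure attaining half of the optimal risk reduction."""

    ed50_exposure: float
    hr_at_ed50: float
    ci: tuple[float, float]
    optimal_hr: float


@dataclass
class EValueResult:
    """E-value sensitivity statistic for one estimate and its CI limit."""

    hr_input: float
    evalue_point: float
    evalue_ci: float | None = None

    def rounded(self, ndigits: int = 2) -> tuple[float, float | None]:
        e_ci = None if self.evalue_ci is None else round(self.evalue_ci, ndigits)
        return round(self.evalue_point, ndigits), e_ci


def build_curve(fit, grid_size: int = 512, x_max: float | None = None) -> DoseResponseCurve:
    """Evaluate the adjusted dose-response curve of a fitted model.

    The grid spans [0, x_max] (default: the maximum of the capped analysis
    exposure recorded on the fit). The log hazard ratio at each grid point
    is the contrast ``basis(x)'beta - basis(0)'beta`` restricted to the
    exposure basis; its variance is the quadratic form of that contrast with
    the coefficient covariance, and the 95% band is
    ``exp(log-HR +/- 1.96 SE)``.
    """
    if grid_size < 2:
        raise InputError("grid_size must be >= 2")
    if x_max is None:
        x_max = fit.exposure_max
    if x_max <= 0:
        raise InputError("exposure range must have positive length")
    if x_max > fit.exposure_max * (1 + 1e-9):
        raise InputError(
            f"grid extends beyond the fitted exposure range ({fit.exposure_max:g})"
        )
    grid = np.linspace(0.0, float(x_max), int(grid_size))
    eta, se = fit.log_hr(grid)
    return DoseResponseCurve(
        grid=grid,
        hr=np.exp(eta),
        ci_low=np.exp(eta - Z95 * se),
        ci_high=np.exp(eta + Z95 * se),
        exposure_name=fit.exposure_name,
    )


def hr_at(curve: DoseResponseCurve, x: float) -> tuple[float, tuple[float, float]]:
    """HR and 95% CI at exposure ``x`` by log-scale linear interpolation.

    Exact at grid nodes; interpolated values lie between the neighbouring
    node values.
    """
    x = float(x)
    if x < curve.grid[0] or x > curve.grid[-1]:
        raise InputError(f"exposure {x} outside the curve range")
    hr = float(np.exp(np.interp(x, curve.grid, np.log(curve.hr))))
    lo = float(np.exp(np.interp(x, curve.grid, np.log(curve.ci_low))))
    hi = float(np.exp(np.interp(x, curve.grid, np.log(curve.ci_high))))
    return hr, (lo, hi)


def minimal_dose(curve: DoseResponseCurve) -> MinimalDose:
    """Extract the ED50 minimal dose from a dose-response curve.

    The optimal risk reduction is ``1 - min(HR)`` over the grid; the ED50 is
    the smallest exposure at which the reduction reaches half of that,
    refined by linear interpolation between the bracketing grid points. The
    reported HR and CI are the pointwise curve values at the ED50 exposure.
    """
    hr_min = float(curve.hr.min())
    if hr_min >= 1.0:
        raise NoBenefitError("curve never drops below HR 1; no minimal dose exists")
    target = 1.0 - 0.5 * (1.0 - hr_min)  # HR level at half the optimal reduction
    below = np.flatnonzero(curve.hr <= target)
    k = below[0]
    if k == 0:
        x50 = float(curve.grid[0])
    else:
        x0, x1 = curve.grid[k - 1], curve.grid[k]
        y0, y1 = curve.hr[k - 1], curve.hr[k]
        x50 = float(x0 + (target - y0) / (y1 - y0) * (x1 - x0))
    hr50, ci = hr_at(curve, x50)
    return MinimalDose(ed50_exposure=x50, hr_at_ed50=hr50, ci=ci, optimal_hr=hr_min)


def evalue(hr: float, ci_limit_closer_to_null: float | None = None) -> EValueResult:
    """E-value for an observed hazard ratio (rare-outcome rate-ratio scale).

    A protective estimate (HR < 1) is inverted to ``RR = 1/HR`` before the
    transform ``E = RR + sqrt(RR (RR - 1))``; an estimate at the null maps
    to E = 1. The same transform applies to the confidence limit closer to
    the null (an interval crossing 1 yields E = 1 for the limit).
    """
    if hr <= 0:
        raise InputError(f"hazard ratio must be positive, got {hr}")

    def _e(r: float) -> float:
        if r < 1.0:
            r = 1.0 / r
        if r <= 1.0:
            return 1.0
        return r + np.sqrt(r * (r - 1.0))

    e_ci = None
    if ci_limit_closer_to_null is not None:
        if ci_limit_closer_to_null <= 0:
            raise InputError("CI limit must be positive")
        protective = hr < 1.0
        crosses = (protective and ci_limit_closer_to_null >= 1.0) or (
            not protective and ci_limit_closer_to_null <= 1.0
        )
        e_ci = 1.0 if crosses else _e(float(ci_limit_closer_to_null))
    return EValueResult(hr_input=float(hr), evalue_point=_e(float(hr)), evalue_ci=e_ci)


def plot_curve(curve: DoseResponseCurve, exposures=None, ax=None):
    """Plot the HR curve with its shaded 95% band and, optionally, a
    histogram panel of the sample exposure distribution."""
    import matplotlib.pyplot as plt

    if ax is None:
        if exposures is not None:
            fig, (ax, ax_h) = plt.subplots(
                1, 2, figsize=(8, 4), gridspec_kw={"width_ratios": [3, 1]}
            )
        else:
            fig, ax = plt.subplots(figsize=(6, 4))
            ax_h = None
    else:
        ax_h = None
    ax.fill_between(curve.grid, curve.ci_low, curve.ci_high, alpha=0.25, linewidth=0)
    ax.plot(curve.grid, curve.ci_low, "--", color="C0", linewidth=0.8)
    ax.plot(curve.grid, curve.ci_high, "--", color="C0", linewidth=0.8)
    ax.plot(curve.grid, curve.hr, color="C0")
    ax.axhline(1.0, color="grey", linewidth=0.8)
    ax.set_xlabel(curve.exposure_name)
    ax.set_ylabel("hazard ratio (95% CI)")
    if ax_h is not None and exposures is not None:
        ax_h.hist(np.asarray(exposures, dtype=float), bins=30, orientation="horizontal")
        ax_h.set_xlabel("n")
        ax_h.set_ylabel(curve.exposure_name)
    return ax
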