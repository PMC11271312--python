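"""Plasma-stability and pharmacokinetic quantification.

Two kinds of readout are covered:

* **Disappearance fits** for week-long plasma incubations.  Intact-analyte
  loss in these steady-state incubations is close to linear in time, so the
  default model regresses %-remaining on time and reports the time for the
  fitted line to fall from 100% to 50%.  A log-linear (first-order) model is
  available for exponential decays; a non-negative slope is flagged as
  "stable within the experiment" rather than given a half-life.

* **Non-compartmental analysis** (NCA) of concentration-time profiles:
  linear trapezoidal AUC over a dosing interval (default 0-168 h) and to the
  last quantifiable point, a terminal log-linear rate (lambda_z) with
  half-life ln2/lambda_z, and metabolite exposure expressed as a percentage
  of the parent AUClast.  Values below the lower limit of quantification are
  excluded from every computation, never zero-imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ConcentrationTimeCourse",
    "DisappearanceFit",
    "NCAResult",
    "fit_disappearance",
    "auc_trapezoid",
    "nca",
]


@dataclass(frozen=True)
class ConcentrationTimeCourse:
    """Sampled concentrations for one analyte or metabolite."""

    label: str
    times_h: tuple[float, ...]
    concentrations: tuple[float, ...]
    lloq: float | None = None
    units: str = "nM"

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.shape != c.shape:
            raise ValueError("times and concentrations differ in length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c[~np.isnan(c)] < 0):
            raise ValueError("concentrations must be non-negative")

    @property
    def below_lloq(self) -> np.ndarray:
        c = np.asarray(self.concentrations, dtype=float)
        mask = np.isnan(c)
        if self.lloq is not None:
            mask |= c < self.lloq
        return mask

    def quantified(self) -> tuple[np.ndarray, np.ndarray]:
        """(t, C) restricted to quantifiable points."""
        t = np.asarray(self.times_h, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        keep = ~self.below_lloq
        return t[keep], c[keep]


@dataclass(frozen=True)
class DisappearanceFit:
    model: str  # "linear-percent" | "log-linear"
    slope: float
    intercept: float
    half_life_h: float | None
    r_squared: float
    stable: bool = False

    @property
    def message(self) -> str:
        return "stable within experiment" if self.stable else ""


def _r_squared(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


def fit_disappearance(
    tc: ConcentrationTimeCourse, model: str = "linear-percent"
) -> DisappearanceFit:
    """Fit intact-analyte disappearance and derive a half-life.

    ``linear-percent`` fits C = a + b t and reports the time for the line to
    drop from 100 to 50 (i.e. 50/|b| for %-scale data); ``log-linear`` fits
    ln C = a + b t and reports ln2/|b|.  If the fitted slope is >= 0 the
    analyte did not measurably disappear and the fit is flagged stable.
    """
    t, c = tc.quantified()
    if len(t) < 3:
        raise ValueError("need at least 3 quantified points")

    # regression slope on exactly constant data carries float rounding noise
    flat_tol = 1e-12 * (np.max(np.abs(c)) + 1.0) / (t[-1] - t[0])

    if model == "linear-percent":
        slope, intercept = np.polyfit(t, c, 1)
        fitted = intercept + slope * t
        r2 = _r_squared(c, fitted)
        if slope >= -flat_tol:
            return DisappearanceFit(model, float(slope), float(intercept), None, r2, stable=True)
        half_life = 50.0 / -slope
    elif model == "log-linear":
        if np.any(c <= 0):
            raise ValueError("log-linear model requires positive concentrations")
        slope, intercept = np.polyfit(t, np.log(c), 1)
        fitted = intercept + slope * t
        r2 = _r_squared(np.log(c), fitted)
        if slope >= -flat_tol:
            return DisappearanceFit(model, float(slope), float(intercept), None, r2, stable=True)
        half_life = math.log(2.0) / -slope
    else:
        raise ValueError(f"unknown model {model!r}")

    return DisappearanceFit(
        model, float(slope), float(intercept), float(half_life), r2, stable=False
    )


def auc_trapezoid(
    times_h: Sequence[float],
    concentrations: Sequence[float],
    t_end: float | None = None,
) -> float:
    """Linear trapezoidal AUC, optionally truncated (by interpolation) at
    ``t_end``.  If the data end before ``t_end`` the AUC runs to the last
    point (no extrapolation)."""
    t = np.asarray(times_h, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if len(t) < 2:
        return 0.0
    if t_end is not None and t_end < t[-1]:
        c_end = float(np.interp(t_end, t, c))
        keep = t < t_end
        t = np.append(t[keep], t_end)
        c = np.append(c[keep], c_end)
    return float(np.trapezoid(c, t))


@dataclass(frozen=True)
class NCAResult:
    label: str
    auc_0_168h: float
    auc_last: float
    lambda_z: float | None  # 1/h
    terminal_half_life_h: float | None
    exposure_fraction_vs_parent: float | None  # %
    lambda_z_message: str = ""


def _lambda_z(
    tc: ConcentrationTimeCourse, window: tuple[float, float] | None
) -> tuple[float | None, str]:
    t, c = tc.quantified()
    if window is not None:
        keep = (t >= window[0]) & (t <= window[1])
        t, c = t[keep], c[keep]
    if len(t) < 2:
        return None, "fewer than 2 quantified points in terminal window"
    if np.any(c <= 0):
        return None, "non-positive concentrations in terminal window"
    slope, _ = np.polyfit(t, np.log(c), 1)
    if slope >= 0:
        return None, "terminal slope non-negative"
    return float(-slope), ""


def nca(
    parent: ConcentrationTimeCourse,
    metabolites: Sequence[ConcentrationTimeCourse] = (),
    terminal_window: tuple[float, float] | None = None,
    dosing_interval_h: float = 168.0,
) -> dict[str, NCAResult]:
    """Non-compartmental analysis of a parent and its metabolites.

    Returns one :class:`NCAResult` per analyte keyed by label.  Exposure
    fractions are 100 * AUClast(metabolite) / AUClast(parent); the parent's
    own fraction is 100 by construction.
    """
    results: dict[str, NCAResult] = {}
    t_p, c_p = parent.quantified()
    parent_auc_last = auc_trapezoid(t_p, c_p)

    for tc in (parent, *metabolites):
        t, c = tc.quantified()
        auc_last = auc_trapezoid(t, c)
        auc_interval = auc_trapezoid(t, c, t_end=dosing_interval_h)
        lz, msg = _lambda_z(tc, terminal_window)
        if parent_auc_last > 0:
            fraction = 100.0 * auc_last / parent_auc_last
        else:
            fraction = None
        results[tc.label] = NCAResult(
            label=tc.label,
            auc_0_168h=auc_interval,
            auc_last=auc_last,
            lambda_z=lz,
            terminal_half_life_h=(math.log(2.0) / lz if lz else None),
            exposure_fraction_vs_parent=fraction,
            lambda_z_message=msg,
        )
    return results


def percentages_of_total(results: Mapping[str, NCAResult]) -> dict[str, float]:
    """Each component's AUClast as a percentage of the summed AUClast."""
    total = sum(r.auc_last for r in results.values())
    if total <= 0:
        raise ValueError("total AUC is zero")
    return {k: 100.0 * r.auc_last / total for k, r in results.items()}
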