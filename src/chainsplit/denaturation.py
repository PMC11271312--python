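"""Two-state chemical-denaturation analysis of multi-wavelength CD data.

Unfolding by guanidine hydrochloride (GuHCl) is modelled with the linear
extrapolation method: the unfolding free energy depends linearly on the
denaturant concentration D,

    dG(D) = m * (Cm - D),

so the unfolded fraction is a Boltzmann sigmoid

    f(D) = 1 / (1 + exp(dG(D) / RT)),      f(Cm) = 1/2.

Each wavelength carries its own linear folded and unfolded baselines, and the
observed signal is the population-weighted mixture

    Y(lambda, D) = (1 - f) * (Y_N + s_N D) + f * (Y_U + s_U D).

The global fit shares Cm (the midpoint, in M GuHCl — the headline statistic)
and the m-value across wavelengths while giving every wavelength four
baseline parameters.  Internally the fit profiles the baselines out by linear
least squares, so the nonlinear search runs over (Cm, m) only; this keeps the
86-parameter problem (2 + 4 x 21 wavelengths) fast and well conditioned.

Helpers cover the supporting bench math: the tyrosine extinction-coefficient
ladder for concentration determination at 276 nm, Beer-Lambert conversion,
and the refractometric GuHCl concentration polynomial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "EPSILON_276_FOUR_TYR",
    "GUHCL_RI_COEFFS",
    "RT_KJ_PER_MOL",
    "extinction_coefficient",
    "concentration_from_absorbance",
    "guhcl_from_refractive_index",
    "fraction_unfolded",
    "two_state_signal",
    "TwoStateParams",
    "CDDataset",
    "GlobalFitResult",
    "global_fit_unfolding",
]

#: Molar extinction at 276 nm for an insulin analogue with four tyrosines.
EPSILON_276_FOUR_TYR = 6.20e3  # M-1 cm-1

#: GuHCl molarity from refractive-index increment dN (refractometric method):
#: C = 57.147 dN + 38.68 dN^2 - 91.60 dN^3
GUHCL_RI_COEFFS = (57.147, 38.68, -91.60)

#: RT at 25 C in kJ/mol (CD measured at 25 C).
RT_KJ_PER_MOL = 8.314462618e-3 * 298.15


def extinction_coefficient(n_tyr: int) -> float:
    """Epsilon(276 nm) for an analogue with ``n_tyr`` tyrosines.

    All tyrosines are assumed to contribute equally, so the ladder is exactly
    proportional: 6.20e3 * n/4 (4 -> 6.20e3, 3 -> 4.65e3, 2 -> 3.10e3).
    """
    if not 1 <= n_tyr <= 4:
        raise ValueError(f"n_tyr must be in 1..4, got {n_tyr}")
    return EPSILON_276_FOUR_TYR * n_tyr / 4.0


def concentration_from_absorbance(
    a276: float, n_tyr: int, pathlength_cm: float = 1.0
) -> float:
    """Beer-Lambert protein concentration (M) from A276."""
    if a276 < 0:
        raise ValueError("absorbance must be non-negative")
    if pathlength_cm <= 0:
        raise ValueError("pathlength must be positive")
    return a276 / (extinction_coefficient(n_tyr) * pathlength_cm)


def guhcl_from_refractive_index(n_solution: float, n_buffer: float) -> float:
    """GuHCl concentration (M) from the refractive-index increment at 25 C."""
    dn = n_solution - n_buffer
    if dn < 0:
        raise ValueError("solution refractive index below buffer")
    c1, c2, c3 = GUHCL_RI_COEFFS
    return c1 * dn + c2 * dn**2 + c3 * dn**3


def fraction_unfolded(
    denaturant_M, cm_M: float, m_value: float, rt_kj: float = RT_KJ_PER_MOL
):
    """Unfolded fraction under the linear extrapolation model."""
    d = np.asarray(denaturant_M, dtype=float)
    dg = m_value * (cm_M - d)
    return 1.0 / (1.0 + np.exp(dg / rt_kj))


@dataclass(frozen=True)
class TwoStateParams:
    """Shared (Cm, m) plus per-wavelength linear baselines.

    ``baselines`` maps wavelength -> (Y_N, s_N, Y_U, s_U).
    """

    cm_M: float
    m_value: float  # kJ mol-1 M-1
    baselines: Mapping[float, tuple[float, float, float, float]]
    rt_kj: float = RT_KJ_PER_MOL

    def __post_init__(self) -> None:
        if self.m_value <= 0:
            raise ValueError("m_value must be positive")


def two_state_signal(params: TwoStateParams, wavelength: float, denaturant_M):
    """Model signal at one wavelength over denaturant concentrations."""
    if wavelength not in params.baselines:
        raise KeyError(f"no baseline parameters for wavelength {wavelength}")
    yn, sn, yu, su = params.baselines[wavelength]
    d = np.asarray(denaturant_M, dtype=float)
    f = fraction_unfolded(d, params.cm_M, params.m_value, params.rt_kj)
    return (1.0 - f) * (yn + sn * d) + f * (yu + su * d)


@dataclass(frozen=True)
class CDDataset:
    """Absorbance-normalised CD signal on a wavelength x denaturant grid."""

    wavelengths_nm: tuple[float, ...]
    denaturant_M: tuple[float, ...]
    signal: np.ndarray  # shape (n_wavelengths, n_denaturant)
    temperature_K: float = 298.15
    analyte: str = ""

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        if sig.shape != (len(self.wavelengths_nm), len(self.denaturant_M)):
            raise ValueError(
                f"signal shape {sig.shape} does not match grids "
                f"({len(self.wavelengths_nm)} wavelengths x "
                f"{len(self.denaturant_M)} denaturant points)"
            )
        d = np.asarray(self.denaturant_M)
        if np.any(d < 0) or np.any(np.diff(d) <= 0):
            raise ValueError("denaturant grid must be non-negative and increasing")
        object.__setattr__(self, "signal", sig)


@dataclass(frozen=True)
class GlobalFitResult:
    params: TwoStateParams
    sse: float
    n_params: int
    converged: bool
    message: str = ""
    residuals: np.ndarray | None = None

    @property
    def cm_M(self) -> float:
        return self.params.cm_M

    @property
    def m_value(self) -> float:
        return self.params.m_value


def _profiled_residuals(theta, d, signal, rt_kj):
    """Residual matrix after profiling the per-wavelength linear baselines.

    For fixed (Cm, m) the model is linear in (Y_N, s_N, Y_U, s_U); the same
    design matrix serves every wavelength, so one pseudoinverse solves all
    baselines at once.
    """
    cm, m = theta
    f = fraction_unfolded(d, cm, m, rt_kj)
    X = np.column_stack([(1 - f), (1 - f) * d, f, f * d])  # (nD, 4)
    coef, *_ = np.linalg.lstsq(X, signal.T, rcond=None)  # (4, nL)
    fitted = X @ coef  # (nD, nL)
    return fitted.T - signal, coef, f


def global_fit_unfolding(
    data: CDDataset,
    m0: float = 4.0,
    rt_kj: float | None = None,
) -> GlobalFitResult:
    """Globally fit the two-state model to a wavelength x denaturant matrix.

    Cm is initialised at the denaturant concentration of steepest average
    signal change; m at ``m0`` (kJ mol-1 M-1).  If the fitted transition is
    not bracketed by the data (unfolded fraction stays below 0.2 or above 0.8
    everywhere) the result is flagged unconverged.
    """
    if len(data.wavelengths_nm) < 1:
        raise ValueError("need at least one wavelength")
    if len(data.denaturant_M) < 10:
        raise ValueError("need at least 10 denaturant points")
    rt = RT_KJ_PER_MOL if rt_kj is None else rt_kj

    d = np.asarray(data.denaturant_M, dtype=float)
    sig = data.signal

    # steepest mean |dY/dD| across wavelengths
    dmid = 0.5 * (d[1:] + d[:-1])
    slope = np.abs(np.diff(sig, axis=1) / np.diff(d)).mean(axis=0)
    cm0 = float(dmid[np.argmax(slope)])

    def residuals(theta):
        res, _, _ = _profiled_residuals(theta, d, sig, rt)
        return res.ravel()

    sol = least_squares(
        residuals,
        x0=[cm0, m0],
        bounds=([d.min() - 10.0, 1e-6], [d.max() + 10.0, np.inf]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    cm, m = sol.x
    res, coef, f = _profiled_residuals(sol.x, d, sig, rt)
    baselines = {
        wl: tuple(float(c) for c in coef[:, i])
        for i, wl in enumerate(data.wavelengths_nm)
    }
    params = TwoStateParams(cm_M=float(cm), m_value=float(m), baselines=baselines, rt_kj=rt)
    sse = float(np.sum(res**2))
    n_params = 2 + 4 * len(data.wavelengths_nm)

    converged = bool(sol.success)
    message = "" if converged else sol.message
    if np.all(f < 0.2) or np.all(f > 0.8):
        converged = False
        message = "transition not bracketed by the denaturant range"
    return GlobalFitResult(
        params=params,
        sse=sse,
        n_params=n_params,
        converged=converged,
        message=message,
        residuals=res,
    )
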