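"""Glutathione redox-stability assay model.

The assay incubates an insulin analogue for a fixed time across a series of
solution redox potentials set by mixing reduced glutathione (GSH, varied
0-25 mM) against a fixed 1 mM of oxidised glutathione (GSSG).  The solution
potential of the GSSG/2GSH couple follows the Nernst equation

    E = E0' - (RT / 2F) * ln([GSH]^2 / [GSSG])        (concentrations in M)

Remaining intact insulin, normalised to the 0 mM GSH control, is fitted as a
constrained sigmoid of potential (Top = 100, Bottom = Baseline = 0):

    y(E) = 100 / (1 + 10 ** (h * (E50 - E)))

E50, the potential at which half the material survives the incubation, is the
stability readout: the more negative E50, the more reducing the environment
has to be before the analogue splits, i.e. the more stable the analogue.

The standard potential E0' of the glutathione couple is a configurable
constant (default -240 mV, the conventional value at pH 7, 25 C); no pH
correction is applied, so the potential axis is relative to that convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "GAS_CONSTANT",
    "FARADAY",
    "E0_PRIME_DEFAULT_MV",
    "RAT_PLASMA_POTENTIAL_MV",
    "HUMAN_PLASMA_POTENTIAL_MV",
    "RedoxCondition",
    "RedoxPlate",
    "SigmoidFitResult",
    "nernst_potential",
    "sigmoid_intact",
    "fit_redox_stability",
]

GAS_CONSTANT = 8.314462618  # J mol-1 K-1
FARADAY = 96485.33212  # C mol-1

#: Conventional standard potential of the GSSG/2GSH couple (pH 7, 25 C).
E0_PRIME_DEFAULT_MV = -240.0

#: Literature glutathione redox potentials of plasma, useful as axis markers.
RAT_PLASMA_POTENTIAL_MV = -175.0
HUMAN_PLASMA_POTENTIAL_MV = -137.0


@dataclass(frozen=True)
class RedoxCondition:
    """One well: GSH/GSSG concentrations defining a solution potential."""

    gsh_mM: float
    gssg_mM: float = 1.0
    temperature_K: float = 310.15
    e0_prime_mV: float = E0_PRIME_DEFAULT_MV

    def __post_init__(self) -> None:
        if self.gssg_mM <= 0:
            raise ValueError("gssg_mM must be positive")
        if self.gsh_mM < 0:
            raise ValueError("gsh_mM must be non-negative")

    @property
    def is_control(self) -> bool:
        return self.gsh_mM == 0

    @property
    def potential_mV(self) -> float:
        return nernst_potential(self)


def nernst_potential(condition: RedoxCondition) -> float:
    """Solution potential (mV) of the GSSG/2GSH couple.

    The 0 mM GSH control has no defined potential and returns NaN.
    """
    if condition.is_control:
        return math.nan
    rt_2f_mV = GAS_CONSTANT * condition.temperature_K / (2 * FARADAY) * 1e3
    gsh_M = condition.gsh_mM * 1e-3
    gssg_M = condition.gssg_mM * 1e-3
    return condition.e0_prime_mV - rt_2f_mV * math.log(gsh_M**2 / gssg_M)


@dataclass(frozen=True)
class RedoxPlate:
    """A titration series with its measured intact-insulin signals."""

    analyte: str
    conditions: tuple[RedoxCondition, ...]
    intact_signal: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.conditions) != len(self.intact_signal):
            raise ValueError("conditions and signals differ in length")
        if any(s < 0 for s in self.intact_signal):
            raise ValueError("signals must be non-negative")
        n_controls = sum(c.is_control for c in self.conditions)
        if n_controls != 1:
            raise ValueError(
                f"expected exactly one 0 mM GSH control, found {n_controls}"
            )

    @property
    def control_signal(self) -> float:
        for cond, sig in zip(self.conditions, self.intact_signal):
            if cond.is_control:
                return sig
        raise AssertionError("unreachable: control enforced in __post_init__")

    def normalized(self) -> tuple[np.ndarray, np.ndarray]:
        """(potentials mV, % intact) for the non-control wells, normalised so
        the control reads exactly 100."""
        ctrl = self.control_signal
        if ctrl <= 0:
            raise ValueError("control signal must be positive for normalisation")
        pot, pct = [], []
        for cond, sig in zip(self.conditions, self.intact_signal):
            if cond.is_control:
                continue
            pot.append(cond.potential_mV)
            pct.append(100.0 * sig / ctrl)
        return np.asarray(pot), np.asarray(pct)


@dataclass(frozen=True)
class SigmoidFitResult:
    """Constrained absolute-IC50 sigmoid fit (Top=100, Bottom=Baseline=0)."""

    e50_mV: float
    hill_slope: float
    residual_sse: float
    converged: bool
    message: str = ""
    top: float = 100.0
    bottom: float = 0.0


def sigmoid_intact(potential_mV, e50_mV: float, hill_slope: float):
    """% intact as a function of potential for the constrained sigmoid."""
    e = np.asarray(potential_mV, dtype=float)
    return 100.0 / (1.0 + 10.0 ** (hill_slope * (e50_mV - e)))


def fit_redox_stability(plate: RedoxPlate) -> SigmoidFitResult:
    """Fit E50 and the slope from a normalised titration.

    Normalised values are not clipped at 100; the asymptotes are fixed, not
    fitted, so noise above the control does not bias E50.  If every well
    retains more than 90% intact the transition was not reached within the
    scanned potential range and the fit is flagged unconverged.
    """
    potentials, pct = plate.normalized()
    if len(potentials) < 5:
        raise ValueError("need at least 5 non-control conditions")

    if np.all(pct > 90.0):
        return SigmoidFitResult(
            e50_mV=math.nan,
            hill_slope=math.nan,
            residual_sse=float(np.sum((pct - 100.0) ** 2)),
            converged=False,
            message="no transition observed: E50 below scanned range",
        )

    # start at the well closest to 50% intact
    e50_0 = float(potentials[np.argmin(np.abs(pct - 50.0))])
    h0 = 0.05

    def residuals(theta):
        e50, h = theta
        return sigmoid_intact(potentials, e50, h) - pct

    span = potentials.max() - potentials.min()
    sol = least_squares(
        residuals,
        x0=[e50_0, h0],
        bounds=([potentials.min() - 2 * span, 1e-6], [potentials.max() + 2 * span, np.inf]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    e50, h = sol.x
    return SigmoidFitResult(
        e50_mV=float(e50),
        hill_slope=float(h),
        residual_sse=float(2 * sol.cost),
        converged=bool(sol.success),
        message=sol.message if not sol.success else "",
    )
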