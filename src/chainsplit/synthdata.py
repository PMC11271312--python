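"""Seeded generators for every assay the analysis stages consume.

Each generator is a pure function of its parameters and a
:class:`SimulationConfig`; the same config always produces bit-identical
output.  The generators emulate the statistical structure of the bench
assays — a redox titration plate with a fixed 1 mM GSSG arm, multi-wavelength
CD unfolding curves with per-wavelength linear baselines, linear plasma
disappearance with concomitant B-chain appearance, one-compartment PK with
parent-to-metabolite formation, and toy crystal structures with assigned
B-factors and disulphides — so the full pipeline is testable offline.

The noise model throughout is additive Gaussian on the measured scale with a
standard deviation expressed as a fraction of the signal's dynamic range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .denaturation import CDDataset, TwoStateParams, two_state_signal
from .pk import ConcentrationTimeCourse
from .redox import RedoxCondition, RedoxPlate, sigmoid_intact
from .structure import Atom, StructureModel

__all__ = [
    "SimulationConfig",
    "PLASMA_SAMPLING_GRID_H",
    "HUMAN_SERUM_GRID_H",
    "simulate_redox_plate",
    "simulate_cd_unfolding",
    "simulate_plasma_timecourse",
    "simulate_pk_profile",
    "build_toy_structure",
]

#: In vitro plasma incubation sampling times (hours).
PLASMA_SAMPLING_GRID_H = (0.25, 2.5, 5.0, 24.0, 48.0, 72.0, 96.0, 168.0)

#: Human steady-state serum sampling times after the fifth weekly dose.
HUMAN_SERUM_GRID_H = (0.0, 20.0, 168.0, 348.0, 516.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Seed plus noise level and grid choices shared by the generators."""

    seed: int = 0
    noise_sd: float = 0.02  # fraction of dynamic range
    redox_n_levels: int = 12  # two-fold GSH dilutions from 25 mM
    redox_gsh_max_mM: float = 25.0
    cd_wavelengths_nm: tuple[float, ...] = tuple(
        218.0 + 0.5 * i for i in range(21)
    )  # 218-228 nm at 2 pt/nm
    cd_denaturant_M: tuple[float, ...] = tuple(
        round(8.3 * i / 21, 6) for i in range(22)
    )  # 22 points, 0-8.3 M

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))


def simulate_redox_plate(
    e50_mV: float = -160.0,
    hill: float = 0.05,
    config: SimulationConfig = SimulationConfig(),
    analyte: str = "synthetic",
    gssg_mM: float = 1.0,
    n_levels: int | None = None,
) -> RedoxPlate:
    """Simulate a redox titration plate.

    The GSH arm is a two-fold dilution series from 25 mM (``n_levels``
    concentrations) plus the 0 mM control; GSSG is fixed at 1 mM.  % intact
    follows the constrained sigmoid of the solution potential with additive
    Gaussian noise (sd = ``noise_sd`` x 100%); the control itself is
    noiseless at 100 so normalisation is exact.
    """
    if hill <= 0:
        raise ValueError("hill slope must be positive")
    n = config.redox_n_levels if n_levels is None else n_levels
    gsh = [config.redox_gsh_max_mM / 2**i for i in range(n)]
    conditions = [RedoxCondition(gsh_mM=0.0, gssg_mM=gssg_mM)] + [
        RedoxCondition(gsh_mM=g, gssg_mM=gssg_mM) for g in gsh
    ]
    rng = config.rng(stream=1)
    signals = [100.0]
    for cond in conditions[1:]:
        y = float(sigmoid_intact(cond.potential_mV, e50_mV, hill))
        signals.append(max(y + rng.normal(0.0, config.noise_sd * 100.0), 0.0))
    return RedoxPlate(
        analyte=analyte,
        conditions=tuple(conditions),
        intact_signal=tuple(signals),
    )


def simulate_cd_unfolding(
    cm_M: float = 4.50,
    m_value: float = 4.0,
    config: SimulationConfig = SimulationConfig(),
    analyte: str = "synthetic",
) -> CDDataset:
    """Simulate a multi-wavelength GuHCl unfolding CD matrix.

    21 wavelengths (218-228 nm) x 22 denaturant points (0-8.3 M) by default.
    Per-wavelength folded/unfolded intercepts and slopes are drawn once from
    the seeded generator (folded ellipticity more negative than unfolded,
    gentle slopes), then two-state signals are computed and Gaussian noise
    with sd = ``noise_sd`` x (global signal range) is added.
    """
    d = np.asarray(config.cd_denaturant_M)
    if not (d.min() < cm_M < d.max()):
        raise ValueError("generating midpoint must lie inside the denaturant range")
    rng = config.rng(stream=2)
    baselines = {}
    for wl in config.cd_wavelengths_nm:
        yn = rng.uniform(-12.0, -8.0)
        sn = rng.uniform(-0.15, 0.15)
        yu = rng.uniform(-4.0, -2.0)
        su = rng.uniform(-0.10, 0.10)
        baselines[wl] = (yn, sn, yu, su)
    params = TwoStateParams(cm_M=cm_M, m_value=m_value, baselines=baselines)
    clean = np.vstack(
        [two_state_signal(params, wl, d) for wl in config.cd_wavelengths_nm]
    )
    span = clean.max() - clean.min()
    noisy = clean + rng.normal(0.0, config.noise_sd * span, size=clean.shape)
    return CDDataset(
        wavelengths_nm=tuple(config.cd_wavelengths_nm),
        denaturant_M=tuple(config.cd_denaturant_M),
        signal=noisy,
        analyte=analyte,
    )


def simulate_plasma_timecourse(
    k_split_per_h: float,
    k_chain_loss_per_h: float = 0.0,
    config: SimulationConfig = SimulationConfig(),
    times_h: Sequence[float] = PLASMA_SAMPLING_GRID_H,
) -> tuple[ConcentrationTimeCourse, ConcentrationTimeCourse]:
    """Simulate parent disappearance and B-chain appearance in plasma.

    First-order chain-splitting of the parent (rate ``k_split_per_h``) feeds
    the free B-chain, which itself decays at ``k_chain_loss_per_h``:

        P(t) = 100 exp(-ks t)
        B(t) = 100 ks/(kl - ks) (exp(-ks t) - exp(-kl t))   (kl != ks)

    Units are % of the initial parent, so with ``k_chain_loss_per_h = 0`` the
    noiseless curves conserve P + B = 100 exactly.
    """
    ks, kl = k_split_per_h, k_chain_loss_per_h
    if ks < 0 or kl < 0:
        raise ValueError("rates must be non-negative")
    t = np.asarray(times_h, dtype=float)
    parent = 100.0 * np.exp(-ks * t)
    if ks == 0:
        bchain = np.zeros_like(t)
    elif abs(kl - ks) < 1e-12:
        bchain = 100.0 * ks * t * np.exp(-ks * t)
    else:
        bchain = 100.0 * ks / (kl - ks) * (np.exp(-ks * t) - np.exp(-kl * t))
    rng = config.rng(stream=3)
    if config.noise_sd > 0:
        parent = np.clip(parent + rng.normal(0, config.noise_sd * 100.0, t.shape), 0, None)
        bchain = np.clip(bchain + rng.normal(0, config.noise_sd * 100.0, t.shape), 0, None)
    make = lambda label, c: ConcentrationTimeCourse(
        label=label, times_h=tuple(t), concentrations=tuple(c), units="% of t0"
    )
    return make("parent", parent), make("B-chain", bchain)


def simulate_pk_profile(
    c0_nM: float = 100.0,
    k_elim_per_h: float = 0.01,
    k_split_per_h: float = 0.004,
    k_bchain_elim_per_h: float = 0.006,
    config: SimulationConfig = SimulationConfig(),
    lloq_nM: float = 0.2,
    t_max_h: float = 240.0,
    n_times: int = 49,
) -> tuple[ConcentrationTimeCourse, ConcentrationTimeCourse]:
    """Simulate intravenous parent PK with metabolite formation.

    The parent is a one-compartment mono-exponential with total rate
    kp = k_elim + k_split; the B-chain follows the Bateman curve

        B(t) = c0 ks/(kp - kb) (exp(-kb t) - exp(-kp t)).

    Concentrations are censored at the LLOQ (reported as NaN) after noise.
    """
    for k in (k_elim_per_h, k_split_per_h, k_bchain_elim_per_h):
        if k < 0:
            raise ValueError("rates must be non-negative")
    kp = k_elim_per_h + k_split_per_h
    kb = k_bchain_elim_per_h
    t = np.linspace(0.0, t_max_h, n_times)
    parent = c0_nM * np.exp(-kp * t)
    if k_split_per_h == 0:
        bchain = np.zeros_like(t)
    elif abs(kp - kb) < 1e-12:
        bchain = c0_nM * k_split_per_h * t * np.exp(-kp * t)
    else:
        bchain = c0_nM * k_split_per_h / (kp - kb) * (np.exp(-kb * t) - np.exp(-kp * t))
    rng = config.rng(stream=4)
    if config.noise_sd > 0:
        parent = np.clip(parent * (1 + rng.normal(0, config.noise_sd, t.shape)), 0, None)
        bchain = np.clip(bchain * (1 + rng.normal(0, config.noise_sd, t.shape)), 0, None)

    def censor(c):
        c = c.copy()
        c[c < lloq_nM] = np.nan
        return c

    # keep t=0 of the parent quantifiable even if dosed below LLOQ
    make = lambda label, c: ConcentrationTimeCourse(
        label=label,
        times_h=tuple(t),
        concentrations=tuple(censor(c)),
        lloq=lloq_nM,
        units="nM",
    )
    return make("parent", parent), make("B-chain", bchain)


# ---------------------------------------------------------------------------
# Toy structures


def _place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float):
    """Internal-coordinate atom placement (NeRF): position a new atom at the
    given bond length/angle/dihedral relative to atoms c-b-a."""
    angle = math.radians(angle_deg)
    dihedral = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(dihedral),
            bond * math.sin(angle) * math.sin(dihedral),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _poly_ala_helix(n_res: int) -> list[dict[str, np.ndarray]]:
    """Ideal alpha-helix backbone (phi=-57, psi=-47, omega=180) with CB and O."""
    phi, psi, omega = -57.0, -47.0, 180.0
    # seed atoms for the first residue
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([1.458, 0.0, 0.0])
    c0 = ca0 + 1.525 * np.array(
        [math.cos(math.radians(180 - 111.2)), math.sin(math.radians(180 - 111.2)), 0.0]
    )
    residues = [{"N": n0, "CA": ca0, "C": c0}]
    for _ in range(1, n_res):
        prev = residues[-1]
        n = _place_atom(prev["N"], prev["CA"], prev["C"], 1.329, 116.2, psi)
        ca = _place_atom(prev["CA"], prev["C"], n, 1.458, 121.7, omega)
        c = _place_atom(prev["C"], n, ca, 1.525, 111.2, phi)
        residues.append({"N": n, "CA": ca, "C": c})
    for i, res in enumerate(residues):
        nxt = residues[i + 1]["N"] if i + 1 < n_res else None
        if nxt is not None:
            res["O"] = _place_atom(res["N"], res["CA"], res["C"], 1.231, 120.8, psi + 180.0)
        else:
            res["O"] = _place_atom(res["N"], res["CA"], res["C"], 1.231, 120.8, 0.0)
        res["CB"] = _place_atom(res["C"], res["N"], res["CA"], 1.521, 110.5, -122.0)
    return residues


def _helix_with_b(n_res: int, b_values: Sequence[float]) -> StructureModel:
    residues = _poly_ala_helix(n_res)
    atoms = []
    for i, res in enumerate(residues):
        for name, xyz in res.items():
            element = name[0]
            atoms.append(
                Atom(
                    element=element,
                    name=name,
                    x=float(xyz[0]),
                    y=float(xyz[1]),
                    z=float(xyz[2]),
                    b_iso=float(b_values[i]),
                    chain="A",
                    resnum=i + 1,
                    resname="ALA",
                )
            )
    return StructureModel(atoms=tuple(atoms), label="toy-helix")


def _cystine_atoms(center: np.ndarray, chain_a: str, res_a: int, chain_b: str, res_b: int, b: float = 20.0):
    """A minimal cystine: two CB-SG arms with a 2.05 A S-S bond along x."""
    half = 1.025
    sg1 = center + np.array([-half, 0.0, 0.0])
    sg2 = center + np.array([half, 0.0, 0.0])
    cb1 = sg1 + np.array([-1.1, 1.4, 0.0])
    cb2 = sg2 + np.array([1.1, 1.4, 0.0])
    mk = lambda el, nm, xyz, ch, rn: Atom(
        element=el, name=nm, x=float(xyz[0]), y=float(xyz[1]), z=float(xyz[2]),
        b_iso=b, chain=ch, resnum=rn, resname="CYS",
    )
    return [
        mk("C", "CB", cb1, chain_a, res_a),
        mk("S", "SG", sg1, chain_a, res_a),
        mk("S", "SG", sg2, chain_b, res_b),
        mk("C", "CB", cb2, chain_b, res_b),
    ]


def _buried_vs_exposed(config: SimulationConfig) -> StructureModel:
    """Two-chain toy assembly: one surface disulphide, one shell-buried one.

    The exposed bond links chain A residue 1 to chain B residue 1 and sits on
    top of a small carbon platform; the buried bond (chain A residues 2-3)
    sits at the centre of a dense carbon shell that excludes the probe.
    """
    atoms: list[Atom] = []
    # buried cystine at the origin inside a 5.5 A carbon shell
    atoms += _cystine_atoms(np.array([0.0, 0.0, 0.0]), "A", 2, "A", 3)
    from .structure import sphere_points

    shell = 5.5 * sphere_points(220)
    for i, xyz in enumerate(shell):
        atoms.append(
            Atom(
                element="C",
                name="CA",
                x=float(xyz[0]),
                y=float(xyz[1]),
                z=float(xyz[2]),
                b_iso=30.0,
                chain="A",
                resnum=10 + i,
                resname="SHL",
            )
        )
    # exposed cystine far from the shell, resting on top of a flat platform
    # 3.5 A below: the sulphurs keep their upward hemisphere open to solvent
    center = np.array([30.0, 0.0, 0.0])
    atoms += _cystine_atoms(center, "A", 1, "B", 1)
    k = 0
    for dx in range(-3, 4):
        for dy in range(-3, 4):
            atoms.append(
                Atom(
                    element="C",
                    name="CA",
                    x=float(center[0] + 1.5 * dx),
                    y=float(center[1] + 1.5 * dy),
                    z=-3.5,
                    b_iso=30.0,
                    chain="B",
                    resnum=10 + k,
                    resname="PLT",
                )
            )
            k += 1
    return StructureModel(atoms=tuple(atoms), label="toy-disulphides")


def build_toy_structure(
    kind: str,
    config: SimulationConfig = SimulationConfig(),
    n_res: int = 15,
    b_values: Sequence[float] | None = None,
) -> StructureModel:
    """Generate a toy structure fixture.

    ``"helix-with-B"``: ideal poly-Ala alpha-helix with per-residue B values
    (default all 20).  ``"buried-vs-exposed-disulphide"``: a two-chain
    assembly with one solvent-facing and one shell-enclosed disulphide.
    """
    if kind == "helix-with-B":
        if b_values is None:
            b_values = [20.0] * n_res
        if len(b_values) != n_res:
            raise ValueError("need one B value per residue")
        return _helix_with_b(n_res, b_values)
    if kind == "buried-vs-exposed-disulphide":
        return _buried_vs_exposed(config)
    raise ValueError(f"unknown toy structure kind {kind!r}")
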