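"""Structure analysis: SASA, disulphide exposure, B-factors, superposition.

Reads PDB/mmCIF models (via gemmi), computes Shrake-Rupley solvent-accessible
surface area and the relative solvent exposure of disulphide sulphur pairs,
summarises crystallographic B-factors over residue selections (the
B-helix-normalised flexibility readout), performs Kabsch least-squares
superposition with RMSD, and measures minimum inter-group contact distances.

Relative disulphide exposure is defined against an explicit reference state:
the two bonded cysteines' Cbeta/Sgamma atoms extracted at their in-situ
coordinates and re-evaluated in isolation.  A fully surface-exposed bond
therefore approaches 1, a core-buried bond approaches 0.
"""

from __future__ import annotations

import math
import urllib.request
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .analyte import DisulphideTopology

__all__ = [
    "Atom",
    "StructureModel",
    "ResidueSelection",
    "SasaResult",
    "BFactorReport",
    "SuperpositionResult",
    "BONDI_RADII",
    "read_structure",
    "write_pdb",
    "sphere_points",
    "shrake_rupley_sasa",
    "sasa_relative_exposure",
    "bfactor_table",
    "kabsch",
    "superpose_rmsd",
    "contact_distance",
    "fetch_structure",
    "CHAIN_MAPS",
]

#: Bondi van der Waals radii (Angstrom).
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "SE": 1.90,
}
DEFAULT_VDW = 1.70


@dataclass(frozen=True)
class Atom:
    element: str
    name: str
    x: float
    y: float
    z: float
    b_iso: float = 0.0
    occupancy: float = 1.0
    altloc: str = ""
    chain: str = "A"
    resnum: int = 1
    resname: str = "UNK"
    het: bool = False

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class StructureModel:
    """A flat list of atoms with convenience selectors."""

    atoms: tuple[Atom, ...]
    label: str = ""

    def __post_init__(self) -> None:
        keys = [(a.chain, a.resnum, a.name, a.altloc) for a in self.atoms]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, residue, atom, altloc) key")
        for a in self.atoms:
            if not all(math.isfinite(v) for v in (a.x, a.y, a.z)):
                raise ValueError("non-finite coordinate")
            if not 0.0 <= a.occupancy <= 1.0:
                raise ValueError(f"occupancy {a.occupancy} outside [0, 1]")

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms])

    def select(
        self,
        chain: str | None = None,
        resnums: Iterable[int] | None = None,
        atom_names: Iterable[str] | None = None,
        elements: Iterable[str] | None = None,
        include_het: bool = True,
        exclude_hydrogen: bool = False,
    ) -> "StructureModel":
        resnums = set(resnums) if resnums is not None else None
        atom_names = set(atom_names) if atom_names is not None else None
        elements = {e.upper() for e in elements} if elements is not None else None
        picked = tuple(
            a
            for a in self.atoms
            if (chain is None or a.chain == chain)
            and (resnums is None or a.resnum in resnums)
            and (atom_names is None or a.name in atom_names)
            and (elements is None or a.element.upper() in elements)
            and (include_het or not a.het)
            and not (exclude_hydrogen and a.element.upper() == "H")
        )
        return StructureModel(atoms=picked, label=self.label)

    def find_atom(self, chain: str, resnum: int, name: str) -> Atom | None:
        for a in self.atoms:
            if a.chain == chain and a.resnum == resnum and a.name == name:
                return a
        return None

    @property
    def protein_residue_count(self) -> int:
        return len({(a.chain, a.resnum) for a in self.atoms if not a.het})


def read_structure(path: str | Path) -> StructureModel:
    """Load a PDB or mmCIF file into a :class:`StructureModel`.

    Alternate locations are resolved to the highest-occupancy conformer;
    waters and other heteroatoms are retained but flagged ``het``.
    """
    import gemmi

    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse structure file {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            het = residue.het_flag == "H"
            # resolve altlocs: keep the highest-occupancy conformer per name
            best: dict[str, "gemmi.Atom"] = {}
            for at in residue:
                prev = best.get(at.name)
                if prev is None or at.occ > prev.occ:
                    best[at.name] = at
            for at in best.values():
                atoms.append(
                    Atom(
                        element=at.element.name,
                        name=at.name,
                        x=at.pos.x,
                        y=at.pos.y,
                        z=at.pos.z,
                        b_iso=at.b_iso,
                        occupancy=min(max(at.occ, 0.0), 1.0),
                        altloc="",
                        chain=chain.name,
                        resnum=residue.seqid.num,
                        resname=residue.name,
                        het=het,
                    )
                )
    return StructureModel(atoms=tuple(atoms), label=path.stem)


def write_pdb(model: StructureModel, path: str | Path) -> Path:
    """Write a minimal, standard-conforming PDB file."""
    path = Path(path)
    lines = []
    for i, a in enumerate(model.atoms, start=1):
        record = "HETATM" if a.het else "ATOM  "
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        lines.append(
            f"{record}{i:5d} {name}{a.altloc or ' '}{a.resname:>3s} "
            f"{a.chain[:1]}{a.resnum:4d}    "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}{a.b_iso:6.2f}"
            f"          {a.element.upper():>2s}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (Fibonacci spiral)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    theta = phi * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def atom_radii(elements: Sequence[str]) -> np.ndarray:
    return np.array([BONDI_RADII.get(e.upper(), DEFAULT_VDW) for e in elements])


def shrake_rupley_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Angstrom^2).

    Each atom is expanded by the probe radius and sampled with ``n_points``
    test points; a point survives if it lies outside every neighbouring
    expanded sphere.  An isolated atom returns exactly the closed-form
    4*pi*(r_vdw + r_probe)^2.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float) + probe_radius
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    out = np.zeros(n)
    for i in range(n):
        ri = radii[i]
        pts = coords[i] + ri * unit
        neighbours = [
            j for j in tree.query_ball_point(coords[i], ri + max_r) if j != i
        ]
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            exposed &= d2 > radii[j] ** 2
        out[i] = exposed.mean() * 4.0 * math.pi * ri**2
    return out


@dataclass(frozen=True)
class SasaResult:
    per_atom: np.ndarray
    probe_radius: float
    n_points: int
    #: bond -> dict with pair_sasa, reference_sasa, relative_exposure (or None
    #: when a Sgamma atom is missing)
    disulphides: Mapping[tuple, dict] = field(default_factory=dict)


def _bond_key(bond, chain_map: Mapping[str, str] | None):
    """Map an insulin-numbering bond to structure chain labels."""
    out = []
    for chain_id, pos in bond:
        label = chain_map.get(chain_id, chain_id) if chain_map else chain_id
        out.append((label, pos))
    return tuple(out)


def sasa_relative_exposure(
    model: StructureModel,
    topology: DisulphideTopology,
    chain_map: Mapping[str, str] | None = None,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> SasaResult:
    """SASA of the model plus relative exposure of each disulphide.

    Per bond, exposure is the summed SASA of the two Sgamma atoms in the full
    model divided by the same sum recomputed on the isolated cystine fragment
    (the bonded pair's Cbeta and Sgamma atoms only, in-situ coordinates).
    ``chain_map`` translates insulin chain ids (A/B) to structure chain
    labels when they differ.
    """
    atoms = [a for a in model.atoms if a.element.upper() != "H"]
    coords = np.array([[a.x, a.y, a.z] for a in atoms])
    radii = atom_radii([a.element for a in atoms])
    per_atom = shrake_rupley_sasa(coords, radii, probe_radius, n_points)
    index = {(a.chain, a.resnum, a.name): i for i, a in enumerate(atoms)}

    disulphides: dict[tuple, dict] = {}
    for bond in topology.bonds:
        mapped = _bond_key(bond, chain_map)
        sg_idx = [index.get((ch, pos, "SG")) for ch, pos in mapped]
        if any(i is None for i in sg_idx):
            disulphides[bond] = {
                "pair_sasa": None,
                "reference_sasa": None,
                "relative_exposure": None,
                "missing": True,
            }
            continue
        pair_sasa = float(per_atom[sg_idx[0]] + per_atom[sg_idx[1]])

        frag_idx = [
            index[(ch, pos, nm)]
            for ch, pos in mapped
            for nm in ("CB", "SG")
            if (ch, pos, nm) in index
        ]
        frag_coords = coords[frag_idx]
        frag_radii = radii[frag_idx]
        frag_sasa = shrake_rupley_sasa(frag_coords, frag_radii, probe_radius, n_points)
        frag_sg = [k for k, gi in enumerate(frag_idx) if gi in sg_idx]
        reference = float(frag_sasa[frag_sg].sum())
        disulphides[bond] = {
            "pair_sasa": pair_sasa,
            "reference_sasa": reference,
            "relative_exposure": pair_sasa / reference if reference > 0 else None,
            "missing": False,
        }
    return SasaResult(
        per_atom=per_atom,
        probe_radius=probe_radius,
        n_points=n_points,
        disulphides=disulphides,
    )


# ---------------------------------------------------------------------------
# B-factor analysis

BACKBONE_ATOMS = {"N", "CA", "C", "O"}


@dataclass(frozen=True)
class ResidueSelection:
    chain: str
    start: int
    end: int
    atom_class: str = "heavy"  # "heavy" | "backbone"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("selection start exceeds end")

    def pick(self, model: StructureModel) -> StructureModel:
        sel = model.select(
            chain=self.chain,
            resnums=range(self.start, self.end + 1),
            include_het=False,
            exclude_hydrogen=True,
        )
        if self.atom_class == "backbone":
            sel = sel.select(atom_names=BACKBONE_ATOMS)
        elif self.atom_class != "heavy":
            raise ValueError(f"unknown atom class {self.atom_class!r}")
        if len(sel) == 0:
            raise ValueError(
                f"selection {self.chain}{self.start}-{self.end} "
                f"({self.atom_class}) is empty"
            )
        return sel


@dataclass(frozen=True)
class BFactorReport:
    """Raw selection means plus the loop/helix ratio.

    The crystallographic convention of quoting a 'normalised temperature
    factor' for a flexible loop uses an external scale constant; the report
    therefore carries the raw means and the dimensionless ratio, and applies
    a user-supplied scale only if one is given.
    """

    helix_mean: float
    loop_mean_all: float
    loop_mean_backbone: float
    ratio_all: float
    ratio_backbone: float
    scale: float | None = None

    @property
    def normalised_all(self) -> float | None:
        return self.ratio_all * self.scale if self.scale is not None else None

    @property
    def normalised_backbone(self) -> float | None:
        return self.ratio_backbone * self.scale if self.scale is not None else None


def _mean_b(model: StructureModel) -> float:
    return float(np.mean([a.b_iso for a in model.atoms]))


def bfactor_table(
    model: StructureModel,
    helix_sel: ResidueSelection,
    loop_sel: ResidueSelection,
    scale: float | None = None,
) -> BFactorReport:
    """B-factor summary: helix reference mean and loop means/ratios.

    The helix mean (all non-H atoms) is the normalisation reference; the loop
    is reported both over all non-H atoms and over backbone atoms only.
    """
    helix_mean = _mean_b(helix_sel.pick(model))
    loop_all = _mean_b(replace(loop_sel, atom_class="heavy").pick(model))
    loop_bb = _mean_b(replace(loop_sel, atom_class="backbone").pick(model))
    return BFactorReport(
        helix_mean=helix_mean,
        loop_mean_all=loop_all,
        loop_mean_backbone=loop_bb,
        ratio_all=loop_all / helix_mean,
        ratio_backbone=loop_bb / helix_mean,
        scale=scale,
    )


# ---------------------------------------------------------------------------
# Superposition


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # (3, 3), proper
    translation: np.ndarray  # (3,)
    n_atoms: int
    rmsd: float


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of paired coordinates.

    Returns the proper rotation R and translation t minimising
    ``|| (mobile @ R.T + t) - reference ||`` and the residual RMSD.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("paired coordinate arrays must both be (n, 3)")
    n = len(P)
    if n < 3:
        raise ValueError("need at least 3 paired atoms")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2 or np.linalg.matrix_rank(Q0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, n_atoms=n, rmsd=rmsd)


def superpose_rmsd(
    mobile: StructureModel,
    reference: StructureModel,
    pairing: Sequence[tuple[tuple[str, int], tuple[str, int]]],
    atom_name: str = "CA",
) -> SuperpositionResult:
    """Kabsch superposition over paired residues (default Calpha atoms).

    ``pairing`` lists ((mobile_chain, resnum), (reference_chain, resnum))
    correspondences; pairs missing the named atom in either model are
    dropped.
    """
    P, Q = [], []
    for (mc, mr), (rc, rr) in pairing:
        am = mobile.find_atom(mc, mr, atom_name)
        ar = reference.find_atom(rc, rr, atom_name)
        if am is None or ar is None:
            continue
        P.append([am.x, am.y, am.z])
        Q.append([ar.x, ar.y, ar.z])
    if len(P) < 3:
        raise ValueError("fewer than 3 resolvable atom pairs")
    return kabsch(np.array(P), np.array(Q))


def contact_distance(
    model: StructureModel,
    group_a: Sequence[tuple[str, int, str]],
    group_b: Sequence[tuple[str, int, str]],
) -> float:
    """Minimum pairwise distance (Angstrom) between two named atom groups.

    Groups are lists of (chain, resnum, atom_name); atoms missing from the
    model are ignored, but an entirely empty group is an error.
    """

    def _coords(group):
        pts = []
        for chain, resnum, name in group:
            a = model.find_atom(chain, resnum, name)
            if a is not None:
                pts.append([a.x, a.y, a.z])
        return np.array(pts)

    A, B = _coords(group_a), _coords(group_b)
    if len(A) == 0 or len(B) == 0:
        raise ValueError("empty atom group")
    d = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=-1)
    return float(d.min())


# ---------------------------------------------------------------------------
# Deposited-structure helpers

#: Insulin chain maps per accession: one entry per molecule in the
#: asymmetric unit, mapping insulin chain id (A/B) -> structure chain label.
CHAIN_MAPS: dict[str, list[dict[str, str]]] = {
    "6S34": [{"A": "A", "B": "B"}, {"A": "C", "B": "D"}],
    "6S4I": [{"A": "A", "B": "B"}, {"A": "C", "B": "D"}],
    "8RRP": [{"A": "A", "B": "B"}, {"A": "C", "B": "D"}, {"A": "E", "B": "F"}],
}

_PDB_URL = "https://files.rcsb.org/download/{accession}.pdb"


def default_cache_dir() -> Path:
    return Path.home() / ".cache" / "chainsplit" / "pdb"


def fetch_structure(
    accession: str, cache_dir: Path | None = None, timeout: float = 10.0
) -> Path:
    """Return a local path to a deposited PDB entry, downloading on a miss.

    Requires network access on first use for a given accession; afterwards
    the cached file is reused.  Raises ``RuntimeError`` with the accession
    and cache location when the entry is neither cached nor downloadable.
    """
    accession = accession.upper()
    cache = Path(cache_dir) if cache_dir else default_cache_dir()
    cache.mkdir(parents=True, exist_ok=True)
    dest = cache / f"{accession.lower()}.pdb"
    if dest.exists():
        return dest
    url = _PDB_URL.format(accession=accession)
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            data = resp.read()
    except Exception as exc:
        raise RuntimeError(
            f"PDB entry {accession} is not cached at {dest} and could not be "
            f"downloaded from {url}: {exc}. Place the file there manually to "
            f"run deposited-structure analyses offline."
        ) from exc
    dest.write_bytes(data)
    return dest


def load_deposited(accession: str, cache_dir: Path | None = None) -> StructureModel:
    """Fetch (or reuse) and parse a deposited entry."""
    return read_structure(fetch_structure(accession, cache_dir=cache_dir))
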