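"""Elemental composition and monoisotopic mass engine.

Builds peptide compositions residue-by-residue (residue masses plus one water
per chain, minus two hydrogens per disulphide bond), enumerates the molecular
species expected from thiol-disulphide chain-splitting and from proteolysis of
the B-chain, and matches observed deconvoluted masses against a species
library at a ppm tolerance.

Only monoisotopic masses are computed; the deconvoluted high-resolution MS
data this mirrors are interpreted in monoisotopic space.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .analyte import AnalyteError, InsulinAnalogue

__all__ = [
    "MONOISOTOPIC_MASS",
    "RESIDUE_COMPOSITIONS",
    "ElementalComposition",
    "MetaboliteSpecies",
    "MassMatchPolicy",
    "MatchResult",
    "peptide_composition",
    "monoisotopic_mass",
    "enumerate_metabolites",
    "match_masses",
]

# Monoisotopic isotope masses (Da), standard IUPAC values at 1e-7 precision.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.0078250,
    "C": 12.0000000,
    "N": 14.0030740,
    "O": 15.9949146,
    "S": 31.9720707,
    "P": 30.9737615,
    "Se": 79.9165218,
}
# full-precision values used internally; the table above is the documented
# 1e-7 rounding of these
_MASS = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
    "Se": 79.9165218,
}

# Amino-acid residue compositions (residue = amino acid minus water).
RESIDUE_COMPOSITIONS: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

WATER = {"H": 2, "O": 1}


class ElementalComposition(dict):
    """Element -> count map closed under addition and (checked) subtraction."""

    def __init__(self, counts: Mapping[str, int] | None = None, **kw: int):
        super().__init__()
        for el, n in {**(counts or {}), **kw}.items():
            if n < 0:
                raise ValueError(f"negative count for element {el}")
            if n:
                self[el] = int(n)

    def __add__(self, other: Mapping[str, int]) -> "ElementalComposition":
        out = dict(self)
        for el, n in other.items():
            out[el] = out.get(el, 0) + n
        return ElementalComposition(out)

    def __sub__(self, other: Mapping[str, int]) -> "ElementalComposition":
        out = dict(self)
        for el, n in other.items():
            out[el] = out.get(el, 0) - n
            if out[el] < 0:
                raise ValueError(f"subtraction drives element {el} negative")
        return ElementalComposition(out)

    def __mul__(self, k: int) -> "ElementalComposition":
        return ElementalComposition({el: n * k for el, n in self.items()})

    __rmul__ = __mul__

    def formula(self) -> str:
        order = ["C", "H", "N", "O", "S"]
        keys = [k for k in order if k in self] + sorted(set(self) - set(order))
        return "".join(f"{k}{self[k]}" for k in keys)


def peptide_composition(sequence: str) -> ElementalComposition:
    """Composition of a linear peptide with free (water) termini."""
    comp = ElementalComposition(WATER)
    for aa in sequence:
        if aa not in RESIDUE_COMPOSITIONS:
            raise ValueError(f"unknown residue code {aa!r}")
        comp = comp + RESIDUE_COMPOSITIONS[aa]
    return comp


def composition_mass(composition: Mapping[str, int]) -> float:
    total = 0.0
    for el, n in composition.items():
        if el not in _MASS:
            raise ValueError(f"unknown element symbol {el!r}")
        total += _MASS[el] * n
    return total


@dataclass(frozen=True)
class MetaboliteSpecies:
    """A named molecular species with its final elemental composition.

    ``composition`` already reflects the disulphide state: every disulphide
    bond removes two hydrogens relative to the free-dithiol form.
    """

    name: str
    parent: str
    composition: ElementalComposition
    n_disulphides: int = 0
    disulphide_pairing: tuple[tuple[int, int], ...] = ()
    chains_included: tuple[str, ...] = ()
    residue_range: Mapping[str, tuple[int, int]] = field(default_factory=dict)
    modifications: tuple[str, ...] = ()

    @property
    def monoisotopic_mass(self) -> float:
        return composition_mass(self.composition)


def monoisotopic_mass(species) -> float:
    """Monoisotopic mass (Da) of a species, composition or formula mapping."""
    if isinstance(species, MetaboliteSpecies):
        return species.monoisotopic_mass
    return composition_mass(species)


def _chain_composition(
    parent: InsulinAnalogue,
    chain_id: str,
    start: int | None = None,
    end: int | None = None,
) -> tuple[ElementalComposition, list[str]]:
    """Peptide composition of a (sub)chain plus any retained modifications."""
    chain = parent.chain(chain_id)
    lo = chain.numbering_offset if start is None else start
    hi = chain.positions.stop - 1 if end is None else end
    if not (chain.numbering_offset <= lo <= hi <= chain.positions.stop - 1):
        raise ValueError(
            f"residue range {chain_id}{lo}-{chain_id}{hi} outside chain"
        )
    seq = "".join(chain.residue_at(p) for p in range(lo, hi + 1))
    comp = peptide_composition(seq)
    retained = []
    for mod in parent.modifications:
        mchain, mpos, _ = mod.attachment
        if mchain == chain_id and lo <= mpos <= hi:
            comp = comp + mod.elemental_formula
            retained.append(mod.name)
    return comp, retained


def _apply_disulphides(comp: ElementalComposition, n_bonds: int) -> ElementalComposition:
    return comp - {"H": 2 * n_bonds}


def perfect_pairings(positions: Sequence[int]) -> list[tuple[tuple[int, int], ...]]:
    """All complete pairings of an even set of cysteine positions."""
    positions = sorted(positions)
    if len(positions) % 2:
        raise ValueError("odd number of cysteines cannot be fully paired")
    if not positions:
        return [()]
    first, rest = positions[0], positions[1:]
    out = []
    for i, partner in enumerate(rest):
        remainder = rest[:i] + rest[i + 1 :]
        for sub in perfect_pairings(remainder):
            out.append((((first, partner),) + sub))
    return out


def parent_species(parent: InsulinAnalogue) -> MetaboliteSpecies:
    """The intact two-chain analogue with its native disulphides."""
    comp = ElementalComposition()
    mods: list[str] = []
    for chain in parent.chains:
        c, m = _chain_composition(parent, chain.chain_id)
        comp = comp + c
        mods += m
    n_ss = len(parent.topology.bonds)
    return MetaboliteSpecies(
        name=parent.name,
        parent=parent.name,
        composition=_apply_disulphides(comp, n_ss),
        n_disulphides=n_ss,
        chains_included=tuple(c.chain_id for c in parent.chains),
        residue_range={
            c.chain_id: (c.numbering_offset, c.positions.stop - 1)
            for c in parent.chains
        },
        modifications=tuple(mods),
    )


def enumerate_metabolites(
    parent: InsulinAnalogue,
    cleavage_sites: Sequence[int] = (23, 28),
) -> list[MetaboliteSpecies]:
    """Enumerate chain-splitting and proteolytic products of an analogue.

    Chain-splitting products:

    * the free B-chain with its single intrachain disulphide (Cys B7-Cys B19),
      retaining any acyl modification;
    * every complete pairing of the four A-chain cysteines into two intrachain
      disulphides (three distinct connectivities, one shared mass);
    * the B-chain dimer linked by two interchain disulphides ("2B").

    Proteolytic products are C-terminal fragments of the B-chain starting
    after each cleavage site; modifications within the fragment are retained.
    The default sites (after B23 and after B28) produce the acylated B24-29
    and B29 species for a desB30, B29-acylated parent.
    """
    b_chain = parent.chain("B")
    a_chain = parent.chain("A")
    out: list[MetaboliteSpecies] = []

    # free B-chain, one intrachain disulphide
    b_cys = b_chain.cysteine_positions
    if len(b_cys) != 2:
        raise AnalyteError(
            f"B-chain of {parent.name} has {len(b_cys)} cysteines; expected 2"
        )
    b_comp, b_mods = _chain_composition(parent, "B")
    b_last = b_chain.positions.stop - 1
    out.append(
        MetaboliteSpecies(
            name="B-chain",
            parent=parent.name,
            composition=_apply_disulphides(b_comp, 1),
            n_disulphides=1,
            disulphide_pairing=(b_cys,),
            chains_included=("B",),
            residue_range={"B": (1, b_last)},
            modifications=tuple(b_mods),
        )
    )

    # A-chain isoforms: all pairings of the four cysteines into two bonds
    a_cys = a_chain.cysteine_positions
    a_comp, a_mods = _chain_composition(parent, "A")
    a_last = a_chain.positions.stop - 1
    for pairing in perfect_pairings(a_cys):
        label = ",".join(f"{i}-{j}" for i, j in pairing)
        out.append(
            MetaboliteSpecies(
                name=f"A-chain ({label})",
                parent=parent.name,
                composition=_apply_disulphides(a_comp, len(pairing)),
                n_disulphides=len(pairing),
                disulphide_pairing=pairing,
                chains_included=("A",),
                residue_range={"A": (1, a_last)},
                modifications=tuple(a_mods),
            )
        )

    # B-chain dimer via two interchain disulphides; parallel and antiparallel
    # pairings share one composition, so a single species represents them
    out.append(
        MetaboliteSpecies(
            name="2B dimer",
            parent=parent.name,
            composition=_apply_disulphides(b_comp * 2, 2),
            n_disulphides=2,
            chains_included=("B", "B"),
            residue_range={"B": (1, b_last)},
            modifications=tuple(b_mods) * 2,
        )
    )

    # proteolytic C-terminal fragments of the B-chain
    for site in cleavage_sites:
        if not (b_chain.numbering_offset <= site < b_last):
            raise ValueError(
                f"cleavage site B{site} outside chain B1-B{b_last}"
            )
        lo = site + 1
        frag_comp, frag_mods = _chain_composition(parent, "B", lo, b_last)
        frag_cys = [p for p in b_cys if lo <= p]
        n_ss = 1 if len(frag_cys) == 2 else 0
        name = f"B{lo}" if lo == b_last else f"B{lo}-B{b_last}"
        out.append(
            MetaboliteSpecies(
                name=name,
                parent=parent.name,
                composition=_apply_disulphides(frag_comp, n_ss),
                n_disulphides=n_ss,
                chains_included=("B",),
                residue_range={"B": (lo, b_last)},
                modifications=tuple(frag_mods),
            )
        )

    return out


@dataclass(frozen=True)
class MassMatchPolicy:
    """ppm tolerance with strict-less-than comparison."""

    tolerance_ppm: float = 10.0

    def __post_init__(self) -> None:
        if self.tolerance_ppm <= 0:
            raise ValueError("tolerance_ppm must be positive")

    def accepts(self, ppm_error: float) -> bool:
        return abs(ppm_error) < self.tolerance_ppm


@dataclass(frozen=True)
class MatchResult:
    observed_mass: float
    matches: tuple[tuple[MetaboliteSpecies, float], ...]  # (species, signed ppm)

    @property
    def matched(self) -> bool:
        return bool(self.matches)


def ppm_error(observed: float, reference: float) -> float:
    return (observed - reference) / reference * 1e6


def match_masses(
    observed: Iterable[float],
    library: Sequence[MetaboliteSpecies],
    policy: MassMatchPolicy = MassMatchPolicy(),
) -> list[MatchResult]:
    """Match each observed deconvoluted mass against a species library.

    For each observed mass every species with ``|ppm| < tolerance`` is
    reported, sorted by absolute ppm error; masses with no acceptable species
    are reported with an empty match tuple.
    """
    if not library:
        raise ValueError("species library is empty")
    refs = [(sp, sp.monoisotopic_mass) for sp in library]
    out = []
    for m_obs in observed:
        if m_obs <= 0:
            raise ValueError(f"non-positive observed mass {m_obs}")
        hits = [
            (sp, ppm_error(m_obs, m_ref))
            for sp, m_ref in refs
            if policy.accepts(ppm_error(m_obs, m_ref))
        ]
        hits.sort(key=lambda t: abs(t[1]))
        out.append(MatchResult(observed_mass=m_obs, matches=tuple(hits)))
    return out


def library_to_rows(library: Sequence[MetaboliteSpecies]) -> list[dict]:
    """Flatten a species library for CSV export."""
    return [
        {
            "name": sp.name,
            "parent": sp.parent,
            "formula": sp.composition.formula(),
            "n_disulphides": sp.n_disulphides,
            "monoisotopic_mass": round(sp.monoisotopic_mass, 6),
        }
        for sp in library
    ]
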