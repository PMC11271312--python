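"""Insulin analogue definitions.

An analogue is described as edits on a base molecule (human insulin unless
stated otherwise): point substitutions such as ``A14E``, C-terminal
truncations such as ``desB30``, and acyl/linker modification blocks attached
to a side-chain amine (for icodec, a C20 fatty diacid-gammaGlu-2xOEG moiety on
the Lys B29 N-epsilon).  The resulting :class:`InsulinAnalogue` is the root
object consumed by the mass, redox, denaturation and simulation stages.

Chain numbering is 1-based per chain (A1..A21, B1..B30); edits always refer
to native numbering, so substitutions are applied before truncations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

import yaml

__all__ = [
    "ChainSequence",
    "Substitution",
    "Truncation",
    "ModificationBlock",
    "DisulphideTopology",
    "InsulinAnalogue",
    "AnalyteError",
    "build_analogue",
    "load_analogue_library",
    "get_analogue",
    "HUMAN_INSULIN_A",
    "HUMAN_INSULIN_B",
    "NATIVE_TOPOLOGY",
    "MODIFICATION_BLOCKS",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

HUMAN_INSULIN_A = "GIVEQCCTSICSLYQLENYCN"
HUMAN_INSULIN_B = "FVNQHLCGSHLVEALYLVCGERGFFYTPKT"


class AnalyteError(ValueError):
    """Raised when an analogue definition is internally inconsistent."""


@dataclass(frozen=True)
class ChainSequence:
    """One peptide chain with 1-based per-chain numbering."""

    chain_id: str
    residues: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        if not self.residues:
            raise AnalyteError(f"chain {self.chain_id}: empty sequence")
        bad = set(self.residues) - STANDARD_AA
        if bad:
            raise AnalyteError(
                f"chain {self.chain_id}: non-standard residue codes {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def positions(self) -> range:
        return range(self.numbering_offset, self.numbering_offset + len(self.residues))

    def residue_at(self, position: int) -> str:
        idx = position - self.numbering_offset
        if not 0 <= idx < len(self.residues):
            raise AnalyteError(
                f"position {self.chain_id}{position} outside chain "
                f"({self.chain_id}{self.positions.start}-{self.chain_id}{self.positions.stop - 1})"
            )
        return self.residues[idx]

    @property
    def cysteine_positions(self) -> tuple[int, ...]:
        return tuple(
            p for p in self.positions if self.residue_at(p) == "C"
        )


@dataclass(frozen=True)
class Substitution:
    """Point substitution in native numbering, e.g. Tyr A14 -> Glu."""

    chain_id: str
    position: int
    from_aa: str
    to_aa: str

    _PATTERN = re.compile(r"^([A-Za-z])(\d+)([A-Z])$")

    @classmethod
    def parse(cls, text: str, base_chains: Mapping[str, ChainSequence]) -> "Substitution":
        """Parse shorthand like ``A14E`` against the base sequence.

        The shorthand omits the original residue; it is read off the base
        chain so that a later mismatch is impossible by construction.
        """
        m = cls._PATTERN.match(text.strip())
        if not m:
            raise AnalyteError(f"cannot parse substitution {text!r}")
        chain_id, pos, to_aa = m.group(1).upper(), int(m.group(2)), m.group(3)
        if chain_id not in base_chains:
            raise AnalyteError(f"substitution {text!r}: no chain {chain_id!r}")
        from_aa = base_chains[chain_id].residue_at(pos)
        return cls(chain_id, pos, from_aa, to_aa)

    def apply(self, chain: ChainSequence) -> ChainSequence:
        actual = chain.residue_at(self.position)
        if actual != self.from_aa:
            raise AnalyteError(
                f"substitution {self.chain_id}{self.position}: expected "
                f"{self.from_aa!r} at that position, found {actual!r}"
            )
        idx = self.position - chain.numbering_offset
        residues = chain.residues[:idx] + self.to_aa + chain.residues[idx + 1 :]
        return replace(chain, residues=residues)

    def inverse(self) -> "Substitution":
        return Substitution(self.chain_id, self.position, self.to_aa, self.from_aa)


@dataclass(frozen=True)
class Truncation:
    """C-terminal deletion, e.g. desB30 removes residue B30."""

    chain_id: str
    position: int

    _PATTERN = re.compile(r"^des([A-Za-z])(\d+)$")

    @classmethod
    def parse(cls, text: str) -> "Truncation":
        m = cls._PATTERN.match(text.strip())
        if not m:
            raise AnalyteError(f"cannot parse truncation {text!r}")
        return cls(m.group(1).upper(), int(m.group(2)))

    def apply(self, chain: ChainSequence) -> ChainSequence:
        last = chain.positions.stop - 1
        if self.position != last:
            raise AnalyteError(
                f"truncation des{self.chain_id}{self.position}: only the "
                f"C-terminal residue ({self.chain_id}{last}) can be removed"
            )
        return replace(chain, residues=chain.residues[:-1])


@dataclass(frozen=True)
class ModificationBlock:
    """A side-chain modification as incorporated into the molecule.

    ``elemental_formula`` is the net elemental addition to the peptide, i.e.
    condensation water losses (including the one at the attachment amide) are
    already applied.  ``components`` documents the free building blocks and
    the number of condensations so the formula can be re-derived and checked.
    """

    name: str
    elemental_formula: Mapping[str, int]
    attachment: tuple[str, int, str]  # (chain_id, position, atom class)
    components: tuple[str, ...] = ()
    n_condensations: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.elemental_formula.values()):
            raise AnalyteError(f"block {self.name}: negative element count")


@dataclass(frozen=True)
class DisulphideTopology:
    """Pairing of cysteine positions, interchain or intrachain."""

    bonds: tuple[tuple[tuple[str, int], tuple[str, int]], ...]

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for a, b in self.bonds:
            for site in (a, b):
                if site in seen:
                    raise AnalyteError(
                        f"cysteine {site[0]}{site[1]} appears in more than one disulphide"
                    )
                seen.add(site)

    def validate(self, chains: Mapping[str, ChainSequence]) -> None:
        for a, b in self.bonds:
            for chain_id, pos in (a, b):
                if chain_id not in chains:
                    raise AnalyteError(f"disulphide references missing chain {chain_id!r}")
                res = chains[chain_id].residue_at(pos)
                if res != "C":
                    raise AnalyteError(
                        f"disulphide position {chain_id}{pos} is {res!r}, not cysteine"
                    )

    def is_interchain(self, bond: tuple[tuple[str, int], tuple[str, int]]) -> bool:
        return bond[0][0] != bond[1][0]

    @property
    def interchain_bonds(self):
        return tuple(b for b in self.bonds if self.is_interchain(b))

    @property
    def intrachain_bonds(self):
        return tuple(b for b in self.bonds if not self.is_interchain(b))


# Native insulin disulphides: two interchain (A7-B7, A20-B19) and one
# intrachain (A6-A11).
NATIVE_TOPOLOGY = DisulphideTopology(
    bonds=(
        (("A", 6), ("A", 11)),
        (("A", 7), ("B", 7)),
        (("A", 20), ("B", 19)),
    )
)


def _formula(text: str) -> dict[str, int]:
    out: dict[str, int] = {}
    for sym, count in re.findall(r"([A-Z][a-z]?)(\d*)", text):
        if sym:
            out[sym] = out.get(sym, 0) + (int(count) if count else 1)
    return out


#: Free building blocks (intact small molecules) used to assemble acyl side
#: chains.  OEG, also written "Ado", is 8-amino-3,6-dioxaoctanoic acid.
BUILDING_BLOCKS: dict[str, dict[str, int]] = {
    "C20diacid": _formula("C20H38O4"),   # eicosanedioic acid
    "C18diacid": _formula("C18H34O4"),   # octadecanedioic acid
    "gGlu": _formula("C5H9NO4"),         # glutamic acid, gamma-linked
    "OEG": _formula("C6H13NO4"),         # 8-amino-3,6-dioxaoctanoic acid
}


def _assemble_block(components: Iterable[str], n_condensations: int) -> dict[str, int]:
    total: dict[str, int] = {}
    for name in components:
        for el, n in BUILDING_BLOCKS[name].items():
            total[el] = total.get(el, 0) + n
    total["H"] = total["H"] - 2 * n_condensations
    total["O"] = total["O"] - n_condensations
    return total


def _make_block_table() -> dict[str, ModificationBlock]:
    table: dict[str, ModificationBlock] = {}
    # 4 internal amides + 1 attachment amide = 5 condensations
    for diacid in ("C20diacid", "C18diacid"):
        comps = (diacid, "gGlu", "OEG", "OEG")
        name = f"{diacid}-gGlu-2xOEG"
        table[name] = ModificationBlock(
            name=name,
            elemental_formula=_assemble_block(comps, n_condensations=5),
            attachment=("B", 29, "Lys-Neps"),
            components=comps,
            n_condensations=5,
        )
        table[f"{diacid}-gGlu-2xAdo"] = table[name]  # alias: OEG == Ado
    return table


MODIFICATION_BLOCKS = _make_block_table()


@dataclass(frozen=True)
class InsulinAnalogue:
    """A fully specified analogue: edited chains plus topology and acylation."""

    name: str
    chains: tuple[ChainSequence, ...]
    substitutions: tuple[Substitution, ...] = ()
    truncations: tuple[Truncation, ...] = ()
    modifications: tuple[ModificationBlock, ...] = ()
    topology: DisulphideTopology = NATIVE_TOPOLOGY

    def __post_init__(self) -> None:
        self.topology.validate(self.chain_map)
        for mod in self.modifications:
            chain_id, pos, atom_class = mod.attachment
            res = self.chain_map[chain_id].residue_at(pos)
            if atom_class.startswith("Lys") and res != "K":
                raise AnalyteError(
                    f"modification {mod.name}: attachment {chain_id}{pos} is "
                    f"{res!r}, not lysine"
                )

    @property
    def chain_map(self) -> dict[str, ChainSequence]:
        return {c.chain_id: c for c in self.chains}

    def chain(self, chain_id: str) -> ChainSequence:
        try:
            return self.chain_map[chain_id]
        except KeyError:
            raise AnalyteError(f"{self.name}: no chain {chain_id!r}") from None

    @property
    def tyrosine_count(self) -> int:
        return sum(c.residues.count("Y") for c in self.chains)


_SITE_PATTERN = re.compile(r"^([A-Za-z])(\d+)(?:-(.+))?$")


def _parse_site(site: str) -> tuple[str, int, str]:
    m = _SITE_PATTERN.match(site.strip())
    if not m:
        raise AnalyteError(f"cannot parse attachment site {site!r}")
    atom_class = m.group(3) or "Lys-Neps"
    # normalise spellings like "NepsLys" / "NεLys"
    if "Lys" in atom_class or "K" == atom_class:
        atom_class = "Lys-Neps"
    return m.group(1).upper(), int(m.group(2)), atom_class


_BASES: dict[str, tuple[ChainSequence, ChainSequence]] = {
    "human_insulin": (
        ChainSequence("A", HUMAN_INSULIN_A),
        ChainSequence("B", HUMAN_INSULIN_B),
    ),
}


def build_analogue(spec: Mapping) -> InsulinAnalogue:
    """Build an :class:`InsulinAnalogue` from a structured definition.

    ``spec`` is a mapping with keys ``name``, ``base`` (default
    ``"human_insulin"``), ``substitutions`` (list of ``"A14E"`` strings),
    ``truncations`` (list of ``"desB30"`` strings) and ``modifications``
    (list of ``{"block": ..., "site": "B29-NepsLys"}``).  Edits are applied
    in the order substitutions -> truncations -> modifications; positions
    always refer to native numbering.
    """
    base_name = spec.get("base", "human_insulin")
    if base_name not in _BASES:
        raise AnalyteError(f"unknown base molecule {base_name!r}")
    chains = {c.chain_id: c for c in _BASES[base_name]}

    subs = tuple(
        s if isinstance(s, Substitution) else Substitution.parse(s, chains)
        for s in spec.get("substitutions", ())
    )
    for sub in subs:
        chains[sub.chain_id] = sub.apply(chains[sub.chain_id])

    truncs = tuple(
        t if isinstance(t, Truncation) else Truncation.parse(t)
        for t in spec.get("truncations", ())
    )
    for trunc in truncs:
        chains[trunc.chain_id] = trunc.apply(chains[trunc.chain_id])

    mods = []
    for m in spec.get("modifications", ()):
        if isinstance(m, ModificationBlock):
            mods.append(m)
            continue
        block_name = m["block"]
        if block_name not in MODIFICATION_BLOCKS:
            raise AnalyteError(f"unknown modification block {block_name!r}")
        block = MODIFICATION_BLOCKS[block_name]
        if "site" in m:
            block = replace(block, attachment=_parse_site(m["site"]))
        mods.append(block)

    return InsulinAnalogue(
        name=spec.get("name", base_name),
        chains=tuple(chains[cid] for cid in sorted(chains)),
        substitutions=subs,
        truncations=truncs,
        modifications=tuple(mods),
        topology=NATIVE_TOPOLOGY,
    )


def load_analogue_library() -> dict[str, InsulinAnalogue]:
    """Load the bundled analogue series (human insulin, single and combined
    substitutions, acylated variants and icodec)."""
    text = resources.files("chainsplit.data").joinpath("analogues.yaml").read_text()
    raw = yaml.safe_load(text)
    out = {}
    for name, spec in raw.items():
        spec = dict(spec or {})
        spec.setdefault("name", name)
        out[name] = build_analogue(spec)
    return out


def get_analogue(name: str) -> InsulinAnalogue:
    lib = load_analogue_library()
    if name not in lib:
        raise AnalyteError(f"unknown analogue {name!r}; known: {sorted(lib)}")
    return lib[name]
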