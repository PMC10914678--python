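"""Monosaccharide masses, glycan composition arithmetic and N-glycan topologies.

Masses are dehydrated (in-chain) residue masses. Average masses are the
default because intact native MS of 50-80 kDa glycoproteins resolves
envelope-level (average) masses, not isotopes; monoisotopic masses are
provided for glycopeptide-level work.

Topology distinguishes what composition cannot: a hexose node knows whether
it is mannose (core) or galactose (antenna), and a fucose node knows its
linkage (alpha1-6 on the reducing-end GlcNAc = core fucose; alpha1-3/4 on an
antenna GlcNAc = antennary fucose). The exoglycosidase rules in
:mod:`serpinms.enzyme_engine` operate on this topology.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

__all__ = [
    "Monosaccharide",
    "MONOSACCHARIDES",
    "RESIDUE_ALIASES",
    "GlycanComposition",
    "composition_mass",
    "parse_composition",
    "format_composition",
    "GlycanNode",
    "GlycanTopology",
    "AntennaSpec",
    "build_nglycan",
    "biantennary",
]


@dataclass(frozen=True)
class Monosaccharide:
    """A monosaccharide residue class with in-chain (dehydrated) masses in Da."""

    symbol: str
    average_residue_mass: float
    monoisotopic_residue_mass: float


# Classical average residue masses (ExPASy/GlycoMod convention) to 4 d.p.;
# monoisotopic from standard elemental compositions.
#   Hex    C6H10O5   Fuc (dHex) C6H10O4
#   HexNAc C8H13NO5  Neu5Ac     C11H17NO8
MONOSACCHARIDES: dict[str, Monosaccharide] = {
    "Hex": Monosaccharide("Hex", 162.1424, 162.052824),
    "HexNAc": Monosaccharide("HexNAc", 203.1950, 203.079373),
    "Fuc": Monosaccharide("Fuc", 146.1430, 146.057909),
    "Neu5Ac": Monosaccharide("Neu5Ac", 291.2579, 291.095417),
}

# Display/topology names and common synonyms -> mass-level symbol.
# MS cannot distinguish hexose isomers, so Man and Gal both weigh as Hex;
# their identity is preserved only at topology level.
RESIDUE_ALIASES: dict[str, str] = {
    "Hex": "Hex",
    "Man": "Hex",
    "Gal": "Hex",
    "Glc": "Hex",
    "HexNAc": "HexNAc",
    "GlcNAc": "HexNAc",
    "GalNAc": "HexNAc",
    "Fuc": "Fuc",
    "dHex": "Fuc",
    "Neu5Ac": "Neu5Ac",
    "NeuAc": "Neu5Ac",
    "NeuNAc": "Neu5Ac",
    "NANA": "Neu5Ac",
}

# Canonical order for serialization.
_CANONICAL_ORDER = ("HexNAc", "Hex", "Fuc", "Neu5Ac")


class GlycanComposition(dict):
    """A multiset of monosaccharide residue classes (symbol -> count >= 0).

    Behaves like a plain dict but normalizes symbols through
    :data:`RESIDUE_ALIASES`, rejects unknown symbols and negative counts,
    and supports ``+`` for multiset union.
    """

    def __init__(self, counts: Mapping[str, int] | Iterable[tuple[str, int]] = ()):
        super().__init__()
        items = counts.items() if isinstance(counts, Mapping) else counts
        for symbol, count in items:
            self[symbol] = self.get(symbol, 0) + int(count)

    def __setitem__(self, symbol: str, count: int) -> None:
        if symbol not in RESIDUE_ALIASES:
            raise KeyError(f"unknown monosaccharide symbol: {symbol!r}")
        count = int(count)
        if count < 0:
            raise ValueError(f"negative count for {symbol!r}: {count}")
        canonical = RESIDUE_ALIASES[symbol]
        if count == 0:
            super().pop(canonical, None)
        else:
            super().__setitem__(canonical, count)

    def __getitem__(self, symbol: str) -> int:
        return super().__getitem__(RESIDUE_ALIASES.get(symbol, symbol))

    def get(self, symbol: str, default: int = 0) -> int:
        return super().get(RESIDUE_ALIASES.get(symbol, symbol), default)

    def __contains__(self, symbol: object) -> bool:
        return super().__contains__(RESIDUE_ALIASES.get(symbol, symbol))

    def __add__(self, other: Mapping[str, int]) -> "GlycanComposition":
        out = GlycanComposition(self)
        for symbol, count in other.items():
            out[symbol] = out.get(symbol, 0) + count
        return out

    def __sub__(self, other: Mapping[str, int]) -> "GlycanComposition":
        out = GlycanComposition(self)
        for symbol, count in other.items():
            out[symbol] = out.get(symbol, 0) - count
        return out

    def mass(self, mass_type: str = "average") -> float:
        return composition_mass(self, mass_type)

    def total_residues(self) -> int:
        return sum(self.values())

    def __str__(self) -> str:  # canonical serialization
        return format_composition(self)


def composition_mass(comp: Mapping[str, int], mass_type: str = "average") -> float:
    """Sum of residue masses of a composition, in Da.

    Additive and order-independent; the empty composition weighs 0.
    ``mass_type`` is ``"average"`` or ``"monoisotopic"``.
    """
    if mass_type not in ("average", "monoisotopic"):
        raise ValueError(f"mass_type must be 'average' or 'monoisotopic', got {mass_type!r}")
    total = 0.0
    for symbol, count in comp.items():
        if symbol not in RESIDUE_ALIASES:
            raise KeyError(f"unknown monosaccharide symbol: {symbol!r}")
        if count < 0:
            raise ValueError(f"negative count for {symbol!r}: {count}")
        mono = MONOSACCHARIDES[RESIDUE_ALIASES[symbol]]
        total += count * (
            mono.average_residue_mass if mass_type == "average" else mono.monoisotopic_residue_mass
        )
    return total


class CompositionParseError(ValueError):
    """Malformed composition string; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


# known symbols longest-first so "Neu5Ac2" parses as (Neu5Ac, 2), not (Neu, 5)
_TOKEN = re.compile(
    "("
    + "|".join(re.escape(s) for s in sorted(RESIDUE_ALIASES, key=len, reverse=True))
    + r")(\d+)"
)
_ANY_TOKEN = re.compile(r"([A-Za-z][A-Za-z0-9]*?)(\d+)")


def parse_composition(text: str) -> GlycanComposition:
    """Parse a ``(Symbol Count)+`` string such as ``"HexNAc4Hex5Fuc1NeuAc2"``.

    Aliases (NeuAc, dHex, Man, Gal, GlcNAc, ...) are accepted and normalized.
    Round-trips through :func:`format_composition`.
    """
    comp = GlycanComposition()
    pos = 0
    text = text.strip()
    while pos < len(text):
        match = _TOKEN.match(text, pos)
        if match is None:
            loose = _ANY_TOKEN.match(text, pos)
            if loose is not None:
                raise CompositionParseError(
                    f"unknown monosaccharide symbol {loose.group(1)!r}", pos
                )
            raise CompositionParseError(f"malformed composition token in {text!r}", pos)
        symbol, count = match.group(1), int(match.group(2))
        comp[symbol] = comp.get(symbol, 0) + count
        pos = match.end()
    return comp


def format_composition(comp: Mapping[str, int]) -> str:
    """Canonical serialization, HexNAc/Hex/Fuc/Neu5Ac order, zero counts dropped."""
    normalized = GlycanComposition(comp)
    return "".join(
        f"{symbol}{normalized[symbol]}" for symbol in _CANONICAL_ORDER if normalized.get(symbol)
    )


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------


@dataclass
class GlycanNode:
    """One residue in a rooted glycan tree.

    ``residue`` is the display identity (Man/Gal/GlcNAc/Fuc/Neu5Ac);
    ``linkage`` the bond to the parent, e.g. ``"b1-4"``, ``"a1-6"``, ``"a2-6"``
    (empty for the reducing-end root); ``core`` marks membership of the
    Man3GlcNAc2 core.
    """

    residue: str
    linkage: str = ""
    core: bool = False
    children: list["GlycanNode"] = field(default_factory=list)

    def add(self, child: "GlycanNode") -> "GlycanNode":
        self.children.append(child)
        return child

    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["GlycanNode"]:
        yield self
        for child in self.children:
            yield from child.walk()

    def copy(self) -> "GlycanNode":
        return GlycanNode(
            self.residue, self.linkage, self.core, [c.copy() for c in self.children]
        )

    def _canonical(self) -> tuple:
        return (
            self.residue,
            self.linkage,
            self.core,
            tuple(sorted(c._canonical() for c in self.children)),
        )

    def to_dict(self) -> dict:
        d: dict = {"residue": self.residue}
        if self.linkage:
            d["linkage"] = self.linkage
        if self.core:
            d["core"] = True
        if self.children:
            d["children"] = [c.to_dict() for c in self.children]
        return d


@dataclass
class GlycanTopology:
    """A rooted N-glycan tree; the root is the reducing-end GlcNAc."""

    root: GlycanNode
    name: str = ""

    def nodes(self) -> Iterator[GlycanNode]:
        return self.root.walk()

    def composition(self) -> GlycanComposition:
        comp = GlycanComposition()
        for node in self.nodes():
            comp[node.residue] = comp.get(node.residue, 0) + 1
        return comp

    def mass(self, mass_type: str = "average") -> float:
        return composition_mass(self.composition(), mass_type)

    def copy(self) -> "GlycanTopology":
        return GlycanTopology(self.root.copy(), self.name)

    def core_fucose_count(self) -> int:
        """Fucose residues alpha1-6-linked to the reducing-end GlcNAc."""
        return sum(
            1 for c in self.root.children if c.residue == "Fuc" and c.linkage == "a1-6"
        )

    def antennary_fucose_count(self) -> int:
        """Fucose residues alpha1-3/4-linked to non-core (antenna) GlcNAc."""
        count = 0
        for node in self.nodes():
            if node.residue == "GlcNAc" and not node.core:
                count += sum(
                    1
                    for c in node.children
                    if c.residue == "Fuc" and c.linkage in ("a1-3", "a1-4")
                )
        return count

    def antenna_count(self) -> int:
        """Number of antenna (non-core) GlcNAc branch points."""
        return sum(1 for n in self.nodes() if n.residue == "GlcNAc" and not n.core)

    def __eq__(self, other: object) -> bool:
        # Canonical form sorts sibling subtrees, so experimentally
        # indistinguishable antenna orderings compare equal.
        if not isinstance(other, GlycanTopology):
            return NotImplemented
        return self.root._canonical() == other.root._canonical()

    def __hash__(self) -> int:
        return hash(self.root._canonical())

    def to_json(self) -> str:
        return json.dumps(self.root.to_dict(), indent=1)

    @classmethod
    def from_dict(cls, d: dict, name: str = "") -> "GlycanTopology":
        def build(nd: dict) -> GlycanNode:
            node = GlycanNode(nd["residue"], nd.get("linkage", ""), nd.get("core", False))
            for child in nd.get("children", ()):
                node.add(build(child))
            return node

        return cls(build(d), name)

    def to_text(self, indent: str = "  ") -> str:
        lines: list[str] = []

        def emit(node: GlycanNode, depth: int) -> None:
            tag = f"{node.linkage} " if node.linkage else ""
            lines.append(f"{indent * depth}{tag}{node.residue}{' [core]' if node.core else ''}")
            for child in node.children:
                emit(child, depth + 1)

        emit(self.root, 0)
        return "\n".join(lines)


@dataclass(frozen=True)
class AntennaSpec:
    """Elaboration state of one antenna on a complex-type N-glycan."""

    has_glcnac: bool = True
    has_gal: bool = False
    has_neu5ac: bool = False
    has_antennary_fuc: bool = False

    def validate(self) -> None:
        if self.has_gal and not self.has_glcnac:
            raise ValueError("antenna Gal requires a GlcNAc")
        if self.has_neu5ac and not self.has_gal:
            raise ValueError("antenna Neu5Ac requires a Gal")
        if self.has_antennary_fuc and not self.has_glcnac:
            raise ValueError("antennary fucose requires a GlcNAc")


# Linkages used when placing antennae on the two core branch mannoses.
# Antenna 1/3 go on the alpha1-3 Man (b1-2, b1-4); antenna 2/4 on the
# alpha1-6 Man (b1-2, b1-6) — the canonical complex-type arrangement.
_ANTENNA_SLOTS = ((0, "b1-2"), (1, "b1-2"), (0, "b1-4"), (1, "b1-6"))


def build_nglycan(
    antennae: Iterable[AntennaSpec | Mapping[str, bool]],
    core_fucose: bool = False,
    sialyl_linkage: str = "a2-6",
    antennary_fuc_linkage: str = "a1-3",
    name: str = "",
) -> GlycanTopology:
    """Build a canonical complex-type N-glycan on a Man3GlcNAc2 core.

    ``antennae`` is 0-4 antenna specifications; each antenna is a
    GlcNAc(-Fuc)(-Gal(-Neu5Ac)) arm. ``core_fucose`` attaches a fucose
    alpha1-6 to the reducing-end GlcNAc.
    """
    specs: list[AntennaSpec] = []
    for a in antennae:
        spec = a if isinstance(a, AntennaSpec) else AntennaSpec(**dict(a))
        spec.validate()
        specs.append(spec)
    if len(specs) > 4:
        raise ValueError(f"at most 4 antennae supported, got {len(specs)}")
    # canonical antenna order (by elaboration state): antennae are
    # experimentally indistinguishable at the intact level, so topologies
    # differing only in antenna placement must compare equal
    specs.sort(
        key=lambda s: (s.has_glcnac, s.has_gal, s.has_neu5ac, s.has_antennary_fuc),
        reverse=True,
    )

    root = GlycanNode("GlcNAc", core=True)
    glcnac2 = root.add(GlycanNode("GlcNAc", "b1-4", core=True))
    man_beta = glcnac2.add(GlycanNode("Man", "b1-4", core=True))
    man_a3 = man_beta.add(GlycanNode("Man", "a1-3", core=True))
    man_a6 = man_beta.add(GlycanNode("Man", "a1-6", core=True))
    branch_mans = (man_a3, man_a6)

    if core_fucose:
        root.add(GlycanNode("Fuc", "a1-6"))

    for spec, (branch_idx, glcnac_linkage) in zip(specs, _ANTENNA_SLOTS):
        if not spec.has_glcnac:
            continue
        glcnac = branch_mans[branch_idx].add(GlycanNode("GlcNAc", glcnac_linkage))
        if spec.has_antennary_fuc:
            glcnac.add(GlycanNode("Fuc", antennary_fuc_linkage))
        if spec.has_gal:
            gal = glcnac.add(GlycanNode("Gal", "b1-4"))
            if spec.has_neu5ac:
                gal.add(GlycanNode("Neu5Ac", sialyl_linkage))

    return GlycanTopology(root, name)


def biantennary(
    sialylated: bool = True,
    core_fucose: bool = False,
    antennary_fucoses: int = 0,
    name: str = "",
) -> GlycanTopology:
    """Convenience constructor for the workhorse bi-antennary glycans (A2G2/A2G2S2)."""
    if not 0 <= antennary_fucoses <= 2:
        raise ValueError("a bi-antennary glycan carries 0-2 antennary fucoses")
    antennae = [
        AntennaSpec(True, True, sialylated, i < antennary_fucoses) for i in range(2)
    ]
    return build_nglycan(antennae, core_fucose=core_fucose, name=name)
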