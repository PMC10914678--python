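"""Combinatorial proteoform mass libraries for plasma SERPINs.

A proteoform is one backbone variant (common SNP backbones such as SERPINA1
M1V/M1A/M2/M3) combined with one truncation state, a cysteinylation
stoichiometry and one glycan per N-glycosylation site. Masses are average
masses by default, matching envelope-level intact native MS.

Positions use precursor numbering (signal peptide included), the convention
of the residue labels used throughout (Asn70/Asn107/Asn271, Cys256, Glu400);
``ProteinSequence.numbering_offset`` supports other conventions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pyteomics import mass as _ptmass

from .glycan_model import (
    GlycanComposition,
    GlycanTopology,
    composition_mass,
    format_composition,
)

__all__ = [
    "ProteinSequence",
    "VariantDef",
    "Truncation",
    "ProteoformSpec",
    "ComplexSpec",
    "load_fasta",
    "serpina1_sequence",
    "SERPINA1_VARIANTS",
    "SERPINA1_NTERM_TRUNCATION",
    "GLYCOSITE_PRESETS",
    "apply_variant",
    "backbone_mass",
    "find_sequons",
    "make_proteoform",
    "make_complex",
    "enumerate_proteoforms",
    "collision_report",
    "complex_mass",
    "library_frame",
    "glycan_features",
    "CYSTEINYLATION_AVG",
    "CYSTEINYLATION_MONO",
]

# Classical average residue masses (ExPASy convention), consistent with the
# monosaccharide table in glycan_model.
AVERAGE_AA_MASS: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1412, "F": 147.1766, "R": 156.1870, "Y": 163.1760, "W": 186.2132,
}
MONO_AA_MASS: dict[str, float] = {aa: _ptmass.std_aa_mass[aa] for aa in AVERAGE_AA_MASS}
WATER_AVG = 18.0153
WATER_MONO = 18.0105646863

# S-cysteinylation adduct (free cysteine disulfide on a protein Cys): C3H5NO2S.
CYSTEINYLATION_AVG = 119.1442
CYSTEINYLATION_MONO = 119.004099


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence with a numbering convention.

    ``numbering_offset`` shifts reported positions: residue i (1-based in
    ``residues``) is quoted as position ``i + numbering_offset``. The bundled
    precursor fixture uses offset 0 (position 1 = initiator Met).
    ``mature_start`` is the quoted position of the first residue of the
    mature (secreted) chain — proteoform masses are computed on the mature
    chain, which is what native MS observes, while positions stay in
    precursor numbering.
    """

    label: str
    residues: str
    numbering_offset: int = 0
    mature_start: int | None = None

    def __post_init__(self) -> None:
        bad = set(self.residues) - set(AVERAGE_AA_MASS)
        if bad:
            raise ValueError(f"non-canonical residue codes in {self.label!r}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    def residue_at(self, position: int) -> str:
        """Residue at a quoted (offset-adjusted, 1-based) position."""
        idx = position - self.numbering_offset - 1
        if not 0 <= idx < len(self.residues):
            raise IndexError(f"position {position} outside {self.label!r}")
        return self.residues[idx]


@dataclass(frozen=True)
class VariantDef:
    """A named backbone variant as a list of (position, ref, alt) substitutions."""

    name: str
    substitutions: tuple[tuple[int, str, str], ...] = ()

    def mass_delta(self, mass_type: str = "average") -> float:
        table = AVERAGE_AA_MASS if mass_type == "average" else MONO_AA_MASS
        return sum(table[alt] - table[ref] for _, ref, alt in self.substitutions)


# The four most common wild-type SERPINA1 backbones, plus the classical
# deficiency alleles S and Z (masses computable; no polymer biology here).
SERPINA1_VARIANTS: dict[str, VariantDef] = {
    "M1V": VariantDef("M1V"),
    "M1A": VariantDef("M1A", ((237, "V", "A"),)),
    "M3": VariantDef("M3", ((400, "E", "D"),)),
    "M2": VariantDef("M2", ((125, "R", "H"), (400, "E", "D"))),
    "S": VariantDef("S", ((288, "E", "V"),)),
    "Z": VariantDef("Z", ((366, "E", "K"),)),
}


@dataclass(frozen=True)
class Truncation:
    """A contiguous residue range removed from the chain (inclusive, quoted positions)."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"truncation end {self.end} before start {self.start}")


# N-terminal truncated SERPINA1 missing the first five mature residues
# (precursor 25-29, EDPQG).
SERPINA1_NTERM_TRUNCATION = Truncation("des25-29", 25, 29)

# Glycosite presets, precursor numbering. The two SERPINA3 lists reflect the
# two site lists in circulation (Asn133-containing vs Asn33-containing);
# both are kept, neither is arbitrated.
GLYCOSITE_PRESETS: dict[str, tuple[int, ...]] = {
    "SERPINA1": (70, 107, 271),
    "SERPINA3_main": (93, 106, 127, 133, 186, 271),
    "SERPINA3_alt": (33, 93, 106, 127, 186, 271),
}


def load_fasta(
    path: str | Path, numbering_offset: int = 0, mature_start: int | None = None
) -> list[ProteinSequence]:
    """Read protein sequences from a FASTA file."""
    sequences: list[ProteinSequence] = []
    label, chunks = None, []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if label is not None:
                    sequences.append(
                        ProteinSequence(label, "".join(chunks), numbering_offset, mature_start)
                    )
                label, chunks = line[1:].split()[0], []
            else:
                chunks.append(line.upper())
        if label is not None:
            sequences.append(
                ProteinSequence(label, "".join(chunks), numbering_offset, mature_start)
            )
    if not sequences:
        raise ValueError(f"no sequences found in {path}")
    return sequences


def serpina1_sequence() -> ProteinSequence:
    """The bundled canonical (M1V) SERPINA1 precursor, UniProt P01009.

    Precursor numbering; the mature chain starts at Glu25 (signal peptide
    1-24), so proteoform masses come out at the secreted-protein scale.
    """
    with resources.as_file(resources.files("serpinms") / "data" / "P01009.fasta") as path:
        return load_fasta(path, mature_start=25)[0]


def apply_variant(seq: ProteinSequence, variant: VariantDef) -> ProteinSequence:
    """Apply substitutions, checking each reference residue; length unchanged."""
    residues = list(seq.residues)
    for position, ref, alt in variant.substitutions:
        idx = position - seq.numbering_offset - 1
        if not 0 <= idx < len(residues):
            raise ValueError(f"variant {variant.name}: position {position} outside sequence")
        found = residues[idx]
        if found != ref:
            raise ValueError(
                f"variant {variant.name}: expected {ref} at position {position}, found {found}"
            )
        if alt not in AVERAGE_AA_MASS:
            raise ValueError(f"variant {variant.name}: unknown residue {alt!r}")
        residues[idx] = alt
    label = f"{seq.label}|{variant.name}" if variant.substitutions else seq.label
    return replace(seq, label=label, residues="".join(residues))


def backbone_mass(seq: ProteinSequence | str, mass_type: str = "average") -> float:
    """Chain mass: sum of residue masses plus one water.

    The empty sequence is accepted and weighs one water (18.02 Da average) —
    a convenient boundary for fragment arithmetic.
    """
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    if mass_type == "average":
        table, water = AVERAGE_AA_MASS, WATER_AVG
    elif mass_type == "monoisotopic":
        table, water = MONO_AA_MASS, WATER_MONO
    else:
        raise ValueError(f"mass_type must be 'average' or 'monoisotopic', got {mass_type!r}")
    try:
        return sum(table[aa] for aa in residues) + water
    except KeyError as exc:
        raise ValueError(f"unknown residue code {exc.args[0]!r}") from None


def find_sequons(seq: ProteinSequence) -> list[int]:
    """Positions (quoted numbering) of N-glycosylation sequons N-X-[S/T], X != P."""
    residues = seq.residues
    return [
        i + 1 + seq.numbering_offset
        for i in range(len(residues) - 2)
        if residues[i] == "N" and residues[i + 1] != "P" and residues[i + 2] in "ST"
    ]


def _glycan_composition(glycan: GlycanTopology | GlycanComposition | Mapping[str, int]) -> GlycanComposition:
    if isinstance(glycan, GlycanTopology):
        return glycan.composition()
    return GlycanComposition(glycan)


@dataclass(frozen=True)
class ProteoformSpec:
    """One fully specified molecular form: variant + truncation + Cys adduct + glycans."""

    variant: VariantDef
    truncation: Truncation | None
    cysteinylation_count: int
    site_glycans: tuple[tuple[int, object], ...]  # (site, GlycanTopology|GlycanComposition)
    mass: float
    monoisotopic_mass: float = float("nan")
    label: str = ""

    @property
    def glycans(self) -> dict[int, object]:
        return dict(self.site_glycans)

    def total_glycan_composition(self) -> GlycanComposition:
        total = GlycanComposition()
        for _, glycan in self.site_glycans:
            total = total + _glycan_composition(glycan)
        return total

    def feature_counts(self) -> tuple[int, int, int]:
        return glycan_features(self)


def glycan_features(spec: ProteoformSpec) -> tuple[int, int, int]:
    """(core fucoses, antennary fucoses, extra branch units) summed over sites.

    Extra branch units count antennae beyond the bi-antennary baseline
    (two per occupied site); requires topology-level glycans — composition-only
    glycans contribute zero to all three counts.
    """
    core = antennary = extra = 0
    for _, glycan in spec.site_glycans:
        if isinstance(glycan, GlycanTopology):
            core += glycan.core_fucose_count()
            antennary += glycan.antennary_fucose_count()
            extra += max(glycan.antenna_count() - 2, 0)
    return core, antennary, extra


def _mature_chain(seq: ProteinSequence, truncation: Truncation | None) -> str:
    """The observed chain: signal peptide stripped, truncation range removed."""
    start = (seq.mature_start or (1 + seq.numbering_offset)) - seq.numbering_offset - 1
    chain_start = seq.numbering_offset + start + 1  # quoted position of first residue
    residues = seq.residues[start:]
    if truncation is None:
        return residues
    t_start = truncation.start - chain_start
    t_end = truncation.end - chain_start + 1  # exclusive
    if not (0 <= t_start < t_end <= len(residues)):
        raise ValueError(f"truncation {truncation.name} outside mature chain")
    return residues[:t_start] + residues[t_end:]


def _proteoform_mass(
    base: ProteinSequence,
    variant: VariantDef,
    truncation: Truncation | None,
    cys: int,
    glycans: Sequence[tuple[int, object]],
    mass_type: str,
) -> float:
    varied = apply_variant(base, variant)
    total = backbone_mass(_mature_chain(varied, truncation), mass_type)
    cys_delta = CYSTEINYLATION_AVG if mass_type == "average" else CYSTEINYLATION_MONO
    total += cys * cys_delta
    for _, glycan in glycans:
        total += composition_mass(_glycan_composition(glycan), mass_type)
    return total


def _glycan_name(glycan: object) -> str:
    if isinstance(glycan, GlycanTopology) and glycan.name:
        return glycan.name
    return format_composition(_glycan_composition(glycan)) or "none"


def make_proteoform(
    seq: ProteinSequence,
    variant: VariantDef,
    truncation: Truncation | None = None,
    cysteinylation_count: int = 0,
    site_glycans: Mapping[int, object] | Sequence[tuple[int, object]] = (),
) -> ProteoformSpec:
    """Build a single ProteoformSpec with computed average and monoisotopic mass."""
    glycans = tuple(sorted(
        site_glycans.items() if isinstance(site_glycans, Mapping) else site_glycans
    ))
    label_bits = [variant.name]
    if truncation is not None:
        label_bits.append(truncation.name)
    if cysteinylation_count:
        label_bits.append(f"Cys{cysteinylation_count}")
    for site, glycan in glycans:
        label_bits.append(f"N{site}:{_glycan_name(glycan)}")
    return ProteoformSpec(
        variant=variant,
        truncation=truncation,
        cysteinylation_count=cysteinylation_count,
        site_glycans=glycans,
        mass=_proteoform_mass(seq, variant, truncation, cysteinylation_count, glycans, "average"),
        monoisotopic_mass=_proteoform_mass(
            seq, variant, truncation, cysteinylation_count, glycans, "monoisotopic"
        ),
        label="/".join(label_bits),
    )


def enumerate_proteoforms(
    seq: ProteinSequence,
    variants: Iterable[VariantDef],
    truncations: Iterable[Truncation | None] = (None,),
    cys_options: Iterable[int] = (0,),
    per_site_glycan_sets: Mapping[int, Sequence[object]] | None = None,
    dedup: str = "composition",
) -> list[ProteoformSpec]:
    """Cartesian product over variants × truncations × cysteinylation × site glycans.

    Deduplicated by (variant, truncation, cys, per-site glycan key) and
    sorted by mass. With ``dedup="composition"`` (default) glycan isomers
    collapse — the mass-library view, where core- and antennary-fucosylated
    glycoforms are one intact-level peak. ``dedup="topology"`` keeps isomers
    distinct, the view needed when simulating isomer-specific binding.
    """
    if dedup not in ("composition", "topology"):
        raise ValueError(f"dedup must be 'composition' or 'topology', got {dedup!r}")
    variants = list(variants)
    truncations = list(truncations)
    cys_options = list(cys_options)
    per_site = dict(per_site_glycan_sets or {})
    if not variants or not truncations or not cys_options:
        return []
    sites = sorted(per_site)
    site_choices = [per_site[s] for s in sites]
    if any(len(choices) == 0 for choices in site_choices):
        return []

    seen: set = set()
    library: list[ProteoformSpec] = []
    for variant, truncation, cys in itertools.product(variants, truncations, cys_options):
        for combo in itertools.product(*site_choices) if sites else [()]:
            glycans = tuple(zip(sites, combo))
            if dedup == "composition":
                glycan_key = tuple(
                    (s, format_composition(_glycan_composition(g))) for s, g in glycans
                )
            else:
                glycan_key = tuple(
                    (s, g if isinstance(g, GlycanTopology) else format_composition(_glycan_composition(g)))
                    for s, g in glycans
                )
            key = (
                variant.name,
                truncation.name if truncation else None,
                cys,
                glycan_key,
            )
            if key in seen:
                continue
            seen.add(key)
            library.append(make_proteoform(seq, variant, truncation, cys, glycans))
    library.sort(key=lambda p: (p.mass, p.label))
    return library


def collision_report(
    library: Sequence[ProteoformSpec], threshold: float = 6.0
) -> pd.DataFrame:
    """Near-isobaric pairs (|mass difference| < threshold Da) in a sorted library.

    At ~51 kDa the problematic pairs are M2 vs M1A backbones (5.02 Da apart)
    and +2 Fuc vs +1 Neu5Ac glycoforms (1.03 Da apart).
    """
    ordered = sorted(library, key=lambda p: p.mass)
    rows = []
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            delta = b.mass - a.mass
            if delta >= threshold:
                break
            rows.append(
                {"proteoform_a": a.label, "proteoform_b": b.label,
                 "mass_a": a.mass, "mass_b": b.mass, "delta_da": delta}
            )
    return pd.DataFrame(rows, columns=["proteoform_a", "proteoform_b", "mass_a", "mass_b", "delta_da"])


@dataclass(frozen=True)
class ComplexSpec:
    """A SERPIN-protease complex mass model.

    ``intact_sum`` conserves all atoms through acyl-enzyme formation (default);
    ``loop_fragment_released`` additionally subtracts the C-terminal reactive
    center loop fragment (from ``cleavage_position`` to the C terminus, as a
    peptide with water), for the case where the cleaved tail dissociates.
    """

    serpin: ProteoformSpec
    protease_mass: float
    mode: str = "intact_sum"
    cleavage_position: int | None = None
    released_fragment_mass: float = 0.0
    label: str = ""

    @property
    def mass(self) -> float:
        return complex_mass(self)


def make_complex(
    serpin: ProteoformSpec,
    protease_mass: float,
    mode: str = "intact_sum",
    sequence: ProteinSequence | None = None,
    cleavage_position: int | None = None,
    protease_name: str = "protease",
) -> ComplexSpec:
    """Build a ComplexSpec; released mode needs the sequence and cleavage site."""
    if protease_mass <= 0:
        raise ValueError(f"protease_mass must be positive, got {protease_mass}")
    fragment_mass = 0.0
    if mode == "loop_fragment_released":
        if sequence is None or cleavage_position is None:
            raise ValueError("loop_fragment_released mode requires sequence and cleavage_position")
        varied = apply_variant(sequence, serpin.variant)
        idx = cleavage_position - sequence.numbering_offset - 1
        if not 0 <= idx < len(varied.residues):
            raise ValueError(f"cleavage position {cleavage_position} outside sequence")
        fragment_mass = backbone_mass(varied.residues[idx:], "average")
    elif mode != "intact_sum":
        raise ValueError(f"unknown complex mode {mode!r}")
    return ComplexSpec(
        serpin=serpin,
        protease_mass=protease_mass,
        mode=mode,
        cleavage_position=cleavage_position,
        released_fragment_mass=fragment_mass,
        label=f"{serpin.label}+{protease_name}",
    )


def complex_mass(spec: ComplexSpec) -> float:
    """Mass of the complex per its mode."""
    if spec.protease_mass <= 0:
        raise ValueError(f"protease_mass must be positive, got {spec.protease_mass}")
    total = spec.serpin.mass + spec.protease_mass
    if spec.mode == "loop_fragment_released":
        if spec.cleavage_position is None:
            raise ValueError("loop_fragment_released mode requires a cleavage_position")
        total -= spec.released_fragment_mass
    elif spec.mode != "intact_sum":
        raise ValueError(f"unknown complex mode {spec.mode!r}")
    return total


def library_frame(library: Sequence[ProteoformSpec]) -> pd.DataFrame:
    """Library as a table: label, variant, truncation, cys, composition, masses, features."""
    rows = []
    for p in library:
        core, antennary, extra = glycan_features(p)
        rows.append(
            {
                "label": p.label,
                "variant": p.variant.name,
                "truncation": p.truncation.name if p.truncation else "",
                "cysteinylation": p.cysteinylation_count,
                "glycan_composition": format_composition(p.total_glycan_composition()),
                "average_mass": round(p.mass, 4),
                "monoisotopic_mass": round(p.monoisotopic_mass, 4),
                "core_fucoses": core,
                "antennary_fucoses": antennary,
                "extra_branches": extra,
            }
        )
    return pd.DataFrame(rows)
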