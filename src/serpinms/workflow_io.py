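"""Configuration, file I/O and stage binding for reproducible pipeline runs.

A run is fully determined by a YAML config plus its seed: every output file
embeds the config hash and seed in comment headers, and every tolerance and
policy actually used is logged, so a run can be audited and reproduced
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import deconv_assign, enzyme_engine, quantify_stats, spectrum_sim
from .glycan_model import GlycanTopology, build_nglycan, AntennaSpec
from .proteoform_library import (
    GLYCOSITE_PRESETS,
    SERPINA1_NTERM_TRUNCATION,
    SERPINA1_VARIANTS,
    ProteoformSpec,
    Truncation,
    enumerate_proteoforms,
    glycan_features,
    library_frame,
    load_fasta,
    serpina1_sequence,
)

logger = logging.getLogger("serpinms")

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "config_hash",
    "glycoform_from_spec",
    "build_library_from_config",
    "run_build_library",
    "run_digest",
    "run_simulate",
    "run_assign_quantify",
    "analyze_spectra",
]


class ConfigError(ValueError):
    """Invalid run configuration; message names the offending field."""


@dataclass
class RunConfig:
    """Everything needed to reproduce a run (serializable, seed included)."""

    sequence: str = "SERPINA1"
    variants: tuple[str, ...] = ("M1V", "M3")
    truncations: tuple[str, ...] = ("none",)
    cysteinylation: tuple[int, ...] = (0,)
    glycosites: tuple[int, ...] = (70, 107, 271)
    glycoforms: tuple[Mapping, ...] = (
        {"name": "A2G2S2", "antennae": 2, "sialylated": True},
    )
    varied_site: int = 271  # the site whose glycoforms are enumerated
    binding: Mapping = field(
        default_factory=lambda: {
            "base_bound_fraction": 0.5,
            "factor_core_fucose": 1.0,
            "factor_antennary_fucose": 1.0,
            "factor_branch": 1.0,
            "protease_mass": 25900.0,
            "protease_name": "elastase",
        }
    )
    simulation: Mapping = field(
        default_factory=lambda: {
            "charge_center": 14.0,
            "charge_spread": 1.0,
            "resolution": 25000.0,
            "intensity_cv": 0.05,
            "baseline": 0.0,
            "replicates": 3,
        }
    )
    enzyme_panel: Mapping = field(
        default_factory=lambda: {"enzymes": list(enzyme_engine.TRIPLE_PANEL),
                                 "mode": enzyme_engine.INTACT_GLYCOPROTEIN,
                                 "apply": False}
    )
    tolerances: Mapping = field(
        default_factory=lambda: {"assign_da": 1.0, "charge_mass_tol": 2.0, "min_snr": 3.0}
    )
    policies: Mapping = field(
        default_factory=lambda: {"normalization": "per_condition", "ambiguity": "drop"}
    )
    seed: int = 1
    outdir: str = "results"

    def to_dict(self) -> dict:
        return json.loads(json.dumps(asdict(self), default=list))


_STR_FIELDS = ("sequence", "outdir")
_LIST_FIELDS = ("variants", "truncations", "cysteinylation", "glycosites", "glycoforms")
_MAP_FIELDS = ("binding", "simulation", "enzyme_panel", "tolerances", "policies")


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    defaults = RunConfig()
    known = set(asdict(defaults))
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")
    merged: dict = {}
    for name in known:
        value = raw.get(name, getattr(defaults, name))
        if name in _STR_FIELDS and not isinstance(value, str):
            raise ConfigError(f"field {name!r} must be a string")
        if name in _LIST_FIELDS:
            if not isinstance(value, (list, tuple)):
                raise ConfigError(f"field {name!r} must be a list")
            value = tuple(value)
        if name in _MAP_FIELDS:
            if not isinstance(value, Mapping):
                raise ConfigError(f"field {name!r} must be a mapping")
            base = dict(getattr(defaults, name))
            extra = set(value) - set(base)
            if extra:
                raise ConfigError(f"unknown keys in {name!r}: {sorted(extra)}")
            base.update(value)
            value = base
        if name == "seed":
            if not isinstance(value, int):
                raise ConfigError("field 'seed' must be an integer")
        if name == "varied_site" and not isinstance(value, int):
            raise ConfigError("field 'varied_site' must be an integer")
        merged[name] = value
    config = RunConfig(**merged)
    for variant in config.variants:
        if variant not in SERPINA1_VARIANTS:
            raise ConfigError(
                f"unknown variant {variant!r}; known: {sorted(SERPINA1_VARIANTS)}"
            )
    for trunc in config.truncations:
        if trunc not in ("none", SERPINA1_NTERM_TRUNCATION.name):
            raise ConfigError(f"unknown truncation {trunc!r}")
    for enzyme in config.enzyme_panel["enzymes"]:
        if enzyme not in enzyme_engine.ENZYMES:
            raise ConfigError(f"unknown enzyme {enzyme!r}")
    if config.varied_site not in config.glycosites:
        raise ConfigError(f"varied_site {config.varied_site} not among glycosites")
    return config


def config_hash(config: RunConfig) -> str:
    """sha256 of the canonical JSON serialization of the config."""
    canonical = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def glycoform_from_spec(spec: Mapping) -> GlycanTopology:
    """Build a complex-type glycan from a config glycoform mapping.

    Keys: ``antennae`` (int, default 2), ``sialylated`` (default True),
    ``core_fucose`` (default False), ``antennary_fucoses`` (default 0),
    ``name`` (optional). Antennary fucoses sit on galactosylated antennae.
    """
    n = int(spec.get("antennae", 2))
    sialylated = bool(spec.get("sialylated", True))
    core_fucose = bool(spec.get("core_fucose", False))
    antennary = int(spec.get("antennary_fucoses", 0))
    if not 0 <= n <= 4:
        raise ConfigError(f"glycoform antennae must be 0-4, got {n}")
    if not 0 <= antennary <= n:
        raise ConfigError(f"glycoform antennary_fucoses must be 0-{n}, got {antennary}")
    antenna_specs = [
        AntennaSpec(True, True, sialylated, i < antennary) for i in range(n)
    ]
    name = spec.get("name") or (
        f"A{n}{'S' if sialylated else ''}{'Fc' if core_fucose else ''}"
        + (f"Fa{antennary}" if antennary else "")
    )
    return build_nglycan(antenna_specs, core_fucose=core_fucose, name=name)


def _sequence_from_config(config: RunConfig):
    if config.sequence == "SERPINA1":
        return serpina1_sequence()
    return load_fasta(config.sequence)[0]


def build_library_from_config(config: RunConfig):
    """(sequence, apo proteoform library) per the config's combinatorics.

    Non-varied glycosites carry the first configured glycoform; the
    ``varied_site`` enumerates the full glycoform list. When the enzyme
    panel has ``apply: true`` every glycoform is first digested to its panel
    product — the experiment's route to making fucose linkage isomers
    mass-distinguishable before quantification. Topology-keyed dedup keeps
    isomeric glycoforms as distinct (binding-relevant) classes.
    """
    sequence = _sequence_from_config(config)
    variants = [SERPINA1_VARIANTS[name] for name in config.variants]
    truncations = [
        None if name == "none" else SERPINA1_NTERM_TRUNCATION for name in config.truncations
    ]
    glycoforms = [glycoform_from_spec(g) for g in config.glycoforms]
    if config.enzyme_panel.get("apply"):
        digested = []
        for glycan in glycoforms:
            product = enzyme_engine.digest_panel(
                glycan, config.enzyme_panel["enzymes"], config.enzyme_panel["mode"]
            ).product
            product.name = f"{glycan.name}_dig"
            digested.append(product)
        glycoforms = digested
    per_site = {
        site: (glycoforms if site == config.varied_site else glycoforms[:1])
        for site in config.glycosites
    }
    library = enumerate_proteoforms(
        sequence, variants, truncations, config.cysteinylation, per_site,
        dedup="topology",
    )
    return sequence, library


def _header_lines(config: RunConfig) -> list[str]:
    return [f"config_sha256={config_hash(config)}", f"seed={config.seed}"]


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _header_lines(config):
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def run_build_library(config: RunConfig) -> pd.DataFrame:
    """Build the proteoform library and write ``library.csv``."""
    _, library = build_library_from_config(config)
    df = library_frame(library)
    _write_csv(df, Path(config.outdir) / "library.csv", config)
    logger.info("build-library: %d proteoforms, config=%s", len(df), config_hash(config))
    return df


def run_digest(config: RunConfig) -> pd.DataFrame:
    """Digest the configured glycoforms with the configured panel; write report."""
    panel = config.enzyme_panel["enzymes"]
    mode = config.enzyme_panel["mode"]
    logger.info("digest: panel=%s mode=%s", panel, mode)
    glycoforms = [glycoform_from_spec(g) for g in config.glycoforms]
    df = enzyme_engine.digestion_report(glycoforms, panel, mode)
    _write_csv(df, Path(config.outdir) / "digestion.csv", config)
    return df


def _binding_model(config: RunConfig) -> spectrum_sim.BindingModel:
    b = config.binding
    return spectrum_sim.BindingModel(
        base_bound_fraction=float(b["base_bound_fraction"]),
        factor_core_fucose=float(b["factor_core_fucose"]),
        factor_antennary_fucose=float(b["factor_antennary_fucose"]),
        factor_branch=float(b["factor_branch"]),
    )


def _sim_params(config: RunConfig, reference_mass: float | None) -> spectrum_sim.SimParams:
    s = config.simulation
    return spectrum_sim.SimParams(
        charge_center=float(s["charge_center"]),
        charge_spread=float(s["charge_spread"]),
        resolution=float(s["resolution"]),
        intensity_cv=float(s["intensity_cv"]),
        baseline=float(s["baseline"]),
        reference_mass=reference_mass,
        seed=config.seed,
    )


def simulate_from_config(config: RunConfig):
    """(library, mixed ensemble, params, spectra) for the configured run."""
    _, library = build_library_from_config(config)
    if not library:
        raise ValueError("empty proteoform library; nothing to simulate")
    model = _binding_model(config)
    members = [spectrum_sim.EnsembleMember(p, 1.0) for p in library]
    apo, bound = spectrum_sim.simulate_binding(
        members, model, float(config.binding["protease_mass"]),
        protease_name=str(config.binding["protease_name"]),
    )
    reference = float(np.median([m.mass for m in apo]))
    params = _sim_params(config, reference)
    n = int(config.simulation["replicates"])
    spectra = spectrum_sim.simulate_replicates(apo + bound, params, n)
    return library, apo + bound, params, spectra


def run_simulate(config: RunConfig) -> list[spectrum_sim.Spectrum]:
    """Simulate replicate spectra + ground truth; write them under outdir."""
    library, members, params, spectra = simulate_from_config(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for spectrum in spectra:
        rep = spectrum.metadata["replicate"]
        spectrum.write_text(outdir / f"spectrum_rep{rep}.txt", _header_lines(config))
    _write_csv(spectrum_sim.ground_truth_frame(members), outdir / "ground_truth.csv", config)
    logger.info(
        "simulate: %d members, %d replicates, cv=%s, seed=%d",
        len(members), len(spectra), config.simulation["intensity_cv"], config.seed,
    )
    return spectra


def analyze_spectra(
    spectra: Sequence[spectrum_sim.Spectrum],
    library: Sequence[object],
    min_snr: float = 3.0,
    z_range: tuple[int, int] = (8, 26),
    charge_mass_tol: float = 2.0,
    tolerance_da: float = 1.0,
    normalization: str = "per_condition",
    ambiguity: str = "drop",
):
    """pick -> infer charge -> assign -> per-replicate abundance table.

    Returns (assignments per replicate, concatenated abundance table).
    """
    logger.info(
        "assign: min_snr=%s z_range=%s charge_mass_tol=%s tolerance_da=%s "
        "normalization=%s ambiguity=%s",
        min_snr, z_range, charge_mass_tol, tolerance_da, normalization, ambiguity,
    )
    all_assignments, tables = [], []
    for i, spectrum in enumerate(spectra):
        replicate = spectrum.metadata.get("replicate", i + 1)
        peaks = deconv_assign.pick_peaks(spectrum, min_snr=min_snr)
        charges = deconv_assign.infer_charge(peaks, z_range=z_range, mass_tol=charge_mass_tol)
        assignments = deconv_assign.assign(
            peaks, charges, library, tolerance=tolerance_da, replicate=replicate
        )
        all_assignments.append(assignments)
        tables.append(
            quantify_stats.abundance_table(
                assignments, normalization=normalization, ambiguity=ambiguity,
                replicate=replicate,
            )
        )
    table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(
        columns=["class", "condition", "replicate", "abundance"]
    )
    return all_assignments, table


def run_assign_quantify(
    config: RunConfig,
    spectra: Sequence[spectrum_sim.Spectrum] | None = None,
) -> dict:
    """Assign simulated (or provided) spectra and quantify complex:apo ratios.

    Writes ``assignments.csv`` and ``report.json``; returns the report dict.
    The report stratifies ratios by each glycan feature (core fucoses,
    antennary fucoses, extra branch units) and runs the feature trend test
    where >= 3 levels exist.
    """
    library, members, params, simulated = simulate_from_config(config)
    if spectra is None:
        spectra = simulated
    complex_library = [m.species for m in members if m.condition == "complex"]
    full_library = list(library) + complex_library

    tol = config.tolerances
    pol = config.policies
    zmax = int(np.ceil(params.charge_center * np.sqrt(
        max(m.mass for m in members) / min(m.mass for m in members)
    ) + 3 * params.charge_spread))
    assignments, table = analyze_spectra(
        spectra, full_library,
        min_snr=float(tol["min_snr"]),
        z_range=(max(1, int(params.charge_center - 3 * params.charge_spread)), zmax),
        charge_mass_tol=float(tol["charge_mass_tol"]),
        tolerance_da=float(tol["assign_da"]),
        normalization=str(pol["normalization"]),
        ambiguity=str(pol["ambiguity"]),
    )
    flat = pd.concat(
        [deconv_assign.assignments_frame(a) for a in assignments], ignore_index=True
    )
    _write_csv(flat, Path(config.outdir) / "assignments.csv", config)

    features = {p.label: glycan_features(p) for p in library}
    report: dict = {
        "config_sha256": config_hash(config),
        "seed": config.seed,
        "parameters": {
            "tolerances": dict(tol),
            "policies": dict(pol),
            "binding": dict(config.binding),
            "simulation": dict(config.simulation),
        },
        "ratios": {},
        "trends": {},
    }
    feature_names = ("core_fucoses", "antennary_fucoses", "extra_branches")
    for axis, name in enumerate(feature_names):
        results = quantify_stats.complex_apo_ratio(
            table, stratify_by=lambda label, axis=axis: features[label][axis]
        )
        report["ratios"][name] = [
            {
                "level": r.label,
                "mean": r.mean,
                "sd": r.sd,
                "n": r.n,
                "ratios": [x for x in r.ratios.tolist()],
            }
            for r in results
        ]
        by_count = {int(r.label): r for r in results if r.n > 0}
        if len(by_count) >= 3:
            trend = quantify_stats.feature_trend(by_count)
            report["trends"][name] = {
                "direction": trend.direction,
                "rank_correlation": trend.rank_correlation,
                "fold_per_step": trend.fold_per_step,
            }
    out = Path(config.outdir) / "report.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(report, indent=2, default=float))
    logger.info("quantify: report written to %s", out)
    return report
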