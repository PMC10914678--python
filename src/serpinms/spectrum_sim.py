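"""Synthetic native mass spectra of SERPIN proteoform ensembles.

Emulates what the native MS experiment sees: a mixture of apo glycoprotein
proteoforms (51-53 kDa) and SERPIN-protease complexes (~80 kDa), each
species spread over a Gaussian envelope of charge states, with glycoform
fine structure (branch-unit ladders, +/-fucose, +/-cysteinylation,
near-isobaric SNP backbones), replicate-to-replicate log-normal intensity
noise, optional uniform baseline and an optional +203.2 Da GlcNAc adduct
satellite series.

The binding model is multiplicative on the bound odds: a proteoform with c
core fucoses, a antennary fucoses and b extra Gal-GlcNAc branch units binds
with odds ``p0/(1-p0) * f_c**c * f_a**a * f_b**b``, so the expected
complex:apo abundance ratio of a glycoform class equals its odds. Factors
above 1 stabilize the complex, below 1 destabilize it.

Peaks are envelope-level Gaussians (no isotope structure): apex height is
proportional to species abundance times the charge-envelope weight, with
FWHM = (m/z)/R. One master seed drives all randomness.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .proteoform_library import ComplexSpec, ProteoformSpec, glycan_features, make_complex

__all__ = [
    "PROTON_MASS",
    "mz_of",
    "EnsembleMember",
    "BindingModel",
    "SimParams",
    "Spectrum",
    "simulate_binding",
    "simulate_spectrum",
    "simulate_replicates",
    "theoretical_centroids",
    "ground_truth_frame",
    "simulate_ratio_replicates",
]

PROTON_MASS = 1.00728  # Da


def mz_of(mass: float, z: int) -> float:
    """Electrospray m/z of a neutral mass at charge z: (M + z*mp)/z."""
    if z <= 0:
        raise ValueError(f"charge must be a positive integer, got {z}")
    return (mass + z * PROTON_MASS) / z


@dataclass
class EnsembleMember:
    """A species in the simulated mixture with its true (unnormalized) abundance."""

    species: ProteoformSpec | ComplexSpec
    abundance: float
    condition: str = "apo"  # "apo" or "complex"

    def __post_init__(self) -> None:
        if self.abundance < 0:
            raise ValueError("abundance must be non-negative")

    @property
    def mass(self) -> float:
        return self.species.mass

    @property
    def label(self) -> str:
        return self.species.label


@dataclass(frozen=True)
class BindingModel:
    """Glycan-feature-modulated SERPIN-protease binding.

    ``base_bound_fraction`` (p0) is the bound fraction of a feature-free
    proteoform; each feature multiplies the bound odds by its factor raised
    to the per-proteoform feature count.
    """

    base_bound_fraction: float = 0.5
    factor_core_fucose: float = 1.0
    factor_antennary_fucose: float = 1.0
    factor_branch: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.base_bound_fraction < 1.0:
            raise ValueError("base_bound_fraction must be in (0, 1)")
        for name in ("factor_core_fucose", "factor_antennary_fucose", "factor_branch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def odds(self, core_fucoses: int, antennary_fucoses: int, extra_branches: int) -> float:
        """Bound/unbound odds for given feature counts = expected complex:apo ratio."""
        p0 = self.base_bound_fraction
        return (
            p0 / (1.0 - p0)
            * self.factor_core_fucose ** core_fucoses
            * self.factor_antennary_fucose ** antennary_fucoses
            * self.factor_branch ** extra_branches
        )

    def bound_fraction(self, core_fucoses: int, antennary_fucoses: int, extra_branches: int) -> float:
        odds = self.odds(core_fucoses, antennary_fucoses, extra_branches)
        return odds / (1.0 + odds)


def simulate_binding(
    members: Sequence[EnsembleMember],
    model: BindingModel,
    protease_mass: float,
    mode: str = "intact_sum",
    protease_name: str = "protease",
) -> tuple[list[EnsembleMember], list[EnsembleMember]]:
    """Split each proteoform into apo and complex sub-populations.

    Returns (apo ensemble, complex ensemble); the abundance split follows the
    model's bound fraction for the proteoform's feature counts, so the
    expected complex:apo ratio of each class equals its odds.
    """
    if not members:
        raise ValueError("ensemble must contain at least one member")
    apo: list[EnsembleMember] = []
    bound: list[EnsembleMember] = []
    for member in members:
        spec = member.species
        if not isinstance(spec, ProteoformSpec):
            raise TypeError("simulate_binding expects apo ProteoformSpec members")
        frac = model.bound_fraction(*glycan_features(spec))
        apo.append(EnsembleMember(spec, member.abundance * (1.0 - frac), "apo"))
        bound.append(
            EnsembleMember(
                make_complex(spec, protease_mass, mode, protease_name=protease_name),
                member.abundance * frac,
                "complex",
            )
        )
    return apo, bound


@dataclass
class SimParams:
    """Instrument-level simulation parameters.

    ``charge_center``/``charge_spread`` define a Gaussian charge envelope
    (discretized over integer z). If ``reference_mass`` is set, each species'
    envelope center scales as sqrt(mass/reference_mass), the native-MS trend
    that puts an ~80 kDa complex at higher z than a 51 kDa apo protein.
    ``resolution`` defines FWHM = (m/z)/R. Noise = additive uniform baseline
    plus per-peak log-normal height jitter with the given CV. The optional
    adduct series adds satellites at +adduct_mass (neutral) with geometrically
    decaying height.
    """

    charge_center: float = 14.0
    charge_spread: float = 1.0
    resolution: float = 25000.0
    reference_mass: float | None = None
    mz_min: float | None = None
    mz_max: float | None = None
    mz_step: float | None = None
    baseline: float = 0.0
    intensity_cv: float = 0.0
    adduct_mass: float = 203.195
    adduct_decay: float = 0.0  # satellite k has relative height adduct_decay**k
    n_adducts: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.charge_spread <= 0:
            raise ValueError("charge_spread must be positive")
        if self.intensity_cv < 0 or self.baseline < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass
class Spectrum:
    """A profile spectrum on a regular m/z grid."""

    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def total_intensity(self) -> float:
        """Numerically integrated intensity (trapezoid over the grid)."""
        return float(np.trapezoid(self.intensity, self.mz))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mz": self.mz, "intensity": self.intensity})

    def write_text(self, path, header_lines: Iterable[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            for x, y in zip(self.mz, self.intensity):
                fh.write(f"{x:.6f}\t{y:.8g}\n")

    @classmethod
    def read_text(cls, path) -> "Spectrum":
        data = np.loadtxt(path, comments="#")
        return cls(data[:, 0], data[:, 1])


def _charge_states(params: SimParams, mass: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Integer charge states, envelope weights (sum 1) and the envelope center."""
    center = params.charge_center
    if params.reference_mass is not None:
        center *= math.sqrt(mass / params.reference_mass)
    lo = max(1, int(math.floor(center - 3 * params.charge_spread)))
    hi = int(math.ceil(center + 3 * params.charge_spread))
    zs = np.arange(lo, hi + 1)
    weights = np.exp(-0.5 * ((zs - center) / params.charge_spread) ** 2)
    weights /= weights.sum()
    return zs, weights, center


def _peak_table(members: Sequence[EnsembleMember], params: SimParams) -> pd.DataFrame:
    """All theoretical peaks (member x charge x adduct) with noiseless heights."""
    rows = []
    for im, member in enumerate(members):
        zs, weights, _ = _charge_states(params, member.mass)
        n_sat = params.n_adducts if params.adduct_decay > 0 else 0
        for z, w in zip(zs, weights):
            for k in range(n_sat + 1):
                height = member.abundance * w * (params.adduct_decay ** k if k else 1.0)
                rows.append(
                    {
                        "member_index": im,
                        "label": member.label,
                        "condition": member.condition,
                        "mass": member.mass + k * params.adduct_mass,
                        "z": int(z),
                        "adduct": k,
                        "mz": mz_of(member.mass + k * params.adduct_mass, int(z)),
                        "height": height,
                    }
                )
    return pd.DataFrame(rows)


def theoretical_centroids(members: Sequence[EnsembleMember], params: SimParams) -> pd.DataFrame:
    """Noiseless theoretical peak list (the simulation ground truth)."""
    table = _peak_table(members, params)
    return table.sort_values("mz", ignore_index=True)


def simulate_spectrum(
    members: Sequence[EnsembleMember],
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """Render a profile spectrum: Gaussian peak per (member, z, adduct).

    Apex height is abundance x charge-envelope weight (x adduct decay),
    FWHM = (m/z)/R. Deterministic for a given seed.
    """
    if not members:
        raise ValueError("ensemble must contain at least one member")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    peaks = _peak_table(members, params)

    fwhm = peaks["mz"].to_numpy() / params.resolution
    lo = params.mz_min if params.mz_min is not None else float(peaks["mz"].min() - 20 * fwhm.max())
    hi = params.mz_max if params.mz_max is not None else float(peaks["mz"].max() + 20 * fwhm.max())
    step = params.mz_step if params.mz_step is not None else float(fwhm.min() / 6.0)
    if step > fwhm.min() / 3.0:
        warnings.warn(
            f"m/z grid step {step:.4g} coarser than FWHM/3 = {fwhm.min() / 3:.4g}; "
            "peak shapes will be undersampled",
            stacklevel=2,
        )
    grid = np.arange(lo, hi + step, step)
    intensity = np.zeros_like(grid)

    heights = peaks["height"].to_numpy().astype(float)
    if params.intensity_cv > 0:
        sigma = math.sqrt(math.log(1.0 + params.intensity_cv**2))
        # mean-one log-normal jitter so expected heights stay nominal
        heights = heights * rng.lognormal(-0.5 * sigma**2, sigma, size=heights.size)

    sigmas = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    for mu, s, h in zip(peaks["mz"].to_numpy(), sigmas, heights):
        window = (grid > mu - 6 * s) & (grid < mu + 6 * s)
        intensity[window] += h * np.exp(-0.5 * ((grid[window] - mu) / s) ** 2)

    if params.baseline > 0:
        intensity += rng.uniform(0.0, params.baseline, size=grid.size)

    return Spectrum(grid, intensity, {"seed": params.seed, "n_members": len(members)})


def expected_total_intensity(members: Sequence[EnsembleMember], params: SimParams) -> float:
    """Analytic noiseless integral: sum of Gaussian peak areas (height*sigma*sqrt(2pi))."""
    peaks = _peak_table(members, params)
    sigmas = peaks["mz"].to_numpy() / params.resolution / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    return float((peaks["height"].to_numpy() * sigmas).sum() * math.sqrt(2.0 * math.pi))


def simulate_replicates(
    members: Sequence[EnsembleMember],
    params: SimParams,
    n: int,
) -> list[Spectrum]:
    """n spectra with independent noise; replicate seeds derive from the master seed."""
    if n < 1:
        raise ValueError(f"replicate count must be >= 1, got {n}")
    spectra = []
    for i, seq in enumerate(np.random.SeedSequence(params.seed).spawn(n)):
        spectrum = simulate_spectrum(members, params, np.random.default_rng(seq))
        spectrum.metadata["replicate"] = i + 1
        spectra.append(spectrum)
    return spectra


def ground_truth_frame(members: Sequence[EnsembleMember]) -> pd.DataFrame:
    """True abundances per species and condition, for scoring recoveries."""
    return pd.DataFrame(
        [
            {
                "label": m.label,
                "condition": m.condition,
                "mass": m.mass,
                "true_abundance": m.abundance,
            }
            for m in members
        ]
    )


def simulate_ratio_replicates(
    classes: Sequence[tuple[str, tuple[int, int, int], float]],
    model: BindingModel,
    cv: float,
    n_replicates: int,
    seed: int,
) -> pd.DataFrame:
    """Replicate abundance tables under the binding model, at the abundance level.

    ``classes`` is (label, (core_fuc, antennary_fuc, extra_branch), weight).
    Each replicate applies independent mean-one log-normal noise with the
    given CV to the apo and complex abundances of every class — the same
    noise the spectrum simulator puts on peak heights, without the rendering
    and re-picking round trip. Returns rows (class, condition, replicate,
    abundance) ready for :func:`serpinms.quantify_stats.complex_apo_ratio`.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + cv**2)) if cv > 0 else 0.0
    rows = []
    for rep in range(1, n_replicates + 1):
        for label, features, weight in classes:
            frac = model.bound_fraction(*features)
            for condition, mean in (("apo", weight * (1 - frac)), ("complex", weight * frac)):
                noise = rng.lognormal(-0.5 * sigma**2, sigma) if sigma > 0 else 1.0
                rows.append(
                    {
                        "class": label,
                        "condition": condition,
                        "replicate": rep,
                        "abundance": mean * noise,
                    }
                )
    return pd.DataFrame(rows)
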