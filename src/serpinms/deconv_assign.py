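"""Peak picking, charge inference, and library matching for native spectra.

Charge inference uses mass coincidence across the envelope: a peak's charge
is the one whose implied neutral mass agrees with the implied mass of other
peaks of the same species at neighbouring charges (the classical
adjacent-charge relation z = round((m2 - mp)/(m1 - m2)) generalized to the
whole envelope). Peaks with no or ambiguous support are flagged rather than
guessed.

Assignment is tolerance-based against a proteoform/complex mass library and
keeps ambiguity explicit: every candidate within tolerance is reported, and
peaks whose candidate sets contain more than one entry carry an ambiguity
group id — near-isobaric pairs such as +2 Fuc vs +1 Neu5Ac (1.03 Da) or the
M2 vs M1A backbones (5.02 Da) are never silently collapsed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .spectrum_sim import PROTON_MASS, Spectrum

__all__ = [
    "PeakList",
    "Candidate",
    "Assignment",
    "pick_peaks",
    "estimate_noise",
    "infer_charge",
    "neutral_mass",
    "assign",
    "assignments_frame",
    "read_peaklist_csv",
    "load_mzml_spectrum",
]


@dataclass
class PeakList:
    """Centroided peaks: strictly increasing m/z, non-negative intensities."""

    mz: np.ndarray
    intensity: np.ndarray
    area: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return self.mz.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"mz": self.mz, "intensity": self.intensity})
        if self.area is not None:
            df["area"] = self.area
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_peaklist_csv(path, mz_column: str = "mz", intensity_column: str = "intensity") -> PeakList:
    """Read a centroided peak list from CSV/TSV (auto-detected separator)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if mz_column not in df or intensity_column not in df:
        raise ValueError(f"peak list must have columns {mz_column!r} and {intensity_column!r}")
    df = df.sort_values(mz_column)
    return PeakList(df[mz_column].to_numpy(), df[intensity_column].to_numpy())


def load_mzml_spectrum(path, index: int = 0) -> Spectrum:
    """Read one profile spectrum from an mzML file (via pyteomics)."""
    from pyteomics import mzml

    with mzml.MzML(str(path)) as reader:
        for i, entry in enumerate(reader):
            if i == index:
                return Spectrum(
                    np.asarray(entry["m/z array"], dtype=float),
                    np.asarray(entry["intensity array"], dtype=float),
                    {"source": str(path), "index": index},
                )
    raise IndexError(f"spectrum index {index} not found in {path}")


def estimate_noise(intensity: np.ndarray) -> tuple[float, float]:
    """(baseline, noise) from the lowest-intensity quartile: median and scaled MAD."""
    intensity = np.asarray(intensity, dtype=float)
    if intensity.size == 0:
        return 0.0, 0.0
    quartile = np.sort(intensity)[: max(1, intensity.size // 4)]
    baseline = float(np.median(quartile))
    noise = float(1.4826 * np.median(np.abs(quartile - baseline)))
    return baseline, noise


def pick_peaks(
    spectrum: Spectrum,
    min_snr: float = 3.0,
    min_spacing: float | None = None,
) -> PeakList:
    """Centroid local maxima above baseline + min_snr x noise.

    Each apex is centroided by log-parabolic interpolation over the three
    points around the maximum (exact for a Gaussian peak), falling back to
    the intensity-weighted mean over the FWHM window; ``area`` integrates
    that window. ``min_spacing`` keeps only the most intense apex within
    that m/z radius.
    """
    x, y = spectrum.mz, spectrum.intensity
    if x.size < 3:
        return PeakList(np.empty(0), np.empty(0), np.empty(0))
    baseline, noise = estimate_noise(y)
    threshold = baseline + min_snr * noise + 1e-9 * float(y.max(initial=0.0))

    apex = np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:]) & (y[1:-1] > threshold)) + 1
    if min_spacing is not None and apex.size:
        kept: list[int] = []
        for i in sorted(apex, key=lambda i: -y[i]):
            if all(abs(x[i] - x[j]) >= min_spacing for j in kept):
                kept.append(i)
        apex = np.array(sorted(kept), dtype=int)

    mzs, heights, areas = [], [], []
    for i in apex:
        half = baseline + (y[i] - baseline) / 2.0
        lo = i
        while lo > 0 and y[lo - 1] >= half and y[lo - 1] <= y[lo]:
            lo -= 1
        hi = i
        while hi < y.size - 1 and y[hi + 1] >= half and y[hi + 1] <= y[hi]:
            hi += 1
        window = slice(lo, hi + 1)
        weights = np.clip(y[window] - baseline, 0.0, None)
        if weights.sum() <= 0:
            continue
        centroid = float(np.average(x[window], weights=weights))
        if 0 < i < y.size - 1:
            triple = y[i - 1: i + 2] - baseline
            if np.all(triple > 0):
                la, lb, lc = np.log(triple)
                denom = la - 2 * lb + lc
                if denom < 0:  # concave in log space, as a Gaussian apex is
                    delta = 0.5 * (la - lc) / denom
                    if abs(delta) <= 1.0:
                        centroid = float(x[i] + delta * (x[i + 1] - x[i]))
        mzs.append(centroid)
        heights.append(float(y[i] - baseline))
        areas.append(float(np.trapezoid(weights, x[window])))

    order = np.argsort(mzs)
    return PeakList(
        np.asarray(mzs)[order], np.asarray(heights)[order], np.asarray(areas)[order]
    )


def neutral_mass(mz: float, z: int) -> float:
    """Neutral mass from an observed m/z at charge z."""
    if z <= 0:
        raise ValueError(f"charge must be positive, got {z}")
    return z * (mz - PROTON_MASS)


def infer_charge(
    peaklist: PeakList,
    z_range: tuple[int, int] = (8, 22),
    mass_tol: float = 2.0,
    fixed_z: int | None = None,
) -> np.ndarray:
    """Charge per peak by envelope mass coincidence; 0 marks a flagged peak.

    For each peak and candidate z, the implied neutral mass is compared with
    the implied masses of all other peaks over their candidate charges; the
    z with the most coincidences (within ``mass_tol`` Da) wins. No support,
    or a tie between charges, flags the peak (z = 0). ``fixed_z`` bypasses
    inference (single-peak spectra with user-known charge).
    """
    n = len(peaklist)
    if fixed_z is not None:
        if fixed_z <= 0:
            raise ValueError("fixed_z must be positive")
        return np.full(n, fixed_z, dtype=int)
    lo, hi = z_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid charge range {z_range}")
    zs = np.arange(lo, hi + 1)
    masses = zs[None, :] * (peaklist.mz[:, None] - PROTON_MASS)

    out = np.zeros(n, dtype=int)
    for i in range(n):
        support = np.zeros(zs.size, dtype=int)
        for k in range(zs.size):
            m = masses[i, k]
            for j in range(n):
                if j == i:
                    continue
                if np.min(np.abs(masses[j] - m)) < mass_tol:
                    support[k] += 1
        best = int(support.max())
        if best == 0:
            continue  # flagged
        winners = np.flatnonzero(support == best)
        if winners.size > 1:
            continue  # ambiguous spacing, flagged
        out[i] = int(zs[winners[0]])
    return out


@dataclass(frozen=True)
class Candidate:
    """One library entry explaining a peak, with its mass error."""

    entry: object  # ProteoformSpec or ComplexSpec
    error_da: float
    error_ppm: float

    @property
    def label(self) -> str:
        return self.entry.label


@dataclass
class Assignment:
    """A peak with inferred charge, neutral mass, and matching library entries."""

    mz: float
    intensity: float
    z: int
    neutral_mass: float
    candidates: tuple[Candidate, ...]
    ambiguity_group: int | None = None
    replicate: int | None = None

    @property
    def matched(self) -> bool:
        return len(self.candidates) > 0

    @property
    def unique(self) -> bool:
        return len(self.candidates) == 1

    @property
    def best(self) -> Candidate | None:
        return self.candidates[0] if self.candidates else None


def assign(
    peaklist: PeakList,
    charges: np.ndarray | Sequence[int],
    library: Sequence[object],
    tolerance: float = 1.0,
    unit: str = "Da",
    replicate: int | None = None,
) -> list[Assignment]:
    """Match every charged peak against the library within tolerance.

    All candidates within tolerance are reported, ordered by |error| (ties
    by label, so library order never matters). Peaks with multiple
    candidates receive an ambiguity group id shared by all peaks with the
    same candidate set; unmatched and charge-flagged peaks are reported with
    an empty candidate list.
    """
    if tolerance <= 0:
        raise ValueError(f"tolerance must be positive, got {tolerance}")
    if unit not in ("Da", "ppm"):
        raise ValueError(f"unit must be 'Da' or 'ppm', got {unit!r}")
    if len(library) == 0:
        raise ValueError("library must be non-empty")
    charges = np.asarray(charges, dtype=int)
    if charges.shape != (len(peaklist),):
        raise ValueError("one charge per peak required")

    group_ids: dict[frozenset, int] = {}
    assignments: list[Assignment] = []
    for mz, intensity, z in zip(peaklist.mz, peaklist.intensity, charges):
        if z <= 0:
            assignments.append(Assignment(float(mz), float(intensity), 0, float("nan"), ()))
            continue
        mass = neutral_mass(float(mz), int(z))
        tol_da = tolerance if unit == "Da" else tolerance * 1e-6 * mass
        found = []
        for entry in library:
            err = entry.mass - mass
            if abs(err) <= tol_da:
                found.append(Candidate(entry, err, err / mass * 1e6))
        found.sort(key=lambda c: (abs(c.error_da), c.label))
        group = None
        if len(found) > 1:
            key = frozenset(c.label for c in found)
            group = group_ids.setdefault(key, len(group_ids) + 1)
        assignments.append(
            Assignment(float(mz), float(intensity), int(z), mass, tuple(found), group, replicate)
        )
    return assignments


def assignments_frame(assignments: Sequence[Assignment]) -> pd.DataFrame:
    """Flat table of assignments (one row per peak) for CSV export."""
    rows = []
    for a in assignments:
        rows.append(
            {
                "mz": a.mz,
                "intensity": a.intensity,
                "z": a.z,
                "neutral_mass": a.neutral_mass,
                "n_candidates": len(a.candidates),
                "best_match": a.best.label if a.best else "",
                "error_da": a.best.error_da if a.best else float("nan"),
                "error_ppm": a.best.error_ppm if a.best else float("nan"),
                "all_candidates": ";".join(c.label for c in a.candidates),
                "ambiguity_group": a.ambiguity_group if a.ambiguity_group else "",
                "replicate": a.replicate if a.replicate is not None else "",
            }
        )
    return pd.DataFrame(rows)
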