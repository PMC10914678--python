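"""Relative abundances, complex:apo ratios, replicate statistics and trends.

The quantitative readout of the experiment is the complex:apo abundance
ratio of a proteoform class — computed per replicate, then summarized as
mean +/- SD across replicates (the bar-graph convention). Feature trends
(e.g. ratio vs number of antennary fucoses) are tested with a Spearman rank
correlation of mean ratio against feature count, and the per-step fold
change is the slope of log(mean ratio) on count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .deconv_assign import Assignment
from .proteoform_library import ComplexSpec

__all__ = [
    "abundance_table",
    "RatioResult",
    "complex_apo_ratio",
    "TTestResult",
    "compare_ratio_groups",
    "GlycopeptideRecord",
    "site_fucosylation_summary",
    "TrendResult",
    "feature_trend",
]


def _default_classifier(entry) -> tuple[str, str]:
    """(class label, condition) for a library entry; complexes map to their serpin."""
    if isinstance(entry, ComplexSpec):
        return entry.serpin.label, "complex"
    return entry.label, "apo"


def abundance_table(
    assignments: Sequence[Assignment],
    normalization: str = "per_condition",
    ambiguity: str = "drop",
    replicate: int = 1,
    classifier: Callable[[object], tuple[str, str]] = _default_classifier,
) -> pd.DataFrame:
    """Relative-abundance table from assignments.

    Intensities are summed over charge states per (class, condition);
    ambiguous peaks are dropped (default) or split equally among their
    candidates. Normalization is within condition (default) or global.
    Returns columns (class, condition, replicate, abundance).
    """
    if normalization not in ("per_condition", "global"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if ambiguity not in ("drop", "split"):
        raise ValueError(f"unknown ambiguity policy {ambiguity!r}")

    totals: dict[tuple[str, str], float] = {}
    for a in assignments:
        if not a.matched:
            continue
        if not a.unique and ambiguity == "drop":
            continue
        share = a.intensity / len(a.candidates)
        for candidate in a.candidates if ambiguity == "split" else a.candidates[:1]:
            key = classifier(candidate.entry)
            totals[key] = totals.get(key, 0.0) + share
    if not totals:
        return pd.DataFrame(columns=["class", "condition", "replicate", "abundance"])

    df = pd.DataFrame(
        [
            {"class": cls, "condition": cond, "replicate": replicate, "abundance": value}
            for (cls, cond), value in sorted(totals.items())
        ]
    )
    if normalization == "per_condition":
        df["abundance"] = df.groupby("condition")["abundance"].transform(lambda s: s / s.sum())
    else:
        df["abundance"] = df["abundance"] / df["abundance"].sum()
    return df


@dataclass
class RatioResult:
    """complex:apo ratio of one class: per-replicate values, mean, SD (n-1)."""

    label: str
    ratios: np.ndarray
    mean: float
    sd: float
    n: int
    flagged_replicates: tuple[int, ...] = ()

    @property
    def flagged(self) -> bool:
        return len(self.flagged_replicates) > 0


def complex_apo_ratio(
    table: pd.DataFrame,
    stratify_by: Callable[[str], object] | None = None,
) -> list[RatioResult]:
    """Per-replicate complex/apo abundance ratios per class (or stratum).

    ``stratify_by`` maps a class label to a stratum key (e.g. the antennary
    fucose count); classes mapping to the same key are pooled by summing
    abundances within each condition/replicate before forming the ratio.
    Replicates with zero apo abundance are flagged and excluded from the
    mean/SD rather than silently propagated.
    """
    required = {"class", "condition", "replicate", "abundance"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    work = table.copy()
    work["stratum"] = work["class"].map(stratify_by) if stratify_by else work["class"]

    results: list[RatioResult] = []
    for stratum, group in work.groupby("stratum", sort=True):
        pivot = (
            group.pivot_table(
                index="replicate", columns="condition", values="abundance", aggfunc="sum"
            )
            .reindex(columns=["apo", "complex"])
            .fillna(0.0)
        )
        if (pivot["complex"] == 0).all() and (pivot["apo"] == 0).all():
            continue
        ratios, flagged = [], []
        for rep, row in pivot.iterrows():
            if row["apo"] <= 0:
                flagged.append(int(rep))
                ratios.append(float("nan"))
            else:
                ratios.append(float(row["complex"] / row["apo"]))
        values = np.asarray(ratios, dtype=float)
        valid = values[~np.isnan(values)]
        results.append(
            RatioResult(
                label=str(stratum),
                ratios=values,
                mean=float(valid.mean()) if valid.size else float("nan"),
                sd=float(valid.std(ddof=1)) if valid.size > 1 else float("nan"),
                n=int(valid.size),
                flagged_replicates=tuple(flagged),
            )
        )
    return results


@dataclass(frozen=True)
class TTestResult:
    mean_a: float
    mean_b: float
    t: float
    p: float
    variant: str


def compare_ratio_groups(
    group_a: Sequence[float],
    group_b: Sequence[float],
    variant: str = "pooled",
) -> TTestResult:
    """Two-sided two-sample t test between replicate ratio groups.

    The default is the classical equal-variance Student's test, which holds
    its nominal size at triplicate scale; ``variant="welch"`` gives the
    unequal-variance form (conservative at n=3, where the Welch-Satterthwaite
    degrees of freedom are poorly estimated). Degenerate zero-variance input
    is guarded: identical
    constant groups give (t=0, p=1); constant groups with different means
    give (t=+/-inf, p=0).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two replicates")
    if variant not in ("welch", "pooled"):
        raise ValueError(f"variant must be 'welch' or 'pooled', got {variant!r}")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if math.isclose(mean_a, mean_b, rel_tol=0.0, abs_tol=0.0):
            return TTestResult(mean_a, mean_b, 0.0, 1.0, variant)
        sign = 1.0 if mean_a > mean_b else -1.0
        return TTestResult(mean_a, mean_b, sign * float("inf"), 0.0, variant)
    res = _stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return TTestResult(mean_a, mean_b, float(res.statistic), float(res.pvalue), variant)


@dataclass(frozen=True)
class GlycopeptideRecord:
    """One glycopeptide identification: site, composition, fucose placement, intensity."""

    site: int
    composition: str
    placement: str  # "core", "antennary", or "none"
    intensity: float


_PLACEMENTS = ("core", "antennary", "none")


def site_fucosylation_summary(
    records: Sequence[GlycopeptideRecord] | pd.DataFrame,
    known_sites: Sequence[int] | None = None,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-site % core / % antennary / % non-fucosylated from a glycopeptide table.

    Accepts GlycopeptideRecord sequences or any DataFrame mappable onto the
    minimal column contract (site, placement, intensity) via ``column_map``
    — so real glycopeptide search exports adapt with a thin rename. Site
    percentages are intensity shares and sum to 100 per site.
    """
    if isinstance(records, pd.DataFrame):
        df = records.rename(columns=dict(column_map or {}))
    else:
        df = pd.DataFrame(
            [{"site": r.site, "placement": r.placement, "intensity": r.intensity} for r in records]
        )
    needed = {"site", "placement", "intensity"}
    if df.empty or not needed.issubset(df.columns):
        raise ValueError(f"glycopeptide table must have columns {sorted(needed)} and >=1 record")
    bad = set(df["placement"]) - set(_PLACEMENTS)
    if bad:
        raise ValueError(f"unknown fucose placement classes: {sorted(bad)}")
    if (df["intensity"] < 0).any():
        raise ValueError("intensities must be non-negative")
    if known_sites is not None:
        unknown = set(df["site"]) - set(known_sites)
        if unknown:
            raise ValueError(f"unknown glycosites: {sorted(unknown)}")

    rows = []
    for site, group in df.groupby("site", sort=True):
        total = group["intensity"].sum()
        if total <= 0:
            raise ValueError(f"site {site} has zero total intensity")
        shares = group.groupby("placement")["intensity"].sum() / total * 100.0
        rows.append(
            {
                "site": site,
                "percent_core": float(shares.get("core", 0.0)),
                "percent_antennary": float(shares.get("antennary", 0.0)),
                "percent_nonfucosylated": float(shares.get("none", 0.0)),
                "total_intensity": float(total),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class TrendResult:
    """Monotone-trend summary of ratio vs integer feature count."""

    direction: str  # "increasing", "decreasing" or "flat"
    rank_correlation: float
    fold_per_step: float
    mean_ratios: dict[int, float]


def feature_trend(
    ratios_by_count: Mapping[int, RatioResult | float | Sequence[float]],
) -> TrendResult:
    """Trend of complex:apo ratio against an integer feature count.

    Needs >= 3 distinct counts. Direction follows the sign of the Spearman
    rank correlation of mean ratio vs count (flat when the means are
    constant); fold change per unit count is exp(slope) of the least-squares
    fit of log(mean ratio) on count — exact for geometric series.
    """
    if len(ratios_by_count) < 3:
        raise ValueError("feature_trend needs ratios at >= 3 distinct feature counts")
    counts = np.array(sorted(ratios_by_count), dtype=float)
    means = []
    for count in sorted(ratios_by_count):
        value = ratios_by_count[count]
        if isinstance(value, RatioResult):
            means.append(value.mean)
        elif np.isscalar(value):
            means.append(float(value))
        else:
            means.append(float(np.mean(np.asarray(value, dtype=float))))
    means = np.asarray(means)
    if np.any(~np.isfinite(means)) or np.any(means <= 0):
        raise ValueError("mean ratios must be finite and positive")

    mean_map = {int(c): float(m) for c, m in zip(counts, means)}
    if np.ptp(means) == 0.0:
        return TrendResult("flat", 0.0, 1.0, mean_map)
    rho = float(_stats.spearmanr(counts, means).statistic)
    slope = float(np.polyfit(counts, np.log(means), 1)[0])
    direction = "flat" if rho == 0.0 else ("increasing" if rho > 0 else "decreasing")
    return TrendResult(direction, rho, float(math.exp(slope)), mean_map)
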