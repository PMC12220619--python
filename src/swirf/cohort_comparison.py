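"""Pre- vs post-treatment comparison of cohort outlier fractions.

Per species, f is computed for four cohorts — PRE, POST d1, POST d2 and the
pooled POST (d1+d2) — with treatment cycles pooled inside each collection-day
class.  Consecutive-day differences in f are gated by the scanning
measurement tolerance tau: |later - earlier| <= tau means "no change", in
which case the relative difference (plain ratio later/earlier) is reported
as 0.  A rise in f beyond tau indicates younger recruits replacing killed
older mosquitoes; a fall indicates recruitment of older ones.

Each species is then placed into one of four trend groups by combining the
abundance triple (PRE, d1, d2 trap counts) with the f triple:

A   control knocks abundance down on d1 with younger recruits (f up), and
    older recruits restore abundance by d2 (f back down, counts recover);
B   as A on d1, but the older d2 recruitment does not restore abundance;
C   no f rise on d1; younger recruits appear on d2 (f up) without restoring
    abundance;
D   everything else.

The decision tree is a formalisation of narrative group descriptions; the
raw predicates are exported alongside the group label so the assignments
can be re-derived under other rules.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import math

import numpy as np
import pandas as pd

from .outlier_stats import (
    MIN_SCANS,
    PUBLISHED_TOLERANCE,
    CohortResult,
    Tolerance,
    cohort_outlier_fraction,
)
from .spectra_io import CollectionDay, ScanSpectrum

__all__ = [
    "Direction",
    "TrendGroup",
    "SpeciesFProfile",
    "DifferenceRecord",
    "TrendClassification",
    "build_profiles",
    "difference_record",
    "actual_difference",
    "relative_difference",
    "count_increased",
    "classify_trend_group",
    "classify_all",
    "difference_table",
    "profile_table",
]


class Direction(str, enum.Enum):
    YOUNGER = "younger"      # f rose beyond tolerance
    OLDER = "older"          # f fell beyond tolerance
    NO_CHANGE = "no_change"  # |delta f| within tolerance


class TrendGroup(str, enum.Enum):
    A = "A"
    B = "B"
    C = "C"
    D = "D"


def _tol_value(tolerance: Tolerance | float) -> float:
    return tolerance.value if isinstance(tolerance, Tolerance) else float(tolerance)


@dataclass
class SpeciesFProfile:
    """f values of one species across the four collection-day cohorts."""

    species: str
    f_pre: float | None
    f_d1: float | None
    f_d2: float | None
    f_post_combined: float | None
    n_scans: dict = field(default_factory=dict)
    results: dict = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        return None not in (self.f_pre, self.f_d1, self.f_d2, self.f_post_combined)


@dataclass
class DifferenceRecord:
    """Tolerance-gated actual and relative difference between two f values."""

    actual: float
    relative: float
    gated: bool
    direction: Direction
    undefined: bool = False  # earlier f was 0 and the pair not gated


@dataclass
class TrendClassification:
    species: str
    group: TrendGroup
    abundance: tuple[float, float, float]
    f: tuple[float, float, float]
    predicates: dict = field(default_factory=dict)


def build_profiles(
    scans: Iterable[ScanSpectrum],
    k: float = 1.5,
    method: str = "linear",
    ddof: int = 1,
    min_scans: int = MIN_SCANS,
) -> list[SpeciesFProfile]:
    """Per-species f for PRE / POST d1 / POST d2 / POST (d1+d2) cohorts.

    Treatment cycles are pooled within a collection-day class, and the
    combined post cohort pools the d1 and d2 scans before fencing — the
    fences are recomputed on each pool, so combined f is deliberately not
    any average of the per-day values.  A species missing a day class gets
    ``None`` for that f with a warning; the combined cohort then uses
    whatever post-treatment scans exist.
    """
    by_species: dict[str, list[ScanSpectrum]] = {}
    for s in scans:
        by_species.setdefault(s.species, []).append(s)

    profiles = []
    for species in sorted(by_species):
        group = by_species[species]
        day_sets = {
            "pre": [s for s in group if s.collection_day is CollectionDay.PRE],
            "d1": [s for s in group if s.collection_day is CollectionDay.POST_D1],
            "d2": [s for s in group if s.collection_day is CollectionDay.POST_D2],
        }
        day_sets["post_combined"] = day_sets["d1"] + day_sets["d2"]
        fs: dict[str, float | None] = {}
        n_scans: dict[str, int] = {}
        results: dict[str, CohortResult] = {}
        for name, subset in day_sets.items():
            n_scans[name] = len(subset)
            if len(subset) < min_scans:
                warnings.warn(
                    f"{species}: {name} cohort has {len(subset)} scans "
                    f"(< {min_scans}); f not computed",
                    stacklevel=2,
                )
                fs[name] = None
                continue
            res = cohort_outlier_fraction(
                subset,
                k=k,
                method=method,
                ddof=ddof,
                min_scans=min_scans,
                labels={"species": species, "day_class": name},
            )
            results[name] = res
            fs[name] = res.f
        profiles.append(
            SpeciesFProfile(
                species=species,
                f_pre=fs["pre"],
                f_d1=fs["d1"],
                f_d2=fs["d2"],
                f_post_combined=fs["post_combined"],
                n_scans=n_scans,
                results=results,
            )
        )
    return profiles


def difference_record(
    f_later: float, f_earlier: float, tolerance: Tolerance | float = PUBLISHED_TOLERANCE
) -> DifferenceRecord:
    """Actual and relative difference between two cohort f values, gated by tau.

    actual = later - earlier; the pair is gated when |actual| <= tau, in
    which case the direction is ``no_change`` and the relative difference is
    reported as 0.  Otherwise relative = later / earlier (undefined when the
    earlier f is 0).
    """
    tau = _tol_value(tolerance)
    actual = f_later - f_earlier
    gated = abs(actual) <= tau
    undefined = False
    if gated:
        relative = 0.0
        direction = Direction.NO_CHANGE
    else:
        direction = Direction.YOUNGER if actual > 0 else Direction.OLDER
        if f_earlier == 0:
            relative = math.nan
            undefined = True
        else:
            relative = f_later / f_earlier
    return DifferenceRecord(
        actual=actual,
        relative=relative,
        gated=gated,
        direction=direction,
        undefined=undefined,
    )


def actual_difference(
    f_later: float, f_earlier: float, tolerance: Tolerance | float = PUBLISHED_TOLERANCE
) -> DifferenceRecord:
    return difference_record(f_later, f_earlier, tolerance)


def relative_difference(
    f_later: float, f_earlier: float, tolerance: Tolerance | float = PUBLISHED_TOLERANCE
) -> float:
    return difference_record(f_later, f_earlier, tolerance).relative


def count_increased(
    profiles: Sequence[SpeciesFProfile] | pd.DataFrame,
) -> int:
    """Number of species whose pooled post-treatment f exceeds the PRE f."""
    if isinstance(profiles, pd.DataFrame):
        return int((profiles["f_post_combined"] > profiles["f_pre"]).sum())
    n = 0
    for p in profiles:
        if p.f_pre is None or p.f_post_combined is None:
            raise ValueError(f"{p.species}: profile incomplete, cannot compare")
        if p.f_post_combined > p.f_pre:
            n += 1
    return n


def classify_trend_group(
    abundance: tuple[float, float, float],
    f: tuple[float, float, float],
    tolerance: Tolerance | float = PUBLISHED_TOLERANCE,
    species: str = "",
) -> TrendClassification:
    """Assign a species to trend group A-D from its abundance and f triples.

    The predicates (tau-gated f movements and raw trap-count comparisons,
    "offsets abundance reduction" meaning d2 abundance back at or above the
    PRE count) are returned so users can audit or re-derive the call.
    """
    a_pre, a_d1, a_d2 = abundance
    f_pre, f_d1, f_d2 = f
    tau = _tol_value(tolerance)

    pred = {
        "abundance_down_d1": a_d1 < a_pre,
        "abundance_recovered_d2": a_d2 >= a_pre,
        "f_up_d1": (f_d1 - f_pre) > tau,
        "f_down_d2": (f_d2 - f_d1) < -tau,
        "f_up_d2": (f_d2 - f_d1) > tau,
    }
    if pred["abundance_down_d1"] and pred["f_up_d1"] and pred["f_down_d2"]:
        group = TrendGroup.A if pred["abundance_recovered_d2"] else TrendGroup.B
    elif not pred["f_up_d1"] and pred["f_up_d2"] and not pred["abundance_recovered_d2"]:
        group = TrendGroup.C
    else:
        group = TrendGroup.D
    return TrendClassification(
        species=species,
        group=group,
        abundance=(a_pre, a_d1, a_d2),
        f=(f_pre, f_d1, f_d2),
        predicates=pred,
    )


def classify_all(
    metadata: pd.DataFrame,
    f_table: pd.DataFrame,
    tolerance: Tolerance | float = PUBLISHED_TOLERANCE,
) -> pd.DataFrame:
    """Trend-group calls for every species in aligned metadata and f tables."""
    rows = []
    for species in f_table.index:
        m = metadata.loc[species]
        cls = classify_trend_group(
            (m["abundance_pre"], m["abundance_post_d1"], m["abundance_post_d2"]),
            (
                f_table.loc[species, "f_pre"],
                f_table.loc[species, "f_post_d1"],
                f_table.loc[species, "f_post_d2"],
            ),
            tolerance,
            species=species,
        )
        row = {"species": species, "group": cls.group.value}
        row.update(cls.predicates)
        rows.append(row)
    return pd.DataFrame(rows).set_index("species")


def difference_table(
    f_table: pd.DataFrame, tolerance: Tolerance | float = PUBLISHED_TOLERANCE
) -> pd.DataFrame:
    """Consecutive-day actual and relative differences in f, per species.

    Columns mirror the study's reporting: actual differences to 4 decimals,
    relative differences to 1 decimal, gated cells flagged and their ratios
    set to 0.
    """
    rows = []
    for species in f_table.index:
        f_pre = f_table.loc[species, "f_pre"]
        f_d1 = f_table.loc[species, "f_post_d1"]
        f_d2 = f_table.loc[species, "f_post_d2"]
        r1 = difference_record(f_d1, f_pre, tolerance)
        r2 = difference_record(f_d2, f_d1, tolerance)
        rows.append(
            {
                "species": species,
                "actual_d1_pre": round(r1.actual, 4),
                "actual_d2_d1": round(r2.actual, 4),
                "gated_d1_pre": r1.gated,
                "gated_d2_d1": r2.gated,
                "relative_d1_pre": round(r1.relative, 1),
                "relative_d2_d1": round(r2.relative, 1),
                "direction_d1_pre": r1.direction.value,
                "direction_d2_d1": r2.direction.value,
            }
        )
    return pd.DataFrame(rows).set_index("species")


def profile_table(profiles: Sequence[SpeciesFProfile]) -> pd.DataFrame:
    """Profiles as a species x day-class f table (plus scan counts)."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "species": p.species,
                "f_pre": p.f_pre,
                "f_post_d1": p.f_d1,
                "f_post_d2": p.f_d2,
                "f_post_combined": p.f_post_combined,
                "n_pre": p.n_scans.get("pre", 0),
                "n_post_d1": p.n_scans.get("d1", 0),
                "n_post_d2": p.n_scans.get("d2", 0),
            }
        )
    return pd.DataFrame(rows).set_index("species")
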