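"""Deterministic clinical grading rules for the lumbar spine.

Two rules are implemented:

* **Facet-joint asymmetry (tropism).**  A segment's paired facet joints are
  called asymmetric when the left-right orientation-angle difference is
  *strictly greater than* 7 degrees.  Exactly 7 degrees is symmetric.

* **Disc-height degeneration.**  A disc's measured height is compared
  against the level-specific normal range (L3/4: 1.073-1.247 cm, L4/5:
  1.18-1.272 cm, L5/S1: 0.939-1.121 cm).  With ``ratio = height /
  reference``: ratio > 80 % is a *slight decrease*; 60 % < ratio <= 80 % a
  *moderate decrease*; ratio <= 60 % *gap collapse*.  The published ranges
  give no scalar "normal height", so the reference defaults to the range
  midpoint (lower/upper selectable for sensitivity analysis).  Boundary
  values (exactly 80 % or 60 %) fall into the more severe class, reading
  "higher than" strictly; the three intervals then partition (0, inf).

Facet degeneration grades 0-3 and disc degeneration grades I-V are ordinal
*inputs* (scored from images by other instruments); this module does not
compute them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import LEVELS

#: published normal disc-height ranges in cm per lumbar level
NORMAL_HEIGHT_RANGES: dict[str, tuple[float, float]] = {
    "L3/4": (1.073, 1.247),
    "L4/5": (1.18, 1.272),
    "L5/S1": (0.939, 1.121),
}

HEIGHT_CATEGORIES = ("slight_decrease", "moderate_decrease", "gap_collapse")


@dataclass(frozen=True)
class AsymmetryRule:
    """Strictly-greater threshold on the left-right facet angle difference."""

    threshold_degrees: float = 7.0

    def __post_init__(self) -> None:
        if self.threshold_degrees <= 0:
            raise ValueError("threshold must be > 0")


@dataclass(frozen=True)
class NormalHeightTable:
    """Level-specific normal height intervals and the scalar convention."""

    ranges: tuple = tuple(sorted(NORMAL_HEIGHT_RANGES.items()))
    reference_convention: str = "midpoint"  # midpoint | lower | upper

    def __post_init__(self) -> None:
        if self.reference_convention not in ("midpoint", "lower", "upper"):
            raise ValueError(f"unknown convention {self.reference_convention!r}")
        for level, (lo, hi) in self.ranges:
            if not 0 < lo < hi:
                raise ValueError(f"invalid range for {level}: [{lo}, {hi}]")

    def reference(self, level: str) -> float:
        """Scalar normal height (cm) for *level* under the convention."""
        table = dict(self.ranges)
        if level not in table:
            raise KeyError(f"unknown lumbar level {level!r}; expected one of {LEVELS}")
        lo, hi = table[level]
        if self.reference_convention == "lower":
            return lo
        if self.reference_convention == "upper":
            return hi
        return 0.5 * (lo + hi)


@dataclass(frozen=True)
class HeightGrade:
    """Category plus the height/reference ratio that produced it."""

    category: str
    ratio: float


def classify_asymmetry(
    left_angle: float, right_angle: float, rule: AsymmetryRule = AsymmetryRule()
) -> bool:
    """True iff ``|left - right|`` strictly exceeds the threshold.

    Symmetric in its two arguments.  Angles must be anatomically plausible
    (strictly between 0 and 90 degrees).
    """
    for name, a in (("left", left_angle), ("right", right_angle)):
        if not 0.0 < a < 90.0:
            raise ValueError(f"{name} angle {a} outside the anatomical range (0, 90)")
    return abs(left_angle - right_angle) > rule.threshold_degrees


def grade_disc_height(
    height_cm: float, level: str, table: NormalHeightTable = NormalHeightTable()
) -> HeightGrade:
    """Classify a disc height against the level's normal reference."""
    if height_cm <= 0:
        raise ValueError(f"disc height must be > 0, got {height_cm}")
    ref = table.reference(level)
    ratio = height_cm / ref
    if ratio > 0.8:
        category = "slight_decrease"
    elif ratio > 0.6:
        category = "moderate_decrease"
    else:
        category = "gap_collapse"
    return HeightGrade(category=category, ratio=ratio)


def grade_cohort(
    records: pd.DataFrame,
    asymmetry_rule: AsymmetryRule = AsymmetryRule(),
    height_table: NormalHeightTable = NormalHeightTable(),
) -> pd.DataFrame:
    """Annotate a cohort table with asymmetry flags and height grades.

    Adds ``asymmetric`` (0/1), ``height_grade`` and ``height_ratio``
    columns.  Per-record validation failures are re-raised with the
    offending patient/level named.
    """
    if records.empty:
        raise ValueError("empty cohort")
    out = records.copy()
    asym = np.zeros(len(out), dtype=int)
    cats: list[str] = []
    ratios = np.zeros(len(out))
    for i, row in enumerate(out.itertuples(index=False)):
        try:
            asym[i] = int(
                classify_asymmetry(row.facet_angle_left, row.facet_angle_right, asymmetry_rule)
            )
            hg = grade_disc_height(row.disc_height, row.level, height_table)
        except (ValueError, KeyError) as exc:
            raise ValueError(
                f"record patient={row.patient_id} level={row.level}: {exc}"
            ) from exc
        cats.append(hg.category)
        ratios[i] = hg.ratio
    out["asymmetric"] = asym
    out["height_grade"] = cats
    out["height_ratio"] = np.round(ratios, 6)
    return out


def asymmetry_counts_by_level(graded: pd.DataFrame) -> pd.DataFrame:
    """Count asymmetric records per level x herniation category."""
    sub = graded[graded["asymmetric"] == 1]
    tab = pd.crosstab(sub["level"], sub["ldh_category"])
    return tab.reindex(index=list(LEVELS), fill_value=0)
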