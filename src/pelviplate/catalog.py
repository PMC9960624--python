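"""Plate-catalog design and population coverage verification.

A catalog of anterior quadrilateral-plate models is derived from
population statistics in two steps:

1. **Totals.** The cohort mean total trajectory length is rounded to
   integer mm to give the medium plate total; small and large totals
   sit 20 mm below and above, so three tiers with a ±10 mm acceptance
   band tile the population range without gaps.

2. **Region proportions.** With the pubic region normalized to 1, the
   quadrilateral ratio r1 = LQR/LPR is fixed at chosen values (1.1 and
   1.3 by default) and the iliac ratio r2 = LIR/LPR follows from the
   population regression of LIR/LPR on LQR/LPR, rounded to one
   decimal.  Each tier therefore carries two subtypes, six models in
   all (A1/A2 small, B1/B2 medium, C1/C2 large).

Region lengths of a plate are integer mm: with base = total /
(1 + r1 + r2), the quadrilateral and iliac regions are base*r1 and
base*r2 rounded half-up, and the pubic region takes the remainder so
the three regions always sum to the total exactly.

Coverage verification matches every population record against every
plate: a record fits a plate when all three region lengths fall inside
the plate's closed ±tolerance acceptance intervals (design mode), or
when the plate is no longer than the anatomy in every region and
within a slack below it (clinical mode).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import TrajectoryMeasurement

__all__ = [
    "round_half_up",
    "RatioFamily",
    "PlateSpec",
    "PlateCatalog",
    "AcceptanceInterval",
    "CoverageReport",
    "design_totals",
    "derive_ratio_family",
    "build_plate",
    "design_catalog",
    "acceptance_intervals",
    "plate_matches",
    "catalog_coverage",
]

DEFAULT_TOLERANCE_MM = 10.0
REGIONS = ("lpr", "lqr", "lir")

_SIZE_BY_LETTER = {"A": "small", "B": "medium", "C": "large"}


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero toward +inf).

    Distinct from Python's builtin banker's rounding; used everywhere a
    printed value is produced (integer mm, one-decimal ratios,
    two-decimal percentages).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RatioFamily:
    """Region proportions (1 : r1 : r2) = (pubic : quadrilateral : iliac)."""

    r1: float
    r2: float

    def __post_init__(self) -> None:
        if not (self.r1 > 1 and self.r2 > 1):
            raise ValueError(f"ratios must exceed 1, got r1={self.r1}, r2={self.r2}")

    @property
    def label(self) -> str:
        return f"1/{self.r1:g}/{self.r2:g}"


@dataclass(frozen=True)
class PlateSpec:
    """One plate model: total and integer region lengths in mm."""

    model: str
    size_class: str
    side: str
    total_mm: float
    lpr_mm: float
    lqr_mm: float
    lir_mm: float
    family: RatioFamily

    def __post_init__(self) -> None:
        if min(self.lpr_mm, self.lqr_mm, self.lir_mm) <= 0:
            raise ValueError(f"plate {self.model}: every region must be positive")
        if abs(self.lpr_mm + self.lqr_mm + self.lir_mm - self.total_mm) > 1e-9:
            raise ValueError(f"plate {self.model}: regions do not sum to total")

    def region_lengths(self) -> tuple[float, float, float]:
        return (self.lpr_mm, self.lqr_mm, self.lir_mm)


@dataclass(frozen=True)
class PlateCatalog:
    plates: tuple[PlateSpec, ...]

    def __post_init__(self) -> None:
        if not self.plates:
            raise ValueError("catalog is empty")
        models = [p.model for p in self.plates]
        if len(set(models)) != len(models):
            raise ValueError("duplicate plate model ids")

    def __iter__(self):
        return iter(self.plates)

    def __len__(self) -> int:
        return len(self.plates)

    def by_model(self, model: str) -> PlateSpec:
        for p in self.plates:
            if p.model == model:
                return p
        raise KeyError(model)

    @property
    def size_classes(self) -> list[str]:
        seen: list[str] = []
        for p in self.plates:
            if p.size_class not in seen:
                seen.append(p.size_class)
        return seen


@dataclass(frozen=True)
class AcceptanceInterval:
    """Closed interval [low, high] of acceptable anatomical lengths (mm)."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if self.high < self.low:
            raise ValueError("interval high < low")

    def contains(self, value: float) -> bool:
        return self.low <= value <= self.high


def design_totals(mean_total: float) -> tuple[float, float, float]:
    """(small, medium, large) plate totals from the cohort mean total.

    Medium is the mean rounded half-up to integer mm; small/large sit
    20 mm either side so the three ±10 mm bands tile contiguously.
    """
    if not mean_total > 0:
        raise ValueError(f"mean total must be positive, got {mean_total}")
    medium = round_half_up(mean_total)
    return (medium - 20.0, medium, medium + 20.0)


def derive_ratio_family(slope: float, intercept: float, x: float) -> RatioFamily:
    """Family (1, x, round1(slope*x + intercept)) from the design regression."""
    return RatioFamily(r1=x, r2=round_half_up(slope * x + intercept, 1))


def build_plate(
    total: float,
    family: RatioFamily,
    model: str = "",
    size_class: str = "",
    side: str = "left",
) -> PlateSpec:
    """Split a total into integer region lengths under the remainder rule.

    base = total / (1 + r1 + r2); quadrilateral and iliac regions are
    base*r1 and base*r2 rounded half-up to integer mm; the pubic region
    takes the remainder, so the sum invariant holds exactly.
    """
    if not total > 0:
        raise ValueError(f"total must be positive, got {total}")
    base = total / (1.0 + family.r1 + family.r2)
    lqr = round_half_up(base * family.r1)
    lir = round_half_up(base * family.r2)
    lpr = total - lqr - lir
    return PlateSpec(
        model=model or f"{total:g}/{family.label}",
        size_class=size_class,
        side=side,
        total_mm=float(total),
        lpr_mm=lpr,
        lqr_mm=lqr,
        lir_mm=lir,
        family=family,
    )


def design_catalog(
    mean_total: float,
    slope: float,
    intercept: float,
    x_values: Sequence[float] = (1.1, 1.3),
    side: str = "left",
) -> PlateCatalog:
    """Full six-model catalog from the cohort mean total and regression."""
    totals = design_totals(mean_total)
    families = [derive_ratio_family(slope, intercept, x) for x in x_values]
    plates = []
    for letter, total in zip("ABC", totals):
        for subtype, fam in enumerate(families, start=1):
            plates.append(
                build_plate(
                    total,
                    fam,
                    model=f"{letter}{subtype}",
                    size_class=_SIZE_BY_LETTER[letter],
                    side=side,
                )
            )
    return PlateCatalog(plates=tuple(plates))


def acceptance_intervals(
    plate: PlateSpec, tolerance: float = DEFAULT_TOLERANCE_MM
) -> dict[str, AcceptanceInterval]:
    """Per-region closed intervals [plate value - tol, plate value + tol]."""
    if tolerance < 0:
        raise ValueError(f"tolerance must be >= 0, got {tolerance}")
    return {
        region: AcceptanceInterval(value - tolerance, value + tolerance)
        for region, value in zip(REGIONS, plate.region_lengths())
    }


def _region_values(m) -> tuple[float, float, float]:
    if isinstance(m, TrajectoryMeasurement):
        return (m.lpr, m.lqr, m.lir)
    lpr, lqr, lir = m
    return (float(lpr), float(lqr), float(lir))


def plate_matches(
    m,
    plate: PlateSpec,
    mode: str = "design",
    tolerance: float = DEFAULT_TOLERANCE_MM,
    clinical_slack: float | None = None,
) -> bool:
    """Does a measured trajectory fit a plate?

    ``design`` mode: every region inside the closed ±tolerance
    interval.  ``clinical`` mode: the plate must be no longer than the
    anatomy in every region (a plate may undershoot, never overshoot)
    and not undershoot by more than ``clinical_slack`` (defaults to the
    tolerance).  ``m`` is a TrajectoryMeasurement or an (lpr, lqr,
    lir) triple in mm.
    """
    values = _region_values(m)
    if mode == "design":
        ivals = acceptance_intervals(plate, tolerance)
        return all(ivals[r].contains(v) for r, v in zip(REGIONS, values))
    if mode == "clinical":
        slack = tolerance if clinical_slack is None else clinical_slack
        if slack < 0:
            raise ValueError("clinical_slack must be >= 0")
        return all(
            p <= v <= p + slack for p, v in zip(plate.region_lengths(), values)
        )
    raise ValueError(f"unknown mode {mode!r} (expected 'design' or 'clinical')")


@dataclass(frozen=True)
class CoverageReport:
    """Match counts of a population against a plate catalog.

    ``model_counts``: records fitting each model; ``class_counts``:
    union over each size class's subtypes; ``class_intersections``:
    records fitting both subtypes of a class; ``cross_class_overlap``:
    records fitting plates in two different size classes (the tiers
    are not assumed disjoint); ``overall_count``: records fitting at
    least one plate.  Percentages use denominator ``n`` and half-up
    rounding to 2 decimals.
    """

    n: int
    mode: str
    tolerance: float
    model_counts: Mapping[str, int]
    class_counts: Mapping[str, int]
    class_intersections: Mapping[str, int]
    cross_class_overlap: Mapping[tuple[str, str], int]
    overall_count: int

    def percentage(self, count: int) -> float:
        return round_half_up(100.0 * count / self.n, 2)

    @property
    def overall_percentage(self) -> float:
        return self.percentage(self.overall_count)

    @property
    def class_percentages(self) -> dict[str, float]:
        return {k: self.percentage(v) for k, v in self.class_counts.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"scope": "model", "name": k, "count": v, "percent": self.percentage(v)}
            for k, v in self.model_counts.items()
        ]
        rows += [
            {"scope": "size_class", "name": k, "count": v, "percent": self.percentage(v)}
            for k, v in self.class_counts.items()
        ]
        rows += [
            {"scope": "class_intersection", "name": k, "count": v,
             "percent": self.percentage(v)}
            for k, v in self.class_intersections.items()
        ]
        rows += [
            {"scope": "cross_class_overlap", "name": f"{a}&{b}", "count": v,
             "percent": self.percentage(v)}
            for (a, b), v in self.cross_class_overlap.items()
        ]
        rows.append(
            {"scope": "overall", "name": "any_plate", "count": self.overall_count,
             "percent": self.overall_percentage}
        )
        return pd.DataFrame(rows)

    def to_markdown(self) -> str:
        lines = [
            f"# Coverage report (mode={self.mode}, tolerance=±{self.tolerance:g} mm, "
            f"n={self.n})",
            "",
            "| scope | name | count | percent |",
            "|---|---|---:|---:|",
        ]
        for row in self.to_frame().itertuples(index=False):
            lines.append(
                f"| {row.scope} | {row.name} | {row.count} | {row.percent:.2f} |"
            )
        return "\n".join(lines) + "\n"


def catalog_coverage(
    pop: pd.DataFrame,
    catalog: PlateCatalog,
    mode: str = "design",
    tolerance: float = DEFAULT_TOLERANCE_MM,
    clinical_slack: float | None = None,
) -> CoverageReport:
    """Match every record against every plate and tally coverage.

    ``pop`` must carry ``lpr_mm``/``lqr_mm``/``lir_mm`` columns.
    Counting is vectorized; it is equivalent to the per-record,
    per-plate double loop over :func:`plate_matches`.
    """
    if len(pop) == 0:
        raise ValueError("population table is empty")
    n = len(pop)
    vals = pop[["lpr_mm", "lqr_mm", "lir_mm"]].to_numpy(dtype=float)

    match = {}
    for plate in catalog:
        regions = np.asarray(plate.region_lengths())
        if mode == "design":
            ok = np.all(np.abs(vals - regions) <= tolerance, axis=1)
        elif mode == "clinical":
            slack = tolerance if clinical_slack is None else clinical_slack
            ok = np.all((vals >= regions) & (vals <= regions + slack), axis=1)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        match[plate.model] = ok

    classes: dict[str, list[str]] = {}
    for plate in catalog:
        classes.setdefault(plate.size_class or plate.model, []).append(plate.model)

    class_any = {
        cls: np.logical_or.reduce([match[m] for m in models])
        for cls, models in classes.items()
    }
    class_all = {
        cls: np.logical_and.reduce([match[m] for m in models])
        for cls, models in classes.items()
    }
    cross = {}
    keys = list(class_any)
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            cross[(a, b)] = int(np.sum(class_any[a] & class_any[b]))

    overall = np.logical_or.reduce(list(match.values()))
    return CoverageReport(
        n=n,
        mode=mode,
        tolerance=tolerance,
        model_counts={k: int(v.sum()) for k, v in match.items()},
        class_counts={k: int(v.sum()) for k, v in class_any.items()},
        class_intersections={k: int(v.sum()) for k, v in class_all.items()},
        cross_class_overlap=cross,
        overall_count=int(overall.sum()),
    )
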