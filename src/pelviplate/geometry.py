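"""Exact 3D constructions for arc-based plate-trajectory measurement.

The anterior plate trajectory along the pelvic brim is treated as three
connected circular arcs — pubic, quadrilateral (the medial acetabular
wall), and iliac.  Each region's length is obtained by fitting the
circumcircle through three landmarks (start, mid, end), reading off the
chord between start and end, and converting chord to arc with

    arc = diameter * arcsin(chord / diameter),

which is exact for central angles up to pi.  All coordinates are in mm
in an arbitrary right-handed frame; every output is a length and is
invariant under rigid motion and reflection.

Landmark naming follows the surgical convention for this trajectory:

==========  ==========================================================
``O``       apex of the pubic symphysis (trajectory start)
``C``       junction of pubic tubercle and pecten pubis (pubic mid)
``B``       pubic/quadrilateral boundary, 5 mm outward of ``B_PR``
``Q``       quadrilateral mid-point, 5 mm outward of ``Q_PR``
``Z``       quadrilateral/iliac boundary, 5 mm outward of ``Z_PR``
``E``       iliac mid-point, 10 mm lateral of ``E_AS``
``H``       highest point of the iliac crest (trajectory end)
``S, S1``   arcuate-line / sacroiliac intersections; with ``O`` they
            define the pelvic-ring circle whose center anchors the
            radial offsets
``B_PR``    projection of the posterior obturator-foramen margin on
            the pelvic ring
``Q_PR``    projection of the anterior superior iliac spine on the
            arcuate line
``Z_PR``    projection of the greater sciatic notch on the pelvic ring
``E_AS``    outermost point of the auricular surface
==========  ==========================================================
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "DERIVED_NAMES",
    "RAW_NAMES",
    "DEFAULT_OFFSETS_MM",
    "DegenerateGeometryError",
    "MissingLandmarkError",
    "ArcAmbiguityWarning",
    "Plane",
    "Circle3D",
    "LandmarkSet",
    "TrajectoryMeasurement",
    "as_point",
    "fit_plane",
    "circumcircle_3points",
    "project_to_plane",
    "radial_offset",
    "offset_along",
    "chord_to_arc",
    "measure_region",
    "derive_landmarks",
    "measure_trajectory",
]

#: landmarks required before a trajectory can be measured
DERIVED_NAMES: tuple[str, ...] = ("O", "C", "B", "Q", "Z", "E", "H")
#: raw anatomical landmarks from which the derived set is constructed
RAW_NAMES: tuple[str, ...] = ("O", "C", "H", "S", "S1", "B_PR", "Q_PR", "Z_PR", "E_AS")
#: outward offsets applied when deriving B, Q, Z, E (mm)
DEFAULT_OFFSETS_MM: Mapping[str, float] = {"B": 5.0, "Q": 5.0, "Z": 5.0, "E": 10.0}

# triangles with area below this (mm^2) are treated as collinear
_AREA_TOL = 1e-9
_UNIT_TOL = 1e-9
# arcsin arguments in (1, 1 + _CLAMP_TOL] are clamped to 1
_CLAMP_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Coincident or collinear points where a plane/circle is required."""


class MissingLandmarkError(KeyError):
    """A named landmark required by an operation is absent."""

    def __str__(self) -> str:  # KeyError quotes its message by default
        return self.args[0] if self.args else ""


class ArcAmbiguityWarning(UserWarning):
    """The true arc through the mid landmark exceeds a semicircle.

    The chord/arcsin conversion can only represent central angles up to
    pi; when the mid point sits on the major arc the returned value is
    the minor-arc length, which underestimates the true path.
    """


def as_point(p: Iterable[float]) -> np.ndarray:
    """Coerce to a finite float64 3-vector (mm)."""
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"point has non-finite components: {a}")
    return a


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n == 0.0:
        raise ValueError(f"zero {what} has no direction")
    return v / n


@dataclass(frozen=True)
class Plane:
    """A plane given by a point on it and a unit normal."""

    origin: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", as_point(self.origin))
        n = as_point(self.normal)
        if abs(np.linalg.norm(n) - 1.0) > _UNIT_TOL:
            raise ValueError("plane normal must be a unit vector")
        object.__setattr__(self, "normal", n)

    def signed_distance(self, p: Iterable[float]) -> float:
        return float(np.dot(as_point(p) - self.origin, self.normal))


@dataclass(frozen=True)
class Circle3D:
    """A circle embedded in 3D: center, radius (mm) and plane normal."""

    center: np.ndarray
    radius: float
    normal: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", as_point(self.center))
        if not (self.radius > 0 and math.isfinite(self.radius)):
            raise ValueError(f"radius must be positive, got {self.radius}")
        n = as_point(self.normal)
        if abs(np.linalg.norm(n) - 1.0) > _UNIT_TOL:
            raise ValueError("circle normal must be a unit vector")
        object.__setattr__(self, "normal", n)

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    @property
    def plane(self) -> Plane:
        return Plane(self.center, self.normal)


@dataclass
class LandmarkSet:
    """Named landmarks for one hemipelvis.

    ``derived`` holds the seven trajectory landmarks (O, C, B, Q, Z, E,
    H) once constructed; ``raw`` optionally holds the underlying
    anatomical points.  ``side`` is purely a label — all measured
    lengths are reflection-invariant.
    """

    derived: dict[str, np.ndarray] = field(default_factory=dict)
    raw: dict[str, np.ndarray] | None = None
    side: str = "left"

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        self.derived = {k: as_point(v) for k, v in self.derived.items()}
        if self.raw is not None:
            self.raw = {k: as_point(v) for k, v in self.raw.items()}

    def require_derived(self) -> None:
        missing = [n for n in DERIVED_NAMES if n not in self.derived]
        if missing:
            raise MissingLandmarkError(
                f"missing derived landmark(s): {', '.join(missing)}"
            )

    def require_raw(self) -> None:
        if self.raw is None:
            raise MissingLandmarkError("landmark set has no raw points")
        missing = [n for n in RAW_NAMES if n not in self.raw]
        if missing:
            raise MissingLandmarkError(f"missing raw landmark(s): {', '.join(missing)}")


@dataclass(frozen=True)
class TrajectoryMeasurement:
    """Region arc lengths (mm); ``total`` is their exact sum."""

    lpr: float
    lqr: float
    lir: float
    total: float

    @classmethod
    def from_regions(cls, lpr: float, lqr: float, lir: float) -> "TrajectoryMeasurement":
        if min(lpr, lqr, lir) <= 0:
            raise ValueError("every region length must be positive")
        return cls(lpr=lpr, lqr=lqr, lir=lir, total=lpr + lqr + lir)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.lpr, self.lqr, self.lir, self.total)


def _triangle_or_raise(p1, p2, p3) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    a, b, c = as_point(p1), as_point(p2), as_point(p3)
    n = np.cross(b - a, c - a)
    area = 0.5 * float(np.linalg.norm(n))
    if area < _AREA_TOL:
        raise DegenerateGeometryError(
            f"points are collinear or coincident (triangle area {area:.3g} mm^2): "
            f"{a.tolist()}, {b.tolist()}, {c.tolist()}"
        )
    return a, b, c, n


def fit_plane(p1, p2, p3) -> Plane:
    """Plane through three non-collinear points.

    The normal follows the right-hand rule over (p2 - p1, p3 - p1), so
    its orientation is deterministic in the argument order.
    """
    a, _, _, n = _triangle_or_raise(p1, p2, p3)
    return Plane(a, _unit(n, "normal"))


def circumcircle_3points(p1, p2, p3) -> Circle3D:
    """Circle through three non-collinear points in 3D.

    Classical closed form: with u = p2 - p1, v = p3 - p1 and
    n = u x v, the center is

        p1 + (|u|^2 (v x n) + |v|^2 (n x u)) / (2 |n|^2).
    """
    a, b, c, n = _triangle_or_raise(p1, p2, p3)
    u = b - a
    v = c - a
    n2 = float(np.dot(n, n))
    offset = (np.dot(u, u) * np.cross(v, n) + np.dot(v, v) * np.cross(n, u)) / (2.0 * n2)
    center = a + offset
    radius = float(np.linalg.norm(offset))
    return Circle3D(center=center, radius=radius, normal=_unit(n, "normal"))


def project_to_plane(p, plane: Plane) -> np.ndarray:
    """Orthogonal projection of a point onto a plane (idempotent)."""
    q = as_point(p)
    return q - plane.signed_distance(q) * plane.normal


def radial_offset(p, center, k: float) -> np.ndarray:
    """Move ``p`` by ``k`` mm along the ray from ``center`` through ``p``.

    Positive ``k`` moves outward (away from the center); the result
    stays collinear with (center, p).
    """
    q, c = as_point(p), as_point(center)
    d = q - c
    r = float(np.linalg.norm(d))
    if r < 1e-12:
        raise DegenerateGeometryError(
            f"point coincides with center {c.tolist()}: radial direction undefined"
        )
    return c + d * ((r + k) / r)


def offset_along(p, direction, k: float) -> np.ndarray:
    """``p + k * normalize(direction)``."""
    q = as_point(p)
    d = as_point(direction)
    if float(np.linalg.norm(d)) == 0.0:
        raise ValueError("zero direction vector")
    return q + k * _unit(d)


def chord_to_arc(chord: float, diameter: float) -> float:
    """Arc length from chord length on a circle of given diameter.

    ``arc = diameter * arcsin(chord / diameter)`` — the minor-arc
    length for the chord; ranges from ``chord`` (ratio -> 0) to
    ``pi * diameter / 2`` (chord spanning a full semicircle).  Ratios
    in (1, 1 + 1e-9] are clamped to 1 to absorb floating-point noise.
    """
    if not (diameter > 0 and math.isfinite(diameter)):
        raise ValueError(f"diameter must be positive, got {diameter}")
    if chord < 0 or not math.isfinite(chord):
        raise ValueError(f"chord must be non-negative, got {chord}")
    ratio = chord / diameter
    if ratio > 1.0 + _CLAMP_TOL:
        raise ValueError(
            f"chord {chord} exceeds diameter {diameter} (ratio {ratio:.12g})"
        )
    return diameter * math.asin(min(ratio, 1.0))


def measure_region(a, mid, b, *, warn_major_arc: bool = True) -> float:
    """Arc length from ``a`` to ``b`` on the circumcircle through all three.

    ``mid`` fixes the circle but the conversion always returns the
    minor-arc length of chord ab.  If ``mid`` actually lies on the
    major arc (central angle through mid > pi) the formula cannot
    represent the true path; an :class:`ArcAmbiguityWarning` is issued
    and the minor-arc value returned regardless.
    """
    pa, pm, pb = as_point(a), as_point(mid), as_point(b)
    circle = circumcircle_3points(pa, pm, pb)
    chord = float(np.linalg.norm(pb - pa))
    if warn_major_arc:
        # mid lies on the major arc iff it falls on the same side of the
        # chord as the circle center (in the circle plane)
        chord_mid = 0.5 * (pa + pb)
        side = float(np.dot(pm - chord_mid, circle.center - chord_mid))
        if side > _AREA_TOL:
            warnings.warn(
                "mid landmark lies on the major arc; returned minor-arc length "
                "underestimates the true path",
                ArcAmbiguityWarning,
                stacklevel=2,
            )
    return chord_to_arc(chord, circle.diameter)


def _default_e_direction(
    ring: Circle3D, z_pr: np.ndarray, e_as: np.ndarray, h: np.ndarray
) -> np.ndarray:
    """Lateral offset direction for E when none is supplied.

    Take the pelvic-ring normal oriented toward the iliac crest (H) and
    project it onto the iliac-fossa plane fit through (Z_PR, E_AS, H),
    so E moves away from the ring plane while staying in the plane of
    the iliac arc.
    """
    n = ring.normal
    if float(np.dot(h - ring.center, n)) < 0:
        n = -n
    try:
        fossa = fit_plane(z_pr, e_as, h)
        in_plane = n - float(np.dot(n, fossa.normal)) * fossa.normal
        if np.linalg.norm(in_plane) > 1e-6:
            return _unit(in_plane)
    except DegenerateGeometryError:
        pass
    return n


def derive_landmarks(
    raw: LandmarkSet,
    offsets: Mapping[str, float] = DEFAULT_OFFSETS_MM,
    e_direction: Iterable[float] | None = None,
) -> LandmarkSet:
    """Construct the seven trajectory landmarks from raw anatomical points.

    The pelvic-ring circle is fit through O, S and S1; B, Q and Z are
    the radial outward offsets of B_PR, Q_PR and Z_PR from its center
    (default 5 mm each), and E is offset 10 mm from E_AS along
    ``e_direction`` (default: away from the ring plane within the
    iliac-fossa plane).  O, C and H carry over unchanged.
    """
    raw.require_raw()
    assert raw.raw is not None
    pts = raw.raw
    off = {**DEFAULT_OFFSETS_MM, **dict(offsets)}
    ring = circumcircle_3points(pts["O"], pts["S"], pts["S1"])

    derived: dict[str, np.ndarray] = {
        "O": pts["O"].copy(),
        "C": pts["C"].copy(),
        "H": pts["H"].copy(),
    }
    for name, src in (("B", "B_PR"), ("Q", "Q_PR"), ("Z", "Z_PR")):
        derived[name] = radial_offset(pts[src], ring.center, off[name])
    if e_direction is None:
        e_dir = _default_e_direction(ring, pts["Z_PR"], pts["E_AS"], pts["H"])
    else:
        e_dir = as_point(e_direction)
    derived["E"] = offset_along(pts["E_AS"], e_dir, off["E"])
    return LandmarkSet(derived=derived, raw=dict(pts), side=raw.side)


_REGIONS: tuple[tuple[str, tuple[str, str, str]], ...] = (
    ("pubic", ("O", "C", "B")),
    ("quadrilateral", ("B", "Q", "Z")),
    ("iliac", ("Z", "E", "H")),
)


def measure_trajectory(lm: LandmarkSet) -> TrajectoryMeasurement:
    """Measure the three region arcs (OB, BZ, ZH) and their total."""
    lm.require_derived()
    lengths: list[float] = []
    for region, (na, nm, nb) in _REGIONS:
        try:
            lengths.append(measure_region(lm.derived[na], lm.derived[nm], lm.derived[nb]))
        except (DegenerateGeometryError, ValueError) as exc:
            raise DegenerateGeometryError(f"{region} region ({na},{nm},{nb}): {exc}") from exc
    return TrajectoryMeasurement.from_regions(*lengths)
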