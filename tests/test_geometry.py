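"""Geometry: planes, circumcircles, offsets, chord-to-arc, trajectories."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pelviplate.geometry import (
    ArcAmbiguityWarning,
    DegenerateGeometryError,
    LandmarkSet,
    MissingLandmarkError,
    Plane,
    TrajectoryMeasurement,
    chord_to_arc,
    circumcircle_3points,
    derive_landmarks,
    fit_plane,
    measure_region,
    measure_trajectory,
    offset_along,
    project_to_plane,
    radial_offset,
)


def circle_points(radius, angles, center=(0, 0, 0), rotation=None):
    """Points at given angles on a circle in the (rotated) xy-plane."""
    pts = np.array(
        [[radius * math.cos(a), radius * math.sin(a), 0.0] for a in angles]
    )
    if rotation is not None:
        pts = pts @ rotation.T
    return pts + np.asarray(center, dtype=float)


class TestFitPlane:
    def test_symmetric_triple_has_diagonal_normal(self):
        plane = fit_plane((1, 0, 0), (0, 1, 0), (0, 0, 1))
        assert plane.normal == pytest.approx(np.ones(3) / math.sqrt(3))

    def test_collinear_points_raise_with_offenders_named(self):
        with pytest.raises(DegenerateGeometryError, match=r"\[2\.0, 0\.0, 0\.0\]"):
            fit_plane((0, 0, 0), (1, 0, 0), (2, 0, 0))

    def test_points_lie_on_fitted_plane(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            pts = rng.normal(size=(3, 3)) * 40
            try:
                plane = fit_plane(*pts)
            except DegenerateGeometryError:
                continue
            for p in pts:
                assert abs(plane.signed_distance(p)) < 1e-9

    def test_normal_orientation_right_hand_rule(self):
        plane = fit_plane((0, 0, 0), (1, 0, 0), (0, 1, 0))
        assert plane.normal @ np.array([0, 0, 1]) == pytest.approx(1.0)


class TestCircumcircle:
    def test_unit_circle_triple(self):
        c = circumcircle_3points((1, 0, 0), (0, 1, 0), (-1, 0, 0))
        assert c.center == pytest.approx(np.zeros(3), abs=1e-12)
        assert c.radius == pytest.approx(1.0)
        assert abs(c.normal @ np.array([0, 0, 1.0])) == pytest.approx(1.0)

    @pytest.mark.parametrize("s", [1.0, 7.3, 120.0])
    def test_equilateral_triangle_radius(self, s):
        h = s * math.sqrt(3) / 2
        c = circumcircle_3points((0, 0, 0), (s, 0, 0), (s / 2, h, 0))
        assert c.radius == pytest.approx(s / math.sqrt(3), rel=1e-12)

    def test_collinear_raises(self):
        with pytest.raises(DegenerateGeometryError):
            circumcircle_3points((0, 0, 0), (1, 1, 1), (2, 2, 2))

    def test_matches_in_plane_algebraic_oracle(self):
        # independent oracle: express the triple in a 2D basis of its own
        # plane and solve the linear equidistance system for the center
        rng = np.random.default_rng(11)
        for _ in range(50):
            pts = rng.normal(size=(3, 3)) * 30
            try:
                circ = circumcircle_3points(*pts)
            except DegenerateGeometryError:
                continue
            e1 = pts[1] - pts[0]
            e1 = e1 / np.linalg.norm(e1)
            v = pts[2] - pts[0]
            e2 = v - (v @ e1) * e1
            e2 = e2 / np.linalg.norm(e2)
            uv = np.array([[(p - pts[0]) @ e1, (p - pts[0]) @ e2] for p in pts])
            # |p - c|^2 equal for the three points -> 2x2 linear system
            A = 2 * (uv[1:] - uv[0])
            b = (uv[1:] ** 2).sum(axis=1) - (uv[0] ** 2).sum()
            cen2d = np.linalg.solve(A, b)
            center = pts[0] + cen2d[0] * e1 + cen2d[1] * e2
            radius = np.linalg.norm(uv[0] - cen2d)
            assert circ.center == pytest.approx(center, abs=1e-8)
            assert circ.radius == pytest.approx(radius, rel=1e-10)

    def test_all_points_equidistant_and_center_on_plane(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(3, 3)) * 50
        circ = circumcircle_3points(*pts)
        for p in pts:
            assert np.linalg.norm(p - circ.center) == pytest.approx(circ.radius, abs=1e-9)
        plane = fit_plane(*pts)
        assert abs(plane.signed_distance(circ.center)) < 1e-9


class TestProjection:
    def test_point_on_plane_is_fixed(self):
        plane = Plane((0, 0, 0), (0, 0, 1))
        p = np.array([3.0, -2.0, 0.0])
        assert project_to_plane(p, plane) == pytest.approx(p)

    def test_axis_projection(self):
        plane = Plane((0, 0, 0), (0, 0, 1))
        assert project_to_plane((0, 0, 5), plane) == pytest.approx([0, 0, 0])

    def test_minimizes_distance_and_idempotent(self):
        rng = np.random.default_rng(5)
        n = rng.normal(size=3)
        plane = Plane(rng.normal(size=3), n / np.linalg.norm(n))
        p = rng.normal(size=3) * 20
        proj = project_to_plane(p, plane)
        assert abs(plane.signed_distance(proj)) < 1e-9
        # displacement parallel to the normal
        d = p - proj
        assert np.linalg.norm(np.cross(d, plane.normal)) < 1e-9
        assert project_to_plane(proj, plane) == pytest.approx(proj)
        # no sampled plane point is closer
        u = np.cross(plane.normal, [1.0, 0.0, 0.0])
        u /= np.linalg.norm(u)
        v = np.cross(plane.normal, u)
        for a in np.linspace(-5, 5, 11):
            for b in np.linspace(-5, 5, 11):
                q = proj + a * u + b * v
                assert np.linalg.norm(p - q) >= np.linalg.norm(p - proj) - 1e-12


class TestOffsets:
    def test_radial_offset_along_axis(self):
        assert radial_offset((10, 0, 0), (0, 0, 0), 5) == pytest.approx([15, 0, 0])

    def test_radial_offset_zero_is_identity(self):
        p = np.array([3.0, 4.0, 5.0])
        assert radial_offset(p, (0, 0, 0), 0.0) == pytest.approx(p)

    def test_radial_offset_norm_and_collinearity(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            c = rng.normal(size=3) * 10
            p = c + rng.normal(size=3)
            k = rng.uniform(-0.5, 10)
            q = radial_offset(p, c, k)
            assert np.linalg.norm(q - c) == pytest.approx(
                np.linalg.norm(p - c) + k, abs=1e-9
            )
            assert np.linalg.norm(np.cross(q - c, p - c)) < 1e-6

    def test_radial_offset_from_center_undefined(self):
        with pytest.raises(DegenerateGeometryError):
            radial_offset((1, 2, 3), (1, 2, 3), 5)

    def test_offset_along_basics(self):
        assert offset_along((0, 0, 0), (0, 0, 2), 10) == pytest.approx([0, 0, 10])
        p = np.array([1.0, 2.0, 3.0])
        assert offset_along(p, (1, 1, 0), 0.0) == pytest.approx(p)
        with pytest.raises(ValueError):
            offset_along(p, (0, 0, 0), 1.0)

    def test_offset_along_additivity(self):
        rng = np.random.default_rng(13)
        p, d = rng.normal(size=3), rng.normal(size=3)
        k = 7.5
        twice = offset_along(offset_along(p, d, k / 2), d, k / 2)
        assert twice == pytest.approx(offset_along(p, d, k), abs=1e-12)


class TestChordToArc:
    def test_zero_chord(self):
        assert chord_to_arc(0.0, 100.0) == 0.0

    @pytest.mark.parametrize("d", [1.0, 100.0, 57.3])
    def test_semicircle_closed_form(self, d):
        assert chord_to_arc(d, d) == pytest.approx(math.pi * d / 2, rel=1e-15)

    def test_quarter_circle_value(self):
        # central angle pi/2 on diameter 100: chord = 100 sin(pi/4)
        chord = 100 * math.sin(math.pi / 4)
        assert chord_to_arc(chord, 100.0) == pytest.approx(78.5398, abs=1e-4)

    def test_matches_polyline_integration_oracle(self):
        r = 50.0
        for theta in (0.3, 1.2, 2.5, math.pi):
            chord = 2 * r * math.sin(theta / 2)
            phis = np.linspace(0.0, theta, 200_001)
            poly = np.sum(
                np.hypot(np.diff(r * np.cos(phis)), np.diff(r * np.sin(phis)))
            )
            assert chord_to_arc(chord, 2 * r) == pytest.approx(poly, rel=1e-9)

    def test_domain_errors_and_clamp(self):
        with pytest.raises(ValueError):
            chord_to_arc(-1.0, 10.0)
        with pytest.raises(ValueError):
            chord_to_arc(1.0, 0.0)
        with pytest.raises(ValueError):
            chord_to_arc(10.1, 10.0)
        # ratio barely above 1 clamps to the semicircle
        d = 10.0
        assert chord_to_arc(d * (1 + 5e-10), d) == pytest.approx(math.pi * d / 2)

    def test_arc_at_least_chord_and_monotone(self):
        d = 80.0
        chords = np.linspace(0, d, 50)
        arcs = [chord_to_arc(c, d) for c in chords]
        assert all(a >= c for a, c in zip(arcs, chords))
        assert all(b > a for a, b in zip(arcs, arcs[1:]))
        assert max(arcs) <= math.pi * d / 2 + 1e-12


class TestMeasureRegion:
    def test_known_central_angles(self):
        a, m, b = circle_points(50.0, [0, math.pi / 4, math.pi / 2])
        assert measure_region(a, m, b) == pytest.approx(50 * math.pi / 2, rel=1e-12)
        a, m, b = circle_points(100.0, np.radians([0, 10, 20]))
        assert measure_region(a, m, b) == pytest.approx(100 * math.radians(20), rel=1e-12)

    def test_rigid_invariance(self):
        a, m, b = circle_points(60.0, [0.1, 0.8, 1.9])
        ref = measure_region(a, m, b)
        rng = np.random.default_rng(17)
        for rot in Rotation.random(50, rng=rng):
            t = rng.uniform(-200, 200, 3)
            moved = [rot.apply(p) + t for p in (a, m, b)]
            assert measure_region(*moved) == pytest.approx(ref, abs=1e-6)

    def test_polyline_oracle_on_sampled_circles(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            r = rng.uniform(20, 120)
            theta = rng.uniform(0.2, math.pi)
            start = rng.uniform(0, 2 * math.pi)
            rot = Rotation.random(rng=rng)
            pts = circle_points(
                r, [start, start + theta / 2, start + theta],
                center=rng.uniform(-50, 50, 3), rotation=rot.as_matrix(),
            )
            phis = np.linspace(0, theta, 1_000_001)
            poly = r * np.sum(2 * np.sin(np.diff(phis) / 2))
            assert measure_region(*pts) == pytest.approx(poly, rel=1e-6)

    def test_major_arc_warns_but_returns_minor_value(self):
        a, m, b = circle_points(30.0, np.radians([0, 240, 120]))
        with pytest.warns(ArcAmbiguityWarning):
            got = measure_region(a, m, b)
        assert got == pytest.approx(30.0 * math.radians(120), rel=1e-9)

    def test_minor_arc_does_not_warn(self):
        import warnings

        a, m, b = circle_points(30.0, np.radians([0, 60, 120]))
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            measure_region(a, m, b)


def make_raw_ring(radius=80.0):
    """Hand-built raw landmark set on a ring circle in the xy-plane."""
    ang = np.radians([0, 25, 55, 95, 130, 160, 200])
    names = ["O", "C", "B_PR", "Q_PR", "Z_PR", "S", "S1"]
    raw = {n: p for n, p in zip(names, circle_points(radius, ang))}
    raw["E_AS"] = np.array([-40.0, 30.0, 20.0])
    raw["H"] = np.array([-60.0, 10.0, 45.0])
    return raw


class TestDeriveLandmarks:
    def test_offsets_move_points_radially(self):
        raw = make_raw_ring(80.0)
        lm = derive_landmarks(LandmarkSet(raw=raw))
        for name, src in (("B", "B_PR"), ("Q", "Q_PR"), ("Z", "Z_PR")):
            assert np.linalg.norm(lm.derived[name]) == pytest.approx(85.0, abs=1e-9)
            cross = np.cross(lm.derived[name], raw[src])
            assert np.linalg.norm(cross) < 1e-6
        assert np.linalg.norm(lm.derived["E"] - raw["E_AS"]) == pytest.approx(10.0)
        for name in ("O", "C", "H"):
            assert lm.derived[name] == pytest.approx(raw[name])

    def test_zero_offsets_give_raw_points(self):
        raw = make_raw_ring()
        lm = derive_landmarks(
            LandmarkSet(raw=raw), offsets={"B": 0, "Q": 0, "Z": 0, "E": 0}
        )
        for name, src in (("B", "B_PR"), ("Q", "Q_PR"), ("Z", "Z_PR"), ("E", "E_AS")):
            assert lm.derived[name] == pytest.approx(raw[src])

    def test_missing_raw_landmark_named_in_error(self):
        raw = make_raw_ring()
        del raw["Q_PR"]
        with pytest.raises(MissingLandmarkError, match="Q_PR"):
            derive_landmarks(LandmarkSet(raw=raw))

    def test_explicit_e_direction(self):
        raw = make_raw_ring()
        lm = derive_landmarks(LandmarkSet(raw=raw), e_direction=(0, 0, 1))
        assert lm.derived["E"] == pytest.approx(raw["E_AS"] + [0, 0, 10])


class TestMeasureTrajectory:
    def test_total_is_exact_sum_and_requires_all_landmarks(self):
        raw = make_raw_ring()
        lm = derive_landmarks(LandmarkSet(raw=raw))
        m = measure_trajectory(lm)
        assert m.total == m.lpr + m.lqr + m.lir
        with pytest.raises(MissingLandmarkError):
            measure_trajectory(LandmarkSet(derived={"O": (0, 0, 0)}))

    def test_rigid_and_mirror_invariance(self):
        raw = make_raw_ring()
        lm = derive_landmarks(LandmarkSet(raw=raw))
        ref = measure_trajectory(lm)
        rng = np.random.default_rng(31)
        rot = Rotation.random(rng=rng)
        t = rng.uniform(-100, 100, 3)
        moved = LandmarkSet(
            derived={k: rot.apply(v) + t for k, v in lm.derived.items()}
        )
        assert measure_trajectory(moved).as_tuple() == pytest.approx(
            ref.as_tuple(), abs=1e-6
        )
        mirrored = LandmarkSet(
            derived={k: v * np.array([-1.0, 1.0, 1.0]) for k, v in lm.derived.items()},
            side="right",
        )
        assert measure_trajectory(mirrored).as_tuple() == pytest.approx(
            ref.as_tuple(), abs=1e-9
        )

    def test_degenerate_region_error_names_region(self):
        lm = derive_landmarks(LandmarkSet(raw=make_raw_ring()))
        lm.derived["Q"] = 0.5 * (lm.derived["B"] + lm.derived["Z"])  # collinear
        with pytest.raises(DegenerateGeometryError, match="quadrilateral"):
            measure_trajectory(lm)

    def test_from_regions_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            TrajectoryMeasurement.from_regions(0.0, 1.0, 1.0)
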