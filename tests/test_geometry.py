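"""Planes, fixed landmarks, semilandmarks, mirroring, PSCI1 and the profile."""

import numpy as np
import pytest

import canalmorph as cm
from canalmorph.geometry import (
    DegenerateGeometryError,
    DegenerateIndexError,
    GeometryError,
    LandmarkingError,
    Plane,
    VARIABLE_REGISTRY,
    _arc_lengths_by_side,
)
from conftest import random_rotation


# ---------------------------------------------------------------------------
# fit_plane
# ---------------------------------------------------------------------------


class TestFitPlane:
    def test_coplanar_points_recovered_exactly(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.normal(size=(20, 2)), np.zeros(20)])
        plane = cm.fit_plane(pts)
        np.testing.assert_allclose(plane.normal, [0, 0, 1], atol=1e-12)
        assert abs(plane.offset) < 1e-12

    def test_tilted_circle_normal_recovered(self):
        # circle tilted 30 degrees about the x axis: analytic normal
        theta = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        circle = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(100)])
        a = np.radians(30)
        R = np.array([[1, 0, 0],
                      [0, np.cos(a), -np.sin(a)],
                      [0, np.sin(a), np.cos(a)]])
        plane = cm.fit_plane(circle @ R.T)
        np.testing.assert_allclose(plane.normal, R @ np.array([0, 0, 1.0]),
                                   atol=1e-9)

    def test_collinear_points_rejected(self):
        pts = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateGeometryError):
            cm.fit_plane(pts)

    def test_orientation_convention_superior_positive(self):
        pts = np.column_stack([np.random.default_rng(1).normal(size=(10, 2)),
                               np.full(10, 2.0)])
        assert cm.fit_plane(pts).normal @ [0, 0, 1] > 0


# ---------------------------------------------------------------------------
# Fixed landmarks
# ---------------------------------------------------------------------------


class TestFixedLandmarks:
    def test_template_crossings_match_analytic_circle_plane_intersection(self, template):
        # HSC is the radius-3 circle about the origin in z=0; the ASC plane
        # contains the z axis and the in-plane direction at asc_tilt degrees,
        # so the crossings are at +-3*(cos(tilt), sin(tilt), 0)
        t = np.radians(10.0)
        expected = 3.0 * np.array([np.cos(t), np.sin(t), 0.0])
        lds = cm.extract_fixed_landmarks(template)
        np.testing.assert_allclose(lds["Ld1"], expected, atol=5e-3)
        np.testing.assert_allclose(lds["Ld2"], -expected, atol=5e-3)

    def test_ampullae_and_crus_are_marker_points(self, template):
        lds = cm.extract_fixed_landmarks(template)
        np.testing.assert_array_equal(lds["Ld3"], template.ampullae["PSC"])
        np.testing.assert_array_equal(lds["Ld4"], template.common_crus)
        np.testing.assert_array_equal(lds["Ld5"], template.ampullae["ASC"])

    def test_rigid_equivariance(self, template):
        rng = np.random.default_rng(3)
        R = random_rotation(rng)
        t = rng.normal(size=3)
        moved = template.transformed(R, t)
        lds = cm.extract_fixed_landmarks(template)
        lds_moved = cm.extract_fixed_landmarks(moved)
        for name in lds:
            np.testing.assert_allclose(lds_moved[name], R @ lds[name] + t,
                                       atol=1e-9)

    def test_no_crossing_raises(self, template):
        import dataclasses

        shifted = dataclasses.replace(
            template,
            canals={**template.canals,
                    "HSC": template.canals["HSC"] + np.array([0, 10.0, 0])},
            ampullae={**template.ampullae,
                      "HSC": template.ampullae["HSC"] + np.array([0, 10.0, 0])})
        with pytest.raises(LandmarkingError, match="crosses the ASC plane"):
            cm.extract_fixed_landmarks(shifted)


# ---------------------------------------------------------------------------
# Semilandmarks
# ---------------------------------------------------------------------------


class TestSemilandmarks:
    def test_midpoint_of_straight_segment(self):
        seg = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        np.testing.assert_allclose(cm.resample_semilandmarks(seg, 1),
                                   [[0.5, 0, 0]])

    def test_semicircle_analytic_positions(self):
        # k=7 on a unit semicircle: points at 22.5-degree increments
        theta = np.linspace(0, np.pi, 2001)
        arc = np.column_stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)])
        pts = cm.resample_semilandmarks(arc, 7)
        want = np.radians(np.arange(1, 8) * 22.5)
        np.testing.assert_allclose(
            pts, np.column_stack([np.cos(want), np.sin(want), np.zeros(7)]),
            atol=1e-5)

    def test_equal_arc_spacing(self, template):
        pts = cm.resample_semilandmarks(template.canals["ASC"], 48)
        assert pts.shape == (48, 3)
        gaps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        assert np.ptp(gaps) / gaps.mean() < 1e-3  # chords of equal arcs

    def test_resampling_stable_under_vertex_density(self, template):
        coarse = template.canals["PSC"]
        theta_fine = None  # refine by midpoint insertion
        fine = np.empty((2 * len(coarse) - 1, 3))
        fine[0::2] = coarse
        fine[1::2] = (coarse[:-1] + coarse[1:]) / 2
        a = cm.resample_semilandmarks(coarse, 18)
        b = cm.resample_semilandmarks(fine, 18)
        seg = np.linalg.norm(np.diff(coarse, axis=0), axis=1).max()
        assert np.linalg.norm(a - b, axis=1).max() < seg

    def test_k_zero_rejected(self):
        with pytest.raises(GeometryError):
            cm.resample_semilandmarks(np.eye(3), 0)


# ---------------------------------------------------------------------------
# Configurations and mirroring
# ---------------------------------------------------------------------------


class TestConfiguration:
    @pytest.mark.parametrize("k,total", [(1, 8), (7, 26), (18, 59), (48, 149)])
    def test_point_counts(self, template, k, total):
        assert cm.build_configuration(template, k).n_points == total

    def test_left_side_mirrored_to_right_convention(self, template):
        left = cm.mirror(template)
        assert left.side == "left"
        cfg_r = cm.build_configuration(template, 7)
        cfg_l = cm.build_configuration(left, 7)
        np.testing.assert_array_equal(cfg_l.points, cfg_r.points)
        assert cfg_l.side == "right"

    def test_mirror_reflects_x(self):
        cfg = cm.LandmarkConfiguration(
            points=np.arange(24.0).reshape(8, 3), k=1, side="right")
        m = cm.mirror(cfg)
        np.testing.assert_array_equal(m.points[:, 0], -cfg.points[:, 0])
        np.testing.assert_array_equal(m.points[:, 1:], cfg.points[:, 1:])
        assert m.side == "left"

    def test_mirror_is_involution_and_isometry(self, template):
        twice = cm.mirror(cm.mirror(template))
        for key in template.canals:
            np.testing.assert_array_equal(twice.canals[key],
                                          template.canals[key])
        cfg = cm.build_configuration(template, 7)
        assert cm.centroid_size(cm.mirror(cfg).points) == pytest.approx(
            cm.centroid_size(cfg.points), rel=1e-12)


# ---------------------------------------------------------------------------
# PSCI1
# ---------------------------------------------------------------------------


def _vertical_circle(center_z, radius=1.0, n=200, span=(0, 360)):
    phi = np.radians(np.linspace(span[0], span[1], n))
    return np.column_stack([np.zeros(n), radius * np.cos(phi),
                            center_z + radius * np.sin(phi)])


class TestPsci1:
    HPLANE = Plane(normal=np.array([0.0, 0.0, 1.0]), offset=0.0)

    def test_symmetric_arc_gives_one(self):
        arc = _vertical_circle(0.0, span=(-135, 135))
        assert cm.psci1(arc, self.HPLANE) == pytest.approx(1.0, abs=1e-9)

    def test_two_to_one_split_matches_dense_oracle(self):
        # full circle centred at z = -r/2: 240 deg below, 120 deg above
        coarse = _vertical_circle(-0.5, n=200)
        dense = _vertical_circle(-0.5, n=10_001)
        below, above = _arc_lengths_by_side(dense, self.HPLANE)
        oracle = below / above
        assert oracle == pytest.approx(2.0, rel=1e-4)
        assert cm.psci1(coarse, self.HPLANE) == pytest.approx(oracle, rel=1e-3)

    def test_oracle_agreement_on_random_arcs(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            cz = rng.uniform(-0.6, 0.6)
            coarse = _vertical_circle(cz, n=300)
            dense = _vertical_circle(cz, n=10_001)
            b, a = _arc_lengths_by_side(dense, self.HPLANE)
            assert cm.psci1(coarse, self.HPLANE) == pytest.approx(
                b / a, rel=1e-3)

    def test_no_crossing_raises(self):
        arc = _vertical_circle(5.0)
        with pytest.raises(DegenerateIndexError):
            cm.psci1(arc, self.HPLANE)


# ---------------------------------------------------------------------------
# 35-variable profile
# ---------------------------------------------------------------------------


class TestProfile:
    def test_registry_category_counts(self):
        from collections import Counter

        counts = Counter(cat for cat, *_ in VARIABLE_REGISTRY.values())
        assert counts == {"area": 1, "arc_length": 6, "distance": 6,
                          "index": 12, "angle": 10}

    def test_complete_profile_and_ranges(self, template):
        prof = cm.compute_profile(template, owa=4.0)
        assert prof.complete and len(prof.values) == 35
        for name, val in prof.values.items():
            cat = VARIABLE_REGISTRY[name][0]
            if cat in ("area", "arc_length", "distance", "index"):
                assert val > 0, name
            else:
                assert 0.0 <= val <= 180.0, name

    def test_similarity_invariance_of_indices_and_angles(self, template):
        import dataclasses

        prof = cm.compute_profile(template, owa=4.0)
        scaled = dataclasses.replace(
            template,
            canals={k: 2.0 * v for k, v in template.canals.items()},
            ampullae={k: 2.0 * v for k, v in template.ampullae.items()},
            common_crus=2.0 * template.common_crus)
        prof2 = cm.compute_profile(scaled, owa=4.0)
        for name in VARIABLE_REGISTRY:
            cat = VARIABLE_REGISTRY[name][0]
            if cat in ("arc_length", "distance"):
                assert prof2.values[name] == pytest.approx(
                    2.0 * prof.values[name], rel=1e-9), name
            elif cat in ("index", "angle"):
                assert prof2.values[name] == pytest.approx(
                    prof.values[name], rel=1e-9), name
        assert prof2.values["OWA"] == prof.values["OWA"]

    def test_orthogonal_canal_planes_give_right_angles(self):
        t = cm.generate_canal_template(cm.CanalTemplateParams(asc_tilt=0.0))
        prof = cm.compute_profile(t, owa=4.0)
        for name in ("ANG_ASC_PSC", "ANG_ASC_HSC", "ANG_PSC_HSC"):
            assert prof.values[name] == pytest.approx(90.0, abs=1e-6)

    def test_mirror_invariance(self, template):
        prof = cm.compute_profile(template, owa=4.0)
        prof_m = cm.compute_profile(cm.mirror(template), owa=4.0)
        for name in prof.values:
            assert prof_m.values[name] == pytest.approx(
                prof.values[name], abs=1e-9), name

    def test_missing_canal_flagged_not_fatal(self, template):
        import dataclasses

        partial = dataclasses.replace(
            template,
            canals={k: v for k, v in template.canals.items() if k != "PSC"},
            ampullae={k: v for k, v in template.ampullae.items() if k != "PSC"})
        prof = cm.compute_profile(partial, owa=4.0)
        assert not prof.complete
        assert "ARC_PSC" in prof.missing and "PSCI1" in prof.missing
        assert "ARC_HSC" in prof.values
        assert len(prof.values) + len(prof.missing) == 35

    def test_nonpositive_owa_rejected(self, template):
        with pytest.raises(GeometryError):
            cm.compute_profile(template, owa=0.0)


def test_profile_rigid_invariance_property(template):
    """Arc lengths, indices and angles are invariant to rigid motion."""
    rng = np.random.default_rng(42)
    prof = cm.compute_profile(template, owa=4.0)
    for _ in range(5):
        moved = template.transformed(random_rotation(rng), rng.normal(size=3))
        prof_m = cm.compute_profile(moved, owa=4.0)
        for name, val in prof.values.items():
            assert prof_m.values[name] == pytest.approx(val, abs=1e-8), name
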