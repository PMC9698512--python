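"""Canonical frame, subdivision combinatorics, and fitting fixed points."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from shapeforge.geometry import LandmarkSet, Scheme, TriangleMesh
from shapeforge.synthetic_mandible import LatentFactors, deform_reference
from shapeforge.template_fit import (
    DegenerateFrameError,
    FitParams,
    TemplateFitter,
    build_cohort,
    canonical_frame,
    fit_template,
    subdivide,
)


class TestCanonicalFrame:
    def test_canonical_landmarks_give_identity(self, reference1):
        _, tm, _ = reference1
        frame = canonical_frame(tm)
        posed = LandmarkSet(list(tm.names), frame.apply(tm.points), tm.scheme)
        again = canonical_frame(posed)
        assert np.allclose(again.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(again.translation, 0.0, atol=1e-9)

    def test_known_rigid_motion_is_inverted(self, reference1, rng):
        _, tm, _ = reference1
        base = canonical_frame(tm)
        rot = Rotation.from_euler("xyz", [31.0, -12.0, 57.0], degrees=True).as_matrix()
        t = np.array([4.0, -8.0, 15.0])
        moved = LandmarkSet(list(tm.names), tm.points @ rot.T + t, tm.scheme)
        frame = canonical_frame(moved)
        # canonical coordinates must be identical for both poses
        assert np.allclose(
            frame.apply(moved.points), base.apply(tm.points), atol=1e-9
        )

    def test_frame_conditions_hold(self, reference1):
        _, tm, _ = reference1
        canon = canonical_frame(tm).apply(tm.points)
        lm = dict(zip(tm.names, canon))
        mid = (lm["Right condylar head"] + lm["Left condylar head"]) / 2
        assert np.allclose(mid, 0.0, atol=1e-9)  # origin at condylar midpoint
        inter = lm["Right condylar head"] - lm["Left condylar head"]
        assert np.allclose(inter[1:], 0.0, atol=1e-9)  # x-axis inter-condylar
        assert lm["Right condylar head"][0] > 0  # right side at +x
        # symmetric reference: mentaris lies in the y-z plane
        assert abs(lm["Centre of mentaris"][0]) <= 1e-9

    def test_hm_frame_puts_mentaris_in_yz_plane(self, reference1):
        _, _, hm = reference1
        canon = canonical_frame(hm).apply(hm.points)
        lm = dict(zip(hm.names, canon))
        assert np.allclose(lm["Right condylar head"], 0.0, atol=1e-9)
        m = lm["Centre of mentaris"]
        assert abs(m[0]) <= 1e-9 and abs(m[2]) <= 1e-9 and m[1] > 0

    def test_coincident_condyles_degenerate(self, reference1):
        _, tm, _ = reference1
        pts = tm.points.copy()
        i = tm.names.index("Right condylar head")
        j = tm.names.index("Left condylar head")
        pts[i] = pts[j]
        with pytest.raises(DegenerateFrameError):
            canonical_frame(LandmarkSet(list(tm.names), pts, Scheme.TM20))


class TestSubdivide:
    def test_zero_levels_identity(self, reference0):
        mesh, _, _ = reference0
        out = subdivide(mesh, 0)
        assert np.array_equal(out.vertices, mesh.vertices)
        assert np.array_equal(out.faces, mesh.faces)

    def test_single_triangle_one_level(self):
        tri = TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
        out = subdivide(tri, 1)
        assert out.n_faces == 4
        assert out.n_vertices == 6
        # original vertices keep their indices
        assert np.allclose(out.vertices[:3], tri.vertices)

    def test_two_levels_sixteen_fold(self, reference0):
        mesh, _, _ = reference0
        assert subdivide(mesh, 2).n_faces == 16 * mesh.n_faces


class TestFitting:
    def test_self_fit_is_fixed_point(self, tm_template, reference1):
        mesh, _, _ = reference1
        lms = tm_template.landmark_points()
        res = fit_template(tm_template, mesh.vertices, lms)
        expect = canonical_frame(lms).apply(mesh.vertices)
        disp = np.linalg.norm(res.model.mesh.vertices - expect, axis=1).max()
        assert disp <= 1e-6
        assert res.final_energy[0] <= 1e-12  # external energy ~ 0

    def test_rigid_motion_absorbed_by_canonical_frame(self, tm_template, reference1):
        mesh, _, _ = reference1
        lms = tm_template.landmark_points()
        base = fit_template(tm_template, mesh.vertices, lms)
        rot = Rotation.from_euler("xyz", [15.0, 25.0, -40.0], degrees=True).as_matrix()
        t = np.array([5.0, 0.0, -7.0])
        moved_lms = LandmarkSet(list(lms.names), lms.points @ rot.T + t, lms.scheme)
        res = fit_template(tm_template, mesh.vertices @ rot.T + t, moved_lms)
        disp = np.linalg.norm(
            res.model.mesh.vertices - base.model.mesh.vertices, axis=1
        ).max()
        assert disp <= 1e-6

    def test_energy_monotone_within_stage(self, tm_template, reference1):
        mesh, tm, hm = reference1
        spec = deform_reference(
            (mesh, tm, hm),
            LatentFactors(size=1.1, ramus_length=3.0, ramus_angle=4.0, arch_shape=0.7),
            seed=0,
        )
        fitter = TemplateFitter(tm_template, FitParams(tps_init=False))
        fitter.fit(spec.surface.vertices, landmarks=spec.tm_landmarks)
        trace = np.array(fitter.energy_trace_)
        assert len(trace) >= 2
        assert np.all(np.diff(trace) <= 1e-9 * np.maximum(trace[:-1], 1.0))

    def test_topology_preserved_and_subdivided(self, tm_template, reference1):
        mesh, tm, hm = reference1
        spec = deform_reference((mesh, tm, hm), LatentFactors(size=1.05), seed=0)
        res = fit_template(
            tm_template, spec.surface.vertices, spec.tm_landmarks,
            FitParams(subdivision_schedule=(0, 1)),
        )
        assert np.array_equal(res.model.mesh.faces, subdivide(tm_template.mesh, 1).faces)
        assert res.model.template_id.endswith("+sub1")

    def test_smooth_warp_recovered(self, tm_template, reference1):
        # smooth bending of known amplitude; fitted surface must land within
        # 5% of the amplitude (verified by exhaustive distance, see helper)
        mesh, tm, _ = reference1
        amp = 4.0

        def bend(p):
            out = p.copy()
            out[:, 2] += amp * np.sin(p[:, 1] / 40.0) * np.cos(p[:, 0] / 60.0)
            return out

        warped = TriangleMesh(bend(mesh.vertices), mesh.faces)
        warped_lms = LandmarkSet(list(tm.names), bend(tm.points), tm.scheme)
        res = fit_template(
            tm_template, warped.vertices, warped_lms, FitParams(w_int=0.1)
        )
        frame = canonical_frame(warped_lms)
        target = TriangleMesh(frame.apply(warped.vertices), warped.faces)
        # exhaustive oracle on a subsample (it is O(points x triangles))
        d = _brute_force_point_mesh(res.model.mesh.vertices[::25], target)
        assert d.mean() <= 0.05 * amp

    def test_landmark_weight_increases_landmark_fidelity(self, tm_template, reference1):
        mesh, tm, hm = reference1
        spec = deform_reference(
            (mesh, tm, hm), LatentFactors(size=1.1, arch_shape=0.8), seed=0
        )
        dists = []
        for w_lm in (1.0, 10.0, 100.0):
            res = fit_template(
                tm_template, spec.surface.vertices, spec.tm_landmarks,
                FitParams(w_lm=w_lm, tps_init=False),
            )
            model = res.model
            frame = canonical_frame(spec.tm_landmarks)
            lm_target = frame.apply(spec.tm_landmarks.points)
            ids = [model.landmark_vertex_ids[n] for n in spec.tm_landmarks.names]
            dists.append(
                np.linalg.norm(model.mesh.vertices[ids] - lm_target, axis=1).mean()
            )
        assert dists[0] > dists[1] > dists[2]

    def test_empty_and_tiny_targets_rejected(self, tm_template, reference1):
        _, tm, _ = reference1
        with pytest.raises(Exception, match="empty|100"):
            fit_template(tm_template, np.zeros((0, 3)), tm)
        with pytest.raises(Exception, match="100"):
            fit_template(tm_template, np.zeros((5, 3)), tm)

    def test_scheme_mismatch_rejected(self, tm_template, reference1):
        _, _, hm = reference1
        with pytest.raises(ValueError, match="scheme"):
            fit_template(tm_template, np.zeros((200, 3)), hm)


class TestCohort:
    def test_cohort_counts_and_determinism(self, tm_template, hm_template, reference1):
        mesh, tm, hm = reference1
        spec = deform_reference((mesh, tm, hm), LatentFactors(size=1.03), seed=0)
        specimens = [spec, spec, spec]
        tm_models, hm_models = build_cohort(tm_template, hm_template, specimens)
        assert len(tm_models) == len(hm_models) == 3
        for m in tm_models[1:]:
            assert np.linalg.norm(
                m.mesh.vertices - tm_models[0].mesh.vertices, axis=1
            ).max() <= 1e-6

    def test_missing_landmarks_error_names_specimen(self, tm_template, hm_template,
                                                    reference1):
        mesh, tm, hm = reference1
        good = deform_reference((mesh, tm, hm), LatentFactors(), seed=0)

        class Broken:
            surface = good.surface
            tm_landmarks = good.tm_landmarks
            hm_landmarks = None

        with pytest.raises(Exception, match="specimen 1"):
            build_cohort(tm_template, hm_template, [good, Broken()])


def _brute_force_point_mesh(points, mesh):
    """Independent exhaustive point-to-mesh distance (plane + in-plane 2D)."""
    from shapely.geometry import Point, Polygon

    tris = mesh.triangles()
    out = np.empty(len(points))
    for i, p in enumerate(points):
        best = np.inf
        for a, b, c in tris:
            n = np.cross(b - a, c - a)
            nn = np.linalg.norm(n)
            if nn < 1e-14:
                continue
            n = n / nn
            h = np.dot(p - a, n)
            proj = p - h * n
            e1 = (b - a) / np.linalg.norm(b - a)
            e2 = np.cross(n, e1)

            def to2(q):
                return (np.dot(q - a, e1), np.dot(q - a, e2))

            d2 = Polygon([to2(a), to2(b), to2(c)]).distance(Point(to2(proj)))
            best = min(best, float(np.hypot(h, d2)))
        out[i] = best
    return out
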