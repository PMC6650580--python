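"""Kinematic chain, muscle geometry, and rigid-tendon Hill mechanics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capgap.errors import DomainError, InfeasibleGeometryError, ModelError
from capgap.model import (
    JointCoordinate,
    MuscleCurveSet,
    MuscleTendonActuator,
    MusculoskeletalModel,
    PathPoint,
    Segment,
    evaluate_curve,
    fiber_state,
    forward_kinematics,
    muscle_force,
    musculotendon_geometry,
)

from conftest import make_hinge_toy


# ---------------------------------------------------------------------------
# Independent geometry oracle: straight-line polyline length with scipy
# rotations, recursing the chain independently of the implementation.
# ---------------------------------------------------------------------------

def oracle_lengths(model, q):
    from scipy.spatial.transform import Rotation

    seg_coord = {c.segment: i for i, c in enumerate(model.coordinates)}
    poses = {}

    def pose(name):
        if name in poses:
            return poses[name]
        seg = model.segment(name)
        if seg.parent is None:
            Rp, tp = np.eye(3), np.zeros(3)
        else:
            Rp, tp = pose(seg.parent)
        if name in seg_coord:
            Rj = Rotation.from_rotvec(q[seg_coord[name]] * seg.joint_axis).as_matrix()
        else:
            Rj = np.eye(3)
        Ro = seg.joint_offset if seg.joint_offset is not None else np.eye(3)
        poses[name] = (Rp @ Ro @ Rj, Rp @ seg.joint_center + tp)
        return poses[name]

    out = []
    for m in model.muscles:
        pts = [pose(p.segment)[0] @ p.location + pose(p.segment)[1] for p in m.path]
        out.append(sum(np.linalg.norm(b - a) for a, b in zip(pts, pts[1:])))
    return np.asarray(out)


class TestGeometry:
    def test_lengths_match_independent_oracle(self, model0):
        rng = np.random.default_rng(0)
        for _ in range(5):
            q = rng.uniform(-0.4, 0.4, len(model0.coordinates))
            l_mt, _ = musculotendon_geometry(model0, q, check_range=False)
            assert np.allclose(l_mt, oracle_lengths(model0, q), atol=1e-12)

    def test_moment_arms_match_finite_difference_oracle(self, model0):
        rng = np.random.default_rng(1)
        h = 1e-6
        for _ in range(3):
            q = rng.uniform(-0.3, 0.3, len(model0.coordinates))
            _, r = musculotendon_geometry(model0, q, check_range=False)
            for j in range(len(model0.coordinates)):
                dq = np.zeros_like(q)
                dq[j] = h
                fd = -(oracle_lengths(model0, q + dq)
                       - oracle_lengths(model0, q - dq)) / (2 * h)
                assert np.abs(r[:, j] - fd).max() < 1e-8

    def test_axis_collinear_path_has_zero_moment_arm(self):
        segs = [Segment("base", None),
                Segment("arm", "base", joint_axis=[0, 0, 1])]
        coords = [JointCoordinate("hinge", "arm")]
        # both points on the rotation axis (z): length cannot change
        mus = [MuscleTendonActuator(
            "onaxis",
            [PathPoint("base", [0, 0, 0.1], "origin"),
             PathPoint("arm", [0, 0, -0.1], "insertion")],
            F_max=1.0, l_mo=0.1, l_ts=0.05)]
        model = MusculoskeletalModel(segs, coords, mus)
        _, r = musculotendon_geometry(model, [0.3])
        assert abs(r[0, 0]) < 1e-9

    def test_non_spanning_muscle_has_zero_moment_arm(self, model0):
        _, r = musculotendon_geometry(model0, np.zeros(4))
        names = model0.muscle_names
        j_ankle = model0.coordinate_names.index("ankle_flexion")
        # hip muscles do not cross the ankle
        assert r[names.index("glutmax_toy"), j_ankle] == 0.0
        assert r[names.index("iliopsoas_toy"), j_ankle] == 0.0

    def test_biarticular_muscles_span_two_joints(self, model0):
        _, r = musculotendon_geometry(model0, np.zeros(4))
        names = model0.muscle_names
        jk = model0.coordinate_names.index("knee_flexion")
        ja = model0.coordinate_names.index("ankle_flexion")
        jh = model0.coordinate_names.index("hip_flexion")
        assert abs(r[names.index("gastroc_toy"), jk]) > 1e-4
        assert abs(r[names.index("gastroc_toy"), ja]) > 1e-4
        assert abs(r[names.index("hamstrings_toy"), jh]) > 1e-4
        assert abs(r[names.index("hamstrings_toy"), jk]) > 1e-4

    def test_out_of_range_posture_rejected(self, model0):
        q = np.zeros(4)
        q[0] = 10.0
        with pytest.raises(DomainError, match="hip_flexion"):
            musculotendon_geometry(model0, q)


class TestModelValidation:
    def test_non_unit_axis_rejected(self):
        with pytest.raises(ModelError, match="unit"):
            Segment("a", None, joint_axis=[0, 0, 2])

    def test_unknown_parent_rejected(self):
        with pytest.raises(ModelError, match="parent"):
            MusculoskeletalModel(
                [Segment("a", None), Segment("b", "nope")], [], [])

    def test_two_roots_rejected(self):
        with pytest.raises(ModelError, match="root"):
            MusculoskeletalModel([Segment("a", None), Segment("b", None)], [], [])

    def test_path_needs_origin_and_insertion(self):
        with pytest.raises(ModelError, match="origin"):
            MuscleTendonActuator(
                "bad", [PathPoint("a", [0, 0, 0], "via"),
                        PathPoint("a", [1, 0, 0], "via")],
                F_max=1, l_mo=0.1, l_ts=0.1)

    def test_unresolved_path_segment_rejected(self):
        with pytest.raises(ModelError, match="unknown segment"):
            MusculoskeletalModel(
                [Segment("a", None)], [],
                [MuscleTendonActuator(
                    "m", [PathPoint("a", [0, 0, 0], "origin"),
                          PathPoint("ghost", [1, 0, 0], "insertion")],
                    F_max=1, l_mo=0.1, l_ts=0.1)])


class TestFiberState:
    def test_optimal_length_identity(self):
        m = MuscleTendonActuator(
            "m", _straight_path(), F_max=1.0, l_mo=0.1, l_ts=0.2, alpha=0.3)
        l, ln = fiber_state(0.2 + 0.1 * np.cos(0.3), m)
        assert ln == pytest.approx(1.0, abs=1e-12)

    def test_zero_pennation_example(self):
        m = MuscleTendonActuator("m", _straight_path(), F_max=1.0,
                                 l_mo=0.10, l_ts=0.20, alpha=0.0)
        l, ln = fiber_state(0.30, m)
        assert l == pytest.approx(0.10)
        assert ln == pytest.approx(1.0)

    @settings(deadline=None, max_examples=50)
    @given(l_fib=st.floats(0.01, 0.5), l_ts=st.floats(0.0, 0.5),
           l_mo=st.floats(0.01, 0.5), alpha=st.floats(0.0, 1.2))
    def test_formula_oracle(self, l_fib, l_ts, l_mo, alpha):
        """Rigid-tendon identity l_mt = l_ts + l*cos(alpha) holds exactly."""
        m = MuscleTendonActuator("m", _straight_path(), F_max=1.0,
                                 l_mo=l_mo, l_ts=l_ts, alpha=alpha)
        l_mt = l_ts + l_fib * np.cos(alpha)
        l, ln = fiber_state(l_mt, m)
        assert l == pytest.approx(l_fib, rel=1e-12)
        assert ln == pytest.approx(l_fib / l_mo, rel=1e-12)
        assert l_mt == pytest.approx(m.l_ts + l * np.cos(m.alpha), rel=1e-12)

    def test_infeasible_geometry_names_muscle(self):
        m = MuscleTendonActuator("gastroc", _straight_path(), F_max=1.0,
                                 l_mo=0.1, l_ts=0.3)
        with pytest.raises(InfeasibleGeometryError, match="gastroc"):
            fiber_state(0.25, m)


class TestCurves:
    def test_passive_anchor_at_1_5(self):
        curves = MuscleCurveSet()
        assert evaluate_curve(curves, "passive", 1.5) == pytest.approx(0.5, abs=0.05)

    def test_passive_near_zero_at_optimum(self):
        curves = MuscleCurveSet()
        assert evaluate_curve(curves, "passive", 1.0) <= 0.02

    def test_active_peaks_at_one(self):
        curves = MuscleCurveSet()
        ln = np.linspace(0.2, 2.0, 401)
        vals = evaluate_curve(curves, "active", ln)
        assert evaluate_curve(curves, "active", 1.0) == pytest.approx(1.0)
        assert vals.max() <= 1.0 + 1e-12

    def test_active_unimodal(self):
        curves = MuscleCurveSet()
        ln = np.linspace(0.4, 1.6, 241)
        v = np.asarray(evaluate_curve(curves, "active", ln))
        peak = np.argmax(v)
        assert np.all(np.diff(v[:peak + 1]) >= -1e-12)
        assert np.all(np.diff(v[peak:]) <= 1e-12)

    def test_passive_nondecreasing_on_stretch(self):
        curves = MuscleCurveSet()
        v = np.asarray(evaluate_curve(curves, "passive", np.linspace(1.0, 2.0, 201)))
        assert np.all(np.diff(v) >= 0)

    def test_half_force_length_by_bisection(self):
        """The normalized length where passive force reaches half of F_max."""
        from scipy.optimize import brentq

        curves = MuscleCurveSet()
        root = brentq(lambda x: float(evaluate_curve(curves, "passive", x)) - 0.5,
                      1.0, 2.0, xtol=1e-12)
        assert root == pytest.approx(1.5, abs=0.05)

    def test_unknown_kind_rejected(self):
        with pytest.raises(DomainError, match="kind"):
            evaluate_curve(MuscleCurveSet(), "velocity", 1.0)


class TestMuscleForce:
    def test_subset_n_proportionality(self):
        m = MuscleTendonActuator("m", _straight_path(), F_max=100.0,
                                 l_mo=0.1, l_ts=0.1, subset="N")
        assert muscle_force(m, MuscleCurveSet(), 0.3) == pytest.approx(30.0)

    def test_subset_n_invariant_to_fiber_parameters(self):
        c = MuscleCurveSet()
        forces = []
        for lmo, lts, alpha in [(0.1, 0.1, 0.0), (0.2, 0.05, 0.3), (0.05, 0.3, 0.1)]:
            m = MuscleTendonActuator("m", _straight_path(), F_max=100.0,
                                     l_mo=lmo, l_ts=lts, alpha=alpha, subset="N")
            forces.append(muscle_force(m, c, 0.42, l_norm=1.3))
        assert np.ptp(forces) == 0.0

    def test_subset_m_zero_activation_at_optimum(self):
        m = MuscleTendonActuator("m", _straight_path(), F_max=500.0,
                                 l_mo=0.1, l_ts=0.1, subset="M")
        assert muscle_force(m, MuscleCurveSet(), 0.0, l_norm=1.0) < 1.0

    def test_subset_m_passive_force_at_stretch(self):
        m = MuscleTendonActuator("m", _straight_path(), F_max=200.0,
                                 l_mo=0.1, l_ts=0.1, subset="M")
        f = muscle_force(m, MuscleCurveSet(), 0.0, l_norm=1.5)
        assert f == pytest.approx(100.0, abs=10.0)  # F_max * passive(1.5)

    def test_activation_outside_unit_interval_rejected(self):
        m = MuscleTendonActuator("m", _straight_path(), F_max=1.0,
                                 l_mo=0.1, l_ts=0.1)
        with pytest.raises(DomainError):
            muscle_force(m, MuscleCurveSet(), 1.2, l_norm=1.0)


def _straight_path():
    return [PathPoint("a", [0, 0, 0], "origin"), PathPoint("a", [1, 0, 0], "insertion")]


def test_forward_kinematics_hinge_rotation():
    model = make_hinge_toy()
    poses = forward_kinematics(model, [np.pi / 2])
    R, t = poses["arm"]
    assert np.allclose(R @ [1, 0, 0], [0, 1, 0], atol=1e-12)
    assert np.allclose(t, 0.0)
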