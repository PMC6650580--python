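"""Virtual surgery operators: identities, inverses, geometric oracles."""

import numpy as np
import pytest

from capgap.errors import SurgeryError
from capgap.fixtures import make_toy_model, perturb_model
from capgap.model import musculotendon_geometry, rotation_about_axis
from capgap.surgery import (
    SurgeryOperation,
    SurgeryPlan,
    apply_derotation_osteotomy,
    apply_extension_derotation_osteotomy,
    apply_muscle_transfer,
    apply_operation,
    apply_patella_advancement,
    apply_plan,
    apply_strength_change,
    bone_morphometrics,
    read_plan,
    rectus_transfer,
    write_plan,
)

PLANE = ([0.0, -0.2, 0.0], [0.0, 1.0, 0.0])  # mid-femur cut, shaft normal


def all_points(model, segment):
    seg = model.segment(segment)
    pts = dict(seg.landmarks)
    for m in model.muscles:
        for i, p in enumerate(m.path):
            if p.segment == segment:
                pts[f"{m.name}:{i}"] = p.location
    return pts


class TestDerotation:
    def test_zero_angle_is_identity(self, model0):
        out = apply_derotation_osteotomy(model0, "thigh", *PLANE, 0.0)
        for k, v in all_points(model0, "thigh").items():
            assert np.array_equal(v, all_points(out, "thigh")[k])

    def test_opposite_rotations_invert(self, model0):
        fwd = apply_derotation_osteotomy(model0, "thigh", *PLANE,
                                         np.radians(15.0))
        back = apply_derotation_osteotomy(fwd, "thigh", *PLANE,
                                          np.radians(-15.0))
        for k, v in all_points(model0, "thigh").items():
            assert np.abs(v - all_points(back, "thigh")[k]).max() < 1e-10

    def test_distal_azimuth_matches_rotation_oracle(self, model0):
        angle = np.radians(30.0)
        out = apply_derotation_osteotomy(model0, "thigh", *PLANE, angle)
        R = rotation_about_axis(np.array([0.0, 1.0, 0.0]), angle)
        p = np.array(PLANE[0])
        for name in ("condyle_medial", "condyle_lateral", "shaft_distal"):
            expect = p + R @ (model0.segment("thigh").landmarks[name] - p)
            got = out.segment("thigh").landmarks[name]
            assert np.abs(got - expect).max() < 1e-12

    def test_proximal_side_untouched(self, model0):
        out = apply_derotation_osteotomy(model0, "thigh", *PLANE,
                                         np.radians(25.0))
        for name in ("femoral_head_center", "neck_base", "shaft_proximal"):
            assert np.array_equal(out.segment("thigh").landmarks[name],
                                  model0.segment("thigh").landmarks[name])

    def test_rigidity_of_comoving_points(self, model0):
        out = apply_derotation_osteotomy(model0, "thigh", *PLANE,
                                         np.radians(40.0),
                                         translation=[0.01, 0.0, 0.005])
        pre = all_points(model0, "thigh")
        post = all_points(out, "thigh")
        distal = [k for k in pre
                  if (pre[k] - PLANE[0]) @ np.array(PLANE[1]) < 0]
        for i, a in enumerate(distal):
            for b in distal[i + 1:]:
                d0 = np.linalg.norm(pre[a] - pre[b])
                d1 = np.linalg.norm(post[a] - post[b])
                assert abs(d0 - d1) < 1e-10

    def test_input_model_never_mutated(self, model0):
        snapshot = {k: v.copy() for k, v in all_points(model0, "thigh").items()}
        out = apply_derotation_osteotomy(model0, "thigh", *PLANE, 0.5)
        assert out.lineage == model0.name
        for k, v in all_points(model0, "thigh").items():
            assert np.array_equal(v, snapshot[k])

    def test_missing_content_warns_identity(self, model0):
        with pytest.warns(UserWarning, match="misses"):
            out = apply_derotation_osteotomy(
                model0, "foot", [0, -9.0, 0], [0, 1, 0], 0.3)
        for k, v in all_points(model0, "foot").items():
            assert np.array_equal(v, all_points(out, "foot")[k])


class TestExtensionDerotation:
    def test_coincident_parallel_planes_are_identity(self, model0):
        out = apply_extension_derotation_osteotomy(
            model0, "thigh",
            ([0, -0.2, 0], [0, 1, 0]), ([0, -0.2, 0], [0, -1, 0]),
            wedge_shape="trapezoidal")
        for k, v in all_points(model0, "thigh").items():
            assert np.abs(v - all_points(out, "thigh")[k]).max() < 1e-12

    def test_wedge_rotation_equals_dihedral_angle(self, model0):
        """A 20-degree anterior wedge about the knee-transverse axis rotates
        the distal femur by exactly the dihedral angle (extension correction)."""
        ang = np.radians(20.0)
        na = np.array([0.0, -1.0, 0.0])  # interior normal: down into the wedge
        nb = rotation_about_axis([0, 0, 1.0], ang) @ np.array([0.0, 1.0, 0.0])
        out = apply_extension_derotation_osteotomy(
            model0, "thigh", ([0, -0.30, 0], na), ([0, -0.30, 0], nb),
            wedge_shape="triangular")
        p0 = np.array([0, -0.30, 0])
        # in-plane landmark: the rotation angle is read off directly
        v0 = model0.segment("thigh").landmarks["shaft_distal"]
        v1 = out.segment("thigh").landmarks["shaft_distal"]
        cosang = ((v0 - p0) @ (v1 - p0)) / (np.linalg.norm(v0 - p0)
                                            * np.linalg.norm(v1 - p0))
        assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) == pytest.approx(
            20.0, abs=1e-6)
        # every distal landmark follows the closing rotation about the apex
        R = rotation_about_axis([0.0, 0.0, -1.0], ang)
        for name in ("condyle_medial", "condyle_lateral", "shaft_distal"):
            w0 = model0.segment("thigh").landmarks[name]
            w1 = out.segment("thigh").landmarks[name]
            assert np.abs(w1 - (p0 + R @ (w0 - p0))).max() < 1e-10

    def test_trapezoidal_wedge_translates_by_offset(self, model0):
        offset = 0.02
        out = apply_extension_derotation_osteotomy(
            model0, "thigh",
            ([0, -0.28, 0], [0, -1.0, 0]),  # normals face each other: the
            ([0, -0.30, 0], [0, 1.0, 0]),   # 2 cm slab between them goes away
            wedge_shape="trapezoidal")
        v0 = model0.segment("thigh").landmarks["condyle_medial"]
        v1 = out.segment("thigh").landmarks["condyle_medial"]
        assert np.allclose(v1 - v0, [0.0, offset, 0.0], atol=1e-12)

    def test_attachment_in_wedge_is_a_hard_error(self, model0):
        # vasti distal via point sits at y=-0.38: cut a slab containing it
        with pytest.raises(SurgeryError, match="vasti_toy"):
            apply_extension_derotation_osteotomy(
                model0, "thigh",
                ([0, -0.37, 0], [0, -1.0, 0]), ([0, -0.39, 0], [0, 1.0, 0]),
                wedge_shape="trapezoidal")

    def test_shape_plane_consistency_enforced(self, model0):
        with pytest.raises(SurgeryError, match="parallel"):
            apply_extension_derotation_osteotomy(
                model0, "thigh", ([0, -0.3, 0], [0, 1, 0]),
                ([0, -0.3, 0], [0.3, -0.95, 0]), wedge_shape="trapezoidal")


class TestMuscleTransfer:
    def test_noop_keeps_tendon_slack_length(self, model0):
        out = apply_muscle_transfer(model0, "soleus_toy", [])
        assert out.muscle("soleus_toy").l_ts == model0.muscle("soleus_toy").l_ts

    def test_insertion_shift_changes_lts_by_polyline_delta(self, model0):
        """Moving the insertion distally along the straight line of action
        lengthens the path and the tendon by exactly that amount."""
        m = model0.muscle("soleus_toy")
        q0 = np.zeros(4)
        l0, _ = musculotendon_geometry(model0, q0)
        k = model0.muscle_names.index("soleus_toy")
        # direction of the last path segment at the reference posture
        from capgap.model import forward_kinematics

        poses = forward_kinematics(model0, q0)
        Ra, ta = poses[m.path[-2].segment]
        Rb, tb = poses[m.path[-1].segment]
        a = Ra @ m.path[-2].location + ta
        b = Rb @ m.path[-1].location + tb
        d_world = (b - a) / np.linalg.norm(b - a)
        new_world = b + 0.02 * d_world
        new_local = Rb.T @ (new_world - tb)
        out = apply_muscle_transfer(
            model0, "soleus_toy",
            [{"op": "move", "index": len(m.path) - 1,
              "location": new_local.tolist()}])
        assert out.muscle("soleus_toy").l_ts == pytest.approx(
            m.l_ts + 0.02, abs=1e-9)
        l1, _ = musculotendon_geometry(out, q0)
        assert l1[k] == pytest.approx(l0[k] + 0.02, abs=1e-9)

    def test_rectus_recipe_preserves_normalized_length(self, model0):
        """Two-step transfer (midpoint via pinned in the femur, insertion to
        the hamstrings insertion) leaves fiber operating length unchanged at
        the reference posture."""
        out = rectus_transfer(model0)
        q0 = np.zeros(4)
        k = model0.muscle_names.index("rectus_toy")
        l_pre, _ = musculotendon_geometry(model0, q0)
        l_post, _ = musculotendon_geometry(out, q0)
        m_pre, m_post = model0.muscle("rectus_toy"), out.muscle("rectus_toy")
        ln_pre = (l_pre[k] - m_pre.l_ts) / m_pre.l_mo
        ln_post = (l_post[k] - m_post.l_ts) / m_post.l_mo
        assert ln_post == pytest.approx(ln_pre, abs=1e-10)
        # fiber architecture untouched; insertion moved to the hamstrings'
        assert m_post.l_mo == m_pre.l_mo and m_post.F_max == m_pre.F_max
        assert np.array_equal(m_post.path[-1].location,
                              model0.muscle("hamstrings_toy").path[-1].location)

    def test_negative_tendon_rejected(self, model0):
        with pytest.raises(SurgeryError, match="negative tendon"):
            apply_muscle_transfer(model0, "soleus_toy", [],
                                  delta_l_ts=-10.0)


class TestPatellaAdvancement:
    def test_zero_delta_is_fixed_point(self, model0):
        out = apply_patella_advancement(model0, 0.0)
        assert np.abs(out.patella.path - model0.patella.path).max() < 1e-6

    def test_shortening_moves_patella_toward_insertion(self, model0):
        from capgap.surgery import _tibial_insertion_2d

        out = apply_patella_advancement(model0, -0.02)
        for row_old, row_new in zip(model0.patella.path, out.patella.path):
            ang = row_old[0]
            tib = _tibial_insertion_2d(model0, ang)
            d_old = np.linalg.norm(row_old[2:4] - tib)
            d_new = np.linalg.norm(row_new[2:4] - tib)
            assert d_new < d_old

    def test_ligament_length_constraint_holds_on_grid(self, model0):
        from capgap.surgery import (_patella_pose_points, _tibial_insertion_2d)

        out = apply_patella_advancement(model0, -0.02)
        p = out.patella
        for row in p.path:
            _, _, wl = _patella_pose_points(p, row[1:4])
            tib = _tibial_insertion_2d(out, row[0])
            assert abs(np.linalg.norm(wl - tib) - p.ligament_length) < 1e-6


class TestStrengthChange:
    def test_scale_one_is_identity(self, model0):
        out = apply_strength_change(model0, "gastroc_toy", 1.0)
        assert out.muscle("gastroc_toy").F_max == model0.muscle("gastroc_toy").F_max

    def test_release_zeroes_moment_contribution(self, model0, desired0):
        from capgap.tuning import linear_force_terms

        out = apply_strength_change(model0, "gastroc_toy", 0.0)
        c1, c0 = linear_force_terms(out, desired0.l_mt)
        k = out.muscle_names.index("gastroc_toy")
        assert np.all(c1[:, k] == 0.0) and np.all(c0[:, k] == 0.0)

    def test_half_scale_halves_max_active_moment(self, model0):
        q = np.zeros(4)
        _, r = musculotendon_geometry(model0, q)
        k = model0.muscle_names.index("soleus_toy")
        out = apply_strength_change(model0, "soleus_toy", 0.5)
        # max active moment is linear in F_max at any fixed posture
        m0, m1 = model0.muscle("soleus_toy"), out.muscle("soleus_toy")
        assert m1.F_max == pytest.approx(0.5 * m0.F_max, rel=1e-12)
        assert np.allclose(r[k] * m1.F_max, 0.5 * r[k] * m0.F_max, atol=1e-15)

    def test_out_of_range_scale_rejected(self, model0):
        with pytest.raises(SurgeryError):
            apply_strength_change(model0, "soleus_toy", 1.2)


class TestMorphometrics:
    def test_constructed_angles_recovered(self, model0):
        bm = bone_morphometrics(model0, "thigh")
        assert bm.anteversion_deg == pytest.approx(20.0, abs=1e-6)
        assert bm.neck_shaft_deg == pytest.approx(130.0, abs=1e-6)

    def test_collinear_neck_gives_180(self):
        m = make_toy_model(seed=0)
        seg = m.segment("thigh")
        seg.landmarks["femoral_head_center"] = (seg.landmarks["neck_base"]
                                                + np.array([0.0, 0.05, 0.0]))
        bm = bone_morphometrics(m, "thigh")
        assert bm.neck_shaft_deg == pytest.approx(180.0)

    def test_derotation_shifts_anteversion_by_the_angle(self, model0):
        out = apply_derotation_osteotomy(model0, "thigh", *PLANE,
                                         np.radians(20.0))
        assert bone_morphometrics(out, "thigh").anteversion_deg == pytest.approx(
            0.0, abs=1e-6)
        out2 = apply_derotation_osteotomy(model0, "thigh", *PLANE,
                                          np.radians(-20.0))
        assert bone_morphometrics(out2, "thigh").anteversion_deg == pytest.approx(
            40.0, abs=1e-6)

    def test_missing_landmark_named(self, model0):
        m = model0.copy()
        del m.segment("thigh").landmarks["neck_base"]
        with pytest.raises(Exception, match="neck_base"):
            bone_morphometrics(m, "thigh")


class TestPlans:
    def test_plan_equals_sequential_fold(self, model0):
        ops = [
            SurgeryOperation("derotation_osteotomy", "thigh",
                             {"plane": {"point": PLANE[0], "normal": PLANE[1]},
                              "angle": 0.3}),
            SurgeryOperation("strength_change", "gastroc_toy", {"scale": 0.5}),
        ]
        plan = SurgeryPlan(operations=ops, label="post")
        folded = model0
        for op in ops:
            folded = apply_operation(folded, op)
        planned = apply_plan(model0, plan)
        assert planned.muscle("gastroc_toy").F_max == folded.muscle("gastroc_toy").F_max
        for k, v in all_points(folded, "thigh").items():
            assert np.array_equal(v, all_points(planned, "thigh")[k])

    def test_provenance_records_operations(self, model0):
        plan = SurgeryPlan(operations=[
            SurgeryOperation("strength_change", "soleus_toy", {"scale": 0.0})])
        out = apply_plan(model0, plan)
        assert out.provenance[-1]["kind"] == "strength_change"
        assert out.lineage == model0.name
        assert out.label == "post-operative"

    def test_plan_file_round_trip_with_unit_conversion(self, tmp_path):
        plan = SurgeryPlan(label="post", operations=[
            SurgeryOperation("derotation_osteotomy", "thigh",
                             {"plane": {"point": [0, -0.2, 0],
                                        "normal": [0, 1, 0]},
                              "angle": np.radians(30.0)}),
            SurgeryOperation("patella_advancement", None,
                             {"delta_ligament_length": -0.02}),
        ])
        import yaml

        write_plan(plan, tmp_path / "p.yaml")
        disk = yaml.safe_load((tmp_path / "p.yaml").read_text())
        # degrees and centimeters at the file boundary
        assert disk["operations"][0]["parameters"]["angle"] == pytest.approx(30.0)
        assert disk["operations"][1]["parameters"][
            "delta_ligament_length"] == pytest.approx(-2.0)
        back = read_plan(tmp_path / "p.yaml")
        assert back.operations[0].parameters["angle"] == pytest.approx(
            np.radians(30.0))
        assert back.operations[1].parameters["delta_ligament_length"] == \
            pytest.approx(-0.02)


class TestDeformityInversion:
    def test_corrective_plan_restores_geometry_and_parameters(self, model0):
        patient, record = perturb_model(model0)
        corrected = apply_plan(patient, record["corrective_plan"])
        for s0, s1 in zip(model0.segments, corrected.segments):
            for k in s0.landmarks:
                assert np.abs(s0.landmarks[k] - s1.landmarks[k]).max() < 1e-9
        for m0, m1 in zip(model0.muscles, corrected.muscles):
            for p0, p1 in zip(m0.path, m1.path):
                assert np.abs(p0.location - p1.location).max() < 1e-9
            assert m1.l_ts == pytest.approx(m0.l_ts, abs=1e-12)

    def test_shortened_tendon_raises_normalized_length(self, model0):
        patient, record = perturb_model(model0)
        q = np.zeros(4)
        k = model0.muscle_names.index("hamstrings_toy")
        l_mt_pre, _ = musculotendon_geometry(model0, q)
        l_mt_pat, _ = musculotendon_geometry(patient, q)
        m0, m1 = model0.muscle("hamstrings_toy"), patient.muscle("hamstrings_toy")
        ln0 = (l_mt_pre[k] - m0.l_ts) / m0.l_mo
        ln1 = (l_mt_pat[k] - m1.l_ts) / m1.l_mo
        assert ln1 > ln0
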