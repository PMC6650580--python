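"""Parametric virtual orthopedic surgeries on the musculoskeletal model.

Five operators transform a pre-operative model into post-operative variants:
single-plane derotation osteotomy, two-plane extension+derotation osteotomy
(wedge removal), muscle transfer (path-point edits with tendon-slack-length
compensation), patella advancement (ligament shortening or re-insertion with
a planar pose optimization), and strength change (botulinum-toxin force
scaling; scale 0 encodes a muscle release). Operators never mutate their
input: each returns a new model whose ``lineage`` points at the parent and
whose ``provenance`` records the operation verbatim.

Conventions: cutting planes are given in the target segment's frame as
(point, unit normal). The "distal" half-space is the side not containing the
segment's own (proximal) joint center, overridable per operation. For the
two-plane osteotomy the normals must point into the wedge to be removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .errors import ConfigurationError, ModelError, SurgeryError
from .model import (
    MusculoskeletalModel,
    forward_kinematics,
    rotation_about_axis,
)

__all__ = [
    "SurgeryOperation",
    "SurgeryPlan",
    "BoneMorphometrics",
    "apply_derotation_osteotomy",
    "apply_extension_derotation_osteotomy",
    "apply_muscle_transfer",
    "apply_patella_advancement",
    "apply_strength_change",
    "apply_operation",
    "apply_plan",
    "bone_morphometrics",
    "rectus_transfer",
    "read_plan",
    "write_plan",
]


@dataclass
class SurgeryOperation:
    kind: str
    target: str | None = None
    parameters: dict = field(default_factory=dict)


@dataclass
class SurgeryPlan:
    operations: list[SurgeryOperation]
    label: str = "post-operative"


@dataclass
class BoneMorphometrics:
    anteversion_deg: float
    neck_shaft_deg: float


# ---------------------------------------------------------------------------
# Geometric helpers
# ---------------------------------------------------------------------------

def _unit(v) -> np.ndarray:
    v = np.asarray(v, float).reshape(3)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise SurgeryError("zero-length plane normal")
    return v / n


def _affine(R: np.ndarray, about: np.ndarray, t: np.ndarray):
    def f(x):
        return about + R @ (np.asarray(x, float) - about) + t
    return f


def _transform_segment_content(
    model: MusculoskeletalModel,
    segment: str,
    is_distal,
    point_map,
    rotation: np.ndarray,
) -> int:
    """Apply ``point_map`` to distal path points, landmarks, mesh vertices and
    child joint frames of ``segment``. Returns the number of moved points."""
    moved = 0
    seg = model.segment(segment)
    for m in model.muscles:
        for p in m.path:
            if p.segment == segment and is_distal(p.location):
                p.location = point_map(p.location)
                moved += 1
    for lname in list(seg.landmarks):
        if is_distal(seg.landmarks[lname]):
            seg.landmarks[lname] = point_map(seg.landmarks[lname])
            moved += 1
    if seg.mesh_vertices is not None:
        for i, v in enumerate(seg.mesh_vertices):
            if is_distal(v):
                seg.mesh_vertices[i] = point_map(v)
                moved += 1
    for child in model.segments:
        if child.parent == segment and is_distal(child.joint_center):
            child.joint_center = point_map(child.joint_center)
            # the joint platform reorients with the distal bone fragment, so
            # the whole distal chain follows the correction
            prev = child.joint_offset if child.joint_offset is not None else np.eye(3)
            child.joint_offset = rotation @ prev
            moved += 1
    return moved


def _default_distal_side(plane_point: np.ndarray, normal: np.ndarray) -> float:
    """Sign of the distal half-space: the side not containing the segment's
    own (proximal) joint, i.e. the local origin."""
    s0 = float(-np.dot(plane_point, normal))
    return 1.0 if s0 <= 0 else -1.0


# ---------------------------------------------------------------------------
# Osteotomies
# ---------------------------------------------------------------------------

def apply_derotation_osteotomy(
    model: MusculoskeletalModel,
    segment: str,
    plane_point,
    plane_normal,
    angle: float,
    translation=(0.0, 0.0, 0.0),
    distal_side: float | None = None,
) -> MusculoskeletalModel:
    """Single-plane osteotomy: rotate the distal bone part by ``angle`` (rad)
    about the plane normal through the plane point, plus an in-plane
    translation (m)."""
    if not -math.pi < angle < math.pi:
        raise SurgeryError(f"derotation angle {angle} rad outside (-pi, pi)")
    p = np.asarray(plane_point, float).reshape(3)
    n = _unit(plane_normal)
    t = np.asarray(translation, float).reshape(3)
    t = t - np.dot(t, n) * n  # in-plane component only
    side = distal_side if distal_side is not None else _default_distal_side(p, n)

    out = model.derive()
    out.name = f"{model.name}+derot"
    R = rotation_about_axis(n, angle)
    amap = _affine(R, p, t)

    def is_distal(x):
        return side * float(np.dot(np.asarray(x, float) - p, n)) > 0.0

    moved = _transform_segment_content(out, segment, is_distal, amap, R)
    if moved == 0:
        import warnings

        warnings.warn(f"cutting plane misses all content of segment {segment!r}; "
                      "identity transform", stacklevel=2)
    out.provenance.append(_op_to_dict(SurgeryOperation(
        kind="derotation_osteotomy", target=segment,
        parameters={"plane": {"point": p.tolist(), "normal": n.tolist()},
                    "angle": angle, "translation": t.tolist()})))
    return out


def apply_extension_derotation_osteotomy(
    model: MusculoskeletalModel,
    segment: str,
    plane_a,  # (point, normal) — proximal cut, normal into the wedge
    plane_b,  # (point, normal) — distal cut, normal into the wedge
    wedge_shape: str = "triangular",
    derotation: float = 0.0,
    translation=(0.0, 0.0, 0.0),
) -> MusculoskeletalModel:
    """Two-plane osteotomy: remove the bone wedge between the planes and
    reconnect by the rigid map taking plane b onto plane a, composed with a
    user derotation about the joined-plane normal and an in-plane translation.

    The wedge angle equals the dihedral angle between the planes; for
    parallel planes (``wedge_shape='trapezoidal'``) the closing map is the
    pure translation by the inter-plane offset.
    """
    pa, na = (np.asarray(plane_a[0], float), _unit(plane_a[1]))
    pb, nb = (np.asarray(plane_b[0], float), _unit(plane_b[1]))
    if wedge_shape not in ("triangular", "trapezoidal"):
        raise SurgeryError(f"unknown wedge shape {wedge_shape!r}")

    cross = np.cross(na, nb)
    parallel = np.linalg.norm(cross) < 1e-10
    if wedge_shape == "trapezoidal" and not parallel:
        raise SurgeryError("trapezoidal wedge requires parallel cutting planes")
    if wedge_shape == "triangular" and parallel:
        raise SurgeryError("triangular wedge requires non-parallel cutting planes")

    if parallel:
        R_close = np.eye(3)
        t_close = float(np.dot(pa - pb, nb)) * nb

        def close(x):
            return np.asarray(x, float) + t_close
    else:
        e = cross / np.linalg.norm(cross)  # intersection-line direction
        # point on the intersection line (least-norm solution)
        A = np.vstack([na, nb])
        b = np.array([np.dot(na, pa), np.dot(nb, pb)])
        p0 = np.linalg.lstsq(A, b, rcond=None)[0]
        target = -na
        theta = math.atan2(float(np.dot(np.cross(nb, target), e)),
                           float(np.dot(nb, target)))
        R_close = rotation_about_axis(e, theta)
        close = _affine(R_close, p0, np.zeros(3))

    t_user = np.asarray(translation, float).reshape(3)
    t_user = t_user - np.dot(t_user, na) * na
    R_derot = rotation_about_axis(na, derotation)
    derot = _affine(R_derot, pa, t_user)

    def classify(x):
        x = np.asarray(x, float)
        da = float(np.dot(x - pa, na))
        db = float(np.dot(x - pb, nb))
        if da <= 0.0:
            return "proximal"
        if db > 0.0:
            return "wedge"
        return "distal"

    out = model.derive()
    out.name = f"{model.name}+extderot"
    # attachments inside the wedge are a hard error: silently deleting them
    # would shorten the muscle without anyone noticing
    for m in out.muscles:
        for p in m.path:
            if p.segment == segment and classify(p.location) == "wedge":
                raise SurgeryError(
                    f"muscle {m.name!r} has a path point inside the resection wedge; "
                    "transfer it before the osteotomy")
    seg = out.segment(segment)
    if seg.mesh_vertices is not None:
        keep = np.array([classify(v) != "wedge" for v in seg.mesh_vertices])
        if not keep.all():
            remap = -np.ones(len(keep), dtype=int)
            remap[keep] = np.arange(keep.sum())
            faces = seg.mesh_faces
            fkeep = keep[faces].all(axis=1)
            seg.mesh_faces = remap[faces[fkeep]]
            seg.mesh_vertices = seg.mesh_vertices[keep]

    R_total = R_derot @ R_close

    def point_map(x):
        return derot(close(x))

    def is_distal(x):
        return classify(x) == "distal"

    _transform_segment_content(out, segment, is_distal, point_map, R_total)
    out.provenance.append(_op_to_dict(SurgeryOperation(
        kind="extension_derotation_osteotomy", target=segment,
        parameters={"plane_a": {"point": pa.tolist(), "normal": na.tolist()},
                    "plane_b": {"point": pb.tolist(), "normal": nb.tolist()},
                    "wedge_shape": wedge_shape, "derotation": derotation,
                    "translation": t_user.tolist()})))
    return out


# ---------------------------------------------------------------------------
# Muscle transfer
# ---------------------------------------------------------------------------

def _length_at(model: MusculoskeletalModel, muscle: str, q: np.ndarray) -> float:
    from .model import _muscle_lengths

    return float(_muscle_lengths(model, q)[model.muscle_names.index(muscle)])


def _resolve_posture(model: MusculoskeletalModel, reference_posture) -> np.ndarray:
    if reference_posture is None:
        return np.zeros(len(model.coordinates))
    if isinstance(reference_posture, dict):
        q = np.zeros(len(model.coordinates))
        for k, v in reference_posture.items():
            q[model.coordinate_names.index(k)] = v
        return q
    return np.asarray(reference_posture, float)


def apply_muscle_transfer(
    model: MusculoskeletalModel,
    muscle: str,
    point_edits: list[dict] | None = None,
    reference_posture=None,
    delta_l_ts: float = 0.0,
) -> MusculoskeletalModel:
    """Edit a muscle's path (add/remove/move points) and compensate the tendon
    slack length by the change in musculotendon length at the reference
    posture, so normalized fiber length there is preserved. Fiber architecture
    (l_mo, F_max, pennation) is untouched. ``delta_l_ts`` adds an explicit
    tendon lengthening (+) or shortening (-) on top, for pure tendon surgery.

    Edits: ``{"op": "move", "index": i, "location": [...], "segment": s?}``,
    ``{"op": "add_via", "index": i, "segment": s, "location": [...]}``,
    ``{"op": "remove", "index": i}``.
    """
    q_ref = _resolve_posture(model, reference_posture)
    l_old = _length_at(model, muscle, q_ref)
    out = model.derive()
    out.name = f"{model.name}+transfer"
    m = out.muscle(muscle)
    from .model import PathPoint

    for e in point_edits or []:
        op = e["op"]
        if op == "move":
            p = m.path[e["index"]]
            p.location = np.asarray(e["location"], float)
            if "segment" in e:
                p.segment = e["segment"]
        elif op == "add_via":
            m.path.insert(e["index"],
                          PathPoint(e["segment"], e["location"], role="via"))
        elif op == "remove":
            if m.path[e["index"]].role != "via":
                raise SurgeryError("only via points can be removed")
            del m.path[e["index"]]
        else:
            raise SurgeryError(f"unknown path edit {op!r}")
    roles = [p.role for p in m.path]
    if roles.count("origin") != 1 or roles.count("insertion") != 1:
        raise SurgeryError(f"edits left muscle {muscle!r} without a valid path")
    out.validate()
    l_new = _length_at(out, muscle, q_ref)
    l_ts_new = m.l_ts + (l_new - l_old) + delta_l_ts
    if l_ts_new < 0:
        raise SurgeryError(
            f"transfer of {muscle!r} would need negative tendon slack length "
            f"({l_ts_new:.4f} m)")
    m.l_ts = float(l_ts_new)
    out.provenance.append(_op_to_dict(SurgeryOperation(
        kind="muscle_transfer", target=muscle,
        parameters={"point_edits": point_edits or [],
                    "reference_posture": np.asarray(q_ref).tolist(),
                    "delta_l_ts": delta_l_ts})))
    return out


def rectus_transfer(
    model: MusculoskeletalModel,
    muscle: str = "rectus_toy",
    target_muscle: str = "hamstrings_toy",
    thigh_segment: str = "thigh",
    reference_posture=None,
) -> MusculoskeletalModel:
    """Canned rectus-femoris transfer: (1) pin a via point fixed in the thigh
    frame at the current path midpoint, (2) move the insertion to the
    target muscle's (semitendinosus-analog) insertion, keeping musculotendon
    length at the reference posture unchanged via the slack-length rule."""
    q_ref = _resolve_posture(model, reference_posture)
    poses = forward_kinematics(model, q_ref)
    m = model.muscle(muscle)
    pts = []
    for p in m.path:
        R, t = poses[p.segment]
        pts.append(R @ p.location + t)
    pts = np.asarray(pts)
    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seglen.sum()
    s = 0.0
    target_s = 0.5 * total
    mid_world = pts[0]
    insert_index = 1
    for i, L in enumerate(seglen):
        if s + L >= target_s:
            f = (target_s - s) / L
            mid_world = pts[i] * (1 - f) + pts[i + 1] * f
            insert_index = i + 1
            break
        s += L
    R_th, t_th = poses[thigh_segment]
    mid_local = R_th.T @ (mid_world - t_th)
    tgt = model.muscle(target_muscle)
    ins = tgt.path[-1]
    edits = [
        {"op": "add_via", "index": insert_index, "segment": thigh_segment,
         "location": mid_local.tolist()},
        {"op": "move", "index": len(m.path), "segment": ins.segment,
         "location": ins.location.tolist()},
    ]
    return apply_muscle_transfer(model, muscle, edits, reference_posture=q_ref)


# ---------------------------------------------------------------------------
# Patella advancement
# ---------------------------------------------------------------------------

def _rot2(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def _dist_to_polyline(p: np.ndarray, poly: np.ndarray) -> float:
    a = poly[:-1]
    b = poly[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom[denom == 0] = 1.0
    t = np.clip(np.einsum("ij,ij->i", p[None, :] - a, ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.min(np.linalg.norm(proj - p[None, :], axis=1)))


def _tibial_insertion_2d(model: MusculoskeletalModel, knee_angle: float) -> np.ndarray:
    """Ligament insertion in the knee plane (origin at the knee joint center)."""
    p = model.patella
    return _rot2(knee_angle) @ p.tibial_insertion[:2]


def _patella_pose_points(patella, x: np.ndarray):
    R = _rot2(x[0])
    tr = x[1:3]
    return (tr + R @ patella.prox_point, tr + R @ patella.dist_point,
            tr + R @ patella.ligament_point)


def _patella_solve_path(
    model: MusculoskeletalModel,
    angles: np.ndarray,
    pose_init: np.ndarray | None = None,
    d_ref: float | None = None,
    reg_weight: float = 0.05,
) -> np.ndarray:
    """Per-knee-angle planar patella pose: minimize the spread of the two
    point-to-femur-profile distances (plus a light pull keeping the mean
    clearance near its reference) subject to constant ligament length."""
    p = model.patella
    if p is None:
        raise ConfigurationError("model has no patella construct")
    if pose_init is None:
        if p.path is None or len(p.path) == 0:
            raise ConfigurationError("no initial patella pose available")
        x0 = p.path[0, 1:4].copy()
    else:
        x0 = np.asarray(pose_init, float).copy()
    if d_ref is None:
        w1, w2, _ = _patella_pose_points(p, x0)
        d_ref = 0.5 * (_dist_to_polyline(w1, p.femoral_profile)
                       + _dist_to_polyline(w2, p.femoral_profile))
    out = np.empty((len(angles), 4))
    for i, ang in enumerate(angles):
        tib = _tibial_insertion_2d(model, float(ang))

        def objective(x):
            w1, w2, _ = _patella_pose_points(p, x)
            d1 = _dist_to_polyline(w1, p.femoral_profile)
            d2 = _dist_to_polyline(w2, p.femoral_profile)
            return (d1 - d2) ** 2 + reg_weight * (0.5 * (d1 + d2) - d_ref) ** 2

        def lig_constraint(x):
            _, _, wl = _patella_pose_points(p, x)
            return float(np.linalg.norm(wl - tib)) - p.ligament_length

        res = minimize(objective, x0, method="SLSQP",
                       constraints=[{"type": "eq", "fun": lig_constraint}],
                       options={"maxiter": 200, "ftol": 1e-14})
        if abs(lig_constraint(res.x)) > 1e-6:
            raise SurgeryError(
                f"patella ligament length constraint infeasible at knee angle "
                f"{float(ang):.3f} rad")
        out[i] = [float(ang), *res.x]
        x0 = res.x.copy()
    return out


def apply_patella_advancement(
    model: MusculoskeletalModel,
    delta_ligament_length: float = 0.0,
    new_insertion=None,
) -> MusculoskeletalModel:
    """Shorten/lengthen the patellar ligament and/or move its tibial
    insertion, then recompute the patella path over the knee angle grid."""
    if model.patella is None:
        raise ConfigurationError("model has no patella construct")
    out = model.derive()
    out.name = f"{model.name}+patella"
    p = out.patella
    p.ligament_length = float(p.ligament_length + delta_ligament_length)
    if p.ligament_length <= 0:
        raise SurgeryError("patella ligament length must stay positive")
    if new_insertion is not None:
        p.tibial_insertion = np.asarray(new_insertion, float).reshape(3)
    angles = (p.path[:, 0] if p.path is not None
              else np.linspace(0.0, 1.2, 13))
    x0 = p.path[0, 1:4] if p.path is not None else None
    p.path = _patella_solve_path(out, np.asarray(angles, float), pose_init=x0)
    out.provenance.append(_op_to_dict(SurgeryOperation(
        kind="patella_advancement", target=None,
        parameters={"delta_ligament_length": delta_ligament_length,
                    "new_insertion": (None if new_insertion is None
                                      else np.asarray(new_insertion).tolist())})))
    return out


# ---------------------------------------------------------------------------
# Strength change (botulinum toxin / release)
# ---------------------------------------------------------------------------

def apply_strength_change(model: MusculoskeletalModel, muscle: str,
                          scale: float) -> MusculoskeletalModel:
    """Scale a muscle's maximum isometric force; scale 0 encodes a release."""
    if not 0.0 <= scale <= 1.0:
        raise SurgeryError(f"strength scale {scale} outside [0, 1]")
    out = model.derive()
    out.name = f"{model.name}+strength"
    try:
        m = out.muscle(muscle)
    except ModelError as e:
        raise ConfigurationError(str(e)) from None
    m.F_max = float(m.F_max * scale)
    out.provenance.append(_op_to_dict(SurgeryOperation(
        kind="strength_change", target=muscle, parameters={"scale": scale})))
    return out


# ---------------------------------------------------------------------------
# Morphometrics
# ---------------------------------------------------------------------------

_MORPHO_LANDMARKS = ["femoral_head_center", "neck_base", "shaft_proximal",
                     "shaft_distal", "condyle_medial", "condyle_lateral"]


def bone_morphometrics(model: MusculoskeletalModel, segment: str) -> BoneMorphometrics:
    """Femoral anteversion and neck-shaft angles from named landmarks.

    Anteversion: signed angle from the condylar axis to the neck axis, both
    projected onto the plane perpendicular to the shaft axis. Neck-shaft:
    angle between the neck axis and the distal shaft direction (collinear
    neck and shaft give 180 degrees).
    """
    seg = model.segment(segment)
    for name in _MORPHO_LANDMARKS:
        if name not in seg.landmarks:
            raise ConfigurationError(f"segment {segment!r} missing landmark {name!r}")
    lm = seg.landmarks
    shaft = lm["shaft_proximal"] - lm["shaft_distal"]
    s = shaft / np.linalg.norm(shaft)  # proximal direction
    neck = lm["femoral_head_center"] - lm["neck_base"]
    n = neck / np.linalg.norm(neck)
    cond = lm["condyle_lateral"] - lm["condyle_medial"]
    c = cond / np.linalg.norm(cond)
    nsa = math.degrees(math.acos(np.clip(np.dot(n, -s), -1.0, 1.0)))
    n_p = n - np.dot(n, s) * s
    c_p = c - np.dot(c, s) * s
    if np.linalg.norm(n_p) < 1e-12 or np.linalg.norm(c_p) < 1e-12:
        av = 0.0
    else:
        av = math.degrees(math.atan2(float(np.dot(np.cross(c_p, n_p), s)),
                                     float(np.dot(c_p, n_p))))
    return BoneMorphometrics(anteversion_deg=av, neck_shaft_deg=nsa)


# ---------------------------------------------------------------------------
# Plans, dispatch, serialization
# ---------------------------------------------------------------------------

def apply_operation(model: MusculoskeletalModel, op: SurgeryOperation
                    ) -> MusculoskeletalModel:
    prm = op.parameters
    if op.kind == "derotation_osteotomy":
        return apply_derotation_osteotomy(
            model, op.target, prm["plane"]["point"], prm["plane"]["normal"],
            prm["angle"], prm.get("translation", (0, 0, 0)),
            prm.get("distal_side"))
    if op.kind == "extension_derotation_osteotomy":
        return apply_extension_derotation_osteotomy(
            model, op.target,
            (prm["plane_a"]["point"], prm["plane_a"]["normal"]),
            (prm["plane_b"]["point"], prm["plane_b"]["normal"]),
            prm.get("wedge_shape", "triangular"),
            prm.get("derotation", 0.0), prm.get("translation", (0, 0, 0)))
    if op.kind == "muscle_transfer":
        return apply_muscle_transfer(
            model, op.target, prm.get("point_edits"),
            prm.get("reference_posture"), prm.get("delta_l_ts", 0.0))
    if op.kind == "patella_advancement":
        return apply_patella_advancement(
            model, prm.get("delta_ligament_length", 0.0),
            prm.get("new_insertion"))
    if op.kind == "strength_change":
        return apply_strength_change(model, op.target, prm["scale"])
    raise ConfigurationError(f"unknown surgery kind {op.kind!r}")


def apply_plan(model: MusculoskeletalModel, plan: SurgeryPlan) -> MusculoskeletalModel:
    """Fold the plan's operations sequentially; lineage points back at the
    original pre-operative model."""
    out = model
    for op in plan.operations:
        out = apply_operation(out, op)
    out.lineage = model.name
    out.label = plan.label
    return out


def _op_to_dict(op: SurgeryOperation) -> dict:
    return {"kind": op.kind, "target": op.target, "parameters": op.parameters}


_ANGLE_KEYS = {"angle", "derotation"}
_CM_KEYS = {"delta_ligament_length", "delta_l_ts"}


def _convert(prm: dict, to_internal: bool) -> dict:
    out = {}
    for k, v in prm.items():
        if k in _ANGLE_KEYS:
            out[k] = math.radians(v) if to_internal else math.degrees(v)
        elif k in _CM_KEYS:
            out[k] = v / 100.0 if to_internal else v * 100.0
        else:
            out[k] = v
    return out


def read_plan(path) -> SurgeryPlan:
    """Surgery plan file: YAML list of operations; angles in degrees and
    tendon/ligament length changes in centimeters at the file boundary."""
    import yaml

    with open(path) as fh:
        d = yaml.safe_load(fh)
    ops = [SurgeryOperation(kind=o["kind"], target=o.get("target"),
                            parameters=_convert(o.get("parameters", {}), True))
           for o in d["operations"]]
    return SurgeryPlan(operations=ops, label=d.get("label", "post-operative"))


def write_plan(plan: SurgeryPlan, path) -> None:
    import yaml

    d = {"label": plan.label,
         "operations": [{"kind": o.kind, "target": o.target,
                         "parameters": _convert(o.parameters, False)}
                        for o in plan.operations]}
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
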