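"""Musculoskeletal model core: kinematic chain, polyline muscle paths, and
rigid-tendon Hill muscle mechanics.

The model is a tree of segments connected by single-axis rotational joints.
Each non-root segment carries one generalized coordinate (its joint angle, in
radians). Muscle-tendon actuators are polylines of path points fixed in
segment frames; musculotendon length is the summed Euclidean length of the
polyline after forward kinematics, and moment arms follow the tendon-excursion
definition r_jm = -dl_mt/dq_j.

Muscle force uses a rigid tendon: fiber length l = (l_mt - l_ts)/cos(alpha),
normalized by the optimal fiber length l_mo. "M" (tuned) muscles produce
F = F_max * (a * fL(l_norm) + fP(l_norm)); "N" muscles produce F = F_max * a
with no length dependence. There is deliberately no force-velocity relation
and no activation dynamics.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DomainError, InfeasibleGeometryError, ModelError

__all__ = [
    "Segment",
    "JointCoordinate",
    "PathPoint",
    "MuscleTendonActuator",
    "MuscleCurveSet",
    "PatellaConstruct",
    "MusculoskeletalModel",
    "MuscleState",
    "rotation_about_axis",
    "forward_kinematics",
    "musculotendon_geometry",
    "fiber_state",
    "evaluate_curve",
    "muscle_force",
]

_FD_STEP = 1e-6  # rad, central-difference step for tendon-excursion moment arms


def _vec3(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).reshape(3)
    return a


@dataclass
class Segment:
    """Rigid body attached to its parent by a hinge joint.

    ``joint_axis`` and ``joint_center`` are expressed in the parent frame;
    ``landmarks`` (used for morphometrics) and ``mesh`` vertices live in the
    segment's own frame.
    """

    name: str
    parent: str | None
    joint_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    joint_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    landmarks: dict[str, np.ndarray] = field(default_factory=dict)
    mesh_vertices: np.ndarray | None = None  # (n, 3) in local frame
    mesh_faces: np.ndarray | None = None  # (m, 3) int
    # fixed rotation of the joint platform in the parent frame; osteotomies on
    # the parent bone update it so distal reorientation propagates down-chain
    joint_offset: np.ndarray | None = None  # 3x3, None = identity

    def __post_init__(self):
        self.joint_axis = _vec3(self.joint_axis)
        self.joint_center = _vec3(self.joint_center)
        self.landmarks = {k: _vec3(v) for k, v in self.landmarks.items()}
        if self.joint_offset is not None:
            self.joint_offset = np.asarray(self.joint_offset, float).reshape(3, 3)
        n = np.linalg.norm(self.joint_axis)
        if abs(n - 1.0) > 1e-9:
            raise ModelError(
                f"segment {self.name!r}: joint_axis must be unit length (|axis|={n:.12g})"
            )


@dataclass
class JointCoordinate:
    """Generalized coordinate (joint angle, rad) actuating one segment."""

    name: str
    segment: str
    range: tuple[float, float] = (-np.pi, np.pi)

    def __post_init__(self):
        lo, hi = self.range
        if not lo < hi:
            raise ModelError(f"coordinate {self.name!r}: range min must be < max")


@dataclass
class PathPoint:
    segment: str
    location: np.ndarray
    role: str = "via"  # origin | via | insertion

    def __post_init__(self):
        self.location = _vec3(self.location)
        if self.role not in ("origin", "via", "insertion"):
            raise ModelError(f"invalid path-point role {self.role!r}")


@dataclass
class MuscleTendonActuator:
    name: str
    path: list[PathPoint]
    F_max: float  # N
    l_mo: float  # optimal fiber length, m
    l_ts: float  # tendon slack length, m
    alpha: float = 0.0  # pennation angle, rad
    subset: str = "M"  # M: tuned, full force-length; N: activation-proportional

    def __post_init__(self):
        if self.F_max < 0:
            raise ModelError(f"muscle {self.name!r}: F_max must be >= 0")
        if self.l_mo <= 0:
            raise ModelError(f"muscle {self.name!r}: l_mo must be > 0")
        if self.l_ts < 0:
            raise ModelError(f"muscle {self.name!r}: l_ts must be >= 0")
        if not 0 <= self.alpha < np.pi / 2:
            raise ModelError(f"muscle {self.name!r}: alpha must be in [0, pi/2)")
        if self.subset not in ("M", "N"):
            raise ModelError(f"muscle {self.name!r}: subset must be 'M' or 'N'")
        roles = [p.role for p in self.path]
        if roles.count("origin") != 1 or roles.count("insertion") != 1:
            raise ModelError(
                f"muscle {self.name!r}: path needs exactly one origin and one insertion"
            )
        if roles[0] != "origin" or roles[-1] != "insertion":
            raise ModelError(
                f"muscle {self.name!r}: path must start at origin and end at insertion"
            )


@dataclass
class MuscleCurveSet:
    """Normalized active and passive force-length curves.

    Active: Gaussian bump exp(-((l_norm-1)/width)^2), peaking at 1 with value 1.
    Passive: (exp(k*(l_norm-1)/eps) - 1)/(exp(k) - 1) for l_norm > 1, else 0.
    With the defaults k=4, eps=0.6 the passive force at l_norm = 1.5 is ~0.50,
    the calibration anchor used throughout: a muscle stretched to 1.5 optimal
    fiber lengths exerts about half its maximum isometric force passively.
    """

    active_width: float = 0.45
    passive_k: float = 4.0
    passive_eps: float = 0.6

    def active(self, l_norm):
        l_norm = np.asarray(l_norm, dtype=float)
        return np.exp(-(((l_norm - 1.0) / self.active_width) ** 2))

    def passive(self, l_norm):
        l_norm = np.asarray(l_norm, dtype=float)
        x = np.clip(l_norm - 1.0, 0.0, None)
        denom = np.expm1(self.passive_k)
        return np.expm1(self.passive_k * x / self.passive_eps) / denom


@dataclass
class PatellaConstruct:
    """Planar patella mechanism in the plane perpendicular to the knee axis.

    All 2D coordinates are in the femur's knee plane (origin at the knee joint
    center, axes spanning the plane). The patella is a rigid 2D body with two
    femur-facing tracking points and a ligament attachment point in its local
    frame; the ligament runs to an insertion fixed on the tibia. The femoral
    surface is a 2D polyline profile.
    """

    femur_segment: str
    tibia_segment: str
    knee_coordinate: str
    prox_point: np.ndarray  # patella-local 2D
    dist_point: np.ndarray  # patella-local 2D
    ligament_point: np.ndarray  # patella-local 2D
    ligament_length: float  # m
    tibial_insertion: np.ndarray  # tibia-local 3D
    femoral_profile: np.ndarray  # (n, 2) polyline in femur knee plane
    path: np.ndarray | None = None  # (n_angles, 4): knee angle, theta, tx, ty

    def __post_init__(self):
        self.prox_point = np.asarray(self.prox_point, float).reshape(2)
        self.dist_point = np.asarray(self.dist_point, float).reshape(2)
        self.ligament_point = np.asarray(self.ligament_point, float).reshape(2)
        self.tibial_insertion = _vec3(self.tibial_insertion)
        self.femoral_profile = np.asarray(self.femoral_profile, float)
        if self.path is not None:
            self.path = np.asarray(self.path, float)


@dataclass
class MusculoskeletalModel:
    segments: list[Segment]
    coordinates: list[JointCoordinate]
    muscles: list[MuscleTendonActuator]
    curves: MuscleCurveSet = field(default_factory=MuscleCurveSet)
    lineage: str | None = None
    label: str = "pre-operative"
    name: str = "model"
    patella: PatellaConstruct | None = None
    provenance: list = field(default_factory=list)  # applied surgery ops, verbatim

    def __post_init__(self):
        self.validate()

    # -- lookups -----------------------------------------------------------
    def segment(self, name: str) -> Segment:
        for s in self.segments:
            if s.name == name:
                return s
        raise ModelError(f"unknown segment {name!r}")

    def muscle(self, name: str) -> MuscleTendonActuator:
        for m in self.muscles:
            if m.name == name:
                return m
        raise ModelError(f"unknown muscle {name!r}")

    @property
    def muscle_names(self) -> list[str]:
        return [m.name for m in self.muscles]

    @property
    def coordinate_names(self) -> list[str]:
        return [c.name for c in self.coordinates]

    def coordinate(self, name: str) -> JointCoordinate:
        for c in self.coordinates:
            if c.name == name:
                return c
        raise ModelError(f"unknown coordinate {name!r}")

    def validate(self) -> None:
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ModelError("duplicate segment names")
        name_set = set(names)
        roots = [s for s in self.segments if s.parent is None]
        if len(roots) != 1:
            raise ModelError(f"model must have exactly one root segment, found {len(roots)}")
        # acyclicity / resolvable parents
        for s in self.segments:
            if s.parent is not None and s.parent not in name_set:
                raise ModelError(f"segment {s.name!r}: unknown parent {s.parent!r}")
        seen: set[str] = set()
        for s in self.segments:
            chain = []
            cur: Segment | None = s
            while cur is not None:
                if cur.name in chain:
                    raise ModelError(f"cycle in segment tree through {cur.name!r}")
                chain.append(cur.name)
                cur = self.segment(cur.parent) if cur.parent is not None else None
            seen.update(chain)
        mnames = [m.name for m in self.muscles]
        if len(set(mnames)) != len(mnames):
            raise ModelError("duplicate muscle names")
        for m in self.muscles:
            for p in m.path:
                if p.segment not in name_set:
                    raise ModelError(
                        f"muscle {m.name!r}: path point references unknown segment {p.segment!r}"
                    )
        for c in self.coordinates:
            if c.segment not in name_set:
                raise ModelError(f"coordinate {c.name!r}: unknown segment {c.segment!r}")

    def copy(self) -> "MusculoskeletalModel":
        return copy.deepcopy(self)

    def derive(self, label: str = "post-operative") -> "MusculoskeletalModel":
        """Deep copy with lineage pointing back at this model."""
        child = self.copy()
        child.lineage = self.name
        child.label = label
        return child


@dataclass
class MuscleState:
    a: float
    l_mt: float
    l: float
    l_norm: float
    F: float


# ---------------------------------------------------------------------------
# Forward kinematics and geometry
# ---------------------------------------------------------------------------

def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix for a unit axis."""
    axis = _vec3(axis)
    c, s = np.cos(angle), np.sin(angle)
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) * c + s * K + (1.0 - c) * np.outer(axis, axis)


def _coordinate_map(model: MusculoskeletalModel) -> dict[str, float]:
    return {c.segment: i for i, c in enumerate(model.coordinates)}


def forward_kinematics(
    model: MusculoskeletalModel, q: np.ndarray
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Pose (R, t) of every segment frame in the ground frame.

    ``q`` is ordered as ``model.coordinates``. Segments without a coordinate
    are rigidly attached to their parent at the joint center.
    """
    q = np.asarray(q, dtype=float).reshape(len(model.coordinates))
    seg_coord = _coordinate_map(model)
    poses: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def pose_of(seg: Segment) -> tuple[np.ndarray, np.ndarray]:
        if seg.name in poses:
            return poses[seg.name]
        if seg.parent is None:
            Rp, tp = np.eye(3), np.zeros(3)
        else:
            Rp, tp = pose_of(model.segment(seg.parent))
        idx = seg_coord.get(seg.name)
        Rj = rotation_about_axis(seg.joint_axis, q[int(idx)]) if idx is not None else np.eye(3)
        Ro = seg.joint_offset if seg.joint_offset is not None else np.eye(3)
        R = Rp @ Ro @ Rj
        t = Rp @ seg.joint_center + tp
        poses[seg.name] = (R, t)
        return poses[seg.name]

    for s in model.segments:
        pose_of(s)
    return poses


def _check_ranges(model: MusculoskeletalModel, q: np.ndarray) -> None:
    q = np.asarray(q, dtype=float)
    for i, c in enumerate(model.coordinates):
        lo, hi = c.range
        if not (lo - 1e-12 <= q[i] <= hi + 1e-12):
            raise DomainError(
                f"coordinate {c.name!r}: value {q[i]:.6g} rad outside range [{lo:.6g}, {hi:.6g}]"
            )


def _muscle_lengths(model: MusculoskeletalModel, q: np.ndarray) -> np.ndarray:
    poses = forward_kinematics(model, q)
    out = np.empty(len(model.muscles))
    for k, m in enumerate(model.muscles):
        pts = np.empty((len(m.path), 3))
        for j, p in enumerate(m.path):
            R, t = poses[p.segment]
            pts[j] = R @ p.location + t
        out[k] = np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))
    return out


def musculotendon_geometry(
    model: MusculoskeletalModel, q: np.ndarray, check_range: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Musculotendon lengths and tendon-excursion moment arms at posture q.

    Returns ``(l_mt, r)`` with ``l_mt`` shaped (n_muscles,) and ``r`` shaped
    (n_muscles, n_coordinates); ``r[m, j] = -dl_mt[m]/dq[j]`` by central
    finite differences, so a positive moment arm contributes a positive
    generalized moment about coordinate j.
    """
    q = np.asarray(q, dtype=float).reshape(len(model.coordinates))
    if check_range:
        _check_ranges(model, q)
    l_mt = _muscle_lengths(model, q)
    n_j = len(model.coordinates)
    r = np.zeros((len(model.muscles), n_j))
    for j in range(n_j):
        dq = np.zeros(n_j)
        dq[j] = _FD_STEP
        lp = _muscle_lengths(model, q + dq)
        lm = _muscle_lengths(model, q - dq)
        r[:, j] = -(lp - lm) / (2.0 * _FD_STEP)
    return l_mt, r


# ---------------------------------------------------------------------------
# Rigid-tendon Hill mechanics
# ---------------------------------------------------------------------------

def fiber_state(l_mt: float, actuator: MuscleTendonActuator) -> tuple[float, float]:
    """Fiber length and normalized fiber length under the rigid-tendon map.

    l = (l_mt - l_ts)/cos(alpha); l_norm = l/l_mo. Exact algebra, no clamping.
    """
    if l_mt <= actuator.l_ts:
        raise InfeasibleGeometryError(actuator.name, float(l_mt), actuator.l_ts)
    l = (l_mt - actuator.l_ts) / np.cos(actuator.alpha)
    return float(l), float(l / actuator.l_mo)


def evaluate_curve(curves: MuscleCurveSet, kind: str, l_norm):
    """Normalized active or passive force at normalized fiber length."""
    if np.any(np.asarray(l_norm) <= 0):
        raise DomainError("l_norm must be > 0")
    if kind == "active":
        return curves.active(l_norm)
    if kind == "passive":
        return curves.passive(l_norm)
    raise DomainError(f"unknown curve kind {kind!r} (expected 'active' or 'passive')")


def muscle_force(
    actuator: MuscleTendonActuator,
    curves: MuscleCurveSet,
    a: float,
    l_norm: float | None = None,
) -> float:
    """Tendon force of one actuator at activation ``a``.

    Subset M: F_max * (a * fL(l_norm) + fP(l_norm)). Subset N: F_max * a,
    independent of fiber length.
    """
    if not 0.0 <= a <= 1.0:
        raise DomainError(f"activation {a} outside [0, 1]")
    if actuator.subset == "N":
        return actuator.F_max * a
    if l_norm is None:
        raise DomainError("l_norm is required for subset-M muscles")
    fl = float(curves.active(l_norm))
    fp = float(curves.passive(l_norm))
    return actuator.F_max * (a * fl + fp)
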