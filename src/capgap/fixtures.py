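"""Seeded synthetic fixtures: toy models, gait trials, ROM exams, deformities.

Desk-scale stand-ins for clinical inputs so the whole pipeline is testable
with no external data. The toy model is a planar lower-limb analog (pelvis,
femur with a separate flexion carrier so the hip has both flexion and
long-axis rotation, shank, foot) actuated by eight muscles including
biarticular rectus-femoris, hamstrings and gastrocnemius analogs. Synthetic
trials are built generatively: smooth periodic joint angles, activations
from a known low-rank synergy product W*H*, muscle forces through the
rigid-tendon Hill model, and joint moments defined as the resulting muscle
moment sums — so a zero-reserve solution exists by construction and every
recovery test has exact ground truth. EMG envelopes are the measured
activations plus optional Gaussian noise, clipped at zero and
peak-normalized.

The fiber parameters of the tuned muscles are calibrated from the nominal
cycle so that, under the true parameters, normalized fiber length crosses 1
during gait, stays inside [0.4, 1.5], and reaches ~1.42 in the
range-of-motion tests — the operating conditions the tuning stage assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    JointCoordinate,
    MuscleCurveSet,
    MusculoskeletalModel,
    MuscleTendonActuator,
    PatellaConstruct,
    PathPoint,
    Segment,
)
from .trial import (
    ReferenceGaitTemplate,
    ROMAssessment,
    TrialBundle,
    derive_trial_geometry,
)
from .model import forward_kinematics

__all__ = [
    "ToyModelSpec",
    "SyntheticTrialSpec",
    "DeformitySpec",
    "GroundTruth",
    "make_toy_model",
    "default_rom_assessment",
    "generate_rom_assessment",
    "generate_synthetic_trial",
    "make_reference_template",
    "true_motor_control",
    "perturb_model",
]

COORDS = ["hip_flexion", "hip_rotation", "knee_flexion", "ankle_flexion"]
TUNED = ["glutmax_toy", "vasti_toy", "rectus_toy", "hamstrings_toy",
         "gastroc_toy", "soleus_toy"]


@dataclass
class ToyModelSpec:
    """Parameter ranges for the toy model generator."""

    f_max_range: tuple[float, float] = (600.0, 1500.0)
    l_mo_jitter: float = 0.02  # multiplicative, uniform +-
    # normalized fiber length reached at the clinical end range: just below
    # 1.5, where passive force approaches half the maximum isometric force
    rom_target_lnorm: float = 1.48
    anteversion_deg: float = 20.0
    neck_shaft_deg: float = 130.0


@dataclass
class SyntheticTrialSpec:
    n_cycles: int = 3
    points_per_cycle: int = 51
    k_true: int = 3
    emg_noise_sd: float = 0.0
    measured_channels: list[str] | None = None  # default: all muscles, 1:1
    kinematic_jitter: float = 0.03  # relative amplitude jitter per harmonic


@dataclass
class DeformitySpec:
    derotation_deg: float = 30.0  # internal long-axis femoral derotation
    hamstring_lts_shortening: float = 0.006  # m, tendon shortening of the hamstrings analog


@dataclass
class GroundTruth:
    activations: np.ndarray  # (F, M), clipped product
    product: np.ndarray  # (F, M), pre-clip W*H
    W_true: np.ndarray  # (M, k)
    H_true: np.ndarray  # (k, F)
    l_mo: dict[str, float]
    l_ts: dict[str, float]
    F_max: dict[str, float]
    sigma_true: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Nominal gait kinematics (radians; periodic in the cycle phase)
# ---------------------------------------------------------------------------

_HARMONICS = {
    # coordinate: list of (harmonic order, amplitude, phase) plus constant
    "hip_flexion": (0.15, [(1, 0.35, 0.25)]),
    "hip_rotation": (0.0, [(1, 0.06, 1.2)]),
    # knee flexion is negative rotation about z in this chain
    "knee_flexion": (-0.42, [(1, -0.22, -0.35), (2, -0.14, 0.95)]),
    "ankle_flexion": (0.02, [(1, 0.16, 2.1), (2, 0.06, -0.7)]),
}


def nominal_gait(phase: np.ndarray, amp_scale: dict[str, list[float]] | None = None
                 ) -> np.ndarray:
    """Joint angles (rad) at cycle phase(s) in [0, 2*pi); columns = COORDS."""
    phase = np.atleast_1d(np.asarray(phase, float))
    out = np.empty((len(phase), len(COORDS)))
    for j, name in enumerate(COORDS):
        const, harms = _HARMONICS[name]
        v = np.full(len(phase), const)
        for h, (order, amp, ph) in enumerate(harms):
            s = 1.0 if amp_scale is None else amp_scale[name][h]
            v = v + s * amp * np.cos(order * phase + ph)
        out[:, j] = v
    return out


# ---------------------------------------------------------------------------
# Toy model
# ---------------------------------------------------------------------------

def _toy_segments(spec: ToyModelSpec) -> list[Segment]:
    av = np.radians(spec.anteversion_deg)
    nsa = np.radians(spec.neck_shaft_deg)
    # femoral neck axis from the neck-shaft and anteversion angles: shaft runs
    # along -y (distal); the neck leaves the shaft at gamma = pi - nsa from +y,
    # swung out of the condylar (z) direction by the anteversion about y
    gamma = np.pi - nsa
    u = np.cos(av) * np.array([0.0, 0.0, 1.0]) + np.sin(av) * np.array([1.0, 0.0, 0.0])
    neck_dir = np.cos(gamma) * np.array([0.0, 1.0, 0.0]) + np.sin(gamma) * u
    neck_base = np.array([0.0, -0.05, 0.0])
    head = neck_base + 0.055 * neck_dir
    thigh_landmarks = {
        "femoral_head_center": head,
        "neck_base": neck_base,
        "shaft_proximal": np.array([0.0, -0.05, 0.0]),
        "shaft_distal": np.array([0.0, -0.35, 0.0]),
        "condyle_medial": np.array([0.0, -0.40, -0.04]),
        "condyle_lateral": np.array([0.0, -0.40, 0.04]),
        "thigh_marker": np.array([0.03, -0.22, 0.0]),
    }
    return [
        Segment("pelvis", None, landmarks={
            "pelvis_marker_r": np.array([0.10, 0.02, 0.05]),
            "pelvis_marker_l": np.array([0.10, 0.02, -0.05]),
        }),
        # massless carrier so the hip has flexion (z) then long-axis rotation (y)
        Segment("thigh_flex", "pelvis", joint_axis=[0, 0, 1], joint_center=[0, 0, 0]),
        Segment("thigh", "thigh_flex", joint_axis=[0, 1, 0], joint_center=[0, 0, 0],
                landmarks=thigh_landmarks),
        Segment("shank", "thigh", joint_axis=[0, 0, 1], joint_center=[0, -0.40, 0],
                landmarks={
                    "shank_marker": np.array([0.03, -0.20, 0.0]),
                    "ankle_marker": np.array([0.0, -0.40, 0.03]),
                }),
        Segment("foot", "shank", joint_axis=[0, 0, 1], joint_center=[0, -0.40, 0],
                landmarks={
                    "toe_marker": np.array([0.14, -0.03, 0.0]),
                    "heel_marker": np.array([-0.05, -0.03, 0.01]),
                }),
    ]


def _toy_coordinates() -> list[JointCoordinate]:
    return [
        JointCoordinate("hip_flexion", "thigh_flex", range=(-1.0, 2.0)),
        JointCoordinate("hip_rotation", "thigh", range=(-1.0, 1.0)),
        JointCoordinate("knee_flexion", "shank", range=(-2.0, 0.6)),
        JointCoordinate("ankle_flexion", "foot", range=(-1.0, 1.0)),
    ]


def _toy_muscle_paths() -> dict[str, tuple[list[tuple[str, list[float]]], str]]:
    """name -> (path [(segment, xyz)], subset)."""
    return {
        "iliopsoas_toy": ([("pelvis", [0.04, 0.04, 0.0]),
                           ("thigh", [0.025, -0.10, 0.0])], "N"),
        "glutmax_toy": ([("pelvis", [-0.06, 0.03, 0.0]),
                         ("thigh", [-0.03, -0.14, 0.0])], "M"),
        # anterior distal via points act as the patellar pulley so knee
        # flexion lengthens the extensors monotonically
        "vasti_toy": ([("thigh", [0.045, -0.12, 0.0]),
                       ("thigh", [0.055, -0.38, 0.0]),
                       ("shank", [0.045, -0.07, 0.0])], "M"),
        "rectus_toy": ([("pelvis", [0.055, 0.035, 0.0]),
                        ("thigh", [0.05, -0.22, 0.0]),
                        ("thigh", [0.055, -0.38, 0.0]),
                        ("shank", [0.042, -0.065, 0.0])], "M"),
        "hamstrings_toy": ([("pelvis", [-0.055, 0.01, 0.0]),
                            ("thigh", [-0.042, -0.34, 0.0]),
                            ("shank", [-0.032, -0.07, 0.0])], "M"),
        "gastroc_toy": ([("thigh", [-0.035, -0.33, 0.0]),
                         ("shank", [-0.045, -0.30, 0.0]),
                         ("foot", [-0.055, -0.025, 0.0])], "M"),
        "soleus_toy": ([("shank", [-0.042, -0.12, 0.0]),
                        ("foot", [-0.055, -0.025, 0.0])], "M"),
        "tibant_toy": ([("shank", [0.042, -0.14, 0.0]),
                        ("foot", [0.07, 0.015, 0.0])], "N"),
    }


def _toy_patella() -> PatellaConstruct:
    theta = np.linspace(-np.pi, np.pi, 181)
    # circular condyle profile centered on the knee joint center (plane origin)
    profile = np.column_stack([0.05 * np.cos(theta), 0.05 * np.sin(theta)])
    return PatellaConstruct(
        femur_segment="thigh",
        tibia_segment="shank",
        knee_coordinate="knee_flexion",
        prox_point=[0.0, 0.018],
        dist_point=[0.0, -0.018],
        ligament_point=[0.0, -0.024],
        ligament_length=0.0,  # set after construction from the initial pose
        tibial_insertion=[0.055, -0.075, 0.0],
        femoral_profile=profile,
    )


def default_rom_assessment() -> ROMAssessment:
    """Clinical-exam analog: test postures (rad) and the muscles they stretch.

    Mirrors the standard mapping: knee-flexion test -> knee extensors,
    popliteal angle -> hamstrings, dorsiflexion with knee extended ->
    soleus + gastrocnemius, hip flexion -> gluteals, hip extension with the
    knee flexed -> rectus + iliopsoas. Postures are defaults and
    user-overridable.
    """
    return ROMAssessment(tests=[
        ("knee_flexion_test", {"knee_flexion": -1.35}, ["vasti_toy", "rectus_toy"]),
        ("popliteal_angle", {"hip_flexion": 1.5, "knee_flexion": 0.1},
         ["hamstrings_toy"]),
        ("dorsiflexion_knee_0", {"knee_flexion": 0.15, "ankle_flexion": 0.5},
         ["soleus_toy", "gastroc_toy"]),
        ("hip_flexion_test", {"hip_flexion": 1.7, "knee_flexion": -0.9},
         ["glutmax_toy"]),
        ("hip_extension_test", {"hip_flexion": -0.5, "knee_flexion": -1.2},
         ["rectus_toy", "iliopsoas_toy"]),
    ])


def generate_rom_assessment(model: MusculoskeletalModel,
                            postures: dict | None = None) -> ROMAssessment:
    """ROM assessment for ``model``; ``postures`` overrides test postures."""
    rom = default_rom_assessment()
    if postures:
        rom = ROMAssessment(tests=[
            (name, postures.get(name, posture), muscles)
            for name, posture, muscles in rom.tests
        ])
    return rom


def make_toy_model(spec: ToyModelSpec | None = None, seed: int = 0) -> MusculoskeletalModel:
    """Deterministic planar toy model with Hill parameters calibrated so the
    nominal gait and ROM postures satisfy the tuning-stage assumptions."""
    spec = spec or ToyModelSpec()
    rng = np.random.default_rng(seed)
    segments = _toy_segments(spec)
    coordinates = _toy_coordinates()
    paths = _toy_muscle_paths()

    # provisional actuators so geometry can be evaluated
    muscles = []
    for name, (pts, subset) in paths.items():
        path = [PathPoint(seg, loc, role="origin" if i == 0 else
                          ("insertion" if i == len(pts) - 1 else "via"))
                for i, (seg, loc) in enumerate(pts)]
        muscles.append(MuscleTendonActuator(
            name=name, path=path, F_max=1000.0, l_mo=0.1, l_ts=0.1, subset=subset))
    model = MusculoskeletalModel(
        segments=segments, coordinates=coordinates, muscles=muscles,
        curves=MuscleCurveSet(), name=f"toy-{seed}", patella=_toy_patella())

    # calibrate fiber parameters against the nominal cycle and ROM postures
    phase = np.linspace(0.0, 2.0 * np.pi, 121, endpoint=False)
    q_cycle = nominal_gait(phase)
    from .model import _muscle_lengths  # internal reuse on purpose

    L = np.array([_muscle_lengths(model, q) for q in q_cycle])  # (P, M)
    rom = default_rom_assessment()
    from .trial import rom_musculotendon_lengths

    l_rom = rom_musculotendon_lengths(model, rom)
    for k, m in enumerate(model.muscles):
        lmin, lmax = float(L[:, k].min()), float(L[:, k].max())
        lmid = 0.5 * (lmin + lmax)
        jitter = 1.0 + spec.l_mo_jitter * rng.uniform(-1.0, 1.0)
        if m.name in l_rom and m.name in TUNED:
            l_mo = (l_rom[m.name] - lmid) / (spec.rom_target_lnorm - 1.0)
        else:
            l_mo = (lmax - lmin) / 0.4
        l_mo *= jitter
        l_ts = lmid - l_mo
        if l_ts <= 0.0:  # short untuned muscles: keep a positive tendon
            l_ts = 0.3 * lmid
            l_mo = lmid - l_ts
        m.l_mo = float(l_mo)
        m.l_ts = float(l_ts)
        m.F_max = float(rng.uniform(*spec.f_max_range))

    # close the patella construct: initial pose anterior to the femoral circle
    from .surgery import _patella_solve_path  # lazy; avoids import cycle at top

    knee = model.coordinate("knee_flexion")
    pose0 = np.array([0.0, 0.068, 0.0])  # theta, tx, ty in the knee plane
    lig_w = pose0[1:] + _rot2(pose0[0]) @ model.patella.ligament_point
    tib0 = _tibial_insertion_2d(model, 0.0)
    model.patella.ligament_length = float(np.linalg.norm(lig_w - tib0))
    angles = np.linspace(0.0, -1.2, 13)
    model.patella.path = _patella_solve_path(model, angles, pose_init=pose0)
    return model


def _rot2(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def _tibial_insertion_2d(model: MusculoskeletalModel, knee_angle: float) -> np.ndarray:
    """Ligament insertion in the knee plane (origin at the knee joint center)."""
    p = model.patella
    return _rot2(knee_angle) @ p.tibial_insertion[:2]


# ---------------------------------------------------------------------------
# Synthetic trials
# ---------------------------------------------------------------------------

_SYNERGY_BASE: dict[int, tuple[float, dict[str, float]]] = {
    # synergy bump centers (cycle phase fraction) and dominant muscles;
    # groups are near-disjoint so each synergy carries its own variance share
    0: (0.05, {"glutmax_toy": 1.0, "hamstrings_toy": 0.8, "soleus_toy": 0.2}),
    1: (0.30, {"gastroc_toy": 1.0, "soleus_toy": 0.95}),
    2: (0.80, {"iliopsoas_toy": 1.0, "rectus_toy": 0.8, "tibant_toy": 0.85}),
    3: (0.55, {"vasti_toy": 1.0, "tibant_toy": 0.3}),
}


def generate_synthetic_trial(
    model: MusculoskeletalModel,
    spec: SyntheticTrialSpec | None = None,
    seed: int = 0,
) -> tuple[TrialBundle, GroundTruth]:
    """Internally consistent gait trial with known synergy ground truth.

    Joint moments are defined as the muscle-moment sums under the model's
    true parameters and the generated activations, so the trial is exactly
    reserve-free feasible.
    """
    spec = spec or SyntheticTrialSpec()
    rng = np.random.default_rng(seed)
    P = spec.points_per_cycle
    F = spec.n_cycles * P
    phase = 2.0 * np.pi * (np.arange(F) % P) / P
    amp_scale = {
        name: [1.0 + spec.kinematic_jitter * rng.uniform(-1.0, 1.0)
               for _ in _HARMONICS[name][1]]
        for name in COORDS
    }
    q = nominal_gait(phase, amp_scale)
    time = np.arange(F) / P  # one cycle per "second"

    # synergy ground truth: periodic von-Mises activation bumps
    k = spec.k_true
    names = model.muscle_names
    W = np.zeros((len(names), k))
    H = np.zeros((k, F))
    for s in range(k):
        center, weights = _SYNERGY_BASE[s % len(_SYNERGY_BASE)]
        for m, w in weights.items():
            W[names.index(m), s] = w
        mu = 2.0 * np.pi * (center + 0.03 * rng.uniform(-1.0, 1.0))
        H[s] = 0.65 * np.exp(14.0 * (np.cos(phase - mu) - 1.0)) + 0.02
    W = W + 0.05 * rng.uniform(0.0, 1.0, W.shape)

    product = (W @ H).T  # (F, M)
    act = np.clip(product, 0.0, 1.0)

    bundle = TrialBundle(time=time, coordinate_names=model.coordinate_names,
                         muscle_names=names, q=q)
    bundle = derive_trial_geometry(model, bundle)

    # infeasible geometry (l_mt <= l_ts) forces a regeneration at lower amplitude
    for attempt in range(5):
        slack = bundle.l_mt - np.array([m.l_ts for m in model.muscles])[None, :]
        if slack.min() > 1e-4:
            break
        amp_scale = {n: [0.8 * s for s in v] for n, v in amp_scale.items()}
        q = nominal_gait(phase, amp_scale)
        bundle = derive_trial_geometry(
            model, TrialBundle(time=time, coordinate_names=model.coordinate_names,
                               muscle_names=names, q=q))
    else:
        raise RuntimeError("could not generate feasible kinematics")

    forces = np.empty_like(act)
    curves = model.curves
    for mi, m in enumerate(model.muscles):
        if m.subset == "M":
            l_norm = (bundle.l_mt[:, mi] - m.l_ts) / (np.cos(m.alpha) * m.l_mo)
            forces[:, mi] = m.F_max * (act[:, mi] * curves.active(l_norm)
                                       + curves.passive(l_norm))
        else:
            forces[:, mi] = m.F_max * act[:, mi]
    tau = np.einsum("fmj,fm->fj", bundle.r, forces)

    measured = spec.measured_channels or list(names)
    channels = [f"ch_{m}" for m in measured]
    eps = act[:, [names.index(m) for m in measured]].copy()
    if spec.emg_noise_sd > 0:
        eps = eps + rng.normal(0.0, spec.emg_noise_sd, eps.shape)
    eps = np.clip(eps, 0.0, None)
    peaks = eps.max(axis=0)
    peaks[peaks == 0] = 1.0
    eps = eps / peaks

    bundle = TrialBundle(
        time=time, coordinate_names=model.coordinate_names, muscle_names=names,
        q=q, tau_ID=tau, l_mt=bundle.l_mt, r=bundle.r, emg=eps,
        channel_names=channels,
        channel_map={ch: [m] for ch, m in zip(channels, measured)},
    )
    gt = GroundTruth(
        activations=act, product=product, W_true=W, H_true=H,
        l_mo={m.name: m.l_mo for m in model.muscles},
        l_ts={m.name: m.l_ts for m in model.muscles},
        F_max={m.name: m.F_max for m in model.muscles},
        sigma_true={m: 1.0 / p for m, p in zip(measured, peaks)},
    )
    return bundle, gt


def make_reference_template(model: MusculoskeletalModel, mass: float = 35.0,
                            n_points: int = 201) -> ReferenceGaitTemplate:
    """Reference gait template built from the undeformed chain: nominal
    kinematics, moments per kg from the noise-free generative trial, and
    landmark marker trajectories.

    Synthetic stand-in for an average typically-developing dataset, which is
    not shipped with the package.
    """
    spec = SyntheticTrialSpec(n_cycles=1, points_per_cycle=n_points - 1,
                              kinematic_jitter=0.0, emg_noise_sd=0.0)
    bundle, _ = generate_synthetic_trial(model, spec, seed=0)
    # close the cycle periodically
    q = np.vstack([bundle.q, bundle.q[0]])
    tau = np.vstack([bundle.tau_ID, bundle.tau_ID[0]])
    percent = np.linspace(0.0, 100.0, n_points)
    markers: dict[str, np.ndarray] = {}
    marker_names = [(s.name, ln) for s in model.segments for ln in s.landmarks
                    if ln.endswith("_marker") or ln.startswith("condyle")
                    or ln.endswith("_marker_r") or ln.endswith("_marker_l")]
    for i, qi in enumerate(q):
        poses = forward_kinematics(model, qi)
        for seg, ln in marker_names:
            R, t = poses[seg]
            pos = R @ model.segment(seg).landmarks[ln] + t
            markers.setdefault(ln, np.empty((n_points, 3)))[i] = pos
    return ReferenceGaitTemplate(
        percent=percent, coordinate_names=model.coordinate_names,
        q=q, moments_per_kg=tau / mass, markers=markers,
        reference_height=1.5,
    )


def true_motor_control(model: MusculoskeletalModel, gt: GroundTruth):
    """Motor-control model from the generative synergies, padded with one
    extra uniform synergy (max-normalized columns, product-preserving)."""
    from .synergy import MotorControlModel

    W = gt.W_true.copy()
    H = gt.H_true.copy()
    scale = W.max(axis=0)
    W = W / scale
    H = H * scale[:, None]
    W = np.column_stack([W, np.ones(W.shape[0])])
    H = np.vstack([H, np.zeros(H.shape[1])])
    return MotorControlModel(W_pre=W, H_pre=H, N_s=gt.W_true.shape[1])


def perturb_model(model: MusculoskeletalModel, spec: DeformitySpec | None = None
                  ) -> tuple[MusculoskeletalModel, dict]:
    """Apply a known deformity (femoral long-axis derotation + hamstring
    tendon shortening) and return the patient model plus a record holding
    the exact corrective surgery plan."""
    from .surgery import SurgeryOperation, SurgeryPlan, apply_plan

    spec = spec or DeformitySpec()
    plane = {"point": [0.0, -0.20, 0.0], "normal": [0.0, 1.0, 0.0]}
    # negative rotation about the (proximal) shaft axis increases anteversion:
    # an internal-torsion deformity
    deform = SurgeryPlan(label="deformity", operations=[
        SurgeryOperation(kind="derotation_osteotomy", target="thigh",
                         parameters={"plane": plane,
                                     "angle": -np.radians(spec.derotation_deg),
                                     "translation": [0.0, 0.0, 0.0]}),
        SurgeryOperation(kind="muscle_transfer", target="hamstrings_toy",
                         parameters={"delta_l_ts": -spec.hamstring_lts_shortening}),
    ])
    corrective = SurgeryPlan(label="corrective", operations=[
        SurgeryOperation(kind="derotation_osteotomy", target="thigh",
                         parameters={"plane": plane,
                                     "angle": np.radians(spec.derotation_deg),
                                     "translation": [0.0, 0.0, 0.0]}),
        SurgeryOperation(kind="muscle_transfer", target="hamstrings_toy",
                         parameters={"delta_l_ts": spec.hamstring_lts_shortening}),
    ])
    patient = apply_plan(model, deform)
    patient.label = "patient"
    record = {"deformity": deform, "corrective_plan": corrective,
              "derotation_deg": spec.derotation_deg,
              "hamstring_lts_shortening": spec.hamstring_lts_shortening}
    return patient, record
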