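"""Capability gap: synergy-constrained static optimization of a desired gait.

The capability gap (CG) quantifies how far a personalized model is from
producing the joint moments of a desired (typically-developing) gait
pattern. Per-frame moment equilibrium always holds because ideal reserve
actuators absorb whatever the muscles cannot produce; the reserves are
heavily penalized, and the per-joint CG is

    CG_j = sum_i |tau^R_ji| / sum_i |tau^ID_ji|,

zero when the motion is fully achievable. Impaired motor control enters as a
constraint: activations are generated by the patient's synergy weights,
a_i = (W_pre + dW) H_i, with H_i >= 0 free per frame and dW a small shared
deviation (|dW| <= 0.05 elementwise after max-normalization of W_pre).

Stage 1 solves the convex per-frame problems with dW = 0; stage 2 alternates
exact least-squares steps in dW (H fixed) and H (dW fixed), so the objective
is non-increasing. Toggles reproduce the alternative analyses: without
synergy constraints activations are optimized freely per frame (classic
static optimization), and without the force-length relation muscle force is
activation-proportional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .model import MusculoskeletalModel
from .qp import boxed_lsq_batch
from .synergy import MotorControlModel
from .trial import TrialBundle
from .tuning import linear_force_terms

__all__ = [
    "CGConfig",
    "CapabilityGapResult",
    "compute_capability_gap",
    "muscle_operating_report",
    "gait_profile_rmse",
    "compare_conditions",
]


@dataclass
class CGConfig:
    use_synergies: bool = True
    use_force_length: bool = True
    delta_w_bound: float = 0.05
    w1: float = 1.0  # activation (synergy) effort
    # reserves must be penalized hard enough that they absorb only what the
    # muscles cannot produce; at low w2 the effort/reserve trade leaks
    # reserve moments into perfectly achievable motions and contaminates CG
    w2: float = 1000.0  # reserve penalty, per (N*m)^2
    max_alternations: int = 20
    tol: float = 1e-6
    tau_floor: float = 1.0  # N*m*frames floor on the CG denominator
    seed: int = 0

    def __post_init__(self):
        if self.delta_w_bound < 0:
            raise ConfigurationError("delta_w_bound must be >= 0")


@dataclass
class CapabilityGapResult:
    joint_names: list[str]
    CG_j: dict[str, float]
    CG_mean: float
    reserves: np.ndarray  # (F, J)
    activations: np.ndarray  # (F, M)
    H_opt: np.ndarray | None  # (k, F) when synergies used
    delta_W: np.ndarray | None  # (M, k)
    objective_trace: list[float] = field(default_factory=list)
    clip_fraction: float = 0.0  # fraction of activations clamped into [0, 1]
    config: dict = field(default_factory=dict)

    def recompute_cg(self, tau_ID: np.ndarray, floor: float = 1.0) -> dict[str, float]:
        denom = np.maximum(np.sum(np.abs(tau_ID), axis=0), floor)
        vals = np.sum(np.abs(self.reserves), axis=0) / denom
        return dict(zip(self.joint_names, vals))


def _synergy_frame_system(W: np.ndarray, c1: np.ndarray, c0: np.ndarray,
                          trial: TrialBundle, w1: float, w2: float
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Stacked LS system over frames for H >= 0 with activations a = W h."""
    F, M = c1.shape
    J = trial.tau_ID.shape[1]
    K = W.shape[1]
    A = np.zeros((F, M + J, K))
    b = np.zeros((F, M + J))
    sw1, sw2 = np.sqrt(w1), np.sqrt(w2)
    A[:, :M, :] = sw1 * W[None, :, :]
    B = trial.r.transpose(0, 2, 1) * c1[:, None, :]  # (F, J, M)
    A[:, M:, :] = sw2 * np.einsum("fjm,mk->fjk", B, W)
    b[:, M:] = sw2 * (trial.tau_ID - np.einsum("fmj,fm->fj", trial.r, c0))
    return A, b


def _objective(a, resid, w1, w2):
    return w1 * float(np.sum(a ** 2)) + w2 * float(np.sum(resid ** 2))


def compute_capability_gap(
    model: MusculoskeletalModel,
    motor_control: MotorControlModel | None,
    desired: TrialBundle,
    config: CGConfig | None = None,
) -> CapabilityGapResult:
    """Reserve moments and per-joint CG for a desired-motion bundle.

    ``desired`` must carry tau_ID, l_mt and r computed on ``model`` (see
    :func:`capgap.trial.make_reference_trial`)."""
    config = config or CGConfig()
    desired.validate_against(model)
    for req in ("tau_ID", "l_mt", "r"):
        if getattr(desired, req) is None:
            raise ConfigurationError(f"desired trial lacks {req!r}")
    F, M = desired.l_mt.shape
    J = desired.tau_ID.shape[1]
    c1, c0 = linear_force_terms(model, desired.l_mt,
                                use_force_length=config.use_force_length)
    B = desired.r.transpose(0, 2, 1) * c1[:, None, :]  # (F, J, M)
    tau_net = desired.tau_ID - np.einsum("fmj,fm->fj", desired.r, c0)

    trace: list[float] = []
    H = None
    dW = None
    if motor_control is None or not config.use_synergies:
        # unconstrained coordination: classic per-frame static optimization
        A = np.zeros((F, M + J, M))
        b = np.zeros((F, M + J))
        A[:, :M, :] = np.sqrt(config.w1) * np.eye(M)[None]
        A[:, M:, :] = np.sqrt(config.w2) * B
        b[:, M:] = np.sqrt(config.w2) * tau_net
        a = boxed_lsq_batch(A, b, 0.0, 1.0)
        clip_frac = 0.0
        resid = tau_net - np.einsum("fjm,fm->fj", B, a)
        trace.append(_objective(a, resid, config.w1, config.w2))
    else:
        W0 = np.asarray(motor_control.W_pre, float)
        if W0.shape[0] != M:
            raise ConfigurationError(
                f"motor-control weights cover {W0.shape[0]} muscles, model has {M}")
        K = W0.shape[1]
        dW = np.zeros((M, K))

        def solve_H(Wc):
            A, b = _synergy_frame_system(Wc, c1, c0, desired,
                                         config.w1, config.w2)
            return boxed_lsq_batch(A, b, 0.0, np.inf)

        def eval_obj(Wc, H):
            a_raw = H @ Wc.T  # (F, M)
            a = np.clip(a_raw, 0.0, 1.0)
            resid = tau_net - np.einsum("fjm,fm->fj", B, a)
            return a_raw, a, resid, _objective(a, resid, config.w1, config.w2)

        H = solve_H(W0)
        _, a, resid, obj = eval_obj(W0, H)
        trace.append(obj)

        bound = config.delta_w_bound
        if bound > 0 and config.max_alternations > 0:
            lb = np.maximum(-bound, -W0).ravel()
            ub = np.full(M * K, bound)
            for _ in range(config.max_alternations):
                # exact LS step in dW with H fixed: a = W0 h + dW h is linear
                # in dW (rows: sqrt(w1) per activation, sqrt(w2) per moment)
                Adw = np.zeros((F * (M + J), M * K))
                bdw = np.zeros(F * (M + J))
                sw1, sw2 = np.sqrt(config.w1), np.sqrt(config.w2)
                a0 = H @ W0.T  # (F, M)
                # activation rows
                for m in range(M):
                    rows = np.arange(F) * (M + J) + m
                    Adw[rows[:, None], m * K + np.arange(K)[None, :]] = sw1 * H
                    bdw[rows] = -sw1 * a0[:, m]
                # moment rows
                resid0 = tau_net - np.einsum("fjm,fm->fj", B, a0)
                for j in range(J):
                    rows = np.arange(F) * (M + J) + M + j
                    # d resid / d dW[m,k] = -B[f,j,m] * H[k,f]
                    Gm = np.einsum("fm,fk->fmk", B[:, j, :], H).reshape(F, M * K)
                    Adw[rows, :] = sw2 * Gm
                    bdw[rows] = sw2 * resid0[:, j]
                dW_new = boxed_lsq_batch(Adw[None], bdw[None], lb, ub)[0]
                dW = dW_new.reshape(M, K)
                H = solve_H(W0 + dW)
                _, a, resid, obj = eval_obj(W0 + dW, H)
                if trace and trace[-1] - obj < config.tol * max(abs(trace[-1]), 1.0):
                    trace.append(obj)
                    break
                trace.append(obj)
        Wc = W0 + (dW if dW is not None else 0.0)
        a_raw, a, resid, obj = eval_obj(Wc, H)
        clip_frac = float(np.mean((a_raw < 0.0) | (a_raw > 1.0)))
        H = H.T  # store as (k, F)

    reserves = resid
    denom = np.maximum(np.sum(np.abs(desired.tau_ID), axis=0), config.tau_floor)
    cg = np.sum(np.abs(reserves), axis=0) / denom
    joint_names = desired.coordinate_names
    return CapabilityGapResult(
        joint_names=list(joint_names),
        CG_j={j: float(v) for j, v in zip(joint_names, cg)},
        CG_mean=float(np.mean(cg)),
        reserves=reserves,
        activations=a,
        H_opt=H,
        delta_W=dW,
        objective_trace=trace,
        clip_fraction=clip_frac,
        config={k: getattr(config, k) for k in CGConfig.__dataclass_fields__},
    )


# ---------------------------------------------------------------------------
# Muscle operating-length report
# ---------------------------------------------------------------------------

def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as inclusive (start, stop) frame intervals."""
    idx = np.flatnonzero(mask)
    if not len(idx):
        return []
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[splits + 1]]
    stops = np.r_[idx[splits], idx[-1]]
    return [(int(s), int(e)) for s, e in zip(starts, stops)]


def muscle_operating_report(
    model: MusculoskeletalModel,
    result: CapabilityGapResult,
    desired: TrialBundle,
    passive_threshold: float = 0.5,
    activation_threshold: float = 0.25,
    short_lnorm: float = 0.6,
) -> dict[str, dict[str, list[tuple[int, int]]]]:
    """Flag frames where muscles operate at problematic lengths.

    "stretched": passive force exceeds ``passive_threshold`` of the maximum
    isometric force. "short_active": activation above
    ``activation_threshold`` while normalized fiber length is below
    ``short_lnorm``. Intervals are maximal runs of flagged frames.
    """
    report: dict[str, dict[str, list[tuple[int, int]]]] = {}
    curves = model.curves
    for k, m in enumerate(model.muscles):
        ln = (desired.l_mt[:, k] - m.l_ts) / (np.cos(m.alpha) * m.l_mo)
        stretched = curves.passive(ln) > passive_threshold
        short = ((result.activations[:, k] > activation_threshold)
                 & (ln < short_lnorm))
        report[m.name] = {"stretched": _runs(stretched),
                          "short_active": _runs(short)}
    return report


# ---------------------------------------------------------------------------
# Comparisons
# ---------------------------------------------------------------------------

def gait_profile_rmse(q_subject: np.ndarray, q_reference: np.ndarray,
                      joint_names: list[str] | None = None
                      ) -> tuple[dict[str, float], float]:
    """Per-joint RMSE (degrees) between two cycle-normalized angle sets and
    the aggregate root-mean-square of the per-joint values (the Gait Variable
    Score / Gait Profile Score construction)."""
    qs = np.asarray(q_subject, float)
    qr = np.asarray(q_reference, float)
    if qs.shape != qr.shape:
        raise ConfigurationError(
            f"kinematics shapes differ: {qs.shape} vs {qr.shape}")
    rmse = np.degrees(np.sqrt(np.mean((qs - qr) ** 2, axis=0)))
    names = joint_names or [f"joint_{j}" for j in range(qs.shape[1])]
    agg = float(np.sqrt(np.mean(rmse ** 2)))
    return dict(zip(names, rmse.astype(float))), agg


def compare_conditions(pre: CapabilityGapResult, post: CapabilityGapResult
                       ) -> dict:
    """Per-joint and mean capability-gap change, post minus pre."""
    if pre.joint_names != post.joint_names:
        raise ConfigurationError("pre/post joint sets differ")
    delta = {j: post.CG_j[j] - pre.CG_j[j] for j in pre.joint_names}
    return {
        "joints": pre.joint_names,
        "CG_pre": pre.CG_j,
        "CG_post": post.CG_j,
        "delta_CG": delta,
        "CG_mean_pre": pre.CG_mean,
        "CG_mean_post": post.CG_mean,
        "delta_CG_mean": post.CG_mean - pre.CG_mean,
    }
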