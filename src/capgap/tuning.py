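"""Muscle-tendon parameter personalization by frame-coupled static optimization.

Estimates optimal fiber lengths and tendon slack lengths of the tuned muscle
subset so that, over the gait trial, muscles reproduce the inverse-dynamics
joint moments with activations proportional to the measured EMG envelopes
while operating around their optimal fiber length, and reach the passive
force-generating range in the clinical range-of-motion tests.

Formulation. Optimization variables are the per-frame activations a_mi and
reserve moments tau^R_ji, the fiber parameters (l_mo, l_ts) of the tuned
muscles, and one EMG scale factor sigma_m per EMG-mapped muscle. The cost is

    sum_i [ sum_m w1 a_mi^2 + sum_j w2 (tau^R_ji)^2 ]          (tracking/reserve)
  + sum_i sum_{m in eps} w3 (sigma_m a_mi - emg_mi)^2          (EMG similarity)
  + sum_{m in R} w4 (lnorm^R_m - 1.5)^2                        (ROM stretch pull)

subject to per-frame moment equilibrium, normalized fiber lengths in
[0.4, 1.5] over the trial with the max above and the min below 1 (strictly,
via a small tolerance delta), and ROM normalized lengths in (1, 1.5].

Solution strategy. The equilibrium constraint defines the reserves, so they
are eliminated; for fixed parameters the activations solve independent
per-frame convex box-constrained least-squares problems (solved exactly, in
batch). The remaining outer problem over (l_mo, l_ts, sigma) — a few dozen
variables — is solved with SLSQP on this reduced value function, with the
fiber-length constraints evaluated at the per-muscle extreme frames (for
fixed kinematics, normalized fiber length is increasing in musculotendon
length, so the extremes are at the precomputed argmin/argmax frames). A KKT
point of the reduced problem together with the exact inner minimizers is a
KKT point of the full coupled program. The outer problem is nonconvex, so a
seeded multi-start (default 3) is used and the best objective kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .errors import ConfigurationError, InfeasibleGeometryError
from .model import MusculoskeletalModel
from .qp import boxed_lsq_batch
from .trial import ROMAssessment, TrialBundle, rom_musculotendon_lengths

__all__ = [
    "TuningConfig",
    "TuningResult",
    "tune_muscle_parameters",
    "apply_tuned_parameters",
    "scale_fmax_by_mass",
    "linear_force_terms",
    "solve_activations",
]


@dataclass
class TuningConfig:
    # Weights: the EMG-similarity term must dominate the activation-effort
    # term, otherwise the free EMG scale factors leave parameter drift toward
    # "stronger" length configurations unpenalized and the calibration is
    # poorly identified. Reserves are heavily penalized as usual.
    w1: float = 0.2  # activation effort
    w2: float = 10.0  # reserve penalty, per (N*m)^2
    w3: float = 20.0  # EMG-similarity penalty
    w4: float = 10.0  # ROM stretch pull toward 1.5
    strict_tol: float = 1e-3  # delta for the strict parts of the length bounds
    lnorm_bounds: tuple[float, float] = (0.4, 1.5)
    param_range: tuple[float, float] = (0.5, 1.5)  # multiplicative on initial l_mo, l_ts
    sigma_bounds: tuple[float, float] = (0.05, 20.0)
    maxiter: int = 150
    ftol: float = 1e-10
    n_starts: int = 3
    start_spread: float = 0.1  # relative perturbation of the extra starts
    seed: int = 0

    def __post_init__(self):
        if min(self.w1, self.w2, self.w3, self.w4) < 0:
            raise ConfigurationError("cost weights must be >= 0")
        for lo, hi in (self.lnorm_bounds, self.param_range, self.sigma_bounds):
            if not lo < hi:
                raise ConfigurationError("bounds must be ordered")


@dataclass
class TuningResult:
    l_mo: dict[str, float]
    l_ts: dict[str, float]
    sigma: dict[str, float]
    activations: np.ndarray  # (F, M)
    reserves: np.ndarray  # (F, J)
    objective: float
    cost_so: float
    cost_emg: float
    cost_rom: float
    converged: bool
    iterations: int
    message: str = ""
    config: dict = field(default_factory=dict)
    start_objectives: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Shared static-optimization building blocks
# ---------------------------------------------------------------------------

def linear_force_terms(model: MusculoskeletalModel, l_mt: np.ndarray,
                       l_mo: np.ndarray | None = None,
                       l_ts: np.ndarray | None = None,
                       use_force_length: bool = True,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame linearization F_m = c1_m * a_m + c0_m of muscle force.

    For tuned-subset muscles with the force-length relation on, c1 is the
    activation-scaled active curve value and c0 the passive force; for
    activation-proportional muscles (or with the relation off) c1 = F_max
    and c0 = 0.
    """
    F, M = l_mt.shape
    c1 = np.empty((F, M))
    c0 = np.zeros((F, M))
    curves = model.curves
    for k, m in enumerate(model.muscles):
        fmax = m.F_max
        if m.subset == "M" and use_force_length:
            lmo = float(l_mo[k]) if l_mo is not None else m.l_mo
            lts = float(l_ts[k]) if l_ts is not None else m.l_ts
            if np.any(l_mt[:, k] <= lts):
                raise InfeasibleGeometryError(m.name, float(l_mt[:, k].min()), lts)
            ln = (l_mt[:, k] - lts) / (np.cos(m.alpha) * lmo)
            c1[:, k] = fmax * curves.active(ln)
            c0[:, k] = fmax * curves.passive(ln)
        else:
            c1[:, k] = fmax
    return c1, c0


def _so_system(trial: TrialBundle, c1: np.ndarray, c0: np.ndarray,
               sigma: np.ndarray, eps: np.ndarray, eps_idx: np.ndarray,
               w1: float, w2: float, w3: float
               ) -> tuple[np.ndarray, np.ndarray]:
    """Stacked least-squares system whose solution is the per-frame optimal
    activation vector (reserves eliminated into the w2 rows)."""
    F, M = c1.shape
    J = trial.tau_ID.shape[1]
    E = len(eps_idx)
    A = np.zeros((F, M + J + E, M))
    b = np.zeros((F, M + J + E))
    sw1 = np.sqrt(w1)
    A[:, :M, :] = sw1 * np.eye(M)[None]
    B = trial.r.transpose(0, 2, 1) * c1[:, None, :]  # (F, J, M)
    sw2 = np.sqrt(w2)
    A[:, M:M + J, :] = sw2 * B
    b[:, M:M + J] = sw2 * (trial.tau_ID - np.einsum("fmj,fm->fj", trial.r, c0))
    if E:
        sw3 = np.sqrt(w3)
        A[:, M + J + np.arange(E), eps_idx] = sw3 * sigma
        b[:, M + J:] = sw3 * eps
    return A, b


def solve_activations(trial: TrialBundle, c1: np.ndarray, c0: np.ndarray,
                      sigma: np.ndarray, eps: np.ndarray, eps_idx: np.ndarray,
                      w1: float, w2: float, w3: float) -> np.ndarray:
    """Exact per-frame activations minimizing the static-optimization cost."""
    A, b = _so_system(trial, c1, c0, sigma, eps, eps_idx, w1, w2, w3)
    return boxed_lsq_batch(A, b, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Parameter tuning
# ---------------------------------------------------------------------------

def tune_muscle_parameters(
    model: MusculoskeletalModel,
    trial: TrialBundle,
    rom: ROMAssessment | None = None,
    config: TuningConfig | None = None,
) -> TuningResult:
    config = config or TuningConfig()
    trial.validate_against(model)
    for req in ("tau_ID", "l_mt", "r", "emg"):
        if getattr(trial, req) is None:
            raise ConfigurationError(f"tuning requires trial field {req!r}")

    names = model.muscle_names
    tuned = [i for i, m in enumerate(model.muscles) if m.subset == "M"]
    mapped = trial.mapped_muscles()
    eps_idx = np.array([names.index(m) for m in mapped], dtype=int)
    eps = np.column_stack([trial.emg_for_muscle(m) for m in mapped]) if mapped \
        else np.zeros((trial.n_frames, 0))

    l_mo0 = np.array([m.l_mo for m in model.muscles])
    l_ts0 = np.array([m.l_ts for m in model.muscles])
    cosa = np.array([np.cos(m.alpha) for m in model.muscles])
    L = trial.l_mt
    imax = np.argmax(L, axis=0)
    imin = np.argmin(L, axis=0)

    rom_len: dict[str, float] = {}
    if rom is not None:
        rom_len = rom_musculotendon_lengths(model, rom)
    rom_tuned = [i for i in tuned if names[i] in rom_len]
    l_rom = np.array([rom_len[names[i]] for i in rom_tuned])

    nt = len(tuned)
    ne = len(mapped)
    # outer variables: multiplicative scales on l_mo and l_ts of the tuned
    # muscles, then the EMG scale factors
    def unpack(x):
        s_mo = x[:nt]
        s_ts = x[nt:2 * nt]
        sigma = x[2 * nt:]
        lmo = l_mo0.copy()
        lts = l_ts0.copy()
        lmo[tuned] = l_mo0[tuned] * s_mo
        lts[tuned] = l_ts0[tuned] * s_ts
        return lmo, lts, sigma

    delta = config.strict_tol
    lo_n, hi_n = config.lnorm_bounds

    def rom_lnorm(lmo, lts):
        return (l_rom - lts[rom_tuned]) / (cosa[rom_tuned] * lmo[rom_tuned])

    def cost_rom(lmo, lts):
        if not len(rom_tuned):
            return 0.0
        return config.w4 * float(np.sum((rom_lnorm(lmo, lts) - hi_n) ** 2))

    def inner(x):
        lmo, lts, sigma = unpack(x)
        # infeasible geometry inside the solve: return a large smooth penalty
        slack = L[:, tuned].min(axis=0) - lts[tuned]
        if np.any(slack <= 1e-6):
            return None, None, 1e9 * (1.0 + float(np.sum(np.minimum(slack, 0.0) ** 2)))
        c1, c0 = linear_force_terms(model, L, lmo, lts)
        a = solve_activations(trial, c1, c0, sigma, eps, eps_idx,
                              config.w1, config.w2, config.w3)
        resid = trial.tau_ID - np.einsum("fmj,fm->fj", trial.r, c1 * a + c0)
        val = (config.w1 * float(np.sum(a ** 2))
               + config.w2 * float(np.sum(resid ** 2)))
        if ne:
            val += config.w3 * float(np.sum((sigma[None, :] * a[:, eps_idx] - eps) ** 2))
        val += cost_rom(lmo, lts)
        return a, resid, val

    def objective(x):
        return inner(x)[2]

    def constraints(x):
        lmo, lts, sigma = unpack(x)
        ln_max = (L[imax[tuned], tuned] - lts[tuned]) / (cosa[tuned] * lmo[tuned])
        ln_min = (L[imin[tuned], tuned] - lts[tuned]) / (cosa[tuned] * lmo[tuned])
        g = [
            ln_max - (1.0 + delta),  # max above optimum
            hi_n - ln_max,           # max within 1.5
            (1.0 - delta) - ln_min,  # min below optimum
            ln_min - lo_n,           # min within 0.4
        ]
        if len(rom_tuned):
            ln_r = rom_lnorm(lmo, lts)
            g += [ln_r - (1.0 + delta), hi_n - ln_r]
        return np.concatenate(g)

    lo_s, hi_s = config.param_range
    bounds = ([(lo_s, hi_s)] * (2 * nt)
              + [config.sigma_bounds] * ne)
    x_base = np.concatenate([np.ones(2 * nt), np.ones(ne)])

    rng = np.random.default_rng(config.seed)
    starts = [x_base]
    for _ in range(config.n_starts - 1):
        pert = x_base.copy()
        pert[:2 * nt] *= 1.0 + config.start_spread * rng.uniform(-1, 1, 2 * nt)
        pert[2 * nt:] *= np.exp(config.start_spread * rng.uniform(-1, 1, ne))
        starts.append(np.clip(pert, [b[0] for b in bounds], [b[1] for b in bounds]))

    best = None
    start_objs: list[float] = []
    for x0 in starts:
        res = minimize(
            objective, x0, method="SLSQP", bounds=bounds,
            constraints=[{"type": "ineq", "fun": constraints}],
            options={"maxiter": config.maxiter, "ftol": config.ftol},
        )
        feas = bool(np.all(constraints(res.x) >= -1e-6))
        start_objs.append(float(res.fun))
        key = (not feas, float(res.fun))
        if best is None or key < best[0]:
            best = (key, res, feas)
    _, res, feas = best

    lmo, lts, sigma = unpack(res.x)
    a, resid, val = inner(res.x)
    if a is None:
        raise InfeasibleGeometryError("<tuning>", float(L.min()), float(lts.max()))
    c1, c0 = linear_force_terms(model, L, lmo, lts)
    cost_so = (config.w1 * float(np.sum(a ** 2))
               + config.w2 * float(np.sum(resid ** 2)))
    cost_emg = config.w3 * float(np.sum(
        (sigma[None, :] * a[:, eps_idx] - eps) ** 2)) if ne else 0.0

    return TuningResult(
        l_mo={names[i]: float(lmo[i]) for i in tuned},
        l_ts={names[i]: float(lts[i]) for i in tuned},
        sigma={m: float(s) for m, s in zip(mapped, sigma)},
        activations=a,
        reserves=resid,
        objective=float(val),
        cost_so=cost_so,
        cost_emg=cost_emg,
        cost_rom=float(cost_rom(lmo, lts)),
        converged=bool(res.success and feas),
        iterations=int(res.nit),
        message=str(res.message),
        config={k: getattr(config, k) for k in TuningConfig.__dataclass_fields__},
        start_objectives=start_objs,
    )


def apply_tuned_parameters(model: MusculoskeletalModel,
                           result: TuningResult) -> MusculoskeletalModel:
    """New model with the estimated l_mo, l_ts written into the tuned muscles."""
    out = model.derive(label=model.label)
    out.name = f"{model.name}+tuned"
    for name, v in result.l_mo.items():
        try:
            out.muscle(name).l_mo = float(v)
        except Exception:
            raise ConfigurationError(f"tuned parameters reference unknown muscle {name!r}")
    for name, v in result.l_ts.items():
        out.muscle(name).l_ts = float(v)
    return out


def scale_fmax_by_mass(model: MusculoskeletalModel, mass_ratio: float
                       ) -> MusculoskeletalModel:
    """Maximum isometric forces scaled by a body-mass ratio (plumbing for
    generic-model scaling; not an optimization)."""
    out = model.derive(label=model.label)
    out.name = f"{model.name}+fscaled"
    for m in out.muscles:
        m.F_max = float(m.F_max * mass_ratio)
    return out
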