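"""Motor-control model: muscle synergies from EMG and EMG-informed activations.

The patient's coordination is summarized by non-negative matrix factorization
of EMG envelopes, E ~ W H, with W the muscle weight vectors and H the synergy
activation timings. The number of synergies N_s is selected by a bootstrap:
the EMG and H are consistently resampled over time instants (with
replacement), and N_s is the smallest k whose synergies — extracted once from
the original signal — explain more than the VAF threshold (default 90%) of at
least a coverage fraction (default 95%) of 500 resamples.

All-muscle activations are then estimated by an EMG-informed static
optimization on the gait trial, and a final NNMF with N_s + 1 synergies over
those activations (the extra synergy covers muscles without surface EMG)
yields the motor-control model (W_pre, H_pre) used by the capability gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DomainError
from .model import MusculoskeletalModel
from .trial import TrialBundle

__all__ = [
    "SynergySet",
    "BootstrapConfig",
    "SynergySelection",
    "MotorControlModel",
    "nnmf_factorize",
    "select_num_synergies",
    "emg_informed_activations",
    "build_motor_control",
]

_EPS = 1e-12


@dataclass
class SynergySet:
    W: np.ndarray  # (channels, k), non-negative
    H: np.ndarray  # (k, time), non-negative
    vaf: float
    k: int
    objective_trace: list[float] = field(default_factory=list)


@dataclass
class BootstrapConfig:
    n_resamples: int = 500
    vaf_threshold: float = 0.90
    coverage: float = 0.95
    k_max: int = 6
    seed: int = 0
    nnmf_restarts: int = 10

    def __post_init__(self):
        if not (0.0 < self.vaf_threshold < 1.0 and 0.0 < self.coverage < 1.0):
            raise ConfigurationError("thresholds must lie in (0, 1)")


@dataclass
class SynergySelection:
    n_synergies: int | None  # None: no k <= k_max reached the coverage
    coverage: dict[int, float]
    vaf: dict[int, float]
    insufficient_vaf: bool = False


@dataclass
class MotorControlModel:
    """All-muscle synergy model: columns of W_pre are max-normalized."""

    W_pre: np.ndarray  # (muscles, N_s + 1)
    H_pre: np.ndarray  # (N_s + 1, time)
    N_s: int
    muscle_names: list[str] = field(default_factory=list)
    vaf: float | None = None

    def __post_init__(self):
        if np.any(self.W_pre < 0) or np.any(self.H_pre < 0):
            raise DomainError("synergy matrices must be non-negative")
        colmax = self.W_pre.max(axis=0)
        if np.any(np.abs(colmax - 1.0) > 1e-9):
            raise DomainError("W_pre columns must be max-normalized to 1")


def _vaf(E: np.ndarray, WH: np.ndarray) -> float:
    return 1.0 - float(np.sum((E - WH) ** 2)) / max(float(np.sum(E ** 2)), _EPS)


def nnmf_factorize(E: np.ndarray, k: int, restarts: int = 10, seed: int = 0,
                   tol: float = 1e-6, max_iter: int = 2000) -> SynergySet:
    """Multiplicative-update NNMF, best of seeded random restarts.

    Iterates the classic Lee-Seung updates until the relative change of the
    Frobenius objective drops below ``tol`` (or ``max_iter``); the objective
    is non-increasing along the iterations by construction.
    """
    E = np.asarray(E, float)
    if np.any(E < 0):
        raise DomainError("NNMF input must be non-negative")
    if E.ndim != 2:
        raise DomainError("NNMF input must be a 2-D matrix")
    if np.any(E.sum(axis=1) == 0):
        raise DomainError("NNMF input has an all-zero row")
    n, t = E.shape
    if not 1 <= k <= min(n, t):
        raise DomainError(f"k={k} outside [1, min(dims)={min(n, t)}]")
    rng = np.random.default_rng(seed)
    best: SynergySet | None = None
    for _ in range(max(1, restarts)):
        W = rng.uniform(_EPS, 1.0, (n, k))
        H = rng.uniform(_EPS, 1.0, (k, t))
        prev = float(np.sum((E - W @ H) ** 2))
        trace = [prev]
        for _ in range(max_iter):
            H *= (W.T @ E) / np.maximum(W.T @ W @ H, _EPS)
            W *= (E @ H.T) / np.maximum(W @ (H @ H.T), _EPS)
            obj = float(np.sum((E - W @ H) ** 2))
            trace.append(obj)
            if prev - obj < tol * max(prev, _EPS):
                break
            prev = obj
        cand = SynergySet(W=W, H=H, vaf=_vaf(E, W @ H), k=k, objective_trace=trace)
        if best is None or cand.objective_trace[-1] < best.objective_trace[-1]:
            best = cand
    return best


def select_num_synergies(E: np.ndarray, config: BootstrapConfig | None = None
                         ) -> SynergySelection:
    """Bootstrap model-order selection over the time instants.

    For each k the synergies are extracted once from the original signal;
    resampled time indices are applied consistently to the EMG columns and
    the H columns, and the coverage is the fraction of resamples whose VAF
    (by the fixed W) exceeds the threshold.
    """
    config = config or BootstrapConfig()
    E = np.asarray(E, float)
    coverage: dict[int, float] = {}
    vaf: dict[int, float] = {}
    for k in range(1, config.k_max + 1):
        if k > min(E.shape):
            break
        fac = nnmf_factorize(E, k, restarts=config.nnmf_restarts,
                             seed=config.seed + 1000 * k)
        vaf[k] = fac.vaf
        rng = np.random.default_rng(config.seed + 1000 * k + 1)
        t = E.shape[1]
        hits = 0
        for _ in range(config.n_resamples):
            idx = rng.integers(0, t, t)
            if _vaf(E[:, idx], fac.W @ fac.H[:, idx]) > config.vaf_threshold:
                hits += 1
        coverage[k] = hits / config.n_resamples
        if coverage[k] >= config.coverage:
            return SynergySelection(n_synergies=k, coverage=coverage, vaf=vaf)
    return SynergySelection(n_synergies=None, coverage=coverage, vaf=vaf,
                            insufficient_vaf=True)


def emg_informed_activations(
    model: MusculoskeletalModel,
    trial: TrialBundle,
    w1: float = 0.2,
    w2: float = 10.0,
    w3: float = 20.0,
    sigma_bounds: tuple[float, float] = (0.05, 20.0),
    tol: float = 1e-4,
    max_iter: int = 2000,
) -> tuple[np.ndarray, np.ndarray, dict[str, float], bool]:
    """EMG-informed static optimization on a (tuned) model.

    Minimizes activation effort + reserve penalty + EMG-similarity subject to
    per-frame moment equilibrium. The bilinear sigma*a coupling is resolved
    by alternating exact steps: per-frame box-constrained least squares in
    the activations (sigma fixed), then the closed-form least-squares update
    sigma_m = sum_i a_mi eps_mi / sum_i a_mi^2, clipped to bounds, until the
    largest sigma change is below ``tol``.

    Returns (activations, reserves, sigma, converged).
    """
    from .tuning import linear_force_terms, solve_activations

    trial.validate_against(model)
    names = model.muscle_names
    mapped = trial.mapped_muscles()
    eps_idx = np.array([names.index(m) for m in mapped], dtype=int)
    eps = (np.column_stack([trial.emg_for_muscle(m) for m in mapped])
           if mapped else np.zeros((trial.n_frames, 0)))
    c1, c0 = linear_force_terms(model, trial.l_mt)
    sigma = np.ones(len(mapped))
    converged = False
    a = solve_activations(trial, c1, c0, sigma, eps, eps_idx, w1, w2, w3)
    for _ in range(max_iter):
        if not len(mapped):
            converged = True
            break
        num = np.einsum("fe,fe->e", a[:, eps_idx], eps)
        den = np.maximum(np.einsum("fe,fe->e", a[:, eps_idx], a[:, eps_idx]), _EPS)
        new_sigma = np.clip(num / den, *sigma_bounds)
        change = float(np.max(np.abs(new_sigma - sigma)))
        sigma = new_sigma
        a = solve_activations(trial, c1, c0, sigma, eps, eps_idx, w1, w2, w3)
        if change < tol:
            converged = True
            break
    reserves = trial.tau_ID - np.einsum("fmj,fm->fj", trial.r, c1 * a + c0)
    return a, reserves, {m: float(s) for m, s in zip(mapped, sigma)}, converged


def build_motor_control(activations: np.ndarray, N_s: int,
                        muscle_names: list[str] | None = None,
                        restarts: int = 10, seed: int = 0) -> MotorControlModel:
    """Extract the all-muscle motor-control model with N_s + 1 synergies.

    The extra synergy accounts for muscles without surface EMG. W columns are
    rescaled to max 1 with H rescaled inversely, leaving the product W H
    unchanged.
    """
    activations = np.asarray(activations, float)
    if np.any(activations < 0):
        raise DomainError("activations must be non-negative")
    fac = nnmf_factorize(activations.T, N_s + 1, restarts=restarts, seed=seed)
    W, H = fac.W, fac.H
    scale = np.maximum(W.max(axis=0), _EPS)
    W = W / scale
    H = H * scale[:, None]
    return MotorControlModel(W_pre=W, H_pre=H, N_s=N_s,
                             muscle_names=list(muscle_names or []), vaf=fac.vaf)
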