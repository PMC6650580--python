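"""Batched box-constrained linear least squares.

Static optimization reduces, frame by frame, to

    minimize ||A_f x_f - b_f||^2   subject to  lb <= x_f <= ub,

once the reserve moments are eliminated in closed form from the moment
equilibrium (the reserve is the equilibrium residual and enters the cost as a
weighted sum of squares). The per-frame problems are tiny (a handful of
variables) but there are hundreds of frames, so they are solved together with
a vectorized active-set (BVLS-style) iteration: one stacked normal-equation
solve per iteration across all frames, with per-frame active sets encoded by
row/column substitution. Frames whose KKT conditions are not met within the
iteration budget fall back to ``scipy.optimize.lsq_linear``.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import lsq_linear

__all__ = ["boxed_lsq_batch", "boxed_lsq"]

_KKT_TOL = 1e-8  # target solution accuracy along the softest curvature direction


def _kkt_ok(G, g, x, lb, ub, tol):
    """KKT residual check for 0.5||Ax-b||^2 on a box; G = A'A, g = A'b.

    ``tol`` is a per-frame (F,) absolute tolerance on the gradient.
    """
    grad = np.einsum("fij,fj->fi", G, x) - g
    t = tol[:, None]
    at_lb = x <= lb + 1e-12
    at_ub = x >= ub - 1e-12
    free = ~(at_lb | at_ub)
    ok = np.ones(x.shape[0], dtype=bool)
    ok &= np.all(np.where(free, np.abs(grad) <= t, True), axis=1)
    ok &= np.all(np.where(at_lb & ~at_ub, grad >= -t, True), axis=1)
    ok &= np.all(np.where(at_ub & ~at_lb, grad <= t, True), axis=1)
    return ok, grad


def boxed_lsq_batch(
    A: np.ndarray,
    b: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    tol: float = _KKT_TOL,
    max_iter: int | None = None,
) -> np.ndarray:
    """Solve min ||A[f] x - b[f]||^2 s.t. lb <= x <= ub for every frame f.

    Parameters
    ----------
    A : (F, m, n) stacked design matrices.
    b : (F, m) stacked right-hand sides.
    lb, ub : (n,) bounds shared across frames.
    """
    A = np.asarray(A, float)
    b = np.asarray(b, float)
    F, m, n = A.shape
    lb = np.broadcast_to(np.asarray(lb, float), (n,))
    ub = np.broadcast_to(np.asarray(ub, float), (n,))
    if max_iter is None:
        max_iter = 4 * n + 10

    G = np.einsum("fki,fkj->fij", A, A)
    g = np.einsum("fki,fk->fi", A, b)
    # tiny Tikhonov term keeps the stacked solves well-posed when a muscle has
    # zero moment arm and zero EMG row at some frame
    G = G + 1e-12 * np.eye(n)

    # state: 0 free, -1 at lower bound, +1 at upper bound
    state = np.zeros((F, n), dtype=np.int8)
    x = np.empty((F, n))
    # per-frame gradient tolerance tied to the smallest curvature: a gradient
    # residual of lambda_min * dx moves the solution by dx along the softest
    # direction, so this bounds the solution error directly
    lam_min = np.linalg.eigvalsh(G)[:, 0]
    scale = np.maximum(tol * np.maximum(lam_min, 1e-12),
                       1e-13 * np.abs(g).max(axis=1, initial=1.0))

    for _ in range(max_iter):
        # solve with active variables pinned via row substitution
        Gm = G.copy()
        gm = g.copy()
        active = state != 0
        if active.any():
            fi, vi = np.nonzero(active)
            Gm[fi, vi, :] = 0.0
            Gm[fi, vi, vi] = 1.0
            gm[fi, vi] = np.where(state[fi, vi] < 0, lb[vi], ub[vi])
        x = np.linalg.solve(Gm, gm[..., None])[..., 0]
        # clamp free variables that violated their bounds, activate them
        below = (state == 0) & (x < lb)
        above = (state == 0) & (x > ub)
        state[below] = -1
        state[above] = 1
        x = np.clip(x, lb, ub)
        changed = below.any(axis=1) | above.any(axis=1)
        # release active constraints with wrong-sign multipliers (one per frame)
        grad = np.einsum("fij,fj->fi", G, x) - g
        release_score = np.where(state == -1, -grad, np.where(state == 1, grad, 0.0))
        worst = np.argmax(release_score, axis=1)
        worst_val = release_score[np.arange(F), worst]
        do_release = (worst_val > scale) & ~changed
        state[np.arange(F)[do_release], worst[do_release]] = 0
        if not (changed.any() or do_release.any()):
            break

    ok, _ = _kkt_ok(G, g, x, lb, ub, scale)
    if not ok.all():
        for f in np.nonzero(~ok)[0]:
            res = lsq_linear(A[f], b[f], bounds=(lb, ub), tol=1e-12, method="bvls")
            x[f] = np.clip(res.x, lb, ub)
    return x


def boxed_lsq(A: np.ndarray, b: np.ndarray, lb, ub) -> np.ndarray:
    """Single-problem convenience wrapper around :func:`boxed_lsq_batch`."""
    return boxed_lsq_batch(A[None], b[None], lb, ub)[0]
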