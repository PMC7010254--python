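"""Oblique geomin rotation by gradient projection.

Implements the gradient-projection algorithm for oblique rotation
(Jennrich-style): the rotation matrix T is constrained to have unit-length
columns, the rotated loadings are L = A @ inv(T).T, and the criterion is
minimized by projected-gradient steps with backtracking halving. The geomin
criterion is

    q(L) = sum_i ( prod_k (L[i,k]^2 + eps) )^(1/m),

the row-wise geometric mean of squared loadings plus a small eps, which is
small when each row is dominated by a single factor (simple structure).
"""

from __future__ import annotations

import numpy as np

__all__ = ["geomin_criterion", "oblique_rotate", "RotationError"]


class RotationError(RuntimeError):
    """No rotation start converged."""


def geomin_criterion(L: np.ndarray, eps: float = 0.01) -> tuple[float, np.ndarray]:
    """Geomin criterion value and its gradient with respect to L."""
    L = np.asarray(L, dtype=float)
    m = L.shape[1]
    L2 = L * L + eps
    # row geometric means via logs for numerical safety
    row_gm = np.exp(np.log(L2).sum(axis=1) / m)
    q = float(row_gm.sum())
    grad = (2.0 / m) * row_gm[:, None] * L / L2
    return q, grad


def _gpa_oblique(A: np.ndarray, T0: np.ndarray, eps: float,
                 max_iter: int = 500, tol: float = 1e-7):
    """One gradient-projection run from starting rotation T0.

    Returns (L, Phi, T, q, converged).
    """
    T = T0 / np.sqrt((T0 * T0).sum(axis=0))
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    q, Gq = geomin_criterion(L, eps)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    converged = False
    for _ in range(max_iter):
        Gp = G - T * (T * G).sum(axis=0)    # project onto the constraint surface
        s = np.linalg.norm(Gp)
        if s < tol:
            converged = True
            break
        al *= 2.0
        for _ in range(30):
            X = T - al * Gp
            Tt = X / np.sqrt((X * X).sum(axis=0))
            Ti = np.linalg.inv(Tt)
            Lt = A @ Ti.T
            qt, Gq = geomin_criterion(Lt, eps)
            if qt < q - 0.5 * s * s * al:
                break
            al /= 2.0
        T, L, q = Tt, Lt, qt
        G = -(L.T @ Gq @ Ti).T
    return L, T.T @ T, T, q, converged


def oblique_rotate(A: np.ndarray, eps: float = 0.01, n_starts: int = 30,
                   seed: int = 0, max_iter: int = 500, tol: float = 1e-7):
    """Geomin-rotate an unrotated loading matrix, best of random starts.

    Starts are the identity plus ``n_starts - 1`` random orthonormal
    matrices; the run with the lowest criterion value wins (ties keep the
    first found). Returns ``(L, Phi, q_min, n_converged)``.
    """
    A = np.asarray(A, dtype=float)
    m = A.shape[1]
    if m == 1:
        return A.copy(), np.ones((1, 1)), geomin_criterion(A, eps)[0], 1
    rng = np.random.default_rng(seed)
    best = None
    n_converged = 0
    for k in range(max(1, n_starts)):
        if k == 0:
            T0 = np.eye(m)
        else:
            T0 = np.linalg.qr(rng.standard_normal((m, m)))[0]
        L, Phi, _T, q, conv = _gpa_oblique(A, T0, eps, max_iter=max_iter, tol=tol)
        n_converged += conv
        if conv and (best is None or q < best[2] - 1e-12):
            best = (L, Phi, q)
    if best is None:
        raise RotationError(f"no geomin rotation start converged in {n_starts} starts")
    L, Phi, q = best
    return L, Phi, q, n_converged
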