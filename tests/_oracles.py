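"""Independent second implementations used as test oracles.

Everything here is deliberately written by a different route than the
package code it checks: explicit loops instead of vectorized algebra, direct
optimization over all parameters instead of profiled likelihoods, alternating
projections instead of clip-and-rescale.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def sigma_double_loop(lam, phi, psi):
    """Element-by-element evaluation of Lambda Phi Lambda' + diag(Psi)."""
    p, m = lam.shape
    sigma = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            acc = 0.0
            for a in range(m):
                for b in range(m):
                    acc += lam[i, a] * phi[a, b] * lam[j, b]
            sigma[i, j] = acc + (psi[i] if i == j else 0.0)
    return sigma


def srmr_double_loop(r, sigma):
    """Root mean square residual over entries with i <= j, by explicit loop."""
    p = r.shape[0]
    total, count = 0.0, 0
    for i in range(p):
        for j in range(i, p):
            total += (r[i, j] - sigma[i, j]) ** 2
            count += 1
    return np.sqrt(total / count)


def intersection_count_loop(a, b):
    """Brute-force voxel count of a logical AND of two boolean grids."""
    count = 0
    for idx in np.ndindex(a.shape):
        if a[idx] and b[idx]:
            count += 1
    return count


def nearest_pd_alternating(r, eig_floor=1e-6, n_iter=500):
    """Alternating projection onto {eigenvalues >= floor} and {unit diagonal}."""
    m = 0.5 * (np.asarray(r, float) + np.asarray(r, float).T)
    for _ in range(n_iter):
        w, v = np.linalg.eigh(m)
        m = (v * np.maximum(w, eig_floor)) @ v.T
        np.fill_diagonal(m, 1.0)
        m = 0.5 * (m + m.T)
    return m


def ml_discrepancy_direct(r, m, n_restarts=50, seed=0, psi_floor=1e-3):
    """ML factor-analysis discrepancy by direct optimization.

    Optimizes all p*m loadings and p box-bounded uniquenesses jointly (no
    profiling), with the analytic gradient dF/dSigma = Sigma^-1 (Sigma - R)
    Sigma^-1. Returns the best F over restarts (a principal-axis start plus
    random ones).
    """
    r = np.asarray(r, float)
    p = r.shape[0]
    rng = np.random.default_rng(seed)
    _, logdet_r = np.linalg.slogdet(r)

    def fun(x):
        lam = x[: p * m].reshape(p, m)
        psi = x[p * m:]
        sigma = lam @ lam.T + np.diag(psi)
        sign, logdet_s = np.linalg.slogdet(sigma)
        if sign <= 0:
            return 1e10, np.zeros_like(x)
        si = np.linalg.inv(sigma)
        f = logdet_s + np.trace(si @ r) - logdet_r - p
        dsig = si @ (sigma - r) @ si
        glam = 2.0 * dsig @ lam
        return f, np.concatenate([glam.ravel(), np.diag(dsig)])

    # principal-axis starting point (standard initialization): loadings from
    # the top-m eigenpairs of R with SMC-reduced diagonal
    smc = 1.0 - 1.0 / np.diag(np.linalg.inv(r))
    red = r.copy()
    np.fill_diagonal(red, smc)
    w, v = np.linalg.eigh(red)
    lam_pa = v[:, -m:] * np.sqrt(np.maximum(w[-m:], 0.01))
    psi_pa = np.clip(1.0 - (lam_pa ** 2).sum(axis=1), 0.05, 0.95)

    bounds = [(None, None)] * (p * m) + [(psi_floor, 1.0)] * p
    best = np.inf
    for k in range(n_restarts):
        if k == 0:
            lam0, psi0 = lam_pa, psi_pa
        else:
            lam0 = 0.5 * rng.standard_normal((p, m))
            psi0 = rng.uniform(0.2, 0.8, p)
        x0 = np.concatenate([lam0.ravel(), psi0])
        res = optimize.minimize(fun, x0, jac=True, method="L-BFGS-B",
                                bounds=bounds,
                                options={"maxiter": 2000, "ftol": 1e-14,
                                         "gtol": 1e-10})
        if res.fun < best:
            best = float(res.fun)
    return best


def random_pd_correlation(p, rng, n_factors=4):
    """Random PD correlation matrix with factor-like structure plus noise."""
    lam = 0.6 * rng.standard_normal((p, n_factors))
    e = 0.3 * rng.standard_normal((p, p))
    cov = lam @ lam.T + e @ e.T + 0.2 * np.eye(p)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)
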