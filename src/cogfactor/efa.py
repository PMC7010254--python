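"""Exploratory factor analysis on a correlation matrix.

Maximum-likelihood extraction by profiling the loadings out of the normal
discrepancy function, oblique geomin rotation (see :mod:`.rotation`), the
chi-square model test with the standard SEM fit indices (CFI, TLI, RMSEA,
SRMR), parameter accounting, and Heywood-case diagnostics.

The discrepancy for a candidate uniqueness vector Psi is

    F(Psi) = log|Sigma| + tr(R Sigma^-1) - log|R| - p,
    Sigma  = Lambda Lambda' + diag(Psi),

minimized over Lambda analytically via the eigendecomposition of
Psi^-1/2 R Psi^-1/2 (Lawley-Maxwell): with eigenvalues theta_1 >= ... >=
theta_p the profiled discrepancy is sum_{k>m} (theta_k - log theta_k - 1),
and the conditionally optimal loadings are
Psi^1/2 V_m (max(Theta_m - I, 0))^1/2. The remaining p-dimensional problem
in Psi is solved with bound-constrained quasi-Newton iterations from
several starting points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .rotation import oblique_rotate

__all__ = [
    "CorrelationInput",
    "EFAModel",
    "FitStatistics",
    "UnderIdentifiedModelError",
    "NotPositiveDefiniteError",
    "ConvergenceError",
    "model_df",
    "count_free_parameters",
    "extract_ml",
    "rotate_geomin",
    "chi_square_p",
    "fit_statistics",
    "loading_quality",
    "LOADING_BANDS",
    "MIN_INTERPRETABLE_LOADING",
]


class UnderIdentifiedModelError(ValueError):
    """Requested factor count leaves the model with negative test df."""


class NotPositiveDefiniteError(ValueError):
    """Input correlation matrix is not positive definite (repair it first)."""


class ConvergenceError(RuntimeError):
    """No optimization restart converged."""


@dataclass
class CorrelationInput:
    """A correlation matrix plus the effective sample size behind it.

    ``n_effective`` scales the chi-square test statistic; for behavioral
    data it is a participant count, for map-similarity matrices a voxel
    count (see the pipeline). ``available_n`` optionally records the
    pairwise available-case counts the matrix was computed from.
    """

    matrix: np.ndarray
    n_effective: int
    source: str = "behavioral"
    available_n: np.ndarray | None = None
    task_names: tuple[str, ...] | None = None

    def __post_init__(self):
        r = np.asarray(self.matrix, dtype=float)
        p = r.shape[0]
        if r.shape != (p, p) or p < 3:
            raise ValueError("correlation matrix must be square with p >= 3")
        if not np.allclose(r, r.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-8):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(r).min() <= 0:
            raise NotPositiveDefiniteError(
                "correlation matrix is not positive definite; apply "
                "nearest_pd_repair before factor analysis")
        self.matrix = 0.5 * (r + r.T)

    @property
    def n_tasks(self) -> int:
        return self.matrix.shape[0]


@dataclass
class EFAModel:
    """An m-factor solution for one correlation matrix."""

    loadings: np.ndarray               # p x m, rotated if rotation != "none"
    factor_corr: np.ndarray            # m x m
    uniquenesses: np.ndarray           # length p
    unrotated_loadings: np.ndarray     # p x m
    rotation: str = "none"
    geomin_eps: float = 0.01
    converged: bool = False
    n_restarts_used: int = 0
    discrepancy: float = np.nan        # F_min at the ML solution
    psi_floor: float = 1e-3

    @property
    def n_tasks(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    @property
    def communalities(self) -> np.ndarray:
        return 1.0 - self.uniquenesses

    @property
    def heywood(self) -> bool:
        """True when any uniqueness sits at its lower bound, i.e. the
        unconstrained optimum would have a zero/negative residual variance."""
        return bool(np.any(self.uniquenesses <= self.psi_floor * (1 + 1e-6)))

    def implied(self) -> np.ndarray:
        """Model-implied correlation matrix (rotation-invariant)."""
        return (self.loadings @ self.factor_corr @ self.loadings.T
                + np.diag(self.uniquenesses))


@dataclass
class FitStatistics:
    chi_square: float
    df: int
    p_value: float
    cfi: float
    tli: float
    rmsea: float
    srmr: float
    n_free_params: int
    heywood: bool

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("chi_square", "df", "p_value", "cfi", "tli", "rmsea",
                 "srmr", "n_free_params", "heywood")}


# ---------------------------------------------------------------------------
# Counting

def model_df(p: int, m: int) -> int:
    """Test degrees of freedom of an m-factor model of p indicators:
    ((p - m)^2 - (p + m)) / 2. Raises when negative (under-identified)."""
    if not (p >= m >= 1):
        raise ValueError(f"need p >= m >= 1, got p={p}, m={m}")
    num = (p - m) ** 2 - (p + m)
    if num < 0:
        raise UnderIdentifiedModelError(
            f"{m} factors for {p} indicators leaves df = {num / 2} < 0")
    if num % 2:
        raise UnderIdentifiedModelError(
            f"df for p={p}, m={m} is not an integer")
    return num // 2


def count_free_parameters(p: int, m: int, mean_structure: bool) -> int:
    """Free parameters of an oblique EFA model: p(m+1) loadings and
    uniquenesses minus m(m-1)/2 rotational constraints, plus p indicator
    means when a mean structure is estimated."""
    if not (p >= m >= 1):
        raise ValueError(f"need p >= m >= 1, got p={p}, m={m}")
    n = p * (m + 1) - m * (m - 1) // 2
    return n + p if mean_structure else n


# ---------------------------------------------------------------------------
# ML extraction

def _profile_discrepancy(psi: np.ndarray, R: np.ndarray, m: int):
    """Profiled discrepancy F(Psi) and its gradient."""
    sp = np.sqrt(psi)
    s_star = R / np.outer(sp, sp)
    theta, v = np.linalg.eigh(s_star)        # ascending
    tail = theta[: len(psi) - m]             # the p - m smallest
    f = float(np.sum(tail - np.log(tail) - 1.0))
    vt = v[:, : len(psi) - m]
    grad = -(vt * vt * (tail - 1.0)).sum(axis=1) / psi
    return f, grad


def _loadings_from_psi(psi: np.ndarray, R: np.ndarray, m: int) -> np.ndarray:
    sp = np.sqrt(psi)
    s_star = R / np.outer(sp, sp)
    theta, v = np.linalg.eigh(s_star)
    top = slice(len(psi) - m, len(psi))
    lam = v[:, top] * np.sqrt(np.maximum(theta[top] - 1.0, 0.0))
    lam = sp[:, None] * lam
    return lam[:, ::-1]                      # largest factor first


def extract_ml(R: CorrelationInput, m: int, psi_floor: float = 1e-3,
               n_restarts: int = 10, seed: int = 0) -> EFAModel:
    """Maximum-likelihood factor extraction (unrotated).

    Uniquenesses are box-constrained to ``[psi_floor, 1]``; a solution on
    the lower bound is a Heywood case and is flagged, not silently accepted.
    The first start is the squared-multiple-correlation heuristic
    ``psi = 1 - SMC``; further restarts alternate between log-space
    perturbations of it and uniform draws over (0.05, 0.95), the latter so
    that boundary (Heywood) optima outside the SMC basin are still found.
    The best converged restart is kept.
    """
    r = R.matrix
    p = R.n_tasks
    model_df(p, m)                           # raises if under-identified
    rng = np.random.default_rng(seed)
    smc = 1.0 - 1.0 / np.diag(np.linalg.inv(r))
    psi0 = np.clip(1.0 - smc, 0.05, 0.95)
    bounds = [(psi_floor, 1.0)] * p

    best = None
    n_used = 0
    for k in range(max(1, n_restarts)):
        if k == 0:
            start = psi0
        elif k % 2:
            start = np.clip(psi0 * np.exp(0.5 * rng.standard_normal(p)),
                            psi_floor, 1.0)
        else:
            start = rng.uniform(0.05, 0.95, p)
        res = optimize.minimize(
            _profile_discrepancy, start, args=(r, m), jac=True,
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-8})
        n_used = k + 1
        if not res.success:
            continue
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None:
        raise ConvergenceError(
            f"no ML restart converged for m={m} (tried {n_used})")
    psi = np.asarray(best.x)
    lam = _loadings_from_psi(psi, r, m)
    return EFAModel(
        loadings=lam, factor_corr=np.eye(m), uniquenesses=psi,
        unrotated_loadings=lam, rotation="none", converged=True,
        n_restarts_used=n_used, discrepancy=float(best.fun),
        psi_floor=psi_floor)


def rotate_geomin(model: EFAModel, eps: float = 0.01, n_starts: int = 30,
                  seed: int = 0) -> EFAModel:
    """Oblique geomin rotation of an extracted model.

    A single factor admits no rotation and is returned unchanged. The
    implied correlation matrix is invariant under rotation (the model fits
    identically); only the loading pattern and factor correlations change.
    """
    if model.n_factors == 1:
        return model
    L, phi, _q, _n = oblique_rotate(model.unrotated_loadings, eps=eps,
                                    n_starts=n_starts, seed=seed)
    from dataclasses import replace
    return replace(model, loadings=L, factor_corr=phi,
                   rotation="geomin", geomin_eps=eps)


# ---------------------------------------------------------------------------
# Fit

def chi_square_p(chi2: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution."""
    if chi2 < 0 or df < 1:
        raise ValueError("need chi2 >= 0 and df >= 1")
    return float(stats.chi2.sf(chi2, df))


def _discrepancy_at(R: np.ndarray, sigma: np.ndarray) -> float:
    sign, logdet_s = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    _, logdet_r = np.linalg.slogdet(R)
    p = R.shape[0]
    return float(logdet_s + np.trace(np.linalg.solve(sigma, R)) - logdet_r - p)


def _chi2_multiplier(n: int, p: int, m: int, chi2_scale: str) -> float:
    if chi2_scale == "bartlett":
        # Lawley-Bartlett finite-sample correction for the ML factor test
        return n - 1 - (2 * p + 5) / 6 - 2 * m / 3
    if chi2_scale == "n-1":
        return n - 1
    if chi2_scale == "n":
        return n
    raise ValueError(f"unknown chi2_scale {chi2_scale!r}")


def fit_statistics(R: CorrelationInput, model: EFAModel,
                   mean_structure: bool = True,
                   chi2_scale: str = "bartlett") -> FitStatistics:
    """Chi-square test and SEM fit indices for a converged model.

    The test statistic is ``c * F_min`` where ``c`` is the Lawley-Bartlett
    corrected multiplier ``N - 1 - (2p + 5)/6 - 2m/3`` by default (the
    uncorrected ``N - 1`` and ``N`` scales are selectable); the correction
    keeps the statistic calibrated to its chi-square reference at moderate
    N. The baseline for CFI/TLI is the independence model, whose discrepancy
    for a correlation matrix is ``-log|R|`` (corrected with m = 0). RMSEA is
    zero and CFI one whenever the model chi-square does not exceed its df.
    SRMR averages squared residuals over the p(p+1)/2 entries with i <= j.
    Estimating indicator means adds p parameters but no misfit (means are
    saturated), so only the parameter count depends on ``mean_structure``.
    """
    if not model.converged:
        raise ValueError("fit statistics require a converged model")
    p, m = model.n_tasks, model.n_factors
    n = R.n_effective
    scale = _chi2_multiplier(n, p, m, chi2_scale)
    df = model_df(p, m)
    resid = R.matrix - model.implied()
    iu = np.triu_indices(p)
    srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))
    if n <= p:
        # too few observations for the test statistic to mean anything;
        # report the sample-size-free quantities only
        return FitStatistics(
            chi_square=np.nan, df=df, p_value=np.nan, cfi=np.nan,
            tli=np.nan, rmsea=np.nan, srmr=srmr,
            n_free_params=count_free_parameters(p, m, mean_structure),
            heywood=model.heywood)
    chi2 = scale * model.discrepancy
    df_b = p * (p - 1) // 2
    chi2_b = _chi2_multiplier(n, p, 0, chi2_scale) * _discrepancy_at(R.matrix, np.eye(p))

    excess = max(chi2 - df, 0.0)
    cfi = 1.0 - excess / max(chi2_b - df_b, chi2 - df, 0.0) if excess > 0 else 1.0
    denom = chi2_b / df_b - 1.0
    tli = (chi2_b / df_b - chi2 / df) / denom if df > 0 and denom != 0 else np.nan
    rmsea = np.sqrt(excess / (df * scale)) if df > 0 else 0.0
    return FitStatistics(
        chi_square=float(chi2), df=df,
        p_value=chi_square_p(max(chi2, 0.0), df) if df > 0 else np.nan,
        cfi=float(cfi), tli=float(tli), rmsea=float(rmsea), srmr=srmr,
        n_free_params=count_free_parameters(p, m, mean_structure),
        heywood=model.heywood)


# ---------------------------------------------------------------------------
# Loading interpretation

#: (lower |loading| edge, label) following the conventional guideline that a
#: loading of 0.45 is fair, 0.55 good, 0.63 very good and 0.71 excellent.
LOADING_BANDS = [
    (0.71, "excellent"),
    (0.63, "very good"),
    (0.55, "good"),
    (0.45, "fair"),
    (0.0, "poor"),
]
#: below this magnitude a loading is conventionally not interpreted at all
MIN_INTERPRETABLE_LOADING = 0.32


def factor_congruence(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Tucker congruence coefficients between loading-matrix columns.

    Entry (i, j) is the cosine between column i of ``a`` and column j of
    ``b``; 1 in absolute value means proportional loading patterns.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = np.sqrt((a * a).sum(axis=0))
    nb = np.sqrt((b * b).sum(axis=0))
    return (a.T @ b) / np.outer(na, nb)


def match_factors(target: np.ndarray, estimate: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Column-match an estimated loading matrix to a target.

    Greedy assignment on |congruence| (largest first), followed by sign
    alignment. Returns ``(reordered_estimate, congruence_per_target_column)``
    where the congruence values are signed after alignment (so a perfect
    recovery gives +1s).
    """
    c = factor_congruence(target, estimate)
    m = c.shape[0]
    perm = np.full(m, -1)
    used: set[int] = set()
    order = np.argsort(-np.abs(c), axis=None)
    for flat in order:
        i, j = divmod(int(flat), c.shape[1])
        if perm[i] == -1 and j not in used:
            perm[i] = j
            used.add(j)
        if len(used) == m:
            break
    est = estimate[:, perm].astype(float).copy()
    cong = np.empty(m)
    for i in range(m):
        s = np.sign(c[i, perm[i]]) or 1.0
        est[:, i] *= s
        cong[i] = s * c[i, perm[i]]
    return est, cong


def loading_quality(loading: float) -> str:
    """Qualitative label for a loading magnitude (sign-symmetric)."""
    a = abs(loading)
    for edge, label in LOADING_BANDS:
        if a >= edge:
            return label
    return "poor"
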