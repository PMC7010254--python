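"""Synthetic multi-task behavioral and imaging data with known latent structure.

The generators emulate a within-subject battery of 12 in-scanner cognitive
tasks spanning four domains (episodic memory retrieval, reasoning, processing
speed, vocabulary): a behavioral score table drawn from an oblique common
factor model, group-level z-statistic maps built from overlapping network
templates, and per-subject beta maps whose in-network means covary with the
subject's domain factor score. Everything is a pure function of its spec and
seed, so downstream stages (map similarity, factor analysis, brain-behavior
coupling) can be tested against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit, logit

from .map_stats import StatMap, BetaMap, GridMismatchError

__all__ = [
    "TASKS",
    "DOMAINS",
    "TASK_DOMAIN",
    "TASK_MEASURES",
    "LatentModelSpec",
    "NetworkTemplateSpec",
    "BehavioralData",
    "InvalidSpecError",
    "default_behavioral_spec",
    "default_template_spec",
    "implied_correlation",
    "generate_behavioral",
    "session_missingness",
    "generate_task_maps",
    "generate_subject_betas",
    "behavior_factor_correlation",
    "coupling_for_target_r",
    "write_behavioral_tsv",
]

# Task battery, in administration-domain order: three tasks per domain.
DOMAINS: dict[str, list[str]] = {
    "memory": ["word_order", "paired_associates", "logical_memory"],
    "reasoning": ["matrix_reasoning", "letter_sets", "paper_folding"],
    "speed": ["pattern_comparison", "letter_comparison", "digit_symbol"],
    "vocabulary": ["synonyms", "antonyms", "picture_naming"],
}
TASKS: list[str] = [t for ts in DOMAINS.values() for t in ts]
TASK_DOMAIN: dict[str, str] = {t: d for d, ts in DOMAINS.items() for t in ts}
# The three speed tasks are scored as correct-trial reaction time (lower is
# better); the other nine as proportion of correct responses.
TASK_MEASURES: dict[str, str] = {
    t: ("rt" if d == "speed" else "accuracy") for t, d in TASK_DOMAIN.items()
}

# Primary standardized loadings for the default four-factor battery, one per
# task on its own domain factor (cross-loadings zero).
_DEFAULT_PRIMARY = np.array([
    0.884, 0.628, 0.416,   # memory
    0.844, 0.852, 0.617,   # reasoning
    0.826, 0.815, 0.805,   # speed
    0.903, 0.677, 0.798,   # vocabulary
])


class InvalidSpecError(ValueError):
    """A generator spec violates its invariants."""


@dataclass(frozen=True)
class LatentModelSpec:
    """Oblique common factor model for the behavioral battery.

    The model is specified in the standardized (unit-variance) metric:
    ``diag(loadings @ factor_corr @ loadings.T + diag(uniquenesses)) == 1``
    must hold to 1e-8. ``task_measures[i]`` tags indicator i as ``accuracy``
    (proportion correct, higher = better) or ``rt`` (seconds, lower =
    better); the tag controls the observation-scale transform only, not the
    latent model.
    """

    loadings: np.ndarray
    factor_corr: np.ndarray
    uniquenesses: np.ndarray
    task_measures: tuple[str, ...]
    task_names: tuple[str, ...]
    n_subjects: int = 114
    seed: int = 0

    def __post_init__(self):
        lam = np.atleast_2d(np.asarray(self.loadings, dtype=float))
        phi = np.asarray(self.factor_corr, dtype=float)
        psi = np.asarray(self.uniquenesses, dtype=float)
        p, m = lam.shape
        if p < m:
            raise InvalidSpecError(f"need at least as many tasks as factors ({p} < {m})")
        if phi.shape != (m, m) or not np.allclose(phi, phi.T, atol=1e-10):
            raise InvalidSpecError("factor correlation matrix must be m x m symmetric")
        if not np.allclose(np.diag(phi), 1.0, atol=1e-10):
            raise InvalidSpecError("factor correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(phi).min() <= 0:
            raise InvalidSpecError("factor correlation matrix must be positive definite")
        if psi.shape != (p,) or np.any(psi <= 0):
            raise InvalidSpecError("uniquenesses must be a length-p positive vector")
        if len(self.task_measures) != p or len(self.task_names) != p:
            raise InvalidSpecError("task_measures / task_names must have one entry per task")
        bad = set(self.task_measures) - {"accuracy", "rt"}
        if bad:
            raise InvalidSpecError(f"unknown measure tags: {bad}")
        diag = np.einsum("ij,jk,ik->i", lam, phi, lam) + psi
        if np.max(np.abs(diag - 1.0)) > 1e-8:
            raise InvalidSpecError(
                "model is not in the standardized metric: "
                f"max |diag - 1| = {np.max(np.abs(diag - 1.0)):.3g}")
        object.__setattr__(self, "loadings", lam)
        object.__setattr__(self, "factor_corr", phi)
        object.__setattr__(self, "uniquenesses", psi)
        object.__setattr__(self, "task_measures", tuple(self.task_measures))
        object.__setattr__(self, "task_names", tuple(self.task_names))

    @property
    def n_tasks(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]


def default_behavioral_spec(n_subjects: int = 114, seed: int = 0,
                            factor_corr: np.ndarray | None = None) -> LatentModelSpec:
    """Four-factor, twelve-task battery with simple structure.

    Each task loads only on its own domain factor, with primary loadings in
    the 0.4-0.9 range typical of well-targeted cognitive indicators. Factors
    are moderately oblique: memory-reasoning correlates 0.5 (closely allied
    abilities), every other factor pair 0.3.
    """
    p, m = 12, 4
    lam = np.zeros((p, m))
    for i, t in enumerate(TASKS):
        lam[i, list(DOMAINS).index(TASK_DOMAIN[t])] = _DEFAULT_PRIMARY[i]
    if factor_corr is None:
        phi = np.full((m, m), 0.3)
        phi[0, 1] = phi[1, 0] = 0.5
        np.fill_diagonal(phi, 1.0)
    else:
        phi = np.asarray(factor_corr, dtype=float)
    psi = 1.0 - np.einsum("ij,jk,ik->i", lam, phi, lam)
    return LatentModelSpec(
        loadings=lam, factor_corr=phi, uniquenesses=psi,
        task_measures=tuple(TASK_MEASURES[t] for t in TASKS),
        task_names=tuple(TASKS), n_subjects=n_subjects, seed=seed)


def implied_correlation(spec: LatentModelSpec) -> np.ndarray:
    """Model-implied indicator correlation matrix, Lambda Phi Lambda' + Psi."""
    sigma = spec.loadings @ spec.factor_corr @ spec.loadings.T + np.diag(spec.uniquenesses)
    return 0.5 * (sigma + sigma.T)


# ---------------------------------------------------------------------------
# Behavioral scores

# Observation-scale transforms. EFA consumes correlations, so any strictly
# monotone transform preserves the planted structure up to the (small)
# nonlinearity of Pearson r; these only make fixtures look like real scores.
_ACC_CENTER = float(logit(0.75))   # mean accuracy ~0.75
_ACC_SLOPE = 1.0
_RT_SCALE = 2.0                    # median RT ~2 s
_RT_SLOPE = 0.5


def _accuracy_transform(y: np.ndarray) -> np.ndarray:
    return expit(_ACC_CENTER + _ACC_SLOPE * y)


def _rt_transform(y: np.ndarray) -> np.ndarray:
    # monotone *decreasing*: higher latent ability -> shorter reaction time,
    # which is what makes speed-task loadings oppose accuracy-task loadings
    # in the raw-score factor solution.
    return _RT_SCALE * np.exp(-_RT_SLOPE * y)


@dataclass
class BehavioralData:
    """Generated score table plus the latent draw that produced it."""

    scores: pd.DataFrame            # n_subjects x p, observed scale, NaN = missing
    latent_scores: np.ndarray       # n_subjects x p, pre-transform y = Lambda f + eps
    factor_scores: np.ndarray       # n_subjects x m
    observed: np.ndarray            # n_subjects x p boolean
    spec: LatentModelSpec

    @property
    def task_names(self) -> tuple[str, ...]:
        return self.spec.task_names


def session_missingness(n_subjects: int = 114, n_complete: int = 72,
                        seed: int = 0) -> np.ndarray:
    """Session-structured missingness for the two-session battery design.

    The twelve tasks were administered six per session (memory+reasoning in
    one, speed+vocabulary in the other). Dropout is therefore by session, not
    task-at-random: ``n_complete`` subjects complete both sessions and the
    rest are split between single-session completers, half of whom also
    finish the first task of their missing session. Returns an
    (n_subjects, 12) boolean observed matrix.
    """
    if not 0 < n_complete <= n_subjects:
        raise InvalidSpecError("n_complete must be in (0, n_subjects]")
    rng = np.random.default_rng(seed)
    obs = np.ones((n_subjects, 12), dtype=bool)
    session_a = [i for i, t in enumerate(TASKS) if TASK_DOMAIN[t] in ("memory", "reasoning")]
    session_b = [i for i, t in enumerate(TASKS) if TASK_DOMAIN[t] in ("speed", "vocabulary")]
    partial = rng.permutation(np.arange(n_complete, n_subjects))
    for k, s in enumerate(partial):
        missing = session_b if k % 2 == 0 else session_a
        if k % 4 < 2:          # half the partial subjects start the other session
            missing = missing[1:]
        obs[s, missing] = False
    return obs


def generate_behavioral(spec: LatentModelSpec,
                        missing_pattern: np.ndarray | None = None) -> BehavioralData:
    """Draw behavioral scores from the latent model.

    Latent-scale scores are ``y = f @ Lambda.T + eps`` with
    ``f ~ MVN(0, Phi)`` and ``eps ~ MVN(0, diag(Psi))``; accuracy tasks are
    then squashed into (0, 1) and speed tasks mapped to positive seconds by a
    decreasing transform. ``missing_pattern`` is an (n_subjects, p) boolean
    observed matrix; it must leave every subject at least two observed tasks.
    """
    rng = np.random.default_rng(spec.seed)
    n, p, m = spec.n_subjects, spec.n_tasks, spec.n_factors
    if n < p:
        import warnings
        warnings.warn(
            f"n_subjects ({n}) < n_tasks ({p}): factor analysis of the "
            "resulting table will be unstable", stacklevel=2)
    chol = np.linalg.cholesky(spec.factor_corr)
    f = rng.standard_normal((n, m)) @ chol.T
    eps = rng.standard_normal((n, p)) * np.sqrt(spec.uniquenesses)
    y = f @ spec.loadings.T + eps

    scores = np.empty_like(y)
    for j, meas in enumerate(spec.task_measures):
        scores[:, j] = (_accuracy_transform(y[:, j]) if meas == "accuracy"
                        else _rt_transform(y[:, j]))

    if missing_pattern is None:
        observed = np.ones((n, p), dtype=bool)
    else:
        observed = np.asarray(missing_pattern, dtype=bool)
        if observed.shape != (n, p):
            raise InvalidSpecError(
                f"missing pattern shape {observed.shape} != ({n}, {p})")
        if (observed.sum(axis=1) < 2).any():
            raise InvalidSpecError("every subject needs at least 2 observed tasks")
        scores = np.where(observed, scores, np.nan)

    df = pd.DataFrame(scores, columns=list(spec.task_names))
    df.index.name = "subject"
    return BehavioralData(scores=df, latent_scores=y, factor_scores=f,
                          observed=observed, spec=spec)


def behavior_factor_correlation(spec: LatentModelSpec, domain_index: int,
                                task_indices: list[int]) -> float:
    """Population correlation between a domain factor and the mean of its
    standardized (latent-scale) indicators; used to calibrate couplings."""
    lam, phi = spec.loadings, spec.factor_corr
    k = len(task_indices)
    cov_f_s = np.mean([lam[i] @ phi[:, domain_index] for i in task_indices])
    sigma = implied_correlation(spec)
    var_s = np.mean([[sigma[i, j] for j in task_indices] for i in task_indices])
    return float(cov_f_s / np.sqrt(var_s))


# ---------------------------------------------------------------------------
# Imaging: network templates, group z-maps, subject beta maps

def _blob(grid_shape, center, radius, amplitude=1.0) -> np.ndarray:
    """Spherical bump with graded (quartic) falloff to zero at ``radius``.

    The gradient matters: masked spatial correlation between two maps is
    driven by shared within-mask topography, which a flat (binary) blob
    would not provide.
    """
    idx = np.indices(grid_shape)
    d2 = sum((idx[k] - center[k]) ** 2 for k in range(3))
    profile = 1.0 - (d2 / radius ** 2) ** 2
    return amplitude * np.clip(profile, 0.0, None)


@dataclass(frozen=True)
class NetworkTemplateSpec:
    """Spatial layout and noise model for synthetic task maps.

    ``shared_template`` holds domain-general regions active in every task
    (in the study system: cerebellar and posterior visual cortex); each
    entry of ``domain_templates`` is the network specific to one cognitive
    domain. Group z-maps are ``effect_scale * (shared + domain)`` plus
    smooth Gaussian noise; tasks of the same domain share their domain
    template, which is what makes their masked spatial correlations exceed
    between-domain ones in expectation.

    ``coupling[d]`` is the slope (beta units per factor-score SD) linking a
    subject's domain-d factor score to their in-network mean beta;
    ``subject_noise_sd`` is the SD of the subject-level network-mean
    perturbation and ``beta_voxel_sd`` the SD of unsmoothed voxel noise in
    the beta maps.
    """

    grid_shape: tuple[int, int, int]
    shared_template: np.ndarray
    domain_templates: dict[str, np.ndarray]
    task_domain: dict[str, str]
    smoothing_fwhm: float = 2.0
    noise_sd: float = 1.0
    effect_scale: float = 5.0
    coupling: dict[str, float] = field(default_factory=dict)
    baseline: float = 1.0
    subject_noise_sd: float = 0.5
    beta_voxel_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.smoothing_fwhm < 0:
            raise InvalidSpecError("smoothing_fwhm must be >= 0")
        if self.shared_template.shape != tuple(self.grid_shape):
            raise InvalidSpecError("shared template does not match grid shape")
        for d, t in self.domain_templates.items():
            if t.shape != tuple(self.grid_shape):
                raise InvalidSpecError(f"domain template {d!r} does not match grid shape")
            if not (t > 0).any():
                raise InvalidSpecError(f"domain template {d!r} has no positive voxels")
        counts = {}
        for t, d in self.task_domain.items():
            if d not in self.domain_templates:
                raise InvalidSpecError(f"task {t!r} maps to unknown domain {d!r}")
            counts[d] = counts.get(d, 0) + 1

    @property
    def tasks(self) -> list[str]:
        return list(self.task_domain)

    @property
    def domains(self) -> list[str]:
        return list(self.domain_templates)


def default_template_spec(seed: int = 0, grid: int = 24, noise_sd: float = 0.3,
                          coupling: dict[str, float] | None = None) -> NetworkTemplateSpec:
    """Desk-scale layout: a 24^3 grid, one shared central blob, four disjoint
    domain blobs.

    The shared (domain-general) template peaks at 0.7 of the domain
    templates' unit peak, so between-domain pairs — whose intersection mask
    reduces to the shared regions — correlate positively but more weakly
    than same-domain pairs, whose masks also contain the common domain
    gradient. With ``effect_scale`` 5 and the default z threshold 2.3 each
    domain mask keeps a few hundred voxels.
    """
    shape = (grid, grid, grid)
    c = grid // 2
    shared = _blob(shape, (c, c, c), grid / 5.0, amplitude=0.7)
    lo, hi = round(0.25 * grid), round(0.71 * grid)
    centers = [(lo, lo, lo), (lo, hi, hi), (hi, lo, hi), (hi, hi, lo)]
    domain_templates = {
        d: _blob(shape, ctr, grid / 5.0) for d, ctr in zip(DOMAINS, centers)
    }
    return NetworkTemplateSpec(
        grid_shape=shape, shared_template=shared,
        domain_templates=domain_templates, task_domain=dict(TASK_DOMAIN),
        noise_sd=noise_sd, coupling=coupling or {}, seed=seed)


def _smooth_noise(rng, shape, sd, fwhm, white_frac=0.5) -> np.ndarray:
    """Gaussian field noise: a smoothed component (spatial correlation length
    set by ``fwhm``) mixed with a voxelwise white component.

    The white fraction keeps the effective number of independent voxels per
    mask realistic; purely smooth noise at FWHM 2 leaves so few spatial
    degrees of freedom over a few-hundred-voxel mask that the assembled
    pair-correlation matrix becomes grossly rank-deficient.
    """
    noise = rng.standard_normal(shape)
    if fwhm > 0 and sd > 0 and white_frac < 1.0:
        sigma = fwhm / 2.35482
        smooth = ndimage.gaussian_filter(noise, sigma)
        smooth /= smooth.std()     # restore unit amplitude after smoothing
        white = rng.standard_normal(shape)
        noise = np.sqrt(1.0 - white_frac) * smooth + np.sqrt(white_frac) * white
    return sd * noise


def generate_task_maps(spec: NetworkTemplateSpec) -> dict[str, StatMap]:
    """One group-level z-statistic map per task.

    ``effect_scale * (shared + domain template)`` plus smoothed Gaussian
    noise of SD ``noise_sd``; same-domain tasks differ only in their noise
    realization.
    """
    rng = np.random.default_rng(spec.seed)
    out = {}
    for task in spec.tasks:
        signal = spec.effect_scale * (
            spec.shared_template + spec.domain_templates[spec.task_domain[task]])
        noise = _smooth_noise(rng, spec.grid_shape, spec.noise_sd, spec.smoothing_fwhm)
        out[task] = StatMap(signal + noise, task_id=task)
    return out


def generate_subject_betas(spec: NetworkTemplateSpec, latent: LatentModelSpec,
                           factor_scores: np.ndarray,
                           tasks: list[str] | None = None,
                           ) -> dict[tuple[int, str], BetaMap]:
    """Per-subject, per-task beta maps with planted brain-behavior coupling.

    Subject s's map for a domain-d task is
    ``(baseline + coupling[d] * f[s, d] + eta) * (shared + domain template)``
    plus voxel noise, with ``eta ~ N(0, subject_noise_sd)`` drawn per
    subject-task. The in-network mean beta is therefore linear in the
    subject's domain factor score, so the planted brain-behavior correlation
    is recoverable by the pipeline. ``factor_scores`` must come from the same
    latent draw as the behavioral table (``BehavioralData.factor_scores``).
    """
    f = np.asarray(factor_scores, dtype=float)
    if f.shape != (latent.n_subjects, latent.n_factors):
        raise InvalidSpecError(
            f"factor_scores shape {f.shape} != ({latent.n_subjects}, {latent.n_factors})")
    domains = list(DOMAINS)
    tasks = list(spec.tasks) if tasks is None else list(tasks)
    rng = np.random.default_rng((spec.seed, 1))
    out = {}
    n_vox = int(np.prod(spec.grid_shape))
    for task in tasks:
        d = spec.task_domain[task]
        di = domains.index(d)
        profile = spec.shared_template + spec.domain_templates[d]
        amp = (spec.baseline + spec.coupling.get(d, 0.0) * f[:, di]
               + spec.subject_noise_sd * rng.standard_normal(latent.n_subjects))
        noise = spec.beta_voxel_sd * rng.standard_normal((latent.n_subjects, n_vox))
        vals = amp[:, None] * profile.reshape(1, -1) + noise
        for s in range(latent.n_subjects):
            out[(s, task)] = BetaMap(vals[s].reshape(spec.grid_shape),
                                     subject_id=f"sub-{s:03d}", task_id=task)
    return out


def coupling_for_target_r(target_r: float, tspec: NetworkTemplateSpec,
                          latent: LatentModelSpec, domain: str) -> float:
    """Coupling slope that plants a given population brain-behavior r.

    The pipeline correlates the three-task-average in-network mean beta with
    the three-task-average standardized behavioral score. On the latent
    scale, beta_mean = baseline + c*f + eta_bar with eta_bar SD
    ``subject_noise_sd / sqrt(3)`` (voxel noise averages out over the
    network), and corr(f, behavior score) = rho from the factor model, so
    r = c*rho / sqrt(c^2 + var(eta_bar)). Inverts that for c.
    """
    domains = list(DOMAINS)
    di = domains.index(domain)
    idx = [latent.task_names.index(t) for t in DOMAINS[domain]]
    rho = behavior_factor_correlation(latent, di, idx)
    t = target_r / rho
    if not 0 <= abs(t) < 1:
        raise InvalidSpecError(
            f"target r {target_r} exceeds the behavioral score reliability {rho:.3f}")
    sigma = tspec.subject_noise_sd / np.sqrt(3.0)
    return float(sigma * t / np.sqrt(1.0 - t * t))


# ---------------------------------------------------------------------------
# Tabular output

def write_behavioral_tsv(data: BehavioralData, out_dir: str | Path,
                         stem: str = "behavior") -> Path:
    """TSV score table (empty cell = missing) plus a JSON sidecar with the
    measure types and generating spec."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{stem}.tsv"
    data.scores.to_csv(path, sep="\t", na_rep="")
    sidecar = {
        "task_measures": dict(zip(data.spec.task_names, data.spec.task_measures)),
        "n_subjects": data.spec.n_subjects,
        "seed": data.spec.seed,
        "loadings": data.spec.loadings.tolist(),
        "factor_corr": data.spec.factor_corr.tolist(),
        "uniquenesses": data.spec.uniquenesses.tolist(),
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
    return path
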