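"""End-to-end orchestration of the latent-structure analysis.

Behavioral EFA across candidate factor counts, the parallel EFA of the
task-pair map-similarity matrix, model comparison and selection, loading-
based factor membership, per-domain conjunction masks, and the
brain-behavior coupling analysis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import efa as efa_mod
from . import map_stats as ms
from . import synthetic as syn
from .efa import CorrelationInput, EFAModel, FitStatistics

logger = logging.getLogger("cogfactor")

__all__ = [
    "EFAConfig",
    "ModelComparison",
    "DomainAssignment",
    "BrainBehaviorResult",
    "behavioral_correlation",
    "run_behavioral_efa",
    "run_neural_efa",
    "assign_membership",
    "compare_and_select",
    "brain_behavior",
    "run_pipeline",
    "render_report",
]


@dataclass
class EFAConfig:
    """Tunable knobs shared by the behavioral and neural EFA stages."""

    rotation: str = "geomin"          # "geomin" or "none"
    geomin_eps: float = 0.01
    n_restarts: int = 10              # ML extraction restarts
    rotation_starts: int = 30
    psi_floor: float = 1e-3
    missing_policy: str = "pairwise"  # "pairwise" or "listwise"
    chi2_scale: str = "bartlett"      # "bartlett", "n-1" or "n"
    seed: int = 0


@dataclass
class ModelComparison:
    """Fitted models and fit statistics for each candidate factor count."""

    models: dict[int, EFAModel]
    fits: dict[int, FitStatistics]
    corr: CorrelationInput
    selected_m: int | None = None
    selection_rationale: str = ""

    def table(self) -> pd.DataFrame:
        rows = []
        for m in sorted(self.fits):
            f = self.fits[m]
            rows.append({"n_factors": m, **f.as_dict()})
        return pd.DataFrame(rows).set_index("n_factors")


@dataclass
class DomainAssignment:
    """Task -> factor membership derived from a rotated loading matrix."""

    factors: dict[int, list[str]]         # factor index -> ordered task list
    winning_loading: dict[str, float]
    rule: str = "max_loading"

    def partition(self) -> frozenset[frozenset[str]]:
        """Unlabeled partition of tasks, for cross-modal agreement checks."""
        return frozenset(frozenset(ts) for ts in self.factors.values() if ts)


@dataclass
class DomainCoupling:
    r: float
    p: float
    n: int
    outliers_removed: list[int]
    r_without_outliers: float
    p_without_outliers: float


@dataclass
class BrainBehaviorResult:
    domains: dict[str, DomainCoupling]
    outlier_sd: float


# ---------------------------------------------------------------------------
# Correlation assembly

def behavioral_correlation(data, policy: str = "pairwise",
                           repair: bool = True) -> CorrelationInput:
    """Correlation matrix of the score table under a missing-data policy.

    ``pairwise`` uses all available cases per task pair, with
    ``n_effective`` the median pairwise count; ``listwise`` keeps complete
    rows only. Pairwise-complete matrices are not guaranteed PD, so an
    eigenvalue repair is applied when needed (and logged).
    """
    df = data.scores if isinstance(data, syn.BehavioralData) else pd.DataFrame(data)
    if policy == "listwise":
        df = df.dropna()
        r = df.corr().to_numpy()
        n_eff = len(df)
        counts = np.full((df.shape[1],) * 2, len(df))
    elif policy == "pairwise":
        r = df.corr(min_periods=3).to_numpy()
        obs = df.notna().to_numpy().astype(int)
        counts = obs.T @ obs
        iu = np.triu_indices(df.shape[1], k=1)
        n_eff = int(np.median(counts[iu]))
    else:
        raise ValueError(f"unknown missing-data policy {policy!r}")
    if np.isnan(r).any():
        raise ValueError("correlation undefined for some task pair; "
                         "too few overlapping observations")
    if repair:
        r, touched = ms.clip_rescale_pd(r)
        if touched:
            logger.info("behavioral correlation matrix required PD repair")
    return CorrelationInput(matrix=r, n_effective=n_eff, source="behavioral",
                            available_n=counts,
                            task_names=tuple(df.columns))


# ---------------------------------------------------------------------------
# EFA stages

def _fit_models(corr: CorrelationInput, m_list, config: EFAConfig,
                mean_structure: bool) -> ModelComparison:
    models, fits = {}, {}
    for m in m_list:
        try:
            model = efa_mod.extract_ml(
                corr, m, psi_floor=config.psi_floor,
                n_restarts=config.n_restarts, seed=config.seed)
            if config.rotation == "geomin":
                model = efa_mod.rotate_geomin(
                    model, eps=config.geomin_eps,
                    n_starts=config.rotation_starts, seed=config.seed)
            models[m] = model
            fits[m] = efa_mod.fit_statistics(
                corr, model, mean_structure=mean_structure,
                chi2_scale=config.chi2_scale)
        except (efa_mod.ConvergenceError, efa_mod.UnderIdentifiedModelError) as exc:
            raise type(exc)(f"m={m}: {exc}") from exc
    mc = ModelComparison(models=models, fits=fits, corr=corr)
    if len(fits) >= 2:
        compare_and_select(mc)
    elif fits:
        mc.selected_m = next(iter(fits))
        mc.selection_rationale = "single candidate model"
    return mc


def run_behavioral_efa(data, m_list=(3, 4, 5),
                       config: EFAConfig | None = None) -> ModelComparison:
    """EFA of the behavioral score table for each candidate factor count.

    Indicator means are saturated free parameters (``mean_structure=True``),
    matching how raw-score software counts parameters; they contribute no
    misfit.
    """
    config = config or EFAConfig()
    corr = behavioral_correlation(data, policy=config.missing_policy)
    if corr.available_n is not None:
        iu = np.triu_indices(corr.n_tasks, k=1)
        logger.info("pairwise n: min=%d median=%d max=%d",
                    corr.available_n[iu].min(), np.median(corr.available_n[iu]),
                    corr.available_n[iu].max())
    return _fit_models(corr, m_list, config, mean_structure=True)


def run_neural_efa(matrix: ms.PairCorrelationMatrix, m_list=(3, 4, 5),
                   n_effective: int | None = None,
                   config: EFAConfig | None = None,
                   repair: bool = True, eig_floor: float = 1e-3) -> ModelComparison:
    """EFA of the task-pair map-similarity matrix.

    ``n_effective`` defaults to the voxel count of the union of the tasks'
    positive-activation masks (approximated by the largest pairwise
    intersection support when only the matrix is available); because the
    right effective N for a voxelwise similarity matrix is not well defined,
    treat the resulting chi-square scale as descriptive.
    """
    config = config or EFAConfig()
    if repair:
        # floor at the uniqueness-bound scale: a matrix repaired to machine-
        # level eigenvalues is still numerically singular for ML extraction
        matrix = ms.nearest_pd_repair(matrix, eig_floor=eig_floor)
        if matrix.repaired:
            logger.info("pair-correlation matrix required PD repair")
    if n_effective is None:
        n_effective = int(matrix.n_voxels.max())
    corr = CorrelationInput(matrix=matrix.r, n_effective=n_effective,
                            source="neural", available_n=matrix.n_voxels,
                            task_names=tuple(matrix.tasks))
    return _fit_models(corr, m_list, config, mean_structure=False)


# ---------------------------------------------------------------------------
# Membership and selection

def assign_membership(model: EFAModel, task_names,
                      rule: str = "max_loading",
                      a_priori: dict[str, int] | None = None) -> DomainAssignment:
    """Assign each task to one factor.

    ``max_loading`` takes the argmax of |loading| per task (ties -> lower
    factor index, with a warning); ``a_priori`` uses a supplied task ->
    factor-index map instead.
    """
    task_names = list(task_names)
    lam = model.loadings
    factors: dict[int, list[str]] = {k: [] for k in range(model.n_factors)}
    winning: dict[str, float] = {}
    for i, t in enumerate(task_names):
        if rule == "max_loading":
            row = np.abs(lam[i])
            k = int(np.argmax(row))
            if (row == row[k]).sum() > 1:
                logger.warning("task %s: tied |loading|, keeping factor %d", t, k)
        elif rule == "a_priori":
            if a_priori is None or t not in a_priori:
                raise ValueError(f"a_priori rule needs a factor index for task {t!r}")
            k = a_priori[t]
        else:
            raise ValueError(f"unknown assignment rule {rule!r}")
        factors[k].append(t)
        winning[t] = float(lam[i, k])
    for k, ts in factors.items():
        if not ts:
            logger.warning("factor %d received no tasks under %s rule", k, rule)
    return DomainAssignment(factors=factors, winning_loading=winning, rule=rule)


def compare_and_select(mc: ModelComparison, rmsea_max: float = 0.06,
                       srmr_max: float = 0.08) -> int:
    """Pick the most parsimonious adequately fitting model.

    The smallest m with RMSEA <= ``rmsea_max`` and SRMR <= ``srmr_max``
    wins; if none qualifies, the smallest-RMSEA model does. The rationale
    string records every candidate so alternatives stay visible.
    """
    if not mc.fits:
        raise ValueError("no fitted models to compare")
    lines = []
    qualifying = []
    for m in sorted(mc.fits):
        f = mc.fits[m]
        ok = f.rmsea <= rmsea_max and f.srmr <= srmr_max
        qualifying += [m] if ok else []
        lines.append(f"m={m}: RMSEA={f.rmsea:.3f} SRMR={f.srmr:.3f}"
                     f" {'qualifies' if ok else 'fails'}")
    if qualifying:
        sel = qualifying[0]
        rule = (f"smallest m with RMSEA <= {rmsea_max} and SRMR <= {srmr_max}")
    else:
        sel = min(mc.fits, key=lambda m: mc.fits[m].rmsea)
        rule = "no model qualified; smallest RMSEA"
    mc.selected_m = sel
    mc.selection_rationale = f"{rule} -> m={sel}\n" + "\n".join(lines)
    return sel


# ---------------------------------------------------------------------------
# Brain-behavior coupling

def _domain_behavior_score(df: pd.DataFrame, tasks, measures) -> pd.Series:
    """Mean of per-task standardized scores, RT tasks sign-reflected before
    standardization so that higher always means better."""
    cols = []
    for t in tasks:
        x = df[t].astype(float)
        if measures[t] == "rt":
            x = -x
        cols.append((x - x.mean()) / x.std())
    return pd.concat(cols, axis=1).mean(axis=1)


def brain_behavior(betas: dict[tuple[int, str], ms.BetaMap],
                   masks: dict[str, ms.ActivationMask],
                   behavior, assignment: dict[str, list[str]],
                   outlier_sd: float = 4.0,
                   task_measures: dict[str, str] | None = None) -> BrainBehaviorResult:
    """Correlate in-network activation magnitude with domain performance.

    For each named domain: every subject's beta maps for the domain's tasks
    are averaged over the domain's (conjunction) mask and across tasks; the
    behavioral domain score is the mean of the per-task standardized scores
    (RT reflected). Pearson r and its two-sided p are reported with and
    without mean-beta outliers (subjects beyond ``outlier_sd`` group-SDs).

    ``assignment`` maps domain name -> task list (e.g. from
    :class:`DomainAssignment` or the a-priori battery design). Domains
    without any available beta maps are skipped.
    """
    if isinstance(behavior, syn.BehavioralData):
        df = behavior.scores
        task_measures = dict(zip(behavior.spec.task_names, behavior.spec.task_measures))
    else:
        df = pd.DataFrame(behavior)
        if task_measures is None:
            raise ValueError("task_measures required when behavior is a plain table")
    n_subj = len(df)
    out: dict[str, DomainCoupling] = {}
    for domain, tasks in assignment.items():
        if domain not in masks:
            continue
        mask = masks[domain]
        if mask.voxel_count == 0:
            raise ValueError(f"domain {domain!r} has an empty mask")
        have = [t for t in tasks if any((s, t) in betas for s in range(n_subj))]
        if not have:
            logger.info("no beta maps for domain %r; skipping", domain)
            continue
        mean_beta = np.full(n_subj, np.nan)
        for s in range(n_subj):
            vals = [betas[(s, t)].values[mask.values].mean()
                    for t in have if (s, t) in betas]
            if vals:
                mean_beta[s] = np.mean(vals)
        score = _domain_behavior_score(df, [t for t in tasks if t in df.columns],
                                       task_measures).to_numpy()
        keep = np.isfinite(mean_beta) & np.isfinite(score)
        b, y = mean_beta[keep], score[keep]
        if len(b) <= 3 or b.std() == 0 or y.std() == 0:
            raise ValueError(
                f"domain {domain!r}: too few subjects or degenerate variance "
                "for a correlation")
        r, p = stats.pearsonr(b, y)
        z = (b - b.mean()) / b.std()
        out_ix = np.flatnonzero(keep)[np.abs(z) > outlier_sd]
        if len(out_ix) and len(b) - len(out_ix) > 3:
            good = np.abs(z) <= outlier_sd
            r2, p2 = stats.pearsonr(b[good], y[good])
        else:
            r2, p2 = r, p
        out[domain] = DomainCoupling(
            r=float(r), p=float(p), n=int(len(b)),
            outliers_removed=[int(i) for i in out_ix],
            r_without_outliers=float(r2), p_without_outliers=float(p2))
    return BrainBehaviorResult(domains=out, outlier_sd=outlier_sd)


# ---------------------------------------------------------------------------
# Full run

def run_pipeline(config: dict | None = None, out_dir: str | Path | None = None) -> dict:
    """Run the whole analysis on synthetic data and return the results.

    ``config`` keys (all optional): seed, n_subjects, grid, z_threshold,
    m_list, geomin_eps, target_memory_r, outlier_sd, missing_policy,
    session_missingness (bool). Writes tables, masks, and a Markdown report
    under ``out_dir`` when given.
    """
    cfg = {
        "seed": 0, "n_subjects": 114, "grid": 24, "z_threshold": ms.DEFAULT_Z,
        "m_list": [3, 4, 5], "geomin_eps": 0.01, "target_memory_r": 0.31,
        "outlier_sd": 4.0, "missing_policy": "pairwise",
        "session_missingness": False, "noise_sd": 0.3,
    }
    cfg.update(config or {})
    seed = int(cfg["seed"])
    econf = EFAConfig(geomin_eps=cfg["geomin_eps"],
                      missing_policy=cfg["missing_policy"], seed=seed)

    latent = syn.default_behavioral_spec(n_subjects=cfg["n_subjects"], seed=seed)
    tspec = syn.default_template_spec(seed=seed, grid=cfg["grid"],
                                      noise_sd=cfg["noise_sd"])
    coupling = {"memory": syn.coupling_for_target_r(
        cfg["target_memory_r"], tspec, latent, "memory")}
    from dataclasses import replace as _replace
    tspec = _replace(tspec, coupling=coupling)

    missing = (syn.session_missingness(cfg["n_subjects"], seed=seed)
               if cfg["session_missingness"] else None)
    behav = syn.generate_behavioral(latent, missing_pattern=missing)
    logger.info("behavioral table: %d subjects x %d tasks", *behav.scores.shape)

    behavioral_mc = run_behavioral_efa(behav, m_list=cfg["m_list"], config=econf)

    maps = syn.generate_task_maps(tspec)
    pair = ms.pairwise_matrix(list(maps.values()), z=cfg["z_threshold"])
    neural_mc = run_neural_efa(pair, m_list=cfg["m_list"], config=econf)

    # cross-modal membership is compared at the behaviorally selected factor
    # count (falling back to the neural selection if that m was not fitted
    # on the neural side)
    m_sel = behavioral_mc.selected_m
    m_neu = m_sel if m_sel in neural_mc.models else neural_mc.selected_m
    behav_assign = assign_membership(
        behavioral_mc.models[m_sel], behav.spec.task_names)
    neural_assign = assign_membership(neural_mc.models[m_neu], pair.tasks)

    task_masks = {t: ms.threshold_mask(maps[t], z=cfg["z_threshold"])
                  for t in maps}
    domain_masks = {
        d: ms.domain_conjunction_mask([task_masks[t] for t in tasks])
        for d, tasks in syn.DOMAINS.items()}
    betas = syn.generate_subject_betas(tspec, latent, behav.factor_scores)
    bb = brain_behavior(betas, domain_masks, behav, dict(syn.DOMAINS),
                        outlier_sd=cfg["outlier_sd"])

    results = {
        "config": cfg,
        "behavioral": behavioral_mc,
        "neural": neural_mc,
        "behavioral_assignment": behav_assign,
        "neural_assignment": neural_assign,
        "pair_matrix": pair,
        "brain_behavior": bb,
        "data": behav,
    }
    if out_dir is not None:
        _write_outputs(results, Path(out_dir), domain_masks)
    return results


def _write_outputs(results: dict, out_dir: Path, domain_masks) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = results["config"]
    (out_dir / "config.json").write_text(json.dumps(cfg, indent=2))
    syn.write_behavioral_tsv(results["data"], out_dir)
    ms.save_pair_matrix(results["pair_matrix"], out_dir / "pair_correlations")
    for d, mask in domain_masks.items():
        ms.save_mask(mask, out_dir / f"domain-{d}_conjunction.nii.gz")
    for name in ("behavioral", "neural"):
        mc: ModelComparison = results[name]
        mc.table().to_csv(out_dir / f"{name}_fit.tsv", sep="\t")
        for m, model in mc.models.items():
            pd.DataFrame(model.loadings, index=mc.corr.task_names).to_csv(
                out_dir / f"{name}_m{m}_loadings.tsv", sep="\t")
    (out_dir / "report.md").write_text(render_report(results))


def _loading_table(mc: ModelComparison, title: str) -> list[str]:
    lines = [f"## {title}", ""]
    tasks = mc.corr.task_names
    for m in sorted(mc.models):
        model = mc.models[m]
        lines.append(f"### {m}-factor loadings"
                     + (" (selected)" if m == mc.selected_m else ""))
        header = "| task | " + " | ".join(f"F{k + 1}" for k in range(m)) + " |"
        lines += ["", header, "|" + "---|" * (m + 1)]
        for i, t in enumerate(tasks):
            row = model.loadings[i]
            k_star = int(np.argmax(np.abs(row)))
            cells = [f"**{v:.3f}**" if k == k_star else f"{v:.3f}"
                     for k, v in enumerate(row)]
            lines.append(f"| {t} | " + " | ".join(cells) + " |")
        lines.append("")
    return lines


def render_report(results: dict) -> str:
    """Markdown report: fit tables, loading tables (winning loading bolded),
    cross-modal agreement, and the brain-behavior correlations."""
    lines = ["# Latent-structure analysis report", ""]
    for name, title in (("behavioral", "Behavioral factor structure"),
                        ("neural", "Neural (map-similarity) factor structure")):
        mc: ModelComparison = results[name]
        lines += [f"## {title}: fit", "", mc.table().round(4).to_markdown(), "",
                  "Selection: " + mc.selection_rationale.splitlines()[0], ""]
        lines += _loading_table(mc, f"{title}: loadings")
    ba: DomainAssignment = results["behavioral_assignment"]
    na: DomainAssignment = results["neural_assignment"]
    agree = ba.partition() == na.partition()
    lines += ["## Cross-modal agreement", "",
              f"Behavioral and neural max-loading partitions "
              f"{'agree' if agree else 'differ'}.", ""]
    bb: BrainBehaviorResult = results["brain_behavior"]
    lines += ["## Brain-behavior coupling", "",
              "| domain | r | p | n | outliers | r (no outliers) | p (no outliers) |",
              "|---|---|---|---|---|---|---|"]
    for d, c in bb.domains.items():
        lines.append(
            f"| {d} | {c.r:.3f} | {c.p:.4g} | {c.n} | {len(c.outliers_removed)}"
            f" | {c.r_without_outliers:.3f} | {c.p_without_outliers:.4g} |")
    lines.append("")
    return "\n".join(lines)
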