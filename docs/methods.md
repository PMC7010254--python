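# Methods

## Latent model and estimation

The behavioral battery is modeled by the common factor model in the
standardized metric: indicator scores y satisfy y = Λf + ε with
f ~ MVN(0, Φ), ε ~ MVN(0, Ψ), Φ a unit-diagonal positive-definite factor
correlation matrix and Ψ diagonal, so the implied indicator correlation
matrix is Σ = ΛΦΛ′ + Ψ with unit diagonal (enforced at spec construction to
1e-8).

Maximum-likelihood extraction minimizes
F(Ψ) = log|Σ| + tr(RΣ⁻¹) − log|R| − p over Ψ after profiling Λ out through
the eigendecomposition of Ψ^{-1/2} R Ψ^{-1/2}: with eigenvalues
θ₁ ≥ … ≥ θ_p, the profiled discrepancy is Σ_{k>m}(θ_k − log θ_k − 1) and the
conditionally optimal loadings are Ψ^{1/2} V_m (max(Θ_m − I, 0))^{1/2}. The
remaining p-dimensional bound-constrained problem (Ψ ∈ [1e-3, 1]) is solved
by L-BFGS-B with the analytic gradient
∂F/∂ψ_j = −(1/ψ_j) Σ_{k>m} (θ_k − 1) v_{jk}². Restarts matter: the ML
surface for moderate N routinely has its global minimum on the uniqueness
boundary (a Heywood case), and starts clustered around the
squared-multiple-correlation heuristic can miss it. The default 10 restarts
therefore alternate SMC log-space jitter with uniform draws over
(0.05, 0.95); the best converged restart is kept, and any solution with a
uniqueness at the floor is flagged `heywood` rather than hidden (the floor
of 1e-3 plays the role of the "no negative residual variance" constraint).

Oblique geomin rotation minimizes q(Λ) = Σ_i (Π_k (λ_ik² + eps))^{1/m} over
oblique rotations by the gradient-projection algorithm (unit-length columns
of the rotation matrix T, projected gradient steps with backtracking
halving). eps defaults to 0.01; 30 starts (identity plus random orthonormal
matrices, fixed seed) are run and the lowest criterion wins, ties going to
the first found. Rotation leaves ΛΦΛ′ — and hence every fit statistic —
unchanged (checked to 1e-8), so stages that only need fit indices may skip
it.

### Test statistic and fit indices

The chi-square statistic is c·F_min with c the Lawley–Bartlett multiplier
N − 1 − (2p + 5)/6 − 2m/3 by default ("n-1" and "n" are selectable). The
correction is the package's deliberate default: at the battery's sample
size (N = 114, p = 12) the uncorrected (N−1)·F statistic is noticeably
inflated for a correctly specified model, which biases RMSEA upward and
destabilizes model selection. The independence baseline for CFI/TLI uses
F_b = −log|R| (its multiplier uses m = 0). RMSEA is
√(max(χ²−df, 0)/(df·c)) — zero whenever χ² ≤ df — and CFI is capped at 1 in
the same situation. SRMR averages squared residuals over the p(p+1)/2
entries with i ≤ j. When n_effective ≤ p the test statistics are reported as
NaN while SRMR, parameter counts and the Heywood flag remain available.

Loading magnitudes are labeled by the conventional guideline bands
(≥0.71 excellent, ≥0.63 very good, ≥0.55 good, ≥0.45 fair, else poor), with
0.32 exposed separately as the minimum conventionally interpreted magnitude.

## Map similarity

All volumes live on one shared voxel grid (0-based index space, identity
affine; spatial normalization is assumed done upstream). Activation masks
keep voxels with z strictly greater than the threshold (default 2.3), so
exact-boundary voxels are excluded; negative activations are ignored
throughout. An optional minimum-cluster-size filter (26-neighbor
connectivity, default off) offers crude contiguity pruning; no
random-field or cluster-level inference is attempted. Each unordered task
pair is correlated over the intersection of the two tasks' own masks; a pair
needs at least 10 voxels and nonzero variance, otherwise it is an error that
names the failing pairs. For 12 tasks this yields 66 off-diagonal values
(78 unique entries counting the diagonal).

Because every entry has its own voxel support, the assembled matrix need not
be positive semidefinite. `nearest_pd_repair` alternates eigenvalue clipping
(floor 1e-6) with rescaling to unit diagonal and sets a `repaired` flag. For
factor analysis the neural pipeline repairs with floor 1e-3 instead: a
matrix whose smallest eigenvalues sit at machine-level values is still
numerically singular for ML estimation (log|R| terms of −14 per floored
eigenvalue dominate the discrepancy and break the line search).

The effective sample size behind the neural matrix is not well defined — the
entries are correlations over hundreds of partially overlapping voxels, not
independent observations. The default (the largest pairwise support, a
voxel-scale count) makes the chi-square scale descriptive rather than
inferential; neural chi-squares and p-values should be read accordingly.

## Pipeline conventions

* **Missing behavioral data**: pairwise-complete correlations with
  n_effective = median pairwise count (listwise selectable). Full-information
  ML from raw data is out of scope.
* **Model selection**: smallest m with RMSEA ≤ 0.06 and SRMR ≤ 0.08;
  fallback, smallest RMSEA. The rationale string always lists every
  candidate. A reliability caveat is documented under Limitations.
* **Membership**: default max-|loading| per task (ties to the lower factor
  index, logged); an a-priori task→factor map is also supported because the
  two rules can disagree on real data. Cross-modal agreement is compared at
  the behaviorally selected factor count.
* **Domain behavioral score**: per-task z-scores across subjects, reaction
  times sign-reflected before standardization (higher = better), averaged
  over the domain's available tasks. Standardization is unavoidable when
  averaging proportions with seconds.
* **Beta extraction**: subject × task beta maps are averaged over the
  domain's conjunction mask (the AND of its three thresholded task masks)
  and across the domain's three tasks.
* **Outliers**: subjects whose mean beta lies more than 4 group-SDs from the
  mean (a round-number default near the ~5 SD exclusions seen in practice)
  are reported, and the correlation is recomputed without them; both versions
  are always reported.

## Synthetic data: what it emulates, what it does not

`default_behavioral_spec` plants 12 indicators on 4 oblique factors with
simple structure; primary loadings span 0.42–0.90 (three indicators per
domain, the realistic mix of one strong, one middling, one weaker marker),
memory–reasoning factor correlation 0.5 and all other pairs 0.3. Uniqueness
is set to complete the unit diagonal. Accuracy tasks are displayed through a
logistic squash centered at 0.75; speed tasks through a *decreasing*
exponential map to seconds (median ≈ 2 s), which is what makes observed
speed loadings oppose accuracy loadings in raw-score analyses. Since EFA
consumes correlations, these strictly monotone transforms preserve the
planted structure up to the small nonlinearity of Pearson r; they also make
the indicators realistically non-normal (right-skewed RTs), which fattens
the chi-square tail relative to the multivariate-normal ideal — a feature,
not a bug, shared with real score data. Missingness is session-structured
(six tasks per session, dropout by session), not at random.

`default_template_spec` builds 24³ volumes: one central domain-general blob
(emulating the cerebellar/visual activations common to all tasks, at 0.7 of
the domain peak) and four disjoint domain blobs, all with graded quartic
falloff — the within-mask gradient is what gives masked correlations their
signal. Group z-maps are effect 5 × (shared + domain template) plus noise of
SD 0.3, half spatially smoothed (FWHM 2 voxels), half white; the white
fraction keeps the effective spatial degrees of freedom per mask realistic
(purely smooth noise makes the assembled 12×12 matrix grossly
rank-deficient). Same-domain maps share their domain template, so
within-domain masked correlations (~0.88) exceed between-domain ones
(~0.55), echoing the structure seen in real task batteries. Subject beta
maps are amplitude-modulated templates:
baseline + coupling·(domain factor score) + subject noise, plus voxel noise;
`coupling_for_target_r` inverts r = cρ/√(c² + σ²) analytically (ρ the
factor-score/behavior-score correlation implied by Λ and Φ, σ the
network-mean noise after averaging three tasks) so a chosen population
brain–behavior correlation can be planted exactly.

Not emulated: hemodynamics and task design (no time series, no HRF),
realistic anatomy or atlas geometry, spatially varying noise, site/session
effects, and any negative-activation structure. Passing tests therefore
validate the statistical machinery and its calibration, not robustness to
fMRI artifacts.

## Problem sizes used in the test suite

The suite exercises the battery at its native size (N = 114, p = 12,
24³ grids): 100 replicates for the model-selection study, 500 for the
planted brain–behavior recovery (r = 0.31, memory domain), N = 10⁵ for the
Monte-Carlo convergence of sample correlations, N = 10⁴ for loading
recovery (Tucker congruence > 0.98 per factor after column matching), 20
random 12×12 matrices for the dual-route ML check against a direct joint
optimizer, and a 500-start reference run for geomin stability.

## Known limitations

* **Selection-rule reliability at N = 114.** With a perfectly calibrated
  chi-square, a true 4-factor model of 12 indicators exceeds the
  RMSEA ≤ 0.06 cutoff in P(χ²₂₄ > 33.8) ≈ 9% of samples, and a collapsed
  3-factor alternative slips under both cutoffs in a few percent more; the
  cutoff-based rule therefore tops out near ~87% correct selection under
  ideal conditions, and lower (~75–85%) with realistically non-normal
  scores. The package implements the cutoff rule as specified and reports
  every candidate's indices so parsimony arguments remain visible; treat
  single-sample selections at this N as evidence, not verdicts.
* Neural chi-square scale is descriptive (see above); neural RMSEA values
  can be large even when the loading structure is cleanly recovered.
* No standard errors on loadings, no confirmatory models, no FIML.
* The ~45% Heywood-flag rate for true 4-factor models at N = 114 (three
  indicators per factor, one strong marker) is a property of ML factor
  analysis at this design, not an implementation defect; flagged solutions
  still carry valid fit statistics.
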