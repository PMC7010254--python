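# cogfactor

Bottom-up latent-structure analysis of multi-task cognition. Given a battery
of 12 in-scanner cognitive tasks spanning four putative domains — episodic
memory retrieval, reasoning, processing speed, vocabulary — the package asks,
without assuming the domains in advance:

1. **Behavior.** Does the correlation matrix of task performance (proportion
   correct for nine tasks, correct-trial reaction time for the three speed
   tasks) decompose into a small number of oblique latent abilities?
2. **Brain.** Do the group-level activation maps show the same latent
   structure? Each pair of tasks is compared by the Pearson correlation of
   their z-statistic maps over the intersection of their positive-activation
   masks (z > 2.3), and the resulting 12 × 12 similarity matrix is factor
   analyzed the same way.
3. **Coupling.** Within each recovered domain, does the mean beta value over
   the domain's conjunction mask predict the subject's averaged domain
   performance?

It is written for cognitive-neuroscience and psychometrics researchers who
want a fully scriptable, testable version of this workflow. Because the
original raw data are not redistributable, the package ships a synthetic-data
module that plants a known four-factor ground truth in both the behavioral
table and the imaging volumes, so every stage can be validated end to end.

## The model

Exploratory factor analysis of a correlation matrix R with m factors:

    Sigma = Lambda Phi Lambda' + Psi,   Psi diagonal, Phi unit-diagonal PD

Maximum-likelihood estimation minimizes the discrepancy

    F = log|Sigma| + tr(R Sigma^-1) - log|R| - p

profiling Lambda out through the eigendecomposition of
Psi^-1/2 R Psi^-1/2 (Lawley–Maxwell), with uniquenesses box-constrained to
[1e-3, 1] and Heywood (boundary) solutions flagged. The unrotated solution is
rotated by oblique **geomin** — minimizing the row-wise geometric mean of
squared loadings (+ eps) over oblique rotations by gradient projection with
random restarts. Model fit is summarized by the chi-square test
(Lawley–Bartlett corrected multiplier by default), CFI, TLI, RMSEA and SRMR;
test df is ((p − m)² − (p + m))/2 and the free-parameter count
p(m + 1) − m(m − 1)/2 (+ p when indicator means are estimated).

## Worked example

```python
import cogfactor as cf

results = cf.run_pipeline({"seed": 2}, out_dir="run_demo")
print(results["behavioral"].table().round(3))
```

prints the behavioral model comparison for 114 synthetic subjects drawn from
a four-factor battery:

```
           chi_square  df  p_value    cfi    tli  rmsea   srmr  n_free_params  heywood
n_factors
3              98.130  33    0.000  0.871  0.743  0.136  0.071             57    False
4              29.554  24    0.200  0.989  0.970  0.047  0.029             66    False
5              14.872  16    0.534  1.000  1.009  0.000  0.020             74    False
```

The three-factor model misfits (RMSEA 0.136), the four-factor model fits well
(RMSEA 0.047, SRMR 0.029) and is selected as the most parsimonious adequate
model; the five-factor model buys little. The run directory contains the
loading tables (each task's winning loading grouping the three tasks per
domain), the 12 × 12 map-similarity matrix with its per-pair voxel counts,
the four domain conjunction masks as NIfTI, and the brain–behavior
correlations per domain — here `memory: r = 0.423 (p = 2.7e-06, n = 114)`
for the planted memory coupling and null results for the other three
domains, mirroring the planted effect.

The same stages are scriptable from a shell:

```sh
cogfactor simulate --out data --seed 2
cogfactor similarity --maps 'data/task-*_zmap.nii.gz' --out sim
cogfactor efa --corr sim/pair_correlations.tsv --factors 3,4,5 --out efa_out
cogfactor run --out run_demo --seed 2
```

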