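# dyadsat

Predicting how satisfying a face-to-face conversation between two strangers
will be — *before they ever meet* — from the similarity of their resting-state
functional connectomes.

`dyadsat` implements the complete statistical pipeline for this dyadic
prediction problem: temporal cleaning of ROI-level fMRI time series
(27-regressor confound model, 0.01 Hz discrete-cosine high-pass),
per-subject resting-state functional connectivity (RSFC) matrices,
per-region dyad-similarity features, repeated 10-fold cross-validated
prediction (linear ε-SVR or ridge) with permutation inference,
fold-averaged coefficient and permutation-importance interpretation against
null models, and session-level repeated-measures ANOVA with
Shaffer-corrected post-hoc tests. Because the underlying human dataset is
not publicly deposited, the package ships a fully tested synthetic cohort
generator that reproduces the structure the analysis assumes — 29 same-sex
pairs, pairwise-shared connectivity, and a controllable planted link
between connectome similarity and satisfaction — so every stage is testable
end to end.

It is written for researchers in social and network neuroscience who want
to run, audit, or extend this family of dyadic similarity analyses.

## The analysis in brief

For subjects *a*, *b* of pair *p* with cleaned T×N time series, the RSFC
matrix is `R = corr(ts)` (N×N, Pearson). The similarity feature for region
*j* is

    s_pj = corr( R_a[−j, j], R_b[−j, j] )

— the correlation of the two subjects' j-th RSFC columns with the diagonal
entry removed, giving a P×N feature matrix (29×120). The pair's
satisfaction score y_p (mean of two subjects' 18-item means, scale 1–8) is
predicted from s_p under repeated 10-fold cross-validation; accuracy is
RMSE over held-out pairs, and significance is the fraction of
label-permuted refits with RMSE at or below the observed one. Permutation
feature importance for feature *j* is `i_j = s − (1/K) Σ_k s_kj` (K=5
shuffles of the held-out column; negative = contributive).

## Worked example

```python
import numpy as np
from dyadsat import (SyntheticConfig, generate_cohort, ModelSpec,
                     permutation_test, rm_anova, clean_timeseries,
                     compute_rsfc, build_similarity_matrix)
from dyadsat.pipeline import satisfaction_table, target_vector

cohort = generate_cohort(SyntheticConfig.strong_signal(seed=1))
rsfc = {}
for s in cohort.subjects:
    clean = clean_timeseries(cohort.timeseries[s], cohort.motion[s],
                             cohort.wm[s], cohort.csf[s], tr_seconds=2.0)
    rsfc[s] = compute_rsfc(clean.data)
X = build_similarity_matrix(rsfc, cohort.pairs)          # 29 x 120
table = satisfaction_table(cohort)
y = target_vector(table, "pair_mean", session=1)

res = permutation_test(X, y, ModelSpec(family="ridge"),
                       k=10, n_repeats=5, n_perm=500, seed=1)
print(f"mean RMSE = {res.mean_rmse:.3f}")
print(f"null median = {np.median(res.null_rmses):.3f}")
print(f"permutation p = {res.p_value:.4f}")

# session effects are clearest without the large planted session-1 variance
behav = generate_cohort(SyntheticConfig(seed=4))
t2 = satisfaction_table(behav)
scores = np.column_stack([target_vector(t2, "pair_mean", s)
                          for s in (1, 2, 3)])
a = rm_anova(scores)
print(f"F({a.df_effect:.0f}, {a.df_error:.0f}) = {a.F:.2f}, p = {a.p:.4f}")
```

Output:

```
mean RMSE = 1.614
null median = 2.048
permutation p = 0.0060
F(2, 56) = 8.73, p = 0.0005
```

The observed cross-validated error (1.61 on the 1–8 scale) sits well below
the median of the label-permuted null (2.05), so the permutation p-value is
small: the planted similarity–satisfaction link in this synthetic cohort is
detected. The ANOVA on the second cohort picks up the planted session
effect (session 3 is rated higher; both of its Shaffer-corrected post-hoc
comparisons reject). On a null cohort (`SyntheticConfig(seed=...)`, no
planted signal) the same prediction code yields p-values spread uniformly —
the machinery is calibrated, which the test suite checks explicitly.

The same stages are scriptable from a shell via the `dyadsat` CLI
(`simulate`, `preprocess`, `connectivity`, `similarity`, `predict`,
`interpret`, `anova`, `run-all`); `dyadsat run-all --out DIR --seed 1`
executes everything and writes per-stage TSV/CSV/JSON outputs.

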