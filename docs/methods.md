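# Methods

`dyadsat` implements a dyadic prediction analysis: can the satisfaction two
strangers report after a face-to-face conversation be predicted from how
similar their resting-state functional connectomes were *before* they met?
This note documents the statistical procedures, the synthetic cohort the
package uses in place of undeposited human data, the numerical choices, and
what the test suite does and does not establish.

## The analysis pipeline

**Temporal cleaning.** Each subject contributes a T×N matrix of
region-averaged BOLD signals (default T=180 volumes at TR=2 s, N=120
regions). A 27-column confound design — a linear trend normalized to
[0, 1], the Friston 24-parameter motion expansion
[R(t), R(t)², R(t−1), R(t−1)²] with zero-padded lags, and mean white-matter
and CSF series — is removed by OLS (intercept implicit via demeaning).
Low-frequency drift below 0.01 Hz is then removed by regressing out a
discrete-cosine basis: all ⌊2·T·TR·f_c⌋ components with frequency below the
cutoff (7 regressors at the default geometry) plus the constant. The filter
step re-includes the confound columns so the final residuals are exactly
orthogonal to both sets; a purely sequential projection would leak a small
confound component back in. A rank-deficient confound design is pruned
column-wise with a warning rather than rejected, because degenerate
synthetic motion is legal input.

**Connectivity and dyad similarity.** RSFC is the N×N Pearson correlation
matrix of the cleaned series (diagonal exactly 1; zero-variance regions are
an error naming the region). For a pair of subjects, the similarity of
region j is the Pearson correlation between column j of the two RSFC
matrices after deleting the (j, j) entry from both — N−1 points per
correlation, one feature per region, giving the P×N similarity matrix
(29×120 at study scale). No Fisher z-transform is applied before the
column correlations (an optional flag exists, default off). Personality
similarity is the per-trait Euclidean distance between two subjects'
12-item score vectors (5 features, no standardization).

**Outcome scores.** Each subject rates 18 items on a 1–8 scale per
session; the subject score is the item mean, the pair score the mean of the
two subject scores, and the agreement score their absolute difference.

**Prediction.** A linear model predicts the pair-level target from the
similarity features under repeated 10-fold cross-validation: each repeat
draws a fresh random partition (fold sizes differ by at most one — training
sets of 26 or 27 pairs at P=29), fits one model per fold, and scores a
single RMSE over all out-of-fold predictions; the headline accuracy is the
mean over repeats (20 at full scale). Two families are supported with the
toolkit's default parameters: a linear epsilon-SVR (libsvm via
scikit-learn; C=1, ε=0.1) and ridge regression (α=1, unpenalized
intercept). The ridge solve is an exact closed form (dual form when
samples < features) that matches `sklearn.linear_model.Ridge` to 1e−8; it
exists because the calibration suites refit the model hundreds of thousands
of times. Features are not standardized by default (they are correlations,
already bounded); a flag exists.

**Permutation inference.** The null distribution of the mean RMSE is built
by permuting the target vector — the similarity matrix keeps its structure
— and rerunning the entire repeated cross-validation; p is the plain
proportion of null RMSEs at or below the observed one (10,000 permutations
at full scale; the scaled-down profiles below use 200–2,000). p = 0 means
"< 1/n_perm"; a smoothed estimate (1+count)/(1+n_perm) is always reported
alongside. One permuted target is reused across all repeats within a null
iteration.

**Interpretation.** The 10 fold models of each repeat are averaged, then
the repeat means averaged again (equal fold counts make this identical to
the grand mean over all fold models). Null models from label-permuted
refits give per-feature medians and a [2.5, 97.5] percentile band; a
feature is *flagged* when its mean coefficient falls outside the band.
This operationalizes what was originally a visual inspection of deviation
from null medians; it is a reporting convention, not a formal test — with
120 features, a 5% band flags ~6 features by chance under the null, which
is why downstream summaries intersect the coefficient flags with the
importance flags. Permutation feature importance on each held-out fold
shuffles one test column K=5 times: i_j = s − (1/K)Σ_k s_{k,j}, with s the
intact-test RMSE; because the metric is an error, negative importance marks
a contributive feature. Importances are fold- then repeat-averaged and
compared against baselines from label-permuted refits (100 at full scale);
the contributive flag is importance below the baseline's 2.5th percentile.

**Session statistics.** Pair scores across the three sessions enter a
one-way repeated-measures ANOVA (classical within-subject decomposition;
partial and generalized eta squared; df (2, 56) at 29 pairs). No
sphericity correction is applied by default; Greenhouse–Geisser is behind
a flag. Post-hoc comparisons are paired t-tests with Shaffer's sequentially
rejective correction, implemented for exactly three sessions, where the
logical constraints give per-step thresholds (α/3, α, α).

## The synthetic cohort

The human data are not deposited, so the package generates cohorts with the
statistical structure the analysis assumes. The generator is first-class,
tested code; its defaults are the study conditions.

**Connectomes.** A cohort template, one shared component per pair, and one
individual component per subject are random factor-model correlation
matrices (N×k standard-normal loadings, k=4, unit idiosyncratic variance,
rescaled to correlation form). Each subject's latent correlation is the
convex mixture (1−λ_p−λ_i)·template + λ_p·pair + λ_i·individual with
λ_p=0.5, λ_i=0.45, projected to the nearest correlation matrix (eigenvalue
clipping at 1e−8, then unit-diagonal rescale — a no-op for already-valid
mixtures). How far the two partners diverge is controlled per (pair,
region) by a dyadic-variability dial that scales the individual component's
factor loadings: dial = 1.5·(0.5·G_p + 0.5·U_pj), where the pair-level
G and each region's U column are shuffled evenly-spaced grids on (0, 1).
The stratified grids guarantee every cohort spans the similarity continuum;
with purely independent uniform draws, roughly a third of cohorts clumped
into a range too narrow for any method to detect the planted signal at 29
pairs. The pair-level share (0.5) gives the feature matrix a dominant,
well-estimated global-similarity direction, which is what makes prediction
at 29 pairs feasible at all; the region-level share carries the
feature-specific information that makes the planted support identifiable.

**Observed series.** Given the latent correlation C, the raw series is a
stationary AR(1) process x_t = φ·x_{t−1} + √(1−φ²)·e_t with e_t ~ N(0, C)
and φ=0.3 — the simplest process that makes the high-pass filter
non-trivial. Contamination that the preprocessing stage must remove is
added on top: a 0.003 Hz sinusoidal drift with random per-region phase
(amplitude 1.0 in signal-SD units), plus standardized motion
(cumulative random walk; translations ~0.02 mm, rotations ~2·10⁻⁴ rad per
step) and AR(1) WM/CSF series leaked through random loadings with weight
0.5.

**Planted outcome.** With `signal_scale` > 0 the generator selects 3
support regions from the top-15 high-variability columns of the latent
similarity matrix, ranking candidates by a sum of two ranks — high
across-pair variability (what makes a region predictive) and few strongly
correlated siblings anywhere in the feature set (what makes it
attributable; a region surrounded by near-duplicates cannot be singled out
by any method) — then greedily decorrelating the chosen three. Weights get
2 positive and 1 negative sign (mixed sign, echoing the finding that both
similarity and dissimilarity contribute) with magnitudes proportional to
1/SD of each column, so every support region contributes equally to the
planted component; the whole vector is rescaled so that component has
exactly `signal_scale` SD on the 1–8 scale. Session-1 pair targets are
y = clip(intercept + Σ_j w_j s_pj + ε, 1, 8) with ε ~ N(0, 0.2). The
"strong" preset uses scale 2.4 with intercept 5.5 (limiting ceiling
clipping); "weak" uses 0.6. The support is deliberately small (three
regions): at 29 pairs, weights spread over many
columns leave each feature's marginal association too weak to identify —
mixed-sign weights on mutually correlated columns cancel in the marginal
correlations. Sessions 2 and 3 carry no similarity signal; session 3 adds
+0.4 to the intercept so the session ANOVA has a real effect to find, and
sessions 2–3 use between-pair noise SD 0.6.

**Item chain.** Subject-level targets are antithetic jitters y ± d
(d ~ N(0, 0.3)), so the pair mean is preserved exactly before rounding;
each subject's 18 items are the subject target plus N(0, 0.6) noise,
rounded and clipped to integers 1..8. Planting top-down (pair target →
subject targets → items) rather than bottom-up keeps the planted effect
intact through the averaging chain up to integer rounding (≲0.1 on the
pair score). Personality items are integers 1..7 around per-trait subject
means ~ N(4.5, 1); sex labels (15 male-male, 14 female-female pairs) are
assigned but unused.

**What the generator does not emulate.** Spatial structure (no voxels, no
hemodynamics, no image geometry), realistic motion-artifact coupling
(motion leaks linearly, so confound regression can remove it exactly in
expectation), scanner drift families other than a single sinusoid, item-level
response styles, and any dependence of satisfaction on demographics or
conversation topics. Passing tests therefore show that the statistical
machinery is correct and calibrated under the assumed generative structure —
not that real conversations are predictable.

## Scaled problem sizes

Full-scale settings (10,000 permutations and null models, 100 importance
baselines, 20 repeats) are available via `--full-scale`. The test suite
and the acceptance script use scaled-down profiles chosen as the package's
test conventions: 5 CV repeats; 200–2,000 permutations depending on the
check; 200 coefficient nulls; 100 importance baselines; 50 null cohorts
for calibration; 10 cohorts for recovery. Type-I calibration and the
uniformity check run with the ridge family — both families share the
identical permutation machinery, and the exact closed-form ridge makes
hundreds of thousands of refits cheap; signal-recovery and interpretation
checks use the epsilon-SVR, the headline model.

## Numerical choices and edge cases

- All randomness flows from one integer seed through named CRC-derived
  substreams (`dyadsat._rng.substream`); no global RNG state is touched.
  Importance shuffles draw from a sequentially advancing stream whose
  position does not depend on the weight values, so a zero-weight feature
  (importance exactly 0 by construction) does not shift later draws.
- Pearson computations clip to [−1, 1] against floating-point overshoot;
  RSFC diagonals are set to exactly 1.
- Zero-variance regions, out-of-range items, mismatched manifests and
  truncated files raise errors naming the offending object; rank-deficient
  confound designs are the one deliberate soft failure (pruned + warning).
- Cohort files are plain TSV/CSV/JSON written with `%.17g`, so a
  write/read round trip is bit-exact and a fixed seed reproduces byte-identical
  files (readers use round-trip float parsing).
- The empirical permutation p is reported as a plain proportion per the
  original definition; p=0 therefore means "below 1/n_perm", and the
  smoothed (1+count)/(1+n_perm) variant is carried in every result object.

## Known limitations

- The Shaffer post-hoc supports exactly three sessions; the general-S
  truth-configuration enumeration is future work.
- The permutation test refits serially; at full scale (10,000 × 20
  repeats × 10 folds) the SVR path is hours of compute on one core. The
  ridge path is ~50× faster.
- Coefficient/importance flags are a reporting convention (percentile
  bands), not error-controlled inference; with 120 features the expected
  number of chance flags is material, and only the intersection of the two
  views should be read as support evidence.
- The generator's dyadic-variability dial is a modeling device; nothing in
  the original study constrains the across-pair distribution of connectome
  similarity, so absolute RMSE values from synthetic cohorts are not
  comparable to values measured on human data.
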