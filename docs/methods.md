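# Methods

## Model and procedure

The package implements a two-stage analysis of ROI-level BOLD time series.

**Dynamic states.** Each episode is a `T x p` matrix (time points x ROIs).
Sliding windows — 0-based half-open intervals `[i*s, i*s + w)` with window
length `w = 30` and step `s = 2` time points — yield
`floor((T - w)/s) + 1` Pearson correlation matrices per episode, Fisher-Z
transformed with |r| clipped at `1 - 1e-7` so degenerate windows stay
finite; the diagonal is stored as 0 on the Z scale. Upper-triangle window
vectors from all subjects, episodes and conditions are pooled and clustered
jointly by k-means under the L1 (cityblock) metric: assignment to the
nearest centroid in L1 distance and centroid update by the coordinate-wise
median, which minimizes total L1 distance. The clustering runs in two
steps — many random initializations (default 100) with the best-inertia
centroids retained, then a single refinement initialized at those centroids
(default up to 1000 iterations). The refinement can by construction never
end worse than the best first-step run; if an update empties a cluster, its
centroid is reseeded deterministically at the point farthest from its
assigned centroid. K is selected by the elbow method, operationalized as
the interior k maximizing the discrete second difference
`J(k-1) - 2 J(k) + J(k+1)` of the inertia curve (the sharpest drop in the
rate of improvement); the criterion is explicit because "elbow" alone does
not define an algorithm.

**Emotion decoding and DEFN.** Per episode and state, windows assigned to
the state are averaged (on the Z scale) into a state-average matrix; an
episode that never visits a state is flagged absent, never zero-filled.
For each of the `2^K - 1` state combinations, episodes retaining all the
combination's states contribute one sample: the concatenation, in
ascending state order, of the state-average upper triangles. Decoding is
leave-one-subject-out: per fold, features are standardized with training
statistics, ranked by ReliefF (k = 10 nearest hits/misses, L1 neighbour
metric, run on the standardized features), the top `n_selected` retained,
and a linear SVM (C = 1) fit. The optimal combination maximizes mean fold
accuracy, with the smallest accuracy SD winning among combinations within
0.5 percentage points of the maximum (the dual criterion is needed because
two combinations can print near-identical means). Stable features are the
intersection of the per-fold selections; their ROI-pair identities, pooled
(deduplicated) across state blocks, define the DEFN weight of each network
pair as the fraction of the pair's edges that are stable. Within-network
pairs are first-class entries. Combination models are compared pairwise by
Lilliefors-gated paired t / Wilcoxon signed-rank tests with
Benjamini-Hochberg correction.

**Condition contrasts.** Per state, subjects exhibiting the state under
both conditions contribute condition-wise mean state-FC vectors; each
upper-triangle edge gets a paired t (sign convention: happy minus sad, so
positive means stronger during happy), BH-FDR across edges, and per network
pair the mean t over significant edges (no significant edge -> null flag,
never 0).

**Clinical transfer.** Static FC is the whole-scan Pearson correlation,
Fisher-Z, zero diagonal. Network pairs are ranked by DEFN weight
(descending; ties and zero-weight pairs in lexicographic order at the
tail); the top-n pairs' edge-set union is the feature mask. n is tuned by
nested stratified 10-fold CV: per outer fold, inner 10-fold accuracy over
the candidate grid (default `1..#nonzero-weight pairs`) picks the fold's
mask (ties toward smaller n); the modal n across outer folds (smaller on
tie) is the final mask. Reported accuracy pools outer-fold test
predictions; the ROC/AUC pools decision scores into a single curve. The
whole-brain baseline uses identical fold assignments, making its
predictions strictly paired with the masked model's for McNemar's test
(uncorrected `(b - c)^2 / (b + c)` by default; continuity correction by
flag). Per-pair importance is the mean absolute SVM coefficient over the
pair's masked edges, averaged over outer folds and max-normalized.

**Confound regression.** When age/sex are supplied, a per-feature OLS
model (intercept + age + sex; sex coded 0/1 as supplied) is fit on the
training rows of every partition — inner-train for inner loops, outer-train
for the outer model — and its coefficients applied to the corresponding
validation/test rows. Constant covariates are dropped with a warning. An
instrumented assertion records every row index touched by inner-loop
computations and verifies that no outer-test row ever appears; the result
is exposed as `ClassificationReport.leakage_free`.

**Statistics kernel.** Pooled-variance (Student) two-sample t, also
computable directly from printed group summaries (mean, n-1 SD, n); Pearson
chi-square without continuity correction; paired t; Wilcoxon signed-rank
(zeros dropped, mid-ranks, exact for n <= 25 without ties, else normal
approximation with tie correction); Lilliefors normality; BH step-up FDR.
The pooled-t and uncorrected-chi-square conventions were chosen because
they reproduce all recomputable statistics of the reference demographic
tables from rounded summaries to ~0.1% (one exception: the BAI row deviates
by ~1.7%, consistent with the published value having been computed from
unrounded data). Zero-variance paired differences report p = 1 with a flag
("no evidence of difference" is the conservative reading).

## Synthetic cohorts

The generators provide ground truth the real data cannot.

**Healthy cohort.** K latent states, each a network-block correlation
template: networks whose index is congruent to the state (mod K) are
"active" with within-block r = 0.6, other blocks 0.1, between-block 0.
White variance (`noise_sd^2`, default 0.09) is blended in and the matrix
projected to the nearest positive-definite correlation (eigenvalue clipping
plus unit-diagonal rescale); the projected matrix is what the truth record
stores, so recovery tests compare against exactly what was sampled. Each
episode follows a per-condition sticky Markov chain (stay probability 0.98,
so mean dwell ~50 time points comfortably exceeds the 30-point window);
off-diagonal mass is split by a geometric ramp increasing across states for
happy and decreasing for sad (ratio 1.5), giving the two conditions
distinct stationary occupancies. The condition effect adds +0.25 to the
correlation of every edge inside three designated between-network pairs
under the happy condition. Time points are i.i.d. multivariate normal given
the active state.

Defaults mirror the emulated study design (51 subjects, 3 episodes per
condition, 600 time points, 432 ROIs in 18 networks — 17 cortical
subdivisions plus one subcortical — K = 4). Tests and validation
experiments run a desk-scale configuration (12 subjects, 200 time points,
40 ROIs in 6 networks, K = 3) that keeps a full run to seconds while
preserving every structural property; the full scale remains reachable by
config.

**Clinical cohort.** Subjects are generated directly as static-FC edge
vectors: N(0, 0.2) per edge, with patient edges inside the designated
network pairs shifted by `effect_size * 0.2`. Age is normal per group
(default means 45/40, SD 10), sex Bernoulli per group, and a synthetic
severity score separates groups. Optional confound coupling adds
`slope * (age - mean)` (and/or a sex term) uniformly to all features,
creating a confound shortcut that in-fold regression must remove. The
transfer experiments use a 96-ROI / 12-network parcellation (4560 edges):
with 50 + 50 subjects this gives the whole-brain baseline a realistic
features-to-samples ratio, which is the regime where masking helps; the
planted effect size is 0.25 SD per edge in 3 of 78 network pairs.

**What the generators do not model.** No hemodynamic response, temporal
autocorrelation within a state, scanner noise or motion artifacts, no
multi-site effects, no volumetric images. Passing recovery tests therefore
show that the estimators are correct and leak-free under the stated
generative assumptions — not that real acquisitions satisfy those
assumptions.

## Numerical choices and degenerate inputs

- Correlation clipping at `|r| = 1 - 1e-7` before arctanh; zero-variance
  ROIs yield NaN edges plus a warning and must be rejected downstream.
- Deterministic seeding throughout: a single root seed derives per-stage
  seeds via `numpy.random.SeedSequence`; identical configuration implies
  byte-identical outputs.
- Cluster-order is arbitrary: state identity is meaningful only up to
  relabelling, and tests compare partitions by adjusted Rand index.
- Contrast edges with zero paired variance get t = 0, p = 1.
- Empty stable-feature sets are legal (all DEFN weights 0); the transfer
  grid then falls back to all pairs in lexicographic order.
- McNemar with no discordant pairs reports (0, 1).

## Validation experiments (tests/test_acceptance.py, scripts/acceptance.py)

The reference study's headline real-data accuracies are not reproducible
because the underlying fMRI data are restricted; the package substitutes
property-based checks computed at run time: demographic statistics
recomputed from printed summaries (to 1% / 0.5%), structural dimension
counts, the optimal-model rule applied to the printed accuracy table,
state-recovery ARI >= 0.8, DEFN ranking precision-at-k >= 0.8 over 10
seeds, a masked-over-baseline transfer gain >= 5 points on planted cohorts
and within +/- 5 points on null cohorts (guarding against
selection-induced optimism), permutation-null accuracies and AUCs in
[0.35, 0.65], a leakage instrumentation check, and kernel calibration
(type-I error 5% +/- 1.5% over 2000 simulations; Wilcoxon exact p against
an exhaustive sign-enumeration oracle; BH against a hand-computed
example).

## Known limitations

- The L1 k-means update rule, ReliefF parameters (k = 10, default
  `n_selected` 1000 full-scale / 200 desk-scale), SVM cost (1.0),
  standardization before selection, and the 0.5-point optimal-model
  tolerance are explicit choices where the emulated analysis left details
  unstated; all are configurable.
- The elbow criterion needs at least three candidate k values and can be
  unstable on inertia curves without curvature; the cluster count can
  always be fixed explicitly.
- Window-level state mixing near latent transitions bounds achievable
  recovery; the adjusted-Rand target is calibrated to window-majority
  labels, not time-point labels.
- The pooled-decision-score ROC treats fold scores as commensurable, which
  linear SVMs trained on folds of equal size approximately satisfy.
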