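# Methods

`fcmanifold` implements a whole-brain functional-connectivity (FC)
manifold analysis for task fMRI studies of sensorimotor adaptation and
intermanual transfer, together with a synthetic-cohort generator that
lets every stage be validated without any imaging data.

## Analysis model

### Epochs and covariance estimation

The experiment is a 3 (Task Stage: Baseline, Early, Late) x 2 (Hand:
Left, Right) within-subject design realized as six task epochs in fixed
order: `LH_Baseline, RH_Baseline, RH_Learn_Early, RH_Learn_Late,
LH_Transfer_Early, LH_Transfer_Late`. Scan-level region time series are
spliced into equal-length epochs (default 96 volumes, after discarding
the 6 lead volumes for scanner equilibration); equal lengths avoid
biasing covariance estimates by differing time-series length. Each
epoch's regions x regions FC matrix is the Ledoit-Wolf shrinkage
covariance of the z-scored time series,

S = (1 - a) S_sample + a * mean-variance * I,

with the analytic shrinkage intensity a in [0, 1]; the estimate is
symmetric positive definite (SPD) even with fewer volumes than regions.

### Riemannian centering

Uncentered FC is dominated by who the subject is rather than what they
are doing. Under the affine-invariant metric on the SPD cone, each
epoch matrix S_ij (subject i, epoch j) is log-mapped at the subject's
geometric (Karcher) mean Sbar_i,

T_ij = Sbar_i^{1/2} log(Sbar_i^{-1/2} S_ij Sbar_i^{-1/2}) Sbar_i^{1/2},

transported to the grand mean Sbar_gm with G = Sbar_gm^{1/2}
Sbar_i^{-1/2} (T_ij^c = G T_ij G^T), and exp-mapped back at Sbar_gm.
After centering, every subject's six matrices have Sbar_gm as their
geometric mean exactly (the package tests this identity to relative
Frobenius error 1e-6), so residual variation reflects task epochs.

The grand mean is computed as the Karcher mean of the per-subject means
(each subject weighted equally). Pooling all subject-epoch matrices
instead is available via `grand_mean="all"`; with equal epoch counts
per subject the two differ only slightly, and the subject-mean
composition is the one consistent with the centering identity above.
Karcher means use the standard fixed-point iteration (step size 1,
convergence when the tangent-mean Frobenius norm drops below 1e-10,
maximum 50 iterations, error on non-convergence). All matrix square
roots, logs and exponentials go through symmetric eigendecompositions
with eigenvalues clipped at 1e-12 for numerical safety near-singular
shrinkage outputs.

### Manifolds and eccentricity

A region's connectivity profile is its row of the centered matrix. Rows
are sparsified by keeping the top `floor((R-1) * 0.10)` connections per
row by signed value (the convention of the connectivity-gradient
literature; an absolute-value variant would change which anticorrelations
survive and is deliberately not the default). The thresholded matrix is
not re-symmetrized: cosine similarity between its (zero-padded) rows is
symmetric regardless, and zero-padded full rows are the standard
convention. PCA of the column-centered affinity matrix (by SVD, with a
deterministic sign convention: each component is flipped so its
largest-magnitude loading is positive) gives the low-dimensional
embedding; the default is d = 3 components.

The alignment template is built from the group baseline: within each
subject the arithmetic mean of the two centered Baseline matrices, then
the geometric mean of those across subjects, then the same
affinity -> PCA recipe. Every subject-epoch embedding is aligned to the
template by orthogonal Procrustes — rotation and reflection only, no
translation (PCA output is already centered) and no isotropic scaling,
because uniform scaling would rescale eccentricity and distort
epoch-to-epoch comparisons. A scaling variant exists behind
`allow_scaling=True` for sensitivity analyses.

Manifold eccentricity is each region's Euclidean distance from the
origin of the aligned space. High eccentricity marks a distinctive
(segregated) connectivity profile, low eccentricity an average
(integrated) one; on synthetic templates eccentricity correlates
positively with within-module degree z-score and negatively with
participation coefficient, which the graph-metric validation functions
reproduce against brute-force definitions.

### Statistics

* Region-wise 3 x 2 repeated-measures ANOVA (Hand x Stage), classical
  sum-of-squares partition with subject-by-effect error terms and no
  sphericity correction by default (a Greenhouse-Geisser option was
  considered out of scope since the factorial has only 2 and 3 levels
  and the package's validation is simulation-based). FDR control is
  Benjamini-Hochberg over the pooled vector of all three effects across
  regions (`pool="per-effect"` available).
* Post-hoc paired t contrasts with explicit sidedness.
* Seed-connectivity contrasts: per subject the seed's centered
  covariance row averaged within epoch groups (Early vs Baseline, Late
  vs Early, or contra- vs ipsilateral hand relative to the seed's
  hemisphere), region-wise paired t between groups, and a per-network
  mean-t summary.
* RSA: per subject a 6 x 6 representational similarity matrix of
  Pearson correlations of whole-brain eccentricity between epochs; four
  binary model RSMs (Hand, Epoch, Learning, Time — Time codes
  first-order adjacency in scan order); model scores are uncentered
  cosine similarities of the off-diagonal upper-triangle vectors
  (diagonal self-similarities are uninformative). Uncertainty by
  bootstrap over subjects (default 1000 resamples); one-sided bootstrap
  p-values are the fraction of bootstrap means at or below zero (or the
  noise ceiling) with the +1/(n+1) correction; pairwise model
  differences are two-sided bootstrap tests, FDR-corrected. The noise
  ceiling lower bound is the leave-one-out mean cosine between each
  subject's RSM and the remaining subjects' average.
* Re-expression: across a region subset (typically the Task-Stage
  significant regions), per-subject Pearson correlation between the
  early-learning eccentricity pattern and each of late learning, early
  transfer and late transfer; one-way repeated-measures ANOVA plus
  one-tailed paired contrasts for "early transfer more similar than
  late learning / late transfer".
* Brain-behavior: per-region Pearson correlation across subjects
  between eccentricity change (Early minus Baseline) and early median
  angular error, BH-FDR over regions; at the network level the mean
  change per hemisphere-specific network is correlated with behavior
  and assessed against a spatial null.
* Spin test: the Vasa variant. Each permutation draws a uniform random
  3D rotation (QR of a Gaussian matrix, det +1), applies it to the left
  hemisphere's unit-sphere centroids and its x-mirrored version to the
  right, and reassigns region indices greedily by ascending distance
  without replacement (ties broken by region index), hemispheres
  matched independently. p-values carry the +1 correction and therefore
  live in [1/(n_perm+1), 1]. The network-level null permutes the
  region-to-value assignment through the rotation and recomputes each
  network's correlation, which is the reading of "topography expected
  by chance" that keeps the network partition fixed. Note the test's
  spatial granularity: very small networks (2-3 regions per hemisphere
  on a 30-region hemisphere) are frequently mapped onto themselves by a
  random rotation, which floors their attainable p-value.

### Behavior

Trials from a 45 degree clockwise visuomotor rotation task. Angular
error is the signed shortest difference endpoint minus target, wrapped
to (-180, 180], counterclockwise positive. Exclusion cascade, applied
in order with no double counting: early-start flag, timeout flag,
cursor-jump flag, reaction time below 100 ms, then reaction and
movement times above the 99.95% quantile computed on surviving trials
pooled across all subjects (applied separately to RT and MT; the
source convention does not specify joint vs separate, and separate is
the conservative reading). Epoch summaries are medians of absolute
error over the epoch's trial window (first/last 32 trials of the
relevant scan; a window left empty by filtering is missing, never
zero). Signed-vs-absolute is a genuine ambiguity; absolute is used
because learning curves and epoch errors are magnitude-like. The
transfer rate is exactly early-transfer error minus late-learning
error. The explicit strategy is the mean reported aim direction
relative to the target over the final 8 report trials (the first 8 are
discarded as unreliable).

## Synthetic study conditions

The generator is first-class code and defines the study conditions the
validation runs under; the defaults are fixed and are not tuned per
test.

Desk scale: 12 subjects x 6 epochs x 60 regions x 96 volumes per epoch
(the full pipeline runs in a few seconds per cohort on one CPU).
Regions split equally between hemispheres across 6 networks with
unequal sizes (5, 7, 6, 5, 4, 3 per hemisphere at the default scale)
and spatially concentrated spherical caps per network (right hemisphere
mirrored in x), giving the spatial autocorrelation the spin test
assumes. The first network's left-hemisphere regions are the designated
sensorimotor block; the last network (both hemispheres) is the
transmodal block.

Per subject-epoch covariance:

C_ij = base + fingerprint_i + hand(j) * sensorimotor component
       + learning(j) * transmodal-coupling component + noise_sd^2 I,

floored to the SPD cone at eigenvalue 1e-6 and sampled as zero-mean
multivariate Gaussian time series.

* **Base**: network blocks (within 0.30, between 0.08) plus a rank-two
  graded component (linear loading 0.30 and quadratic loading 0.15 over
  the network ordering), emulating the dominant unimodal-to-transmodal
  gradient of cortical FC. The graded spectrum matters: with equal,
  equally-coupled networks the affinity eigenvalues are nearly
  degenerate, the identity of the top three components is decided by
  sampling noise, and eccentricity becomes unstable. Unequal network
  sizes serve the same purpose.
* **Fingerprint**: symmetric rank-6 random update per subject, constant
  across epochs, normalized to expected Frobenius norm 8.0 — strong
  enough that nearest-centroid subject identification on uncentered
  covariances exceeds 90%, as in real cohorts where subject identity
  dominates FC.
* **Hand effect** (default 0.3): +/- modulation of the sensorimotor
  block's internal covariance, positive in epochs using the hand
  contralateral to the block's hemisphere.
* **Learning effect** (default 0.15): modulation of the transmodal
  block's coupling with the rest of the brain — a connectivity-profile
  reorganization (the DMN-like story), weighted per block region by a
  fixed heterogeneous profile (spread 0.6-1.4) so the effect has a
  spatial pattern and not just a mean shift. Epoch levels: 0 at
  Baseline, 1 at Early, 0.5 at Late (`late_modulation` configurable) —
  the early-learning modulation is deliberately re-applied at early
  transfer.
* **Re-expression scenario** (`reexpression_design()`): effect 0.2,
  weight spread 0.2-1.8, late level 0.25. Pattern correlation is
  scale-invariant, so at high signal-to-noise a merely scaled-down late
  re-expression correlates with the early pattern as strongly as early
  transfer does; a detectable early-vs-late contrast requires the late
  expression to be weak relative to noise. This scenario makes the
  planted re-expression reliably detectable (about 90% of seeds at
  n = 12) while the default conditions keep the recoverability and
  false-positive properties of the main cohort.

Behavior: per subject an explicit strategy s_i drawn in [0, 45] degrees
(truncated normal around 22.5 with SD 12 by default). Baseline errors
are motor noise (SD 3.5 degrees); learning errors start at 45 - s_i and
decay exponentially (tau = 30 trials) to a 4 degree residual; transfer
errors start near 45 - 0.8 s_i (carried strategy drives transfer) plus
half the residual; reports are s_i plus 2 degrees of noise. Flags are
planted at realistic rates (4% early starts, 5% timeouts, 2% cursor
jumps, 1% sub-floor reaction times). These choices reproduce the
qualitative behavioral structure: negative report-vs-error correlation,
positive early-learning-vs-early-transfer correlation, exact transfer
rate identity.

### What the generator does not emulate

No hemodynamic response, no autocorrelated or scanner-specific noise
spectra, no motion artifacts, no spatial smoothness within networks
beyond block membership, no behavioral lapses or savings. Passing tests
therefore demonstrate that the pipeline recovers the planted covariance
and behavioral structure under Gaussian assumptions at desk scale — not
that it would detect effects of any particular size in real fMRI data.

## Numerical and degenerate-input conventions

Constant region time series, constant eccentricity vectors and
zero-norm thresholded rows are rejected with errors rather than
silently propagated. Zero-variance paired differences return t = 0 with
an undefined (NaN) p. Effect sums of squares at roundoff scale are
treated as exactly zero in the ANOVA (F = 0, p = 1). Regions with fewer
than 4 complete subject pairs are flagged missing in brain-behavior
correlations. All tabular output is TSV at full double precision and
round-trips bit-identically.

## Problem sizes used in validation

The test suite and the acceptance script run cohorts of 12 subjects x
60 regions x 96 volumes, 10-20 generator seeds for rate-based checks,
1000 (tests: 200-500) bootstrap resamples, and 99-200 spin permutations
for calibration sweeps; these sizes give stable rates while keeping a
full validation run within a few minutes on one CPU.
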