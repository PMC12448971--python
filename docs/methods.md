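# Methods

This note documents the models, numerical choices, and limitations behind
`repspace`. The package analyzes behavioral studies in which participants
judge the similarity of natural-image pairs on named perceptual or
conceptual dimensions, later perform graded old/new recognition, and (in a
forced-choice variant) pick which of two probes is more similar to a
target. Because no behavioral data ship with the package, a synthetic-data
generator with known ground truth defines the conditions under which every
analysis stage is validated.

## Space reconstruction by sparse least squares

Each similarity rating compares two images on one dimension. Stacking all
ratings of a dimension gives the sparse linear system `M x = r`, where row
t of `M` holds +1 in the column of the first image of trial t and −1 in the
column of the second, and `r_t` is the signed rating on the −50..50 scale.
The minimum-norm least-squares solution `x` assigns each image a 1D
coordinate; two solutions combine into a 2D space whose pairwise Euclidean
distances are the reconstructed representational distances.

Numerical conventions:

* **Sign.** A row (+1 at the first image, −1 at the second) models
  `rating = x_first − x_second`. The behavioral instruction ("rate the last
  image in relation to the first") could be read with the opposite sign;
  that reading only flips each axis globally and changes no distance, so
  the matrix convention is used as printed.
* **Gauge.** Every row of `M` sums to zero, so the solution is identified
  only up to one additive constant per connected component of the pairing
  graph. The minimum-norm LSQR solution is orthogonal to the component
  indicator vectors and therefore already mean-centered per component; the
  solver re-centers explicitly so the convention does not depend on solver
  tolerance. Components are found with `scipy.sparse.csgraph` on the
  co-occurrence graph implied by `M`'s sparsity pattern.
* **No per-dimension rescaling** before combining two 1D solutions: both
  axes share the −50..50 rating unit.
* **Solver.** `scipy.sparse.linalg.lsqr` with `atol = btol = 1e-12`
  (1e-14 in exact-identifiability checks).

### Permutation validation

A reconstruction is validated by shuffling the response vector uniformly at
random (without replacement) while keeping `M` fixed, re-solving, and
ranking the empirical residual L2 norm in the surrogate distribution. The
p-value uses the add-one correction `p = (1 + #{null ≤ empirical}) /
(1 + n_perm)`, so p is never zero; the default is 10,000 shuffles.

Because `M` never changes across shuffles, the residual of every surrogate
refit is computed by projection onto an orthonormal basis `U` of range(M)
(obtained once by SVD with a rank cutoff at machine precision):
`residual² = ‖r‖² − ‖Uᵀ r_perm‖²`, and `‖r‖` is permutation-invariant. This
is algebraically identical to re-solving each system — a unit test asserts
equality against explicit per-shuffle LSQR refits — and reduces the cost of
a 10,000-shuffle validation of a study-scale dimension to a few seconds.
The permutation stream is seeded independently of data generation.

### Task-relevant and task-irrelevant distances

The task-relevant distance of a trial is the Euclidean length of its two
ratings (`hypot(rating_a, rating_b)`): the first image sits at the origin
and the second at the rated offsets. The task-irrelevant distance of the
same image pair is the unweighted mean of the pair's Euclidean distance in
the five canonical 2D spaces the participant did not rate that pair on,
each reconstructed from the pooled ratings of **all other participants**
(leave-one-participant-out; provenance fields on every space assert the
exclusion). Equal weighting of the five spaces is used; weighting by
available rating count would be an alternative, but the counts are balanced
by design. Note a structural property inherited from the design: two of the
five "other" spaces each share one dimension with the rated pair (e.g., the
climate+approach space for a climate+size rating), so irrelevant distances
are not constructed to be orthogonal to relevant ones — they differ by
being consensus-based and by averaging over never-rated-together axes.

### Individual-to-global similarity

Individual and global (all-participant) spaces are compared by Spearman
rank correlation of the strictly-upper-triangle vectorizations of their
distance matrices, with average ranks for ties. Condition differences use a
paired t-test of per-participant correlations (conceptual vs. perceptual);
equality of variances across the six spaces' correlation sets uses Levene's
test.

## Layer-wise representational similarity

A feature bank (one image-by-feature matrix per model layer; concept-level
for the semantic bank) becomes a representational similarity matrix by
Spearman-correlating every pair of rows (average ranks, unit diagonal).
Convolutional-class and fully-connected-class maps are averaged entrywise
in raw correlation units; Fisher's z transform (`arctanh`) is applied
afterward wherever a statistic needs approximately normal values
(`fisher_z_rdm` offers the transform-then-average order behind the same
interface, for sensitivity analyses).

The layer-behavior profile computes, per participant, layer and encoding
condition, the Spearman correlation between trial-rated 2D distances and
model pair dissimilarities (1 − similarity), Fisher-z transformed. Per
layer, a one-sided paired t-test contrasts conditions across participants —
convolutional layers are tested for perceptual > conceptual agreement,
fully-connected and semantic structures for the reverse, matching the
layers' designed content — and the nine p-values are Benjamini–Hochberg
FDR-adjusted. Participants with fewer than 3 usable pairs in a condition
are dropped with a warning.

Triplet distinctiveness on a layer is `d = r_sim − r_dist`, the similarity
of the target to the similar choice minus its similarity to the distractor.
Lure similarity is the maximum similarity of a lure to any encoded item
(image-level for conv/fc, concept-level for the semantic structure).

## Signal-detection description of recognition

Raw confidence lives on −50..50 with "sure old" at −50. For analysis it is
rescaled to 0..50 oriented toward the correct response: old items map by
`(50 − raw)/2`, new items by `(50 + raw)/2` — the unique affine map of the
full scale onto 0..50 with the correct orientation per status. A `fold`
switch implements the alternative reading that keeps only confidence on the
correct side of the midpoint. The old/new binarization for d′ splits at raw
= 0 (scale midpoint). Neither the exact rescaling formula nor the
binarization rule is externally fixed, so real-data statistics would not be
numerically reproducible under a different reading; the linear map is the
default because it uses the whole response range.

ROC curves sweep the bin edges of the raw scale in width-5 steps, calling
an item "old" when its confidence is at or below the threshold; AUC is the
trapezoidal area under the (false-alarm, hit) curve. On confidence-scale-
wide continuous data this binned AUC stays within 0.02 of the exact
rank-sum (Mann–Whitney) AUC; narrow response distributions that occupy only
a few bins can exceed that bound, which is a property of binning, not of
the implementation. d′ is `z(hit) − z(fa)` with the log-linear correction
`(count + 0.5)/(n + 1)` replacing rates of exactly 0 or 1.

## Mixed-model likelihood-ratio recipes

Every results contrast is a named recipe around one machine: a linear mixed
model with participant random intercepts fitted by **maximum likelihood**
(not REML — REML likelihoods are not comparable across fixed-effect
structures), compared with a reduced model by `χ² = 2·ΔLL` (floored at 0)
with degrees of freedom equal to the fixed-parameter-count difference and
an upper-tail χ² p-value. Single effects give χ²(1); a 2×2 interaction term
gives χ²(1) under this convention. For main effects the reduced model drops
the effect of interest (intercept-only when it is the only predictor); for
interactions the full model carries all main effects plus the interaction
and the reduced model drops only the interaction. Post-hoc condition
differences re-fit on data split by the factor of interest against an
intercept-only reduced model. Each recipe also returns outcome residuals of
the reduced model (fixed effects and predicted random intercepts removed)
for effect-focused plotting.

Fitting uses `statsmodels` MixedLM. Boundary variance estimates (estimated
participant variance near zero) break or mislead quasi-Newton optimizers —
L-BFGS can crash on a singular Hessian, return infinite log-likelihoods, or
stop at inferior optima — so fits cascade through Powell → BFGS → L-BFGS,
require a finite log-likelihood, and keep the first converged result. When
the participant variance collapses to zero, predicted random intercepts are
zero and the fixed effects coincide with ordinary least squares (asserted
in tests).

Trial filtering implements the two reaction-time rules used by the studies
(absolute > 150 s; participant mean + 4 SD) plus the >75 %-accuracy triplet
filter.

## The synthetic-data generator

The generator defines the statistical conditions under which the pipeline
is validated. Its defaults are fixed once and shared by tests and the
acceptance script.

* **Latent space.** Each concept draws one coordinate per dimension from
  Normal(0, 15²); typical pairwise differences then occupy the ±50 rating
  range without saturating it (the clipping rate at default settings is
  about 2 % and is excluded or monitored where exactness matters). Images
  of a concept share its conceptual coordinates exactly and jitter the
  perceptual ones by Normal(0, (0.5·15)²), making new-exemplar lures
  perceptually near their targets as the recognition design requires.
* **Design.** Per participant, concepts are split between the perceptual
  and conceptual conditions by seeded shuffle (block assignment varies
  across participants); each of the three within-condition dimension pairs
  receives a random spanning chain over the condition's images, so every
  rated dimension's pairing graph is connected by construction (and
  asserted). Pairs always span two different concepts. Extra cross-concept
  pairs top the count up to the requested trials per participant.
* **Subjective spaces.** Participants judge from idiosyncratically
  distorted copies of the shared space: the effective coordinate on a
  condition-c dimension is `s_c·x + sqrt(1 − s_c²)·η` with η ~ Normal(0,
  15²) drawn once per participant-image-dimension and defaults `s_perc =
  0.45`, `s_conc = 0.70`. The mixture preserves the marginal scale, and
  `s_c` equals the correlation between individual and shared coordinates —
  chosen so that individual-to-global space correlations land in a moderate
  range with conceptual spaces more shared than perceptual ones, the
  qualitative pattern graded-rating studies report. This individuality is
  load-bearing: consensus-reconstructed irrelevant distances share
  dimensions with the rated pair (see above), and only subjective/consensus
  divergence keeps a planted relevant-distance memory effect from leaking
  into the irrelevant-distance analysis. `shared_weight = 1` recovers fully
  shared spaces and exact noiseless identifiability.
* **Ratings.** `clip(x_first − x_second + ε, −50, 50)` on the participant's
  effective coordinates, ε ~ Normal(0, noise_sd²); the default moderate
  rating noise is `noise_sd = 8`.
* **Recognition.** Old-item latent memory strength on the 0..50 scale is
  `25 + intercept_cond + 0.05·(relevant 2D distance, centered) + cueing
  terms + participant intercept (SD 4) + Normal(0, 8²)`, mapped affinely to
  raw confidence (`raw = 50 − 2·strength`) and clipped. Lure confidences
  follow equal-variance Gaussian signal detection against the participant's
  own old-item distribution with planted d′ = 0.7 (new exemplar) and 1.25
  (new concept), the sensitivity levels graded single-probe recognition
  produces; d′ = 0 reproduces the old-item distribution exactly. Cueing is
  between-participant (one cued condition each) and inert unless a
  targeted-memory-reactivation design is requested. Scale saturation
  slightly attenuates realized d′ relative to the planted values.
* **Feature banks.** Each feature column is a zero-mean Gaussian-process
  draw over images with squared-exponential covariance on latent
  coordinates scaled by `sqrt(loading)/15` (length scale 1.5), plus
  feature noise. With many features the inter-image feature correlation
  converges to the kernel, so a bank's similarity structure is a monotone
  function of the loading-weighted latent distance — exactly the property
  the layer analyses assume. A linear feature mixture cannot produce this
  (the correlation of linear features is not monotone in coordinate
  distance), which is why the generative model is a GP with distance-based
  covariance. Default layers: conv1–5 load perceptual dimensions with a
  weak conceptual gradient (0→0.16), fc6–8 load conceptual dimensions with
  a fading perceptual residue (0.24→0.08), and a concept-level semantic
  bank loads conceptual dimensions only.
* **Triplets.** Drawn so the condition-defining layer class (conv for
  perceptual, fc for conceptual) separates similar from distractor by at
  least the requested margin; choices follow a logistic model in
  `r_sim − r_dist` (slope 8 by default) or a deterministic chooser.
  Reaction times are log-normal, decreasing in the margin.
* **Reaction times** elsewhere are a log-normal placeholder
  (median 2 s, σ_log = 0.4) — sufficient for exercising the filtering
  rules, with no claim to chronometric realism.

What the generator does **not** emulate: real image statistics (features
come from the latent space, not from pictures), response biases and scale-
use idiosyncrasies beyond the linear distortion model, sequential and
fatigue effects, and any sleep physiology behind cueing (cueing effects are
planted directly as strength shifts). Passing tests therefore demonstrate
that the analysis chain recovers what its assumptions describe — not that
those assumptions hold for any particular real dataset.

## Validation sizes

The acceptance-style checks run at the studies' design scale where the
property demands it and at reduced replication counts where only a rate is
estimated: permutation validity on a 336-image, 10-participant synthetic
study with 10,000 shuffles per dimension; noiseless identifiability on a
60-image design (latent SD 6, so no rating saturates); permutation null
calibration over 500 pure-noise systems at 199 shuffles; layer dissociation
over 20 replications at n = 100 participants; the relevant/irrelevant
dissociation over 50 replications at n = 40 participants × 112 images; the
likelihood-ratio type-I error over 1,000 null simulations at n = 30
participants × 20 trials. `scripts/acceptance.py` recomputes the same
quantities with smaller replication counts (documented in its sections) and
reports them as JSON.

## Known limitations

* Irrelevant distances are attached to recognition items as the per-image
  mean over the item's encoding trials; the underlying construct is
  pair-level and other aggregations are possible.
* The χ²(df) reference for the LRT is asymptotic; at very small participant
  counts the test can be mildly anticonservative (the calibration check
  bounds this at n = 30).
* The permutation projection trick assumes the design matrix is fixed
  across shuffles; shuffling anything other than the response vector would
  require re-factorization.
* `LayerRDM` structures assume complete image coverage; missing images
  raise rather than impute.
* The optional adapter interface for injecting real pretrained-network
  features accepts any object yielding a `FeatureBank`; the core never
  downloads models or images.
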