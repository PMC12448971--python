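# repspace

Reconstruction and analysis of task-relevant representational spaces from
pairwise similarity ratings, and their relation to graded recognition
memory.

## The problem

In a family of behavioral memory studies, participants compare pairs of
natural images on two named dimensions at a time — perceptual (viewing
orientation, color temperature, camouflage) or conceptual (real-world size,
habitat climate, approachability) — on a −50..50 visual-analogue scale, and
a day later rate their confidence that each image is old or new. The
scientific questions are geometric: do the ratings embed the images in
metric representational spaces; are those spaces shared across people or
idiosyncratic; do distances in the task-relevant space (the dimensions a
participant actually judged) predict later memory strength while distances
in never-judged spaces do not; and do model-derived similarity structures
(convolutional layers of an object-recognition network for perceptual
content, late layers and a sentence-embedding model for conceptual content)
track the corresponding human judgements?

`repspace` implements the full analysis chain as a tested, reusable
library, together with a synthetic-data generator with known ground truth
so every stage can be validated end to end without any data download. It is
aimed at researchers who want to run these analyses on their own rating /
recognition tables (delimited text in, delimited text and JSON out) or to
study the estimators' behavior under a controlled generative model.

## The core machinery

**Space reconstruction.** Each rating contrasts two images on one
dimension: stacking ratings gives the sparse system `M x = r`, with +1/−1
in the columns of the first/second image of each trial and the signed
rating as response. The minimum-norm least-squares solution (LSQR) assigns
every image a coordinate; two solutions form a 2D space with Euclidean
pair distances. Validity is established by a permutation test: shuffle the
response vector, keep `M` fixed, re-solve, and rank the empirical residual
`‖Mx − r‖₂` in the surrogate distribution (default 10,000 shuffles,
`p = (1 + #{null ≤ empirical}) / (1 + n_perm)`).

**Relevant vs. irrelevant distances.** A trial's task-relevant distance is
`√(rating₁² + rating₂²)`. Its task-irrelevant distance is the mean distance
of the same image pair in the five 2D spaces the participant did not rate
that pair on, each reconstructed from all other participants' ratings.

**Representational models.** Feature banks become image-by-image Spearman
similarity matrices; convolutional- and fully-connected-class layer maps
are averaged and Fisher-z transformed where statistics need it; per-layer
one-sided paired t-tests (FDR-corrected) contrast how well each layer
matches perceptual vs. conceptual rated distances. Triplet distinctiveness
(`d = r_sim − r_dist`) and maximum lure-to-encoded similarity supply
model-derived predictors for memory analyses.

**Memory analysis.** Confidence is rescaled to a correctness-oriented 0..50
"memory strength"; discrimination is summarized by width-5-binned ROC/AUC
and equal-variance `d′ = z(hit) − z(fa)`; every results contrast is a named
recipe built on linear mixed models with participant random intercepts
(maximum-likelihood fits, full-vs-reduced likelihood-ratio tests reporting
z, χ², df, p).

See `docs/methods.md` for the complete model description, numerical
conventions, and the generative model behind the synthetic studies.

## Worked example

```python
import pandas as pd
from repspace import synthetic_data as sd, space_reconstruction as sr, memory_analysis as ma

config = sd.generate_latent_configuration(n_concepts=28, images_per_concept=4, seed=2)
encoding = sd.simulate_encoding(config, n_participants=40,
                                trials_per_participant=330, noise_sd=8.0, seed=2)
recognition = sd.simulate_recognition(config, encoding, sd.DEFAULT_EFFECTS, seed=3)

# 1. validate one reconstructed dimension against a shuffle null
system = sr.build_design_matrix(encoding, "climate")
validation = sr.permutation_validate(system, n_perm=10_000, seed=4)
print(f"climate space: residual {validation.empirical_error:.1f}, "
      f"null mean {validation.null_errors.mean():.1f}, p = {validation.p_value:.4f}")

# 2. lure discrimination
old = recognition.loc[recognition.status == "old", "raw_confidence"]
lure = recognition.loc[recognition.status == "new_exemplar", "raw_confidence"]
print(f"old vs new exemplar: AUC = {ma.roc_auc(old, lure).auc:.3f}, "
      f"d' = {ma.dprime(old, lure).dprime:.2f}")

# 3. does memory follow task-relevant, but not task-irrelevant, distances?
distances = sr.compute_trial_distances(encoding)
long = pd.concat([
    distances[["participant_id", "image_first", "irrelevant_distance"]]
    .rename(columns={"image_first": "image_id"}),
    distances[["participant_id", "image_second", "irrelevant_distance"]]
    .rename(columns={"image_second": "image_id"})])
per_image = (long.groupby(["participant_id", "image_id"])
             ["irrelevant_distance"].mean().reset_index())
recognition = recognition.merge(per_image, on=["participant_id", "image_id"],
                                how="left")
for name in ("relevant_distance", "irrelevant_distance"):
    lrt = ma.run_recipe(name, {"recognition": recognition}).results[0]
    print(f"{name}: z = {lrt.z:.2f}, chi2({lrt.df}) = {lrt.chi2:.2f}, "
          f"p = {lrt.p:.4f}")
```

Output:

```
climate space: residual 1095.6, null mean 1432.0, p = 0.0001
old vs new exemplar: AUC = 0.674, d' = 0.62
relevant_distance: z = 2.49, chi2(1) = 6.18, p = 0.0129
irrelevant_distance: z = 0.46, chi2(1) = 0.21, p = 0.6470
```

Reading the numbers: the reconstructed climate space fits the ratings far
better than any of 10,000 response shuffles (the smallest attainable p with
the add-one correction), participants discriminate old images from
same-concept lures well above chance (AUC 0.674; the generator planted
d′ = 0.7, realized here as 0.62 after scale saturation), and the planted
memory-strength slope on the trial-rated 2D distance is detected
(p = 0.013) while the distance of the same pairs in never-rated spaces
carries no effect (p = 0.65), reproducing the relevant/irrelevant
dissociation by construction.

## Command-line pipeline

The same chain runs end to end from the shell, with per-stage seeding and a
machine-readable manifest:

```bash
repspace all --profile I --seed 7 --out runs/study1 --n-perm 1000
repspace validate --profile I --seed 7 --out runs/val   # only through validation
```

Stages: `simulate`, `reconstruct`, `validate`, `rsa`, `memory`, `report`
(each runs the stages it depends on first). A YAML config (`--config`)
overrides the study profile; identical configs produce byte-identical
output directories.

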