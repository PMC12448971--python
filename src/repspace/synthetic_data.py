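"""Synthetic behavioral-study generator with known ground truth.

The studies this package analyzes rated pairs of natural images on six
dimensions, recognized them a day later on a graded old/new confidence
scale, and (in a third study) made forced-choice triplet similarity
judgements.  No behavioral data are distributed, so every analysis stage is
exercised against this generator, which produces trial tables with the
statistical structure the analyses assume and exposes every generative
coefficient for parameter-recovery testing.

Generative model
----------------
* Each concept draws one latent coordinate per dimension from
  Normal(0, 15**2); images of a concept share the conceptual coordinates
  exactly and jitter the perceptual coordinates (new exemplars are
  perceptually near their concept).
* A similarity rating is the clipped latent coordinate difference
  ``clip(x_first - x_second + noise, -50, 50)``, matching the sign
  convention of the reconstruction design matrix.
* Recognition confidence for old items follows a linear memory-strength
  model (condition intercepts, a slope on the trial-rated 2D distance,
  between-participant cueing terms, a participant random intercept, residual
  noise) mapped affinely onto the -50..50 raw scale ("sure old" = -50).
  Lure confidences come from equal-variance Gaussian signal detection with a
  stated d' per lure class.
* Model feature banks are Gaussian-process draws over the latent space with
  a squared-exponential kernel on a weighted latent distance, so that the
  expected inter-image feature correlation decreases monotonically in the
  weighted latent distance a layer is built to care about (convolutional
  layers weight perceptual dimensions, fully connected and semantic layers
  weight conceptual ones).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dimensions import (
    ALL_DIMENSIONS,
    CONCEPTUAL_DIMENSIONS,
    DIMENSION_PAIRS,
    DIMENSION_SETS,
    PERCEPTUAL_DIMENSIONS,
    RATING_MAX,
    RATING_MIN,
)
from .errors import DesignError, InvalidArgumentError

#: Scale of the latent concept coordinates; typical pairwise differences then
#: occupy the +/-50 rating range without saturating it.
LATENT_COORD_SD = 15.0

#: Within-concept perceptual jitter as a fraction of the between-concept SD.
PERCEPTUAL_JITTER_FRAC = 0.5

#: Weight of the shared latent structure in each participant's subjective
#: space, per condition.  A participant's effective coordinate is
#: ``s * x_shared + sqrt(1 - s**2) * x_idiosyncratic`` with both components
#: on the Normal(0, 15**2) scale, so ``s`` equals the correlation between
#: individual and shared coordinates while the rating scale stays equally
#: occupied.  Individual spaces track the shared structure only moderately,
#: and perceptual spaces are more idiosyncratic than conceptual ones.
SHARED_STRUCTURE_WEIGHT: dict[str, float] = {"perceptual": 0.45, "conceptual": 0.70}

ENCODING_COLUMNS = [
    "participant_id", "block_condition", "dim_a", "dim_b",
    "image_first", "image_second", "rating_a", "rating_b",
    "rt_first", "rt_second",
]

RECOGNITION_COLUMNS = [
    "participant_id", "image_id", "concept_id", "status", "raw_confidence",
    "retrieval_task", "encoding_condition", "cued", "relevant_distance", "rt",
]

TRIPLET_COLUMNS = [
    "participant_id", "condition", "target", "similar_choice",
    "distractor_choice", "chosen", "rt",
]

#: Default generative coefficients.  Intercepts and slope are on the 0..50
#: memory-strength scale; d' values sit at the levels the graded-recognition
#: studies report for single-probe retrieval.
DEFAULT_EFFECTS: dict[str, float] = {
    "slope_relevant_distance": 0.05,
    "intercept_perceptual": 7.5,
    "intercept_conceptual": 7.5,
    "cueing_main": 1.0,
    "cueing_x_conceptual": 3.0,
    "participant_sd": 4.0,
    "residual_sd": 8.0,
    "dprime_new_exemplar": 0.7,
    "dprime_new_concept": 1.25,
}

REQUIRED_EFFECT_KEYS = tuple(DEFAULT_EFFECTS)

#: Optional coefficients used only when general/specific retrieval tasks are
#: simulated (forced-choice study recognition design).
OPTIONAL_EFFECT_DEFAULTS: dict[str, float] = {
    "general_main": 1.0,
    "general_x_conceptual": 2.0,
    "dprime_new_exemplar_general": 0.45,
    "dprime_new_concept_general": 1.87,
}


@dataclass(frozen=True)
class LatentConfiguration:
    """Ground-truth latent coordinates of every image on every dimension.

    ``images`` is indexed by image_id with a ``concept_id`` column and one
    column per dimension.  ``dimension_sets`` partitions the six dimensions
    into the perceptual and conceptual condition sets.
    """

    images: pd.DataFrame
    dimension_sets: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DIMENSION_SETS)
    )

    @property
    def image_ids(self) -> list[str]:
        return list(self.images.index)

    @property
    def concept_ids(self) -> list[str]:
        return list(pd.unique(self.images["concept_id"]))

    @property
    def coords(self) -> pd.DataFrame:
        return self.images[list(ALL_DIMENSIONS)]

    def concept_coords(self) -> pd.DataFrame:
        """Concept-level coordinates (mean over the concept's images)."""
        return self.images.groupby("concept_id", sort=True)[list(ALL_DIMENSIONS)].mean()

    def validate(self) -> None:
        dims = [d for s in self.dimension_sets.values() for d in s]
        if sorted(dims) != sorted(ALL_DIMENSIONS):
            raise InvalidArgumentError("dimension sets must partition the 6 dimensions 3+3")
        if self.images[list(ALL_DIMENSIONS)].isna().any().any():
            raise InvalidArgumentError("every image needs a coordinate on every dimension")


def generate_latent_configuration(
    n_concepts: int,
    images_per_concept: int,
    seed: int,
    coord_sd: float = LATENT_COORD_SD,
    perceptual_jitter_frac: float = PERCEPTUAL_JITTER_FRAC,
) -> LatentConfiguration:
    """Draw a ground-truth configuration of ``n_concepts * images_per_concept`` images.

    Concept coordinates are i.i.d. Normal(0, coord_sd**2) per dimension.
    Images of a concept share its conceptual coordinates exactly and perturb
    the perceptual ones by Normal(0, (perceptual_jitter_frac * coord_sd)**2).
    """
    if n_concepts < 2 or images_per_concept < 1:
        raise InvalidArgumentError(
            f"need n_concepts >= 2 and images_per_concept >= 1, "
            f"got {n_concepts}, {images_per_concept}"
        )
    rng = np.random.default_rng(seed)
    concept_ids = [f"con{c:03d}" for c in range(n_concepts)]
    concept_coords = rng.normal(0.0, coord_sd, size=(n_concepts, len(ALL_DIMENSIONS)))

    rows = []
    index = []
    jitter_sd = perceptual_jitter_frac * coord_sd
    for c, cid in enumerate(concept_ids):
        for k in range(images_per_concept):
            coords = dict(zip(ALL_DIMENSIONS, concept_coords[c]))
            for dim in PERCEPTUAL_DIMENSIONS:
                coords[dim] += rng.normal(0.0, jitter_sd)
            rows.append({"concept_id": cid, **coords})
            index.append(f"img{c:03d}_{k}")
    images = pd.DataFrame(rows, index=pd.Index(index, name="image_id"))
    config = LatentConfiguration(images=images)
    config.validate()
    return config


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def _spanning_chain(items: np.ndarray, concept_of: Mapping[str, str],
                    rng: np.random.Generator) -> list[tuple[str, str]]:
    """Random spanning chain over ``items``: consecutive pairs of a permutation.

    Adjacent images of the same concept are repaired by swapping, since image
    pairs are always drawn from different concepts.
    """
    order = list(rng.permutation(items))
    for _ in range(20 * len(order)):
        bad = [i for i in range(len(order) - 1)
               if concept_of[order[i]] == concept_of[order[i + 1]]]
        if not bad:
            break
        i = bad[0]
        j = int(rng.integers(len(order)))
        order[i], order[j] = order[j], order[i]
    else:
        raise DesignError("could not order images without same-concept adjacency")
    return [(order[i], order[i + 1]) for i in range(len(order) - 1)]


def _assert_connected(pairs: Iterable[tuple[str, str]], items: Sequence[str]) -> None:
    """Union-find connectivity check of the pairing graph over ``items``."""
    parent = {x: x for x in items}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pairs:
        parent[find(a)] = find(b)
    roots = {find(x) for x in items}
    if len(roots) > 1:
        comps: dict[str, list[str]] = {}
        for x in items:
            comps.setdefault(find(x), []).append(x)
        raise DesignError(
            f"pairing graph disconnected into {len(roots)} components: "
            f"{sorted(sorted(c) for c in comps.values())}"
        )


def simulate_encoding(
    config: LatentConfiguration,
    n_participants: int,
    trials_per_participant: int,
    noise_sd: float,
    seed: int,
    shared_weight: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Simulate the pairwise-rating encoding phase.

    Each participant's concepts are split between the perceptual and
    conceptual conditions (seeded shuffle, so block assignment varies across
    participants).  Within a condition, each of the three dimension-pair
    block types receives a random spanning chain over the condition's
    images — guaranteeing a connected pairing graph for every dimension a
    participant rates — plus extra random pairs until the participant has at
    least ``trials_per_participant`` trials.  Pairs always span two
    different concepts.

    Each participant judges from an idiosyncratically distorted copy of the
    shared latent space: their effective coordinate on a dimension of
    condition c is ``s_c * x + sqrt(1 - s_c**2) * eta`` with ``eta ~
    Normal(0, 15**2)`` drawn once per (participant, image, dimension) and
    ``s_c = shared_weight[c]``.  ``shared_weight={"perceptual": 1,
    "conceptual": 1}`` recovers fully shared spaces (and exact noiseless
    identifiability of the shared latents).

    Ratings follow ``clip(x_first - x_second + eps, -50, 50)`` on the
    participant's effective coordinates, with ``eps ~ Normal(0,
    noise_sd**2)`` independently per rated dimension.
    """
    if noise_sd < 0:
        raise InvalidArgumentError(f"noise_sd must be >= 0, got {noise_sd}")
    if n_participants < 1 or trials_per_participant < 1:
        raise InvalidArgumentError("participant and trial counts must be positive")
    shared = dict(SHARED_STRUCTURE_WEIGHT if shared_weight is None else shared_weight)
    if any(not (0.0 < v <= 1.0) for v in shared.values()):
        raise InvalidArgumentError("shared_weight values must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    coords = config.coords
    concept_of = config.images["concept_id"].to_dict()
    by_concept = config.images.groupby("concept_id").groups

    records = []
    concept_ids = np.array(config.concept_ids)
    for p in range(n_participants):
        pid = f"sub{p:03d}"
        shuffled = rng.permutation(concept_ids)
        half = len(shuffled) // 2
        assignment = {
            "perceptual": shuffled[:half],
            "conceptual": shuffled[half:],
        }
        # Participant's subjective space: variance-preserving mixture of the
        # shared latents with an idiosyncratic component drawn once here.
        eff = coords.copy()
        for condition, dims in DIMENSION_SETS.items():
            s = shared.get(condition, 1.0)
            if s < 1.0:
                eta = rng.normal(0.0, LATENT_COORD_SD, size=(len(eff), len(dims)))
                eff[list(dims)] = s * eff[list(dims)] + np.sqrt(1.0 - s**2) * eta
        participant_pairs: list[tuple[str, str, str, str, str]] = []
        for condition, concepts in assignment.items():
            images = np.concatenate([np.asarray(by_concept[c]) for c in concepts])
            if len(images) < 2 or len(concepts) < 2:
                raise DesignError(
                    f"condition {condition!r} needs >= 2 concepts with images; "
                    f"got {len(concepts)} concept(s)"
                )
            for dim_a, dim_b in DIMENSION_PAIRS[condition]:
                for first, second in _spanning_chain(images, concept_of, rng):
                    participant_pairs.append((condition, dim_a, dim_b, first, second))
        # Top up with random within-block, cross-concept pairs.
        block_types = [
            (cond, pair) for cond in assignment for pair in DIMENSION_PAIRS[cond]
        ]
        while len(participant_pairs) < trials_per_participant:
            cond, (dim_a, dim_b) = block_types[rng.integers(len(block_types))]
            images = np.concatenate([np.asarray(by_concept[c]) for c in assignment[cond]])
            first, second = rng.choice(images, size=2, replace=False)
            if concept_of[first] == concept_of[second]:
                continue
            participant_pairs.append((cond, dim_a, dim_b, first, second))

        # Connectivity is guaranteed by the spanning chains; assert anyway.
        for condition, concepts in assignment.items():
            images = np.concatenate([np.asarray(by_concept[c]) for c in concepts])
            for dim in DIMENSION_SETS[condition]:
                pairs = [
                    (f, s) for (_, da, db, f, s) in participant_pairs
                    if dim in (da, db)
                ]
                _assert_connected(pairs, list(images))

        n = len(participant_pairs)
        eps = rng.normal(0.0, noise_sd, size=(n, 2)) if noise_sd > 0 else np.zeros((n, 2))
        rts = rng.lognormal(mean=np.log(2.0), sigma=0.4, size=(n, 2))
        for i, (cond, dim_a, dim_b, first, second) in enumerate(participant_pairs):
            ra = np.clip(eff.at[first, dim_a] - eff.at[second, dim_a] + eps[i, 0],
                         RATING_MIN, RATING_MAX)
            rb = np.clip(eff.at[first, dim_b] - eff.at[second, dim_b] + eps[i, 1],
                         RATING_MIN, RATING_MAX)
            records.append((pid, cond, dim_a, dim_b, first, second,
                            float(ra), float(rb), rts[i, 0], rts[i, 1]))
    return pd.DataFrame.from_records(records, columns=ENCODING_COLUMNS)


# ---------------------------------------------------------------------------
# Recognition
# ---------------------------------------------------------------------------

def _check_effects(effects: Mapping[str, float]) -> dict[str, float]:
    missing = [k for k in REQUIRED_EFFECT_KEYS if k not in effects]
    if missing:
        raise InvalidArgumentError(f"missing generative coefficient(s): {missing}")
    merged = dict(OPTIONAL_EFFECT_DEFAULTS)
    merged.update(effects)
    return merged


def trial_rated_distance(rating_a, rating_b):
    """Euclidean length of a trial's two ratings (the task-relevant distance)."""
    return np.hypot(rating_a, rating_b)


def simulate_recognition(
    config: LatentConfiguration,
    encoding: pd.DataFrame,
    effects: Mapping[str, float],
    seed: int,
    retrieval_tasks: Sequence[str] = ("single",),
    tmr: bool = False,
) -> pd.DataFrame:
    """Simulate graded old/new recognition for every encoded image plus lures.

    Old-item latent memory strength (0..50 scale):

    ``strength = intercept_cond + slope * d2_rel + cueing_main * cued
                 + cueing_x_conceptual * (cued & conceptual)
                 + participant_intercept + Normal(0, residual_sd)``

    where ``d2_rel`` is the image's mean trial-rated 2D distance (centered
    within participant so intercepts stay interpretable).  Raw confidence is
    ``clip(50 - 2 * (25 + strength - baseline) ...)``; concretely the affine
    map ``raw = 50 - 2 * (25 + strength_centered)`` so that strength 25 maps
    to raw 0 and higher strength maps toward "sure old" (-50).

    Lure confidences follow equal-variance signal detection: per participant,
    raw lure confidence ~ Normal(m_p + dprime * s_p, s_p**2) where (m_p, s_p)
    are the mean/SD of that participant's pre-clipping old-item raw
    confidences — d' = 0 reproduces the old-item distribution exactly.

    With ``tmr=True`` each participant is assigned one cued condition
    (between-participant targeted-memory-reactivation design); a trial is
    cued when its encoding condition matches the participant's cued
    condition.  Without TMR every trial has ``cued = False`` and the cueing
    coefficients are inert.
    """
    eff = _check_effects(effects)
    rng = np.random.default_rng(seed)
    valid_tasks = {"single", "general", "specific"}
    if not set(retrieval_tasks) <= valid_tasks:
        raise InvalidArgumentError(f"retrieval tasks must be among {valid_tasks}")

    # Per-image mean trial-rated 2D distance and encoding condition.
    enc = encoding.copy()
    enc["d2"] = trial_rated_distance(enc["rating_a"], enc["rating_b"])
    long = pd.concat([
        enc[["participant_id", "block_condition", "image_first", "d2"]]
        .rename(columns={"image_first": "image_id"}),
        enc[["participant_id", "block_condition", "image_second", "d2"]]
        .rename(columns={"image_second": "image_id"}),
    ])
    per_image = (
        long.groupby(["participant_id", "image_id"])
        .agg(relevant_distance=("d2", "mean"), encoding_condition=("block_condition", "first"))
        .reset_index()
    )

    concept_of = config.images["concept_id"]
    records = []
    lure_counter = 0
    for pid, grp in per_image.groupby("participant_id", sort=True):
        b_i = rng.normal(0.0, eff["participant_sd"])
        cued_condition = rng.choice(["perceptual", "conceptual"]) if tmr else None
        d2 = grp["relevant_distance"].to_numpy()
        d2_centered = d2 - d2.mean()
        conds = grp["encoding_condition"].to_numpy()
        cued = conds == cued_condition if tmr else np.zeros(len(grp), bool)
        intercept = np.where(
            conds == "conceptual", eff["intercept_conceptual"], eff["intercept_perceptual"]
        )

        old_raws: dict[str, np.ndarray] = {}
        for task in retrieval_tasks:
            strength = (
                25.0
                + intercept
                + eff["slope_relevant_distance"] * d2_centered
                + eff["cueing_main"] * cued
                + eff["cueing_x_conceptual"] * (cued & (conds == "conceptual"))
                + b_i
                + rng.normal(0.0, eff["residual_sd"], size=len(grp))
            )
            if task == "general":
                strength = strength + eff["general_main"] + eff[
                    "general_x_conceptual"
                ] * (conds == "conceptual")
            raw = 50.0 - 2.0 * strength
            old_raws[task] = raw
            rts = rng.lognormal(np.log(2.0), 0.4, size=len(grp))
            for j, (_, row) in enumerate(grp.iterrows()):
                records.append((
                    pid, row["image_id"], concept_of[row["image_id"]], "old",
                    float(np.clip(raw[j], RATING_MIN, RATING_MAX)), task,
                    row["encoding_condition"], bool(cued[j]),
                    float(d2[j]), float(rts[j]),
                ))

        # Lures: half new exemplars of encoded concepts, half new concepts.
        n_old = len(grp)
        n_lure = max(1, n_old // 2)
        encoded_concepts = concept_of.loc[grp["image_id"]].to_numpy()
        exemplar_concepts = rng.choice(np.unique(encoded_concepts), size=n_lure)
        concept_cond = dict(zip(encoded_concepts, conds))
        for task in retrieval_tasks:
            m_p = float(old_raws[task].mean())
            s_p = float(old_raws[task].std(ddof=1))
            suffix = "_general" if task == "general" else ""
            for status, n_items, concepts in (
                ("new_exemplar", n_lure, exemplar_concepts),
                ("new_concept", n_lure, None),
            ):
                dprime = eff[f"dprime_{status}{suffix}"]
                raw = rng.normal(m_p + dprime * s_p, s_p, size=n_items)
                rts = rng.lognormal(np.log(2.0), 0.4, size=n_items)
                for j in range(n_items):
                    if status == "new_exemplar":
                        cid = concepts[j]
                        enc_cond = concept_cond[cid]
                        is_cued = enc_cond == cued_condition
                        iid = f"lure_{cid}_{lure_counter}"
                    else:
                        cid = f"newcon{lure_counter:05d}"
                        enc_cond = "none"
                        is_cued = False
                        iid = f"img_{cid}"
                    lure_counter += 1
                    records.append((
                        pid, iid, cid, status,
                        float(np.clip(raw[j], RATING_MIN, RATING_MAX)), task,
                        enc_cond, bool(is_cued), np.nan, float(rts[j]),
                    ))
    return pd.DataFrame.from_records(records, columns=RECOGNITION_COLUMNS)


# ---------------------------------------------------------------------------
# Feature banks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerSpec:
    """Specification of one synthetic feature bank.

    ``loadings`` maps dimension name -> nonnegative weight in the layer's
    latent distance metric; dimensions absent from the mapping do not affect
    the layer's similarity structure.
    """

    layer_name: str
    klass: str  # "conv" | "fc" | "semantic"
    loadings: Mapping[str, float]
    noise_sd: float = 0.0


@dataclass(frozen=True)
class FeatureBank:
    """Image-by-feature (or concept-by-feature, for semantic banks) matrix."""

    layer_name: str
    klass: str
    features: pd.DataFrame

    def validate(self) -> None:
        if self.features.shape[1] < 2:
            raise InvalidArgumentError("feature banks need at least 2 feature columns")
        if not np.isfinite(self.features.to_numpy()).all():
            raise InvalidArgumentError("feature banks must be finite")


def default_layer_specs() -> list[LayerSpec]:
    """Eight object-recognition-network-like layers plus one semantic bank.

    Early convolutional layers weight perceptual dimensions almost
    exclusively; the weighting shifts toward conceptual dimensions through
    the fully connected layers; the semantic bank depends on conceptual
    dimensions only (at concept resolution).
    """
    specs: list[LayerSpec] = []
    conv_conc = [0.0, 0.04, 0.08, 0.12, 0.16]
    for i, w in enumerate(conv_conc, start=1):
        loadings = {d: 1.0 for d in PERCEPTUAL_DIMENSIONS}
        loadings.update({d: w for d in CONCEPTUAL_DIMENSIONS})
        specs.append(LayerSpec(f"conv{i}", "conv", loadings, noise_sd=0.5))
    fc_perc = [0.24, 0.16, 0.08]
    for i, w in enumerate(fc_perc, start=6):
        loadings = {d: 1.0 for d in CONCEPTUAL_DIMENSIONS}
        loadings.update({d: w for d in PERCEPTUAL_DIMENSIONS})
        specs.append(LayerSpec(f"fc{i}", "fc", loadings, noise_sd=0.5))
    specs.append(LayerSpec("use", "semantic",
                           {d: 1.0 for d in CONCEPTUAL_DIMENSIONS}, noise_sd=0.3))
    return specs


def simulate_feature_bank(
    config: LatentConfiguration,
    layer_spec: Sequence[LayerSpec],
    seed: int,
    n_features: int = 64,
    length_scale: float = 1.5,
) -> list[FeatureBank]:
    """Draw feature banks whose similarity structure tracks weighted latent distance.

    Each feature column is one draw of a zero-mean Gaussian process over the
    images, with squared-exponential covariance
    ``exp(-||z_i - z_j||^2 / (2 * length_scale**2))`` on coordinates scaled
    by ``sqrt(loading) / LATENT_COORD_SD``, plus i.i.d. Normal(0, noise_sd**2)
    measurement noise.  With many features the inter-image feature
    correlation converges to the kernel, so the bank's RDM is rank-identical
    to the weighted latent distance in the noiseless limit.

    Semantic-class banks are indexed by concept (one row per concept).
    """
    if not layer_spec:
        raise InvalidArgumentError("layer_spec must not be empty")
    rng = np.random.default_rng(seed)
    banks = []
    for spec in layer_spec:
        unknown = set(spec.loadings) - set(ALL_DIMENSIONS)
        if unknown:
            raise InvalidArgumentError(f"loadings reference unknown dimensions {unknown}")
        if spec.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")
        if spec.klass == "semantic":
            coords = config.concept_coords()
        else:
            coords = config.coords
        weights = np.array([spec.loadings.get(d, 0.0) for d in ALL_DIMENSIONS])
        z = coords[list(ALL_DIMENSIONS)].to_numpy() * np.sqrt(weights) / LATENT_COORD_SD
        sq = ((z[:, None, :] - z[None, :, :]) ** 2).sum(axis=-1)
        kernel = np.exp(-sq / (2.0 * length_scale**2))
        # Jitter keeps the Cholesky stable for duplicated coordinates.
        chol = np.linalg.cholesky(kernel + 1e-10 * np.eye(len(kernel)))
        feats = chol @ rng.standard_normal((len(kernel), n_features))
        if spec.noise_sd > 0:
            feats = feats + rng.normal(0.0, spec.noise_sd, size=feats.shape)
        frame = pd.DataFrame(
            feats, index=coords.index,
            columns=[f"f{k:03d}" for k in range(n_features)],
        )
        bank = FeatureBank(spec.layer_name, spec.klass, frame)
        bank.validate()
        banks.append(bank)
    return banks


# ---------------------------------------------------------------------------
# Triplets
# ---------------------------------------------------------------------------

def simulate_triplets(
    config: LatentConfiguration,
    banks: Sequence[FeatureBank],
    n_triplets: int,
    margin: float,
    seed: int,
    n_participants: int = 1,
    chooser: str = "logistic",
    beta: float = 8.0,
    max_attempts: int = 2000,
) -> pd.DataFrame:
    """Simulate forced-choice triplet trials with a planted similarity margin.

    Triplets are drawn so that on the condition-defining layer class (conv
    for perceptual, fc for conceptual) the target-to-similar correlation
    exceeds the target-to-distractor correlation by at least ``margin``.
    The ``logistic`` chooser picks the similar option with probability
    ``1 / (1 + exp(-beta * (r_sim - r_dist)))``; the ``deterministic``
    chooser always picks it.
    """
    from .representational_models import average_rdms, compute_rdm

    if margin <= 0:
        raise InvalidArgumentError(f"margin must be > 0, got {margin}")
    if chooser not in ("logistic", "deterministic"):
        raise InvalidArgumentError(f"unknown chooser {chooser!r}")
    rng = np.random.default_rng(seed)
    class_for = {"perceptual": "conv", "conceptual": "fc"}
    rdms = {}
    for condition, klass in class_for.items():
        members = [compute_rdm(b) for b in banks if b.klass == klass]
        if not members:
            raise InvalidArgumentError(f"no {klass!r}-class bank supplied")
        rdms[condition] = average_rdms(members).sim

    image_ids = np.array(config.image_ids)
    records = []
    for p in range(n_participants):
        pid = f"sub{p:03d}"
        for t in range(n_triplets):
            condition = ("perceptual", "conceptual")[(t + p) % 2]
            sim = rdms[condition]
            found = None
            for _ in range(max_attempts):
                target, a, b = rng.choice(image_ids, size=3, replace=False)
                r_a, r_b = sim.at[target, a], sim.at[target, b]
                if r_a - r_b >= margin:
                    found = (target, a, b, r_a, r_b)
                    break
                if r_b - r_a >= margin:
                    found = (target, b, a, r_b, r_a)
                    break
            if found is None:
                raise DesignError(
                    f"no triplet with margin >= {margin} found on the "
                    f"{condition} layer class after {max_attempts} attempts"
                )
            target, similar, distractor, r_sim, r_dist = found
            delta = r_sim - r_dist
            if chooser == "deterministic":
                pick_similar = True
            else:
                pick_similar = rng.random() < 1.0 / (1.0 + np.exp(-beta * delta))
            rt = float(np.exp(np.log(1.5) - 0.5 * delta + rng.normal(0.0, 0.3)))
            records.append((pid, condition, target, similar, distractor,
                            "similar" if pick_similar else "distractor", rt))
    return pd.DataFrame.from_records(records, columns=TRIPLET_COLUMNS)


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as UTF-8 comma-delimited text with one header row."""
    frame.to_csv(path, index=False, encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")


def write_feature_bank(bank: FeatureBank, prefix: str | Path) -> None:
    """Write a bank as ``<prefix>.tsv`` plus a ``<prefix>.json`` sidecar."""
    prefix = Path(prefix)
    bank.features.to_csv(prefix.with_suffix(".tsv"), sep="\t", encoding="utf-8")
    sidecar = {
        "layer_name": bank.layer_name,
        "class": bank.klass,
        "row_index": list(bank.features.index),
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_feature_bank(prefix: str | Path) -> FeatureBank:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    frame = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t", index_col=0)
    frame = frame.loc[meta["row_index"]]
    return FeatureBank(meta["layer_name"], meta["class"], frame)
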