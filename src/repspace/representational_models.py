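"""Layer-wise representational similarity structures and model-derived predictors.

A feature bank (one matrix of image-by-feature activations per model layer)
becomes a representational similarity matrix by rank-correlating every pair
of images' feature vectors.  Convolutional- and fully-connected-class layer
maps are averaged in raw correlation units; the Fisher z transform is
applied afterward wherever a statistic requires approximately normal values
(a switch allows transforming before averaging instead).  Downstream
predictors derived here: per-layer rating/model agreement profiles with
one-sided paired tests and FDR correction, triplet distinctiveness
(d = r_sim - r_dist), and maximum lure-to-encoded similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr, ttest_rel
from statsmodels.stats.multitest import fdrcorrection

from .errors import (
    InvalidArgumentError,
    MissingImageError,
    UndefinedCorrelationError,
)
from .synthetic_data import FeatureBank, trial_rated_distance


@dataclass
class LayerRDM:
    """Image-by-image (or concept-by-concept) Spearman similarity matrix."""

    layer_name: str
    klass: str
    sim: pd.DataFrame
    fisher_z_applied: bool = False

    def validate(self) -> None:
        a = self.sim.to_numpy()
        if not np.allclose(a, a.T, atol=1e-10):
            raise InvalidArgumentError("similarity matrix must be symmetric")
        if not self.fisher_z_applied:
            if not np.allclose(np.diag(a), 1.0):
                raise InvalidArgumentError("similarity matrix must have unit diagonal")
            off = a[~np.eye(len(a), dtype=bool)]
            if off.size and (np.abs(off) > 1 + 1e-12).any():
                raise InvalidArgumentError("off-diagonal similarities must lie in [-1, 1]")


@dataclass(frozen=True)
class TripletScore:
    """Triplet distinctiveness on one layer: d = r_sim - r_dist."""

    target: str
    similar_choice: str
    distractor_choice: str
    layer_name: str
    r_sim: float
    r_dist: float

    @property
    def d(self) -> float:
        return self.r_sim - self.r_dist


def spatial_average(features: np.ndarray, spatial_axes: tuple[int, ...] = (-2, -1)
                    ) -> np.ndarray:
    """Mean over spatial positions per feature channel; no-op for flat vectors."""
    arr = np.asarray(features, float)
    if arr.ndim <= 2:
        return arr
    axes = tuple(a % arr.ndim for a in spatial_axes)
    if any(arr.shape[a] == 0 for a in axes):
        raise InvalidArgumentError("spatial axes must be non-empty")
    return arr.mean(axis=axes)


def compute_rdm(bank: FeatureBank) -> LayerRDM:
    """Spearman-correlate each row's feature vector with every other row's.

    Average ranks break ties; a constant feature vector has undefined rank
    correlation and is reported by name.
    """
    feats = bank.features.to_numpy(float)
    if feats.shape[0] < 3 or feats.shape[1] < 2:
        raise InvalidArgumentError("need >= 3 rows and >= 2 features")
    spread = feats.max(axis=1) - feats.min(axis=1)
    if (spread == 0).any():
        bad = bank.features.index[int(np.argmax(spread == 0))]
        raise UndefinedCorrelationError(
            f"constant feature vector for {bad!r}; rank correlation undefined"
        )
    ranks = rankdata(feats, axis=1)  # average ranks
    sim = np.corrcoef(ranks)
    np.fill_diagonal(sim, 1.0)
    frame = pd.DataFrame(sim, index=bank.features.index, columns=bank.features.index)
    rdm = LayerRDM(bank.layer_name, bank.klass, frame)
    rdm.validate()
    return rdm


def average_rdms(rdms: Sequence[LayerRDM], klass: str | None = None) -> LayerRDM:
    """Entrywise mean of same-class correlation maps, in raw r units."""
    if not rdms:
        raise InvalidArgumentError("need at least one RDM")
    classes = {r.klass for r in rdms}
    if len(classes) > 1:
        raise InvalidArgumentError(f"cannot average across classes {sorted(classes)}")
    if klass is not None and classes != {klass}:
        raise InvalidArgumentError(f"expected class {klass!r}, got {classes}")
    index = rdms[0].sim.index
    for r in rdms[1:]:
        if not r.sim.index.equals(index):
            raise InvalidArgumentError("all RDMs must share the same image set")
    mean = sum(r.sim.to_numpy() for r in rdms) / len(rdms)
    frame = pd.DataFrame(mean, index=index, columns=index)
    return LayerRDM(f"{rdms[0].klass}_avg", rdms[0].klass, frame)


def fisher_z(rho):
    """arctanh transform of a correlation; strictly increasing and odd."""
    r = np.asarray(rho, float)
    if (np.abs(r) >= 1).any():
        raise InvalidArgumentError("|rho| must be < 1 for the Fisher z transform")
    out = np.arctanh(r)
    return float(out) if np.isscalar(rho) else out


def fisher_z_rdm(rdm: LayerRDM) -> LayerRDM:
    """Fisher-z an averaged map for use as a model predictor (diagonal left 0)."""
    a = rdm.sim.to_numpy().copy()
    np.fill_diagonal(a, 0.0)
    a = np.clip(a, -1 + 1e-12, 1 - 1e-12)
    z = np.arctanh(a)
    return LayerRDM(rdm.layer_name, rdm.klass,
                    pd.DataFrame(z, index=rdm.sim.index, columns=rdm.sim.columns),
                    fisher_z_applied=True)


def _pair_similarity(rdm: LayerRDM, img_i: str, img_j: str,
                     concept_of: Mapping[str, str] | None) -> float:
    """Similarity of an image pair; semantic maps are looked up at concept level.

    For semantic-class structures, image ids are translated through
    ``concept_of`` when supplied; otherwise the ids are taken to be
    concept-level already.
    """
    if rdm.klass == "semantic" and concept_of is not None:
        img_i, img_j = concept_of.get(img_i, img_i), concept_of.get(img_j, img_j)
    try:
        return float(rdm.sim.at[img_i, img_j])
    except KeyError as exc:
        raise MissingImageError(
            f"{exc.args[0]!r} absent from layer {rdm.layer_name!r}"
        ) from exc


#: One-sided test direction per layer class: conv layers are hypothesized to
#: agree better with perceptual ratings, fc/semantic with conceptual ratings.
_DIRECTION = {"conv": "greater", "fc": "less", "semantic": "less"}


def layerwise_behavior_correlation(
    encoding: pd.DataFrame,
    models: Sequence[LayerRDM],
    concept_of: Mapping[str, str] | None = None,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Per-layer agreement profile of rated distances with model structure.

    For every participant, layer and encoding condition: Spearman rho between
    the participant's trial-rated 2D distances and the model's pair
    dissimilarities (1 - similarity), Fisher-z transformed.  Per layer, a
    one-sided paired t-test contrasts the perceptual- vs conceptual-condition
    values across participants (conv layers tested perceptual > conceptual;
    fc and semantic layers conceptual > perceptual), and the resulting
    p-values are Benjamini-Hochberg FDR adjusted across layers.

    Returns a tidy frame with one row per layer: mean perceptual-minus-
    conceptual difference of Fisher-z values, t, raw and FDR-adjusted p.
    Participants with fewer than ``min_pairs`` usable pairs in either
    condition are excluded with a warning.
    """
    enc = encoding.copy()
    enc["d2"] = trial_rated_distance(enc["rating_a"], enc["rating_b"])
    per_participant: dict[str, dict[str, dict[str, float]]] = {}
    for (pid, condition), grp in enc.groupby(["participant_id", "block_condition"]):
        if len(grp) < min_pairs:
            warnings.warn(
                f"participant {pid!r} has {len(grp)} {condition} pairs "
                f"(< {min_pairs}); excluded from the layer profile"
            )
            continue
        for model in models:
            sims = np.array([
                _pair_similarity(model, f, s, concept_of)
                for f, s in zip(grp["image_first"], grp["image_second"])
            ])
            rho = spearmanr(grp["d2"].to_numpy(), 1.0 - sims).statistic
            if not np.isfinite(rho):
                continue
            rho = float(np.clip(rho, -1 + 1e-12, 1 - 1e-12))
            per_participant.setdefault(model.layer_name, {}).setdefault(
                pid, {})[condition] = fisher_z(rho)

    rows = []
    for model in models:
        values = per_participant.get(model.layer_name, {})
        paired = [(v["perceptual"], v["conceptual"]) for v in values.values()
                  if "perceptual" in v and "conceptual" in v]
        if len(paired) < 2:
            raise InvalidArgumentError(
                f"layer {model.layer_name!r}: fewer than 2 participants with "
                "both conditions"
            )
        zp, zc = map(np.asarray, zip(*paired))
        if np.allclose(zp, zc):
            # Degenerate contrast (identical condition profiles): no evidence.
            test = type("T", (), {"statistic": 0.0, "pvalue": 1.0})
        else:
            test = ttest_rel(zp, zc, alternative=_DIRECTION[model.klass])
        rows.append({
            "layer": model.layer_name,
            "class": model.klass,
            "n_participants": len(paired),
            "mean_diff": float(np.mean(zp - zc)),
            "t": float(test.statistic),
            "p": float(test.pvalue),
        })
    table = pd.DataFrame(rows)
    rejected, p_fdr = fdrcorrection(table["p"].to_numpy(), alpha=0.05)
    table["p_fdr"] = p_fdr
    table["significant"] = rejected
    return table


def triplet_distinctiveness(triplet: Mapping, rdm: LayerRDM,
                            concept_of: Mapping[str, str] | None = None
                            ) -> TripletScore:
    """Distinctiveness of one forced-choice triplet on one layer."""
    target = triplet["target"]
    similar, distractor = triplet["similar_choice"], triplet["distractor_choice"]
    r_sim = _pair_similarity(rdm, target, similar, concept_of)
    r_dist = _pair_similarity(rdm, target, distractor, concept_of)
    return TripletScore(target, similar, distractor, rdm.layer_name, r_sim, r_dist)


def triplet_scores(triplets: pd.DataFrame, rdm: LayerRDM,
                   concept_of: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Vectorized triplet_distinctiveness over a triplet table."""
    scores = [triplet_distinctiveness(row, rdm, concept_of)
              for _, row in triplets.iterrows()]
    out = triplets.copy()
    out[f"r_sim_{rdm.layer_name}"] = [s.r_sim for s in scores]
    out[f"r_dist_{rdm.layer_name}"] = [s.r_dist for s in scores]
    out[f"d_{rdm.layer_name}"] = [s.d for s in scores]
    return out


def lure_max_similarity(lure: str, encoded: Iterable[str], rdm: LayerRDM,
                        concept_of: Mapping[str, str] | None = None) -> float:
    """Highest similarity of a lure to any encoded item on the given structure.

    For conv/fc layers ``lure`` and ``encoded`` are image ids; for semantic
    structures they are concept ids (or image ids with ``concept_of``
    supplied for translation).
    """
    encoded = list(encoded)
    if not encoded:
        raise InvalidArgumentError("encoded set must be non-empty")
    return max(_pair_similarity(rdm, lure, e, concept_of) for e in encoded)
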