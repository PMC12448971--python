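"""Signal-detection description of recognition data and mixed-model recipes.

Raw confidences live on a -50..50 visual-analogue scale with "sure old" at
-50 and "sure new" at +50.  For analysis they are rescaled to 0..50 oriented
toward the correct response ("memory strength" for old items, correct-
rejection confidence for lures), binarized at the scale midpoint for d',
and swept through width-5 confidence bins for ROC/AUC.

Every results contrast is expressed as a named recipe: a linear mixed model
with participant random intercepts fitted by maximum likelihood (ML rather
than REML, since REML likelihoods are not comparable across fixed-effect
structures), compared with a reduced model by a likelihood-ratio test with
degrees of freedom equal to the fixed-parameter-count difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import (
    InsufficientDataError,
    InvalidArgumentError,
    UnknownRecipeError,
)

CONFIDENCE_BIN_WIDTH = 5.0


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_trials(trials: pd.DataFrame, study_rule: str,
                  rt_columns: Sequence[str] | None = None,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply a reaction-time exclusion rule; returns (kept, per-participant report).

    ``absolute_150s`` drops trials with any reaction time above 150 s;
    ``sd4`` drops trials whose reaction time exceeds the participant's mean
    plus four standard deviations (pooled over the named rt columns).
    """
    if rt_columns is None:
        rt_columns = [c for c in ("rt", "rt_first", "rt_second") if c in trials.columns]
    if not rt_columns:
        raise InvalidArgumentError("no reaction-time columns present")
    rt = trials[list(rt_columns)].to_numpy(float)
    if study_rule == "absolute_150s":
        drop = (rt > 150.0).any(axis=1)
    elif study_rule == "sd4":
        drop = np.zeros(len(trials), dtype=bool)
        for pid, grp in trials.groupby("participant_id"):
            values = grp[list(rt_columns)].to_numpy(float).ravel()
            cutoff = values.mean() + 4.0 * values.std(ddof=1 if len(values) > 1 else 0)
            mask = (grp[list(rt_columns)].to_numpy(float) > cutoff).any(axis=1)
            drop[trials.index.get_indexer(grp.index)] = mask
    else:
        raise InvalidArgumentError(
            f"unknown study_rule {study_rule!r}; use 'absolute_150s' or 'sd4'"
        )
    kept = trials.loc[~drop]
    report = (
        trials.assign(excluded=drop)
        .groupby("participant_id")["excluded"]
        .agg(n_trials="count", n_excluded="sum")
        .reset_index()
    )
    return kept, report


def filter_triplets_by_accuracy(triplets: pd.DataFrame,
                                threshold: float = 0.75,
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop triplets whose across-participant accuracy is at or below threshold."""
    key = ["condition", "target", "similar_choice", "distractor_choice"]
    acc = (triplets.assign(correct=triplets["chosen"] == "similar")
           .groupby(key)["correct"].mean().rename("accuracy").reset_index())
    keep = acc[acc["accuracy"] > threshold]
    kept = triplets.merge(keep[key], on=key, how="inner")
    return kept, acc


# ---------------------------------------------------------------------------
# Confidence rescaling and signal detection
# ---------------------------------------------------------------------------

def rescale_confidence(recognition: pd.DataFrame, mapping: str = "linear"
                       ) -> pd.DataFrame:
    """Rescale raw confidence to 0..50 oriented toward the correct response.

    ``linear`` (default): old items get (50 - raw) / 2, new items
    (50 + raw) / 2 — the unique affine map of the full scale onto 0..50 with
    correct orientation per status.  ``fold`` instead keeps only confidence
    on the correct side of the midpoint: old items max(0, -raw), new items
    max(0, raw).  Either way ``binary_response`` is "old" iff raw < 0.
    """
    raw = recognition["raw_confidence"].to_numpy(float)
    status = recognition["status"].to_numpy()
    known = np.isin(status, ("old", "new_exemplar", "new_concept"))
    if not known.all():
        bad = sorted(set(status[~known]))
        raise InvalidArgumentError(f"unknown status value(s): {bad}")
    is_old = status == "old"
    if mapping == "linear":
        rescaled = np.where(is_old, (50.0 - raw) / 2.0, (50.0 + raw) / 2.0)
    elif mapping == "fold":
        rescaled = np.where(is_old, np.maximum(0.0, -raw), np.maximum(0.0, raw))
    else:
        raise InvalidArgumentError(f"unknown mapping {mapping!r}")
    out = recognition.copy()
    out["rescaled_confidence"] = rescaled
    out["binary_response"] = np.where(raw < 0, "old", "new")
    return out


@dataclass
class ROCResult:
    """Binned ROC sweep over the raw confidence scale and its trapezoidal AUC."""

    thresholds: np.ndarray
    hit_rate: np.ndarray
    fa_rate: np.ndarray
    auc: float


def roc_auc(old_raw: Sequence[float], lure_raw: Sequence[float]) -> ROCResult:
    """ROC from width-5 confidence bins, old items as the positive class.

    Thresholds sweep the bin edges of the -50..50 scale; at threshold t an
    item is called "old" when its raw confidence is <= t (the "sure old" end
    is -50).  The AUC is the trapezoidal area under (false-alarm, hit).
    """
    old = np.asarray(old_raw, float)
    lure = np.asarray(lure_raw, float)
    if old.size == 0 or lure.size == 0:
        raise InsufficientDataError("both old and lure confidence samples required")
    edges = np.arange(-50.0, 50.0 + CONFIDENCE_BIN_WIDTH, CONFIDENCE_BIN_WIDTH)
    thresholds = np.concatenate([[-50.0 - CONFIDENCE_BIN_WIDTH], edges])
    hit = np.array([(old <= t).mean() for t in thresholds])
    fa = np.array([(lure <= t).mean() for t in thresholds])
    auc = float(np.trapezoid(hit, fa))
    return ROCResult(thresholds, hit, fa, auc)


@dataclass
class DPrimeResult:
    """Equal-variance sensitivity d' = z(hit) - z(false alarm)."""

    hit_rate: float
    fa_rate: float
    dprime: float
    n_old: int
    n_lure: int


def dprime_from_rates(hit: float, fa: float) -> float:
    """Equal-variance sensitivity from already-computed hit/false-alarm rates."""
    if not (0.0 < hit < 1.0 and 0.0 < fa < 1.0):
        raise InvalidArgumentError("rates must lie strictly in (0, 1)")
    return float(norm.ppf(hit) - norm.ppf(fa))


def dprime(old_raw: Sequence[float], lure_raw: Sequence[float]) -> DPrimeResult:
    """d' from the binary old/new split at raw confidence 0.

    Extreme hit/false-alarm rates (0 or 1) are replaced by the log-linear
    correction (count + 0.5) / (n + 1) so d' stays finite.
    """
    old = np.asarray(old_raw, float)
    lure = np.asarray(lure_raw, float)
    if old.size == 0 or lure.size == 0:
        raise InsufficientDataError("both classes must be present")

    def rate(hits: int, n: int) -> float:
        if hits in (0, n):
            return (hits + 0.5) / (n + 1)
        return hits / n

    hit = rate(int((old < 0).sum()), old.size)
    fa = rate(int((lure < 0).sum()), lure.size)
    return DPrimeResult(hit, fa, dprime_from_rates(hit, fa),
                        old.size, lure.size)


# ---------------------------------------------------------------------------
# Mixed models and likelihood-ratio machinery
# ---------------------------------------------------------------------------

@dataclass
class MixedFit:
    """A fitted random-intercept linear mixed model (ML estimation)."""

    formula: str
    fixed_effects: tuple[str, ...]
    exog_names: tuple[str, ...]
    loglike: float
    k_fixed: int
    n_obs: int
    n_groups: int
    params: pd.Series
    zvalues: pd.Series
    conf_int: pd.DataFrame
    converged: bool
    result: object = field(repr=False, default=None)

    def z_of(self, term_fragment: str) -> float:
        """z statistic of the first fixed-effect term containing the fragment."""
        for name, z in self.zvalues.items():
            if term_fragment in name and name != "Group Var":
                return float(z)
        raise KeyError(f"no fixed-effect term matching {term_fragment!r}")

    def ci_of(self, term_fragment: str) -> tuple[float, float]:
        for name in self.params.index:
            if term_fragment in name and name != "Group Var":
                lo, hi = self.conf_int.loc[name]
                return float(lo), float(hi)
        raise KeyError(f"no fixed-effect term matching {term_fragment!r}")


@dataclass
class LrtResult:
    """Full-vs-reduced model comparison for one named effect."""

    effect: str
    z: float
    chi2: float
    df: int
    p: float
    n_obs: int
    n_participants: int
    ci_low: float = np.nan
    ci_high: float = np.nan


def fit_mixed(data: pd.DataFrame, outcome: str,
              fixed_effects: Sequence[str],
              groups: str = "participant_id") -> MixedFit:
    """Fit a linear mixed model with participant random intercepts by ML.

    ``fixed_effects`` are patsy terms (e.g. ``["relevant_distance"]`` or
    ``["C(encoding_condition) * C(cued)"]``); an empty sequence fits the
    intercept-only model.  ML (not REML) estimation keeps log-likelihoods
    comparable across fixed-effect structures.
    """
    if data[groups].nunique() < 2:
        raise InsufficientDataError("need at least 2 participants")
    rhs = " + ".join(fixed_effects) if fixed_effects else "1"
    formula = f"{outcome} ~ {rhs}"
    model = smf.mixedlm(formula, data=data, groups=data[groups])
    # Variance parameters on the boundary break or mislead some optimizers
    # (quasi-Newton methods can stop early or return infinite likelihoods);
    # Powell is robust here, with quasi-Newton fallbacks.
    result = None
    last_error: Exception | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        for method in ("powell", "bfgs", "lbfgs"):
            try:
                candidate = model.fit(reml=False, method=method)
            except Exception as exc:  # singular Hessian etc.
                last_error = exc
                continue
            if not np.isfinite(candidate.llf):
                last_error = ValueError("non-finite log-likelihood")
                continue
            result = candidate
            if getattr(candidate, "converged", False):
                break
        if result is None:
            raise InsufficientDataError(
                f"mixed model {formula!r} could not be fit: {last_error}"
            )
        conf_int = result.conf_int()
        zvalues = result.tvalues
    converged = bool(getattr(result, "converged", True))
    k_fixed = int(model.k_fe)
    return MixedFit(
        formula=formula,
        fixed_effects=tuple(fixed_effects),
        exog_names=tuple(model.exog_names),
        loglike=float(result.llf),
        k_fixed=k_fixed,
        n_obs=int(result.nobs),
        n_groups=int(data[groups].nunique()),
        params=result.params,
        zvalues=zvalues,
        conf_int=conf_int,
        converged=converged,
        result=result,
    )


def likelihood_ratio(full: MixedFit, reduced: MixedFit,
                     effect: str | None = None) -> LrtResult:
    """Likelihood-ratio test of nested ML mixed models.

    chi2 = 2 * (LL_full - LL_reduced) floored at zero; df is the fixed-
    parameter-count difference; p is the upper-tail chi-square probability.
    The reported z (and CI) belong to the full model's term for the effect
    of interest.
    """
    if not set(reduced.exog_names) <= set(full.exog_names):
        raise InvalidArgumentError(
            "reduced model's fixed-effect design columns must nest within "
            "the full model's"
        )
    if full.n_obs != reduced.n_obs:
        raise InvalidArgumentError("full and reduced must be fit on the same rows")
    if not (full.converged and reduced.converged):
        raise InvalidArgumentError(
            "cannot compare likelihoods: a model did not converge"
        )
    df = full.k_fixed - reduced.k_fixed
    if df < 0:
        raise InvalidArgumentError("full model must not have fewer fixed parameters")
    chi2 = max(0.0, 2.0 * (full.loglike - reduced.loglike))
    # Identical specifications: no evidence either way.
    p = 1.0 if df == 0 else float(chi2_dist.sf(chi2, df))
    dropped = [t for t in full.fixed_effects if t not in reduced.fixed_effects]
    name = effect or (dropped[0] if dropped else "effect")
    fragment = _term_fragment(name)
    try:
        z = full.z_of(fragment)
        ci_low, ci_high = full.ci_of(fragment)
    except KeyError:
        z, ci_low, ci_high = np.nan, np.nan, np.nan
    return LrtResult(effect=name, z=z, chi2=chi2, df=df, p=p,
                     n_obs=full.n_obs, n_participants=full.n_groups,
                     ci_low=ci_low, ci_high=ci_high)


def _term_fragment(effect: str) -> str:
    """Map a recipe effect name to a fragment of statsmodels' term naming."""
    base = effect.split("|")[0]
    if ":" in base or "*" in base:
        return ":"
    return base.replace("C(", "").replace(")", "").split()[0]


def lrt_for(data: pd.DataFrame, outcome: str, full_terms: Sequence[str],
            reduced_terms: Sequence[str], effect: str) -> tuple[LrtResult, MixedFit, MixedFit]:
    """Convenience: fit full and reduced models and run the LRT."""
    full = fit_mixed(data, outcome, full_terms)
    reduced = fit_mixed(data, outcome, reduced_terms)
    return likelihood_ratio(full, reduced, effect=effect), full, reduced


def residualized(fit: MixedFit, data: pd.DataFrame,
                 groups: str = "participant_id") -> pd.Series:
    """Outcome residuals of a (reduced) model, random intercepts removed.

    Used for plotting an effect of interest after removing everything the
    reduced model explains, participant intercepts included.  If the
    estimated participant variance collapses to zero the random-intercept
    predictions are zero by definition.
    """
    result = fit.result
    fixed = np.asarray(result.model.exog, float) @ np.asarray(result.fe_params, float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            re = result.random_effects
        offsets = np.array([float(re[g].iloc[0]) for g in data[groups]])
    except (ValueError, np.linalg.LinAlgError):
        offsets = 0.0
    resid = np.asarray(result.model.endog, float) - fixed - offsets
    return pd.Series(resid, index=data.index, name="residual")


# ---------------------------------------------------------------------------
# Named analysis recipes
# ---------------------------------------------------------------------------

@dataclass
class RecipeResult:
    """Output of one named contrast: LRT rows plus residuals for plotting."""

    name: str
    results: list[LrtResult]
    table: pd.DataFrame
    residuals: dict[str, pd.Series] = field(default_factory=dict)


def _old_items(recognition: pd.DataFrame) -> pd.DataFrame:
    rec = rescale_confidence(recognition)
    return rec[rec["status"] == "old"].copy()


def _tidy(results: list[LrtResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "effect": r.effect, "z": r.z, "chi2": r.chi2, "df": r.df, "p": r.p,
        "ci_low": r.ci_low, "ci_high": r.ci_high,
        "n_obs": r.n_obs, "n_participants": r.n_participants,
    } for r in results])


def _recipe_encoding_task_main(tables: Mapping[str, pd.DataFrame]) -> RecipeResult:
    """Does the encoding task (perceptual vs conceptual) shift memory strength?"""
    data = _old_items(tables["recognition"])
    if "cued" in data.columns and data["cued"].any() and not data["cued"].all():
        data = data[~data["cued"].astype(bool)]
    lrt, full, reduced = lrt_for(data, "rescaled_confidence",
                                 ["C(encoding_condition)"], [],
                                 effect="encoding_condition")
    return RecipeResult("encoding_task_main", [lrt], _tidy([lrt]),
                        {"encoding_condition": residualized(reduced, data)})


def _distance_recipe(tables: Mapping[str, pd.DataFrame], column: str,
                     name: str) -> RecipeResult:
    data = _old_items(tables["recognition"]).dropna(subset=[column])
    lrt, full, reduced = lrt_for(data, "rescaled_confidence", [column], [],
                                 effect=column)
    return RecipeResult(name, [lrt], _tidy([lrt]),
                        {column: residualized(reduced, data)})


def _recipe_relevant_distance(tables) -> RecipeResult:
    """Higher trial-rated 2D distance at encoding predicts memory strength."""
    return _distance_recipe(tables, "relevant_distance", "relevant_distance")


def _recipe_irrelevant_distance(tables) -> RecipeResult:
    """Average distance in never-rated spaces should not predict memory."""
    return _distance_recipe(tables, "irrelevant_distance", "irrelevant_distance")


def _recipe_first_vs_second_image(tables) -> RecipeResult:
    """Distance effect estimated separately for first- and second-shown images."""
    data = _old_items(tables["recognition"]).dropna(subset=["relevant_distance"])
    positions = tables["image_positions"]  # image_id -> "first" / "second"
    data = data.merge(positions, on="image_id", how="inner")
    results = []
    residuals = {}
    for position in ("first", "second"):
        subset = data[data["position"] == position]
        lrt, _, reduced = lrt_for(subset, "rescaled_confidence",
                                  ["relevant_distance"], [],
                                  effect=f"relevant_distance_{position}")
        results.append(lrt)
        residuals[position] = residualized(reduced, subset)
    return RecipeResult("first_vs_second_image", results, _tidy(results), residuals)


def _recipe_rt_by_distance(tables) -> RecipeResult:
    """Faster rating responses for higher rated distances during encoding."""
    from .space_reconstruction import trial_relevant_distance

    enc = tables["encoding"].copy()
    enc["relevant_distance"] = trial_relevant_distance(
        enc["rating_a"].to_numpy(), enc["rating_b"].to_numpy())
    enc["log_rt"] = np.log(enc["rt_second"])
    lrt, _, reduced = lrt_for(enc, "log_rt", ["relevant_distance"], [],
                              effect="relevant_distance")
    return RecipeResult("rt_by_distance", [lrt], _tidy([lrt]),
                        {"relevant_distance": residualized(reduced, enc)})


def _interaction_with_splits(data: pd.DataFrame, outcome: str,
                             factor_a: str, factor_b: str, split_by: str,
                             name: str) -> RecipeResult:
    """Full interaction LRT plus post-hoc per-level splits of ``split_by``.

    The full model contains both main effects and their interaction; the
    reduced model drops the interaction term.  Post-hoc models are run on
    data split by ``split_by``, comparing the remaining main effect against
    an intercept-only model.
    """
    full_terms = [f"C({factor_a}) * C({factor_b})"]
    reduced_terms = [f"C({factor_a}) + C({factor_b})"]
    lrt, full, reduced = lrt_for(data, outcome, full_terms, reduced_terms,
                                 effect=f"{factor_a}:{factor_b}")
    results = [lrt]
    residuals = {"interaction": residualized(reduced, data)}
    other = factor_a if split_by == factor_b else factor_b
    for level in sorted(data[split_by].unique()):
        subset = data[data[split_by] == level]
        sub_lrt, _, sub_reduced = lrt_for(subset, outcome, [f"C({other})"], [],
                                          effect=f"{other}|{split_by}={level}")
        results.append(sub_lrt)
        residuals[f"{split_by}={level}"] = residualized(sub_reduced, subset)
    return RecipeResult(name, results, _tidy(results), residuals)


def _recipe_retrieval_by_encoding(tables) -> RecipeResult:
    """Retrieval demand (general/specific) by encoding task interaction, old items."""
    data = _old_items(tables["recognition"])
    data = data[data["retrieval_task"].isin(["general", "specific"])]
    return _interaction_with_splits(data, "rescaled_confidence",
                                    "retrieval_task", "encoding_condition",
                                    split_by="retrieval_task",
                                    name="retrieval_by_encoding")


def _recipe_retrieval_by_encoding_lures(tables) -> RecipeResult:
    """Same interaction for new-exemplar lures (generalization vs separation)."""
    rec = rescale_confidence(tables["recognition"])
    data = rec[(rec["status"] == "new_exemplar")
               & rec["retrieval_task"].isin(["general", "specific"])].copy()
    return _interaction_with_splits(data, "rescaled_confidence",
                                    "retrieval_task", "encoding_condition",
                                    split_by="retrieval_task",
                                    name="retrieval_by_encoding_lures")


def _recipe_tmr_cueing_old(tables) -> RecipeResult:
    """Cueing-by-encoding-task interaction on old-item memory strength."""
    data = _old_items(tables["recognition"])
    data["cued"] = data["cued"].astype(bool)
    return _interaction_with_splits(data, "rescaled_confidence",
                                    "encoding_condition", "cued",
                                    split_by="encoding_condition",
                                    name="tmr_cueing_old")


def _recipe_tmr_cueing_lures(tables) -> RecipeResult:
    """Cueing-by-encoding-task interaction on new-exemplar correct rejection."""
    rec = rescale_confidence(tables["recognition"])
    data = rec[rec["status"] == "new_exemplar"].copy()
    data["cued"] = data["cued"].astype(bool)
    return _interaction_with_splits(data, "rescaled_confidence",
                                    "encoding_condition", "cued",
                                    split_by="encoding_condition",
                                    name="tmr_cueing_lures")


def _recipe_lure_semantic_similarity(tables) -> RecipeResult:
    """Semantic similarity of new concepts to encoded concepts, by cued condition."""
    rec = rescale_confidence(tables["recognition"])
    data = rec[rec["status"] == "new_concept"].dropna(
        subset=["semantic_similarity"]).copy()
    cued_cond = tables["cued_condition"]  # participant_id -> cued condition
    data = data.merge(cued_cond, on="participant_id", how="inner")
    results = []
    residuals = {}
    for level in sorted(data["cued_condition"].unique()):
        subset = data[data["cued_condition"] == level]
        lrt, _, reduced = lrt_for(subset, "rescaled_confidence",
                                  ["semantic_similarity"], [],
                                  effect=f"semantic_similarity|cued={level}")
        results.append(lrt)
        residuals[f"cued={level}"] = residualized(reduced, subset)
    return RecipeResult("lure_semantic_similarity", results, _tidy(results),
                        residuals)


def _recipe_triplet_distinctiveness(tables) -> RecipeResult:
    """Triplet distinctiveness (d = r_sim - r_dist) per layer class vs memory."""
    data = _old_items(tables["recognition"])
    d_cols = [c for c in data.columns if c.startswith("d_")]
    if not d_cols:
        raise InvalidArgumentError(
            "recognition table needs d_<class> triplet-distinctiveness columns"
        )
    results = []
    residuals = {}
    for condition in sorted(data["encoding_condition"].unique()):
        subset = data[data["encoding_condition"] == condition]
        for col in d_cols:
            sub = subset.dropna(subset=[col])
            if sub["participant_id"].nunique() < 2:
                continue
            lrt, _, reduced = lrt_for(sub, "rescaled_confidence", [col], [],
                                      effect=f"{col}|{condition}")
            results.append(lrt)
            residuals[f"{col}|{condition}"] = residualized(reduced, sub)
    return RecipeResult("triplet_distinctiveness", results, _tidy(results),
                        residuals)


RECIPES = {
    "encoding_task_main": _recipe_encoding_task_main,
    "relevant_distance": _recipe_relevant_distance,
    "irrelevant_distance": _recipe_irrelevant_distance,
    "first_vs_second_image": _recipe_first_vs_second_image,
    "rt_by_distance": _recipe_rt_by_distance,
    "retrieval_by_encoding": _recipe_retrieval_by_encoding,
    "retrieval_by_encoding_lures": _recipe_retrieval_by_encoding_lures,
    "tmr_cueing_old": _recipe_tmr_cueing_old,
    "tmr_cueing_lures": _recipe_tmr_cueing_lures,
    "lure_semantic_similarity": _recipe_lure_semantic_similarity,
    "triplet_distinctiveness": _recipe_triplet_distinctiveness,
}


def run_recipe(name: str, tables: Mapping[str, pd.DataFrame]) -> RecipeResult:
    """Run one named results contrast on the supplied tidy tables.

    ``tables`` holds at least a ``recognition`` table (raw recognition
    trials, optionally already carrying distance or distinctiveness
    columns); some recipes additionally need ``encoding``,
    ``image_positions`` or ``cued_condition`` tables.
    """
    try:
        recipe = RECIPES[name]
    except KeyError:
        raise UnknownRecipeError(
            f"unknown recipe {name!r}; available: {sorted(RECIPES)}"
        ) from None
    return recipe(tables)
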