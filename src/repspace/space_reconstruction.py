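"""Metric space reconstruction from pairwise similarity ratings.

Each rating compares two images on one dimension; stacking ratings gives a
sparse linear system ``M @ x = r`` where row t of M holds +1 in the column
of the first image and -1 in that of the second, and r_t is the signed
rating.  The minimum-norm least-squares solution assigns every image a 1D
coordinate per dimension; two solutions combine into a 2D space whose
pairwise Euclidean distances feed the memory analyses.

The solution is identified only up to an additive constant per connected
component of the pairing graph (every row of M sums to zero).  The
minimum-norm solution is orthogonal to the component indicator vectors and
therefore already mean-centered per component; we re-center explicitly to
make the convention independent of solver tolerance.

Validation ranks the empirical least-squares residual within a null
distribution obtained by shuffling the response vector while keeping M
fixed.  Because M never changes, the residual of every shuffled refit is
computed exactly by projection onto an orthonormal basis of range(M)
(``||r||^2 - ||U^T r||^2``), which is algebraically identical to re-solving
each surrogate system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from scipy.stats import levene, spearmanr, ttest_rel

from .dimensions import RATING_MAX, other_space_pairs
from .errors import (
    EmptyDesignError,
    InsufficientDataError,
    InvalidArgumentError,
    MissingImageError,
    UndefinedCorrelationError,
)


@dataclass
class DesignSystem:
    """Sparse ratings-by-images system for one dimension.

    ``provenance`` records which participants' ratings entered the system and
    which participant (if any) was deliberately excluded, so that
    task-irrelevant distances can assert they never used the probe
    participant's own ratings.
    """

    M: sp.csc_matrix
    response: np.ndarray
    dimension_name: str
    image_index: list[str]
    provenance: frozenset[str] = field(default_factory=frozenset)
    excluded_participant: str | None = None

    def validate(self) -> None:
        if self.M.shape[0] != len(self.response):
            raise InvalidArgumentError("response length must equal the row count of M")
        if self.M.shape[1] != len(self.image_index):
            raise InvalidArgumentError("column count of M must equal len(image_index)")
        if np.abs(self.response).max(initial=0.0) > RATING_MAX:
            raise InvalidArgumentError("|response| must be <= 50")
        dense_ok = (self.M.getnnz(axis=1) == 2).all() and not self.M.sum(axis=1).any()
        if not dense_ok:
            raise InvalidArgumentError("every row of M needs exactly one +1 and one -1")


@dataclass
class DimensionSolution:
    """Per-image 1D coordinates with the fit residual and component structure."""

    coords: pd.Series
    residual_norm: float
    n_components: int
    component_labels: np.ndarray
    dimension_name: str


@dataclass
class Space2D:
    """Two combined 1D solutions and the implied pairwise Euclidean distances."""

    dim_a: str
    dim_b: str
    coords2d: pd.DataFrame
    distance: pd.DataFrame
    provenance: frozenset[str] = field(default_factory=frozenset)
    excluded_participant: str | None = None

    def pair_distance(self, image_i: str, image_j: str) -> float:
        try:
            return float(self.distance.at[image_i, image_j])
        except KeyError as exc:
            raise MissingImageError(
                f"image {exc.args[0]!r} absent from space ({self.dim_a}, {self.dim_b})"
            ) from exc


@dataclass
class PermutationResult:
    """Empirical least-squares error ranked within a shuffle null."""

    empirical_error: float
    null_errors: np.ndarray
    p_value: float
    n_perm: int
    seed: int
    dimension_name: str


def build_design_matrix(
    trials: pd.DataFrame,
    dimension: str,
    image_index: Sequence[str] | None = None,
    exclude_participant: str | None = None,
) -> DesignSystem:
    """Assemble the sparse +1/-1 design system for one rated dimension.

    One row per rating of ``dimension``: +1 in the first image's column, -1
    in the second's, response = the signed rating.  ``image_index`` fixes the
    column order (default: sorted union of images appearing in the
    qualifying trials).  ``exclude_participant`` drops that participant's
    ratings and records the exclusion for provenance checks downstream.
    """
    t = trials
    if exclude_participant is not None:
        t = t[t["participant_id"] != exclude_participant]
    on_a = t[t["dim_a"] == dimension]
    on_b = t[t["dim_b"] == dimension]
    firsts = pd.concat([on_a["image_first"], on_b["image_first"]])
    seconds = pd.concat([on_a["image_second"], on_b["image_second"]])
    ratings = pd.concat([on_a["rating_a"], on_b["rating_b"]]).to_numpy(float)
    if len(ratings) == 0:
        raise EmptyDesignError(f"no trial rates dimension {dimension!r}")
    if image_index is None:
        image_index = sorted(set(firsts) | set(seconds))
    image_index = list(image_index)
    col = {img: j for j, img in enumerate(image_index)}
    try:
        first_cols = np.array([col[i] for i in firsts])
        second_cols = np.array([col[i] for i in seconds])
    except KeyError as exc:
        raise MissingImageError(f"image {exc.args[0]!r} not in image_index") from exc
    n = len(ratings)
    rows = np.repeat(np.arange(n), 2)
    cols = np.column_stack([first_cols, second_cols]).ravel()
    data = np.tile([1.0, -1.0], n)
    M = sp.csc_matrix((data, (rows, cols)), shape=(n, len(image_index)))
    participants = frozenset(pd.concat([on_a, on_b])["participant_id"])
    return DesignSystem(
        M=M, response=ratings, dimension_name=dimension, image_index=image_index,
        provenance=participants, excluded_participant=exclude_participant,
    )


def _component_labels(system: DesignSystem) -> tuple[int, np.ndarray]:
    """Connected components of the pairing graph implied by M's sparsity."""
    pattern = abs(system.M)
    adjacency = pattern.T @ pattern
    return connected_components(adjacency, directed=False)


def solve_dimension(system: DesignSystem, atol: float = 1e-12) -> DimensionSolution:
    """Minimum-norm least squares for one dimension, centered per component."""
    if system.M.nnz == 0:
        raise EmptyDesignError("design matrix is all zero")
    x = sp.linalg.lsqr(system.M, system.response, atol=atol, btol=atol,
                       iter_lim=10 * system.M.shape[1])[0]
    n_comp, labels = _component_labels(system)
    for c in range(n_comp):
        mask = labels == c
        x[mask] -= x[mask].mean()
    residual = float(np.linalg.norm(system.M @ x - system.response))
    coords = pd.Series(x, index=pd.Index(system.image_index, name="image_id"),
                       name=system.dimension_name)
    return DimensionSolution(coords=coords, residual_norm=residual,
                             n_components=n_comp, component_labels=labels,
                             dimension_name=system.dimension_name)


def make_space(sol_a: DimensionSolution, sol_b: DimensionSolution,
               provenance: frozenset[str] = frozenset(),
               excluded_participant: str | None = None) -> Space2D:
    """Combine two 1D solutions into a 2D space with its distance matrix."""
    if list(sol_a.coords.index) != list(sol_b.coords.index):
        raise InvalidArgumentError(
            "the two solutions must share an identical image index"
        )
    coords2d = pd.DataFrame({sol_a.dimension_name: sol_a.coords,
                             sol_b.dimension_name: sol_b.coords})
    dist = squareform(pdist(coords2d.to_numpy()))
    distance = pd.DataFrame(dist, index=coords2d.index, columns=coords2d.index)
    return Space2D(sol_a.dimension_name, sol_b.dimension_name, coords2d, distance,
                   provenance=provenance, excluded_participant=excluded_participant)


def trial_relevant_distance(rating_a, rating_b):
    """Task-relevant distance of a trial: Euclidean length of its two ratings.

    The first image is the origin and the second sits at
    (rating_a, rating_b), so the distance is ``hypot(rating_a, rating_b)``;
    it is symmetric in the sign of either rating.
    """
    ra, rb = np.asarray(rating_a, float), np.asarray(rating_b, float)
    if (np.abs(ra) > RATING_MAX).any() or (np.abs(rb) > RATING_MAX).any():
        raise InvalidArgumentError("ratings must lie in [-50, 50]")
    return np.hypot(ra, rb)


def irrelevant_distance(pair: tuple[str, str], spaces: Sequence[Space2D]) -> float:
    """Mean distance of an image pair across the supplied task-irrelevant spaces."""
    if not spaces:
        raise InvalidArgumentError("need at least one other space")
    return float(np.mean([s.pair_distance(*pair) for s in spaces]))


def permutation_validate(system: DesignSystem, n_perm: int = 10_000,
                         seed: int = 0) -> PermutationResult:
    """Rank the empirical least-squares error within a response-shuffle null.

    Each surrogate permutes the response vector uniformly at random (without
    replacement) with M fixed and records the residual norm of the refit
    least-squares solution; the p-value uses the +1 correction
    ``p = (1 + #{null <= empirical}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise InvalidArgumentError(f"n_perm must be >= 1, got {n_perm}")
    if system.M.nnz == 0:
        raise EmptyDesignError("design matrix is all zero")
    rng = np.random.default_rng(seed)
    dense = np.asarray(system.M.todense())
    u, s, _ = np.linalg.svd(dense, full_matrices=False)
    basis = u[:, s > s.max() * max(dense.shape) * np.finfo(float).eps]
    r = system.response
    total_sq = float(r @ r)

    def residual_of(vec: np.ndarray) -> float:
        proj = basis.T @ vec
        return float(np.sqrt(max(total_sq - proj @ proj, 0.0)))

    empirical = residual_of(r)
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = residual_of(rng.permutation(r))
    p = (1.0 + np.count_nonzero(null <= empirical)) / (1.0 + n_perm)
    return PermutationResult(empirical, null, p, n_perm, seed, system.dimension_name)


def global_space(trials: pd.DataFrame, dim_pair: tuple[str, str],
                 image_index: Sequence[str] | None = None,
                 exclude_participant: str | None = None) -> Space2D:
    """Build the pooled 2D space for a dimension pair across all participants."""
    dim_a, dim_b = dim_pair
    sys_a = build_design_matrix(trials, dim_a, image_index, exclude_participant)
    sys_b = build_design_matrix(trials, dim_b, sys_a.image_index
                                if image_index is None else image_index,
                                exclude_participant)
    if sys_a.image_index != sys_b.image_index:
        # Align both dimensions on the union so the solutions are combinable.
        union = sorted(set(sys_a.image_index) | set(sys_b.image_index))
        sys_a = build_design_matrix(trials, dim_a, union, exclude_participant)
        sys_b = build_design_matrix(trials, dim_b, union, exclude_participant)
    sol_a, sol_b = solve_dimension(sys_a), solve_dimension(sys_b)
    return make_space(sol_a, sol_b,
                      provenance=sys_a.provenance | sys_b.provenance,
                      excluded_participant=exclude_participant)


def individual_global_similarity(individual: Space2D, global_: Space2D) -> float:
    """Spearman rho between two spaces' upper-triangle distance vectors."""
    if list(individual.distance.index) != list(global_.distance.index):
        common = sorted(set(individual.distance.index) & set(global_.distance.index))
        if len(common) < 3:
            raise InvalidArgumentError("spaces share fewer than 3 images")
        a = individual.distance.loc[common, common].to_numpy()
        b = global_.distance.loc[common, common].to_numpy()
    else:
        a = individual.distance.to_numpy()
        b = global_.distance.to_numpy()
    iu = np.triu_indices(a.shape[0], k=1)
    va, vb = a[iu], b[iu]
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise UndefinedCorrelationError("constant distance vector; rho undefined")
    return float(spearmanr(va, vb).statistic)


def idiosyncrasy_compare(
    rhos_perceptual: Sequence[float],
    rhos_conceptual: Sequence[float],
    per_space_rhos: dict[str, Sequence[float]] | None = None,
) -> dict:
    """Compare individual-to-global fits between conditions.

    Paired t-test of conceptual vs. perceptual per-participant rhos, plus a
    Levene test of equal variances across the per-space rho sets (the six
    2D spaces when supplied, otherwise the two condition sets).
    """
    rp, rc = np.asarray(rhos_perceptual, float), np.asarray(rhos_conceptual, float)
    if len(rp) != len(rc) or len(rp) < 2:
        raise InsufficientDataError("need paired per-participant rho vectors, n >= 2")
    if np.allclose(rc, rp):
        t = type("T", (), {"statistic": 0.0, "pvalue": 1.0})
    else:
        t = ttest_rel(rc, rp)
    groups = (list(per_space_rhos.values()) if per_space_rhos
              else [rp, rc])
    lev = levene(*[np.asarray(g, float) for g in groups])
    return {
        "t": float(t.statistic),
        "p": float(t.pvalue),
        "levene_stat": float(lev.statistic),
        "levene_p": float(lev.pvalue),
        "n": len(rp),
    }


# ---------------------------------------------------------------------------
# Trial-level relevant / irrelevant distance table
# ---------------------------------------------------------------------------

def leave_one_out_spaces(trials: pd.DataFrame, participant: str,
                         image_index: Sequence[str] | None = None,
                         ) -> dict[tuple[str, str], Space2D]:
    """All six canonical 2D spaces built while excluding one participant."""
    from .dimensions import ALL_SPACE_PAIRS

    return {pair: global_space(trials, pair, image_index,
                               exclude_participant=participant)
            for pair in ALL_SPACE_PAIRS}


def compute_trial_distances(trials: pd.DataFrame,
                            image_index: Sequence[str] | None = None,
                            ) -> pd.DataFrame:
    """Per encoding trial, the task-relevant and task-irrelevant distances.

    The relevant distance is the trial's own rated 2D distance.  The
    irrelevant distance of a trial's image pair averages the pair's Euclidean
    distance over the five canonical 2D spaces the participant did not rate
    the pair on, each reconstructed from all other participants' ratings
    (never the probe participant's own).
    """
    from .dimensions import ALL_DIMENSIONS, ALL_SPACE_PAIRS

    out = trials.reset_index(drop=True).copy()
    out["relevant_distance"] = trial_relevant_distance(
        out["rating_a"].to_numpy(), out["rating_b"].to_numpy())
    irrelevant = np.full(len(out), np.nan)
    if image_index is None:
        image_index = sorted(set(out["image_first"]) | set(out["image_second"]))
    col = {img: j for j, img in enumerate(image_index)}
    first_idx = out["image_first"].map(col).to_numpy()
    second_idx = out["image_second"].map(col).to_numpy()
    participants = sorted(out["participant_id"].unique())

    # Build each dimension's pooled design once; excluding a participant is a
    # row subset, which avoids rebuilding 6 systems per participant.
    loo_coords: dict[str, dict[str, np.ndarray]] = {}
    for dim in ALL_DIMENSIONS:
        system = build_design_matrix(out, dim, image_index)
        on_a = out[out["dim_a"] == dim]
        on_b = out[out["dim_b"] == dim]
        row_pid = pd.concat([on_a["participant_id"],
                             on_b["participant_id"]]).to_numpy()
        M = system.M.tocsr()
        loo_coords[dim] = {}
        for pid in participants:
            keep = row_pid != pid
            assert keep.any(), f"no ratings of {dim} outside participant {pid}"
            sub = DesignSystem(M[keep].tocsc(), system.response[keep], dim,
                               list(image_index),
                               provenance=system.provenance - {pid},
                               excluded_participant=pid)
            loo_coords[dim][pid] = solve_dimension(sub).coords.to_numpy()

    for pid, grp in out.groupby("participant_id", sort=True):
        matrices = {}
        for pair in ALL_SPACE_PAIRS:
            xy = np.column_stack([loo_coords[pair[0]][pid],
                                  loo_coords[pair[1]][pid]])
            matrices[pair] = squareform(pdist(xy))
        for (dim_a, dim_b), sub in grp.groupby(["dim_a", "dim_b"]):
            rows = sub.index.to_numpy()
            fi, si = first_idx[rows], second_idx[rows]
            others = other_space_pairs(dim_a, dim_b)
            acc = np.zeros(len(rows))
            for pair in others:
                acc += matrices[pair][fi, si]
            irrelevant[rows] = acc / len(others)
    out["irrelevant_distance"] = irrelevant
    return out
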