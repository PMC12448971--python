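"""The six rating dimensions and their grouping into encoding conditions.

Participants judge animal-image pairs on three perceptual dimensions
(viewing orientation, color temperature, degree of camouflage) and three
conceptual dimensions (real-world size, climate of the habitat,
approachability).  Encoding blocks pair two dimensions from the same
condition, so each condition contributes three canonical 2D spaces; the six
2D spaces together are the universe from which task-irrelevant distances
are drawn.
"""

from __future__ import annotations

from itertools import combinations

PERCEPTUAL_DIMENSIONS: tuple[str, ...] = ("orientation", "color", "camouflage")
CONCEPTUAL_DIMENSIONS: tuple[str, ...] = ("size", "climate", "approach")
ALL_DIMENSIONS: tuple[str, ...] = PERCEPTUAL_DIMENSIONS + CONCEPTUAL_DIMENSIONS

DIMENSION_SETS: dict[str, tuple[str, ...]] = {
    "perceptual": PERCEPTUAL_DIMENSIONS,
    "conceptual": CONCEPTUAL_DIMENSIONS,
}

#: The three within-condition dimension pairings used as encoding block types
#: and, combined, as the six canonical 2D spaces.
DIMENSION_PAIRS: dict[str, tuple[tuple[str, str], ...]] = {
    condition: tuple(combinations(dims, 2))
    for condition, dims in DIMENSION_SETS.items()
}

#: All six canonical 2D spaces as (dim_a, dim_b) tuples.
ALL_SPACE_PAIRS: tuple[tuple[str, str], ...] = (
    DIMENSION_PAIRS["perceptual"] + DIMENSION_PAIRS["conceptual"]
)

RATING_MIN = -50.0
RATING_MAX = 50.0


def condition_of(dimension: str) -> str:
    """Return the condition ('perceptual' or 'conceptual') owning a dimension."""
    for condition, dims in DIMENSION_SETS.items():
        if dimension in dims:
            return condition
    raise KeyError(f"unknown dimension {dimension!r}; expected one of {ALL_DIMENSIONS}")


def other_space_pairs(dim_a: str, dim_b: str) -> tuple[tuple[str, str], ...]:
    """The canonical 2D spaces excluding the one spanned by (dim_a, dim_b).

    For a pair rated on e.g. (climate, size) this returns the five spaces
    (climate, approach), (size, approach), (orientation, color),
    (orientation, camouflage), (color, camouflage) whose average pairwise
    distance defines the task-irrelevant distance.
    """
    rated = frozenset((dim_a, dim_b))
    return tuple(p for p in ALL_SPACE_PAIRS if frozenset(p) != rated)
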