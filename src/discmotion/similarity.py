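"""Frame-to-frame similarity matrices and the quadrant contrast test.

Two frames are compared by evaluating the non-centered normalized
cross-correlation of co-located lattice subsets (no displacement search) and
aggregating the per-subset scores into one scalar — by default their mean.
All pairwise scores over a participant's happy and sad frames form a
symmetric matrix with unit diagonal whose quadrants (happy-happy, sad-sad,
happy-sad) summarize whether facial responses within an emotion resemble each
other more than responses across emotions.  The within- vs cross-emotion
contrast is tested with a two-sample two-tailed t-test (Welch by default),
counting each unordered frame pair once and excluding the diagonal.

The matrix entries share frames (entry (i,j) and (i,k) both involve frame i),
a dependence the t-test ignores; for the bilinear noise structure of
speckle-frame similarities this correlation is negligible, but the p-values
are descriptive, as discussed in the package documentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .core import (
    DisplacementField,
    GrayFrame,
    GridSpec,
    UndefinedSimilarityError,
    lattice_axes,
    patch_similarity,
)


class DegenerateVarianceError(ValueError):
    """Both quadrant groups are constant with different means."""


Aggregation = Literal["mean", "median", "max"]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric frame-by-frame similarity values with emotion labels."""

    values: np.ndarray  # (n, n) in [0, 1]
    labels: tuple[str, ...]
    participant_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if len(self.labels) != v.shape[0]:
            raise ValueError("one label per frame is required")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class QuadrantTestResult:
    statistic: float
    pvalue: float
    within_mean: float
    cross_mean: float
    n_within: int
    n_cross: int


def _patch_stack(pixels: np.ndarray, grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Flattened lattice subsets of one frame and their squared sums."""
    from numpy.lib.stride_tricks import sliding_window_view

    xs, ys = lattice_axes(pixels.shape, grid)
    ss = grid.subset_size
    view = sliding_window_view(pixels, (ss, ss))
    patches = view[xs[:, None] - grid.half, ys[None, :] - grid.half]
    flat = patches.reshape(-1, ss * ss).astype(np.float32)
    sq = np.einsum("pd,pd->p", flat, flat)
    if np.any(sq == 0.0):
        raise UndefinedSimilarityError("a lattice subset is all zero")
    return flat, sq


def _pair_scores(
    a: np.ndarray, sa: np.ndarray, b: np.ndarray, sb: np.ndarray
) -> np.ndarray:
    """Per-lattice-point similarity between two patch stacks.

    Returns exactly 1 where Cauchy-Schwarz equality is attained in floats
    (identical subsets or power-of-two scalings), matching
    :func:`discmotion.core.patch_similarity`.
    """
    num = np.einsum("pd,pd->p", a, b)
    t = num * num
    d = sa * sb
    with np.errstate(invalid="ignore"):
        s = np.sqrt(np.minimum(t / d, 1.0))
    return np.where(t >= d, 1.0, s)


def _aggregate(scores: np.ndarray, agg: Aggregation) -> float:
    if agg == "mean":
        return float(scores.mean(dtype=np.float64))
    if agg == "median":
        return float(np.median(scores))
    if agg == "max":
        return float(scores.max())
    raise ValueError(f"unknown aggregation {agg!r}")


def frame_similarity(
    frame_a: GrayFrame,
    frame_b: GrayFrame,
    grid: GridSpec,
    agg: Aggregation = "mean",
) -> float:
    """Frame-level similarity: aggregated co-located subset scores in [0, 1]."""
    if frame_a.pixels.shape != frame_b.pixels.shape:
        raise ValueError("frames must have the same shape")
    a, sa = _patch_stack(frame_a.pixels, grid)
    b, sb = _patch_stack(frame_b.pixels, grid)
    return _aggregate(_pair_scores(a, sa, b, sb), agg)


def build_matrix(
    frames: Sequence[GrayFrame],
    grid: GridSpec,
    agg: Aggregation = "mean",
    participant_id: str = "",
) -> SimilarityMatrix:
    """All pairwise frame similarities of one participant's labeled frames.

    Frames should be ordered happy block first, then sad block, so the matrix
    quadrants are contiguous.  The diagonal is identically 1 (a frame is
    fully similar to itself) and the matrix is symmetric bit-exactly.
    """
    if len(frames) < 2:
        raise ValueError("at least two frames are required")
    shape = frames[0].pixels.shape
    for f in frames:
        if f.pixels.shape != shape:
            raise ValueError("frames must have the same shape")
    stacks = []
    sums = []
    for f in frames:
        a, sa = _patch_stack(f.pixels, grid)
        stacks.append(a)
        sums.append(sa)
    n = len(frames)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = _aggregate(_pair_scores(stacks[i], sums[i], stacks[j], sums[j]), agg)
            values[i, j] = s
            values[j, i] = s
    return SimilarityMatrix(
        values=values,
        labels=tuple(f.label for f in frames),
        participant_id=participant_id or frames[0].participant_id,
    )


def field_cosine_similarity(fa: DisplacementField, fb: DisplacementField) -> float:
    """Cosine similarity of two flattened displacement fields (variant metric).

    Alternative frame comparison operating on DISC output rather than raw
    intensities; ranges over [-1, 1] and is undefined (raises) for zero
    fields.
    """
    if not fa.same_lattice(fb):
        raise ValueError("fields do not share a lattice")
    a = np.concatenate([fa.u[fa.valid], fa.v[fa.valid]])
    b = np.concatenate([fb.u[fb.valid], fb.v[fb.valid]])
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise UndefinedSimilarityError("cosine similarity undefined for a zero field")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def quadrant_entries(
    matrix: SimilarityMatrix,
    labels: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(within, cross) similarity pools: each unordered pair counted once.

    ``within`` pools the off-diagonal upper-triangle entries of the
    happy-happy and sad-sad quadrants; ``cross`` is the happy-sad block.
    ``labels`` overrides the matrix's stored labels (used for permutation
    checks).
    """
    lab = np.asarray(labels if labels is not None else matrix.labels)
    happy = np.where(lab == "happy")[0]
    sad = np.where(lab == "sad")[0]
    if len(happy) < 2 or len(sad) < 2:
        raise ValueError("both emotion groups need at least two frames")
    v = matrix.values
    within = np.concatenate(
        [v[np.ix_(g, g)][np.triu_indices(len(g), k=1)] for g in (happy, sad)]
    )
    cross = v[np.ix_(happy, sad)].ravel()
    return within, cross


def quadrant_test(
    matrix: SimilarityMatrix,
    labels: Sequence[str] | None = None,
    equal_var: bool = False,
) -> QuadrantTestResult:
    """Two-tailed t-test of within- vs cross-emotion quadrant similarities.

    Welch's unequal-variance test by default (the pools differ in size and
    spread); pass ``equal_var=True`` for the pooled-variance flavor.  If both
    pools are constant, equal means yield the defined null result (t=0, p=1);
    unequal constant means raise :class:`DegenerateVarianceError`.
    """
    within, cross = quadrant_entries(matrix, labels)
    if np.ptp(within) == 0.0 and np.ptp(cross) == 0.0:
        if within[0] == cross[0]:
            return QuadrantTestResult(0.0, 1.0, float(within[0]), float(cross[0]),
                                      len(within), len(cross))
        raise DegenerateVarianceError(
            "both quadrant pools are constant with different means"
        )
    t, p = stats.ttest_ind(within, cross, equal_var=equal_var)
    return QuadrantTestResult(
        statistic=float(t),
        pvalue=float(p),
        within_mean=float(within.mean()),
        cross_mean=float(cross.mean()),
        n_within=len(within),
        n_cross=len(cross),
    )
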