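"""DISC kernel: neighborhood cross-correlation matching and displacement fields.

Digital image speckle correlation (DISC) estimates how points on a textured
surface move between two frames.  A square neighborhood (the *subset*) around
each grid point of the reference frame is compared against candidate
neighborhoods in the target frame using a non-centered normalized
cross-correlation score

    S = sum(Ia * Ib) / sqrt(sum(Ia^2) * sum(Ib^2))

which lies in [0, 1] for non-negative intensities (Cauchy-Schwarz) and equals
1 exactly when the two subsets are positive scalar multiples of each other.
The displacement that maximizes S over an integer search window, optionally
refined to sub-pixel precision by quadratic interpolation of the similarity
surface, is the estimated motion of that grid point.

Coordinate convention
---------------------
A pixel coordinate ``(x, y)`` is ``(row, col)`` with the origin at the top
left.  The displacement component ``u`` pairs with ``x`` (vertical, positive
down) and ``v`` with ``y`` (horizontal, positive right).  Most image
libraries transpose this; all public APIs in this package use (row, col).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import fft as _fft

logger = logging.getLogger(__name__)

LABELS = ("neutral", "happy", "sad")


class DiscError(Exception):
    """Base class for DISC computation errors."""


class UndefinedSimilarityError(DiscError):
    """Similarity is 0/0 because a subset contains only zero intensities."""


class LatticeError(DiscError):
    """No valid lattice point exists for the requested grid and frame size."""


class InvalidPointError(DiscError):
    """The subset or search window around a point exits the image bounds."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrayFrame:
    """A single grayscale frame with acquisition metadata.

    ``pixels`` holds intensities in [0, 255] (0 = black, 255 = white) as a
    2-D float array; ``frame_index`` is the time index in seconds when frames
    are sampled at 1 fps.
    """

    pixels: np.ndarray
    frame_index: int = 0
    label: str = "neutral"
    participant_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim == 3:
            px = to_grayscale(px)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel intensities must be finite")
        if px.size and (px.min() < 0.0 or px.max() > 255.0):
            raise ValueError("pixel intensities must lie in [0, 255]")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def with_label(self, label: str, frame_index: int | None = None) -> "GrayFrame":
        return replace(
            self,
            label=label,
            frame_index=self.frame_index if frame_index is None else frame_index,
        )


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """Convert an (H, W, 3[+alpha]) color image to grayscale via luma weights."""
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.ndim == 2:
        return rgb
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise ValueError(f"expected (H, W, >=3) color image, got {rgb.shape}")
    return rgb[..., 0] * 0.299 + rgb[..., 1] * 0.587 + rgb[..., 2] * 0.114


@dataclass(frozen=True)
class GridSpec:
    """Analysis lattice: subset side length, grid spacing, and search extent.

    Defaults match the standard facial-DISC setup: an 85x85-pixel subset
    centered on grid points spaced 20 pixels apart.  ``search_radius`` bounds
    the per-axis integer displacement searched around zero motion.  Even
    subset sizes are incremented to the next odd value so the center pixel is
    well defined.
    """

    subset_size: int = 85
    step: int = 20
    search_radius: int = 40

    def __post_init__(self) -> None:
        if self.subset_size < 3:
            raise ValueError("subset_size must be >= 3")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.search_radius < 1:
            raise ValueError("search_radius must be >= 1")
        if self.subset_size % 2 == 0:
            logger.warning(
                "even subset_size %d adjusted to %d so the center pixel is defined",
                self.subset_size,
                self.subset_size + 1,
            )
            object.__setattr__(self, "subset_size", self.subset_size + 1)

    @property
    def half(self) -> int:
        return self.subset_size // 2


@dataclass(frozen=True)
class DisplacementField:
    """Per-lattice-point displacement between a baseline and a target frame.

    Arrays ``u``, ``v`` and ``peak_similarity`` are 2-D over the lattice
    (rows indexed by ``xs``, columns by ``ys``); entries are NaN where the
    point was invalid (its subset or search window exited the image, or its
    subset was blank).  ``valid`` marks the computed points.
    """

    xs: np.ndarray  # lattice row coordinates, shape (nx,)
    ys: np.ndarray  # lattice col coordinates, shape (ny,)
    u: np.ndarray  # vertical displacement, shape (nx, ny)
    v: np.ndarray  # horizontal displacement, shape (nx, ny)
    peak_similarity: np.ndarray  # best score per point, shape (nx, ny)
    valid: np.ndarray  # bool, shape (nx, ny)
    grid: GridSpec | None = None
    baseline_index: int = 0
    target_index: int = 0
    subpixel: bool = False

    def __post_init__(self) -> None:
        for name in ("xs", "ys", "u", "v", "peak_similarity", "valid"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        shape = (len(self.xs), len(self.ys))
        for name in ("u", "v", "peak_similarity", "valid"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} must have lattice shape {shape}")

    @property
    def lattice_shape(self) -> tuple[int, int]:
        return (len(self.xs), len(self.ys))

    @property
    def points(self) -> np.ndarray:
        """(N, 2) array of valid lattice coordinates (x=row, y=col)."""
        gx, gy = np.meshgrid(self.xs, self.ys, indexing="ij")
        return np.column_stack([gx[self.valid], gy[self.valid]])

    @property
    def magnitude(self) -> np.ndarray:
        """Per-point displacement magnitude sqrt(u^2 + v^2); NaN where invalid."""
        return np.hypot(self.u, self.v)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def same_lattice(self, other: "DisplacementField") -> bool:
        return (
            np.array_equal(self.xs, other.xs)
            and np.array_equal(self.ys, other.ys)
            and np.array_equal(self.valid, other.valid)
        )


def zero_field_like(field: DisplacementField, target_index: int | None = None) -> DisplacementField:
    """A zero-displacement field on the same lattice (unit peak similarity)."""
    z = np.where(field.valid, 0.0, np.nan)
    one = np.where(field.valid, 1.0, np.nan)
    return DisplacementField(
        xs=field.xs,
        ys=field.ys,
        u=z.copy(),
        v=z.copy(),
        peak_similarity=one,
        valid=field.valid.copy(),
        grid=field.grid,
        baseline_index=field.baseline_index,
        target_index=field.baseline_index if target_index is None else target_index,
        subpixel=field.subpixel,
    )


# ---------------------------------------------------------------------------
# Similarity
# ---------------------------------------------------------------------------


def patch_similarity(patch_a: np.ndarray, patch_b: np.ndarray) -> float:
    """Non-centered normalized cross-correlation of two equal-shape patches.

    Returns ``sum(Ia*Ib) / sqrt(sum(Ia^2) * sum(Ib^2))``; no mean
    subtraction.  Exactly 1.0 when Cauchy-Schwarz equality is attained in
    floating point (identical patches, or positive scalar multiples by a
    power of two), so self-similarity is identically 1.

    Raises
    ------
    ValueError
        If the shapes differ.
    UndefinedSimilarityError
        If either patch is all zero (0/0).
    """
    a = np.asarray(patch_a, dtype=np.float64)
    b = np.asarray(patch_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"patch shapes differ: {a.shape} vs {b.shape}")
    ar = a.ravel()
    br = b.ravel()
    num = float(ar @ br)
    sa = float(ar @ ar)
    sb = float(br @ br)
    if sa == 0.0 or sb == 0.0:
        raise UndefinedSimilarityError("similarity undefined for an all-zero patch")
    t = num * num
    d = sa * sb
    if t >= d:
        return 1.0 if num >= 0 else -1.0
    return math.copysign(math.sqrt(t / d), num)


def _similarity_at(
    ref: np.ndarray, target: np.ndarray, cx: int, cy: int, u: int, v: int, half: int
) -> float:
    """Direct Eq-style similarity of the subset at (cx, cy) vs offset (u, v)."""
    a = ref[cx - half : cx + half + 1, cy - half : cy + half + 1]
    b = target[cx + u - half : cx + u + half + 1, cy + v - half : cy + v + half + 1]
    return patch_similarity(a, b)


# ---------------------------------------------------------------------------
# Lattice
# ---------------------------------------------------------------------------


def lattice_axes(shape: tuple[int, int], grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Row/col coordinates of lattice points whose subset fits in ``shape``."""
    h, w = shape
    half = grid.half
    xs = np.arange(half, h - half, grid.step)
    ys = np.arange(half, w - half, grid.step)
    if xs.size == 0 or ys.size == 0:
        raise LatticeError(
            f"no lattice point fits: frame {shape} too small for subset "
            f"{grid.subset_size} with step {grid.step}"
        )
    return xs, ys


def _search_valid_mask(
    shape: tuple[int, int], xs: np.ndarray, ys: np.ndarray, grid: GridSpec
) -> np.ndarray:
    """Lattice points whose search window (subset dilated by the radius) fits."""
    h, w = shape
    m = grid.half + grid.search_radius
    okx = (xs >= m) & (xs <= h - 1 - m)
    oky = (ys >= m) & (ys <= w - 1 - m)
    return okx[:, None] & oky[None, :]


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


def _batched_surfaces(
    ref: np.ndarray,
    target: np.ndarray,
    centers: np.ndarray,
    grid: GridSpec,
) -> np.ndarray:
    """Similarity surfaces over the integer search window for many centers.

    Returns an array of shape (P, 2r+1, 2r+1); entry [p, r+u, r+v] is the
    similarity of the subset at centers[p] in ``ref`` against the subset
    displaced by (u, v) in ``target``.  Numerators come from batched FFT
    cross-correlation; denominators from integral images.  Entries where the
    candidate subset has zero energy are -inf.
    """
    ss = grid.subset_size
    half = grid.half
    r = grid.search_radius
    ws = ss + 2 * r

    rows = centers[:, 0]
    cols = centers[:, 1]

    patch_view = sliding_window_view(ref, (ss, ss))
    patches = patch_view[rows - half, cols - half]  # (P, ss, ss)
    win_view = sliding_window_view(target, (ws, ws))
    windows = win_view[rows - half - r, cols - half - r]  # (P, ws, ws)

    # Batched FFT cross-correlation: num[p, u, v] = sum(patch * window shifted)
    n = ws + ss - 1
    nfft = _fft.next_fast_len(n, real=True)
    fw = _fft.rfft2(windows, s=(nfft, nfft))
    fp = _fft.rfft2(patches[:, ::-1, ::-1], s=(nfft, nfft))
    full = _fft.irfft2(fw * fp, s=(nfft, nfft))
    num = full[:, ss - 1 : ss + 2 * r, ss - 1 : ss + 2 * r]  # (P, 2r+1, 2r+1)

    # Sliding sum of window^2 over ss x ss subwindows via integral image.
    sq = windows * windows
    ii = np.zeros((len(centers), ws + 1, ws + 1), dtype=np.float64)
    np.cumsum(sq, axis=1, out=ii[:, 1:, 1:])
    np.cumsum(ii[:, 1:, 1:], axis=2, out=ii[:, 1:, 1:])
    s2 = (
        ii[:, ss:, ss:]
        - ii[:, :-ss, ss:]
        - ii[:, ss:, :-ss]
        + ii[:, :-ss, :-ss]
    )  # (P, 2r+1, 2r+1)
    np.maximum(s2, 0.0, out=s2)

    patch_ss = np.einsum("pij,pij->p", patches, patches)

    with np.errstate(divide="ignore", invalid="ignore"):
        den = np.sqrt(patch_ss[:, None, None] * s2)
        surf = num / den
    surf = np.clip(surf, 0.0, 1.0, out=surf)
    surf[~np.isfinite(surf)] = -np.inf
    surf[s2 <= 0.0] = -np.inf
    surf[patch_ss <= 0.0] = -np.inf
    return surf


def _argmax_with_tiebreak(surface: np.ndarray, r: int) -> tuple[int, int]:
    """Integer (u, v) maximizing the surface; ties resolve toward null motion.

    Among equal peaks, the candidate with smallest u^2+v^2 wins, then
    smallest u, then smallest v.
    """
    m = surface.max()
    cand = np.argwhere(surface == m)
    us = cand[:, 0] - r
    vs = cand[:, 1] - r
    order = np.lexsort((vs, us, us * us + vs * vs))
    k = order[0]
    return int(us[k]), int(vs[k])


def _refine_subpixel(s_grid: np.ndarray) -> tuple[float, float]:
    """Quadratic (parabolic) peak refinement from a 3x3 similarity patch.

    Fits an independent 1-D parabola per axis through the peak; offsets are
    clamped to [-0.5, 0.5] and degenerate (non-concave) axes yield 0.
    """

    def axis_offset(sm: float, s0: float, sp: float) -> float:
        denom = sm - 2.0 * s0 + sp
        if denom >= 0.0:  # not concave at the peak
            return 0.0
        off = 0.5 * (sm - sp) / denom
        return float(np.clip(off, -0.5, 0.5))

    du = axis_offset(s_grid[0, 1], s_grid[1, 1], s_grid[2, 1])
    dv = axis_offset(s_grid[1, 0], s_grid[1, 1], s_grid[1, 2])
    return du, dv


def match_point(
    ref: GrayFrame,
    target: GrayFrame,
    center: tuple[int, int],
    grid: GridSpec,
    subpixel: bool = False,
) -> tuple[float, float, float]:
    """Displacement (u, v) of one subset center and its peak similarity.

    Exhaustive integer search within ``grid.search_radius`` of zero motion,
    followed by optional quadratic sub-pixel refinement.  The reported peak
    similarity is recomputed by direct summation at the integer peak (exact,
    not subject to FFT round-off).

    Raises
    ------
    InvalidPointError
        If the subset around ``center`` exits ``ref`` or the search window
        exits ``target``; the point is never silently clamped.
    """
    cx, cy = int(center[0]), int(center[1])
    half, r = grid.half, grid.search_radius
    h, w = ref.pixels.shape
    if target.pixels.shape != (h, w):
        raise ValueError("ref and target frames must have the same shape")
    if not (half <= cx <= h - 1 - half and half <= cy <= w - 1 - half):
        raise InvalidPointError(f"subset around {center} exits the reference frame")
    if not (half + r <= cx <= h - 1 - half - r and half + r <= cy <= w - 1 - half - r):
        raise InvalidPointError(f"search window around {center} exits the target frame")

    surf = _batched_surfaces(ref.pixels, target.pixels, np.array([[cx, cy]]), grid)[0]
    if not np.isfinite(surf).any():
        raise InvalidPointError(f"subset at {center} has no defined similarity (blank)")
    ui, vi = _argmax_with_tiebreak(surf, r)
    peak = _similarity_at(ref.pixels, target.pixels, cx, cy, ui, vi, half)
    u, v = float(ui), float(vi)
    if subpixel and peak < 1.0 and abs(ui) < r and abs(vi) < r:
        s3 = np.empty((3, 3))
        for i, du_ in enumerate((-1, 0, 1)):
            for j, dv_ in enumerate((-1, 0, 1)):
                if (du_, dv_) == (0, 0):
                    s3[i, j] = peak
                else:
                    s3[i, j] = _similarity_at(
                        ref.pixels, target.pixels, cx, cy, ui + du_, vi + dv_, half
                    )
        du, dv = _refine_subpixel(s3)
        u += du
        v += dv
    return u, v, peak


def compute_field(
    ref: GrayFrame,
    target: GrayFrame,
    grid: GridSpec,
    subpixel: bool = True,
) -> DisplacementField:
    """Whole-frame displacement field between a baseline and a target frame.

    One match per lattice point whose subset fits the frame; points whose
    search window exits the image (or whose subset is blank) are recorded as
    invalid (NaN), not clamped or padded, so fields from equal-sized frames
    share identical lattices.  Deterministic for fixed inputs.
    """
    if ref.pixels.shape != target.pixels.shape:
        raise ValueError("ref and target frames must have the same shape")
    xs, ys = lattice_axes(ref.pixels.shape, grid)
    ok = _search_valid_mask(ref.pixels.shape, xs, ys, grid)
    nx, ny = len(xs), len(ys)
    u = np.full((nx, ny), np.nan)
    v = np.full((nx, ny), np.nan)
    peak = np.full((nx, ny), np.nan)
    valid = np.zeros((nx, ny), dtype=bool)

    idx = np.argwhere(ok)
    if idx.size:
        centers = np.column_stack([xs[idx[:, 0]], ys[idx[:, 1]]])
        surfs = _batched_surfaces(ref.pixels, target.pixels, centers, grid)
        r = grid.search_radius
        half = grid.half
        for (ix, iy), surf, (cx, cy) in zip(idx, surfs, centers):
            if not np.isfinite(surf).any():
                continue  # blank subset: point stays invalid
            ui, vi = _argmax_with_tiebreak(surf, r)
            try:
                pk = _similarity_at(ref.pixels, target.pixels, cx, cy, ui, vi, half)
            except UndefinedSimilarityError:
                continue
            uu, vv = float(ui), float(vi)
            if subpixel and pk < 1.0 and abs(ui) < r and abs(vi) < r:
                s3 = surf[r + ui - 1 : r + ui + 2, r + vi - 1 : r + vi + 2].copy()
                s3[1, 1] = pk
                du, dv = _refine_subpixel(s3)
                uu += du
                vv += dv
            u[ix, iy] = uu
            v[ix, iy] = vv
            peak[ix, iy] = pk
            valid[ix, iy] = True

    n_dropped = int(ok.size - ok.sum())
    if n_dropped:
        logger.debug("compute_field: %d boundary lattice points dropped", n_dropped)
    return DisplacementField(
        xs=xs,
        ys=ys,
        u=u,
        v=v,
        peak_similarity=peak,
        valid=valid,
        grid=grid,
        baseline_index=ref.frame_index,
        target_index=target.frame_index,
        subpixel=subpixel,
    )


def field_magnitude(field: DisplacementField) -> np.ndarray:
    """Per-point displacement magnitude sqrt(u^2 + v^2) over the lattice."""
    return field.magnitude
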