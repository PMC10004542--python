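"""Average displacement-magnitude heatmaps per participant and composites.

A participant's heatmap for one emotion is the pointwise mean, over all
frames of that emotion's viewing block, of the DISC displacement magnitude at
each lattice point.  Composite heatmaps average the participant heatmaps with
equal weight (one participant, one vote); because the same lattice is applied
to every participant, the same number of points is compared across
individuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .core import DisplacementField, GrayFrame


class LatticeMismatchError(ValueError):
    """Heatmaps or fields being averaged do not share a lattice."""


@dataclass(frozen=True)
class EmotionHeatmap:
    """Mean displacement magnitude (pixels) per lattice point for one emotion."""

    xs: np.ndarray
    ys: np.ndarray
    values: np.ndarray  # (nx, ny), NaN where the lattice point is invalid
    valid: np.ndarray
    label: str
    scope: str  # participant id or "composite"
    n_fields: int

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]

    def same_lattice(self, other: "EmotionHeatmap") -> bool:
        return (
            np.array_equal(self.xs, other.xs)
            and np.array_equal(self.ys, other.ys)
            and np.array_equal(self.valid, other.valid)
        )


def participant_heatmap(
    fields: Sequence[DisplacementField],
    label: str,
    participant_id: str,
) -> EmotionHeatmap:
    """Pointwise mean of displacement magnitudes over one participant's frames."""
    if not fields:
        raise ValueError("at least one field is required")
    first = fields[0]
    for f in fields[1:]:
        if not f.same_lattice(first):
            raise LatticeMismatchError("fields do not share a lattice")
    stack = np.stack([f.magnitude for f in fields])
    return EmotionHeatmap(
        xs=first.xs,
        ys=first.ys,
        values=stack.mean(axis=0),
        valid=first.valid.copy(),
        label=label,
        scope=participant_id,
        n_fields=len(fields),
    )


def composite_heatmap(heatmaps: Sequence[EmotionHeatmap]) -> EmotionHeatmap:
    """Unweighted pointwise mean across participants' heatmaps."""
    if not heatmaps:
        raise ValueError("at least one heatmap is required")
    first = heatmaps[0]
    for h in heatmaps[1:]:
        if not h.same_lattice(first):
            raise LatticeMismatchError("heatmaps do not share a lattice")
        if h.label != first.label:
            raise ValueError("composite heatmaps must share an emotion label")
    stack = np.stack([h.values for h in heatmaps])
    return EmotionHeatmap(
        xs=first.xs,
        ys=first.ys,
        values=stack.mean(axis=0),
        valid=first.valid.copy(),
        label=first.label,
        scope="composite",
        n_fields=sum(h.n_fields for h in heatmaps),
    )


def top_decile_mass_fraction(heatmap: EmotionHeatmap, region_mask: np.ndarray) -> float:
    """Fraction of the top-decile heatmap mass lying inside a pixel-space mask.

    The top decile is the set of valid lattice points at or above the 90th
    percentile of valid values; the returned fraction is their summed
    magnitude inside the mask over their total summed magnitude.
    """
    gx, gy = np.meshgrid(heatmap.xs, heatmap.ys, indexing="ij")
    vals = heatmap.values[heatmap.valid]
    px = gx[heatmap.valid]
    py = gy[heatmap.valid]
    thresh = np.percentile(vals, 90.0)
    top = vals >= thresh
    mass = vals[top]
    total = mass.sum()
    if total <= 0:
        return 0.0
    inside = region_mask[px[top], py[top]]
    return float(mass[inside].sum() / total)


def render_overlay(
    frame: GrayFrame,
    heatmap: EmotionHeatmap,
    cmap: str = "inferno",
    alpha: float = 0.55,
    vmax: float | None = None,
) -> np.ndarray:
    """Frame with a color-mapped, bilinearly upsampled heatmap overlay.

    Pure visualization: a zero heatmap returns the (gray-replicated) frame
    unchanged, and values are clamped at the colormap maximum.  Output is an
    (H, W, 3) uint8 RGB image with the input frame's dimensions.
    """
    from matplotlib import colormaps

    h, w = frame.pixels.shape
    if heatmap.xs.max() >= h or heatmap.ys.max() >= w:
        raise ValueError("heatmap lattice does not fit inside the frame")
    filled = np.where(heatmap.valid, heatmap.values, 0.0)
    interp = RegularGridInterpolator(
        (heatmap.xs, heatmap.ys), filled, bounds_error=False, fill_value=0.0
    )
    gx, gy = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    dense = interp(np.stack([gx.ravel(), gy.ravel()], axis=1)).reshape(h, w)
    scale = vmax if vmax is not None else (float(np.nanmax(filled)) or 1.0)
    if scale <= 0:
        scale = 1.0
    weight = np.clip(dense / scale, 0.0, 1.0)
    color = colormaps[cmap](weight)[..., :3] * 255.0
    gray = np.repeat(frame.pixels[..., None], 3, axis=2)
    out = gray * (1.0 - alpha * weight[..., None]) + color * (alpha * weight[..., None])
    return np.clip(out, 0, 255).astype(np.uint8)
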