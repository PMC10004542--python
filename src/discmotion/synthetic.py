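"""Synthetic speckle-face sessions with ground-truth deformation.

Real facial DISC relies on skin pores acting as natural speckles.  This
module generates band-limited random speckle textures standing in for skin,
deforms them with smooth, emotion-specific displacement templates (Gaussian
lobes at the mouth corners for "happy", at the brow for "sad") whose
amplitude ramps up over each viewing block, adds intensity noise and
per-participant idiosyncrasies, and retains the exact ground-truth field for
every frame.  Everything is bit-reproducible under a seed.

The generated sessions are the test surface for the whole pipeline: the
deformations are localized and sub-visible like the facial motions DISC
targets, but their true displacement at every pixel is known analytically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import GrayFrame, GridSpec
from .session import Session, StimulusSchedule, default_schedule, select_baselines


# ---------------------------------------------------------------------------
# Speckle texture
# ---------------------------------------------------------------------------


def make_speckle(
    size: tuple[int, int],
    density: float = 0.10,
    grain: float = 1.6,
    seed: int | np.random.Generator = 0,
) -> GrayFrame:
    """Reproducible band-limited speckle texture with intensities in [20, 235].

    Random impulses of the given ``density`` are blurred with a Gaussian of
    scale ``grain`` (the speckle correlation length, in pixels) and rescaled.
    Every subset of such a texture has positive variance, which is what makes
    it trackable.
    """
    h, w = int(size[0]), int(size[1])
    if h < 3 or w < 3:
        raise ValueError(f"degenerate frame size {size}")
    if not (0.0 < density <= 1.0):
        raise ValueError("density must lie in (0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    impulses = (rng.random((h, w)) < density) * rng.uniform(0.5, 1.0, (h, w))
    tex = ndimage.gaussian_filter(impulses, grain, mode="reflect")
    lo, hi = tex.min(), tex.max()
    if hi <= lo:  # pragma: no cover - vanishingly unlikely for valid density
        raise ValueError("degenerate speckle texture (no contrast)")
    px = 20.0 + (tex - lo) * (215.0 / (hi - lo))
    return GrayFrame(pixels=px)


# ---------------------------------------------------------------------------
# Deformation templates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Lobe:
    """One smooth displacement lobe: a Gaussian envelope times a direction.

    ``center`` is (row, col) in pixels, ``sigma`` the spatial scale in
    pixels, ``direction`` a (du, dv) unit vector, and ``amplitude`` the peak
    displacement in pixels at unit template scale.  The field is truncated to
    exactly zero beyond ``cutoff`` sigmas.
    """

    center: tuple[float, float]
    sigma: float
    direction: tuple[float, float]
    amplitude: float = 1.0
    cutoff: float = 3.0

    def evaluate(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(u, v) displacement of this lobe at pixel coordinates (x, y)."""
        dx = x - self.center[0]
        dy = y - self.center[1]
        r2 = dx * dx + dy * dy
        env = self.amplitude * np.exp(-0.5 * r2 / (self.sigma**2))
        env = np.where(r2 > (self.cutoff * self.sigma) ** 2, 0.0, env)
        return env * self.direction[0], env * self.direction[1]


@dataclass(frozen=True)
class DeformationTemplate:
    """Emotion-specific deformation: a superposition of displacement lobes."""

    label: str
    lobes: tuple[Lobe, ...]

    def evaluate(self, x: np.ndarray, y: np.ndarray, scale: float = 1.0
                 ) -> tuple[np.ndarray, np.ndarray]:
        u = np.zeros(np.broadcast(x, y).shape)
        v = np.zeros_like(u)
        for lobe in self.lobes:
            lu, lv = lobe.evaluate(x, y)
            u += lu
            v += lv
        return u * scale, v * scale

    def scaled(self, factor: float) -> "DeformationTemplate":
        return DeformationTemplate(
            self.label,
            tuple(replace(l, amplitude=l.amplitude * factor) for l in self.lobes),
        )


def happy_template(shape: tuple[int, int]) -> DeformationTemplate:
    """Two mouth-corner lobes moving up and outward (a sub-visible smile)."""
    h, w = shape
    s = 0.09 * min(h, w)
    row = 0.74 * h
    d = math.hypot(0.6, 0.8)
    return DeformationTemplate(
        "happy",
        (
            Lobe((row, 0.30 * w), s, (-0.6 / d, -0.8 / d)),
            Lobe((row, 0.70 * w), s, (-0.6 / d, 0.8 / d)),
        ),
    )


def sad_template(shape: tuple[int, int]) -> DeformationTemplate:
    """One brow lobe moving downward (a sub-visible frown)."""
    h, w = shape
    return DeformationTemplate(
        "sad",
        (Lobe((0.28 * h, 0.50 * w), 0.11 * min(h, w), (1.0, 0.0)),),
    )


def template_field(
    template: DeformationTemplate,
    shape: tuple[int, int],
    scale: float = 1.0,
) -> np.ndarray:
    """Dense ground-truth field (2, H, W): the template evaluated everywhere.

    Linear in ``scale``; exactly zero beyond each lobe's cutoff radius.
    """
    x, y = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    u, v = template.evaluate(x.astype(float), y.astype(float), scale)
    return np.stack([u, v])


def ramp_scale(ramp: tuple[float, float], tau: int, block_frames: int) -> float:
    """Amplitude multiplier at block-relative frame ``tau``.

    The block's first frame (the baseline) is exactly zero; responses then
    start at ``ramp[0]`` and grow linearly to ``ramp[1]`` at the final frame,
    mirroring the build-up of facial movement over a viewing period.
    """
    if tau <= 0:
        return 0.0
    if block_frames <= 2:
        return float(ramp[1])
    frac = (tau - 1) / (block_frames - 2)
    return float(ramp[0] + (ramp[1] - ramp[0]) * frac)


# ---------------------------------------------------------------------------
# Warping
# ---------------------------------------------------------------------------


def warp(
    frame: GrayFrame,
    dense_field: np.ndarray,
    n_iter: int = 8,
) -> tuple[GrayFrame, float]:
    """Deform a frame so that pixel (x, y) moves by ``dense_field[:, x, y]``.

    ``dense_field`` is the *forward* displacement of baseline points.  The
    warped image T satisfies T(x + u(x), y + v(x)) = B(x, y); the required
    inverse map is found by fixed-point iteration (convergent for the smooth,
    moderate-gradient fields generated here), then sampled bilinearly.  A
    zero field returns the input bit-exactly (interpolation at integer
    sites).  Returns the warped frame and the fraction of samples that were
    clamped at the image edge.
    """
    d = np.asarray(dense_field, dtype=np.float64)
    h, w = frame.pixels.shape
    if d.shape != (2, h, w):
        raise ValueError(f"dense field shape {d.shape} does not match frame {(h, w)}")
    mag = np.abs(d).max()
    if mag == 0.0:
        return GrayFrame(frame.pixels.copy(), frame.frame_index, frame.label,
                         frame.participant_id), 0.0

    # Restrict the (comparatively expensive) inverse iteration to the
    # bounding box where the field can have any effect.
    moving = (d[0] != 0) | (d[1] != 0)
    pad = int(np.ceil(mag)) + 1
    rows = np.where(moving.any(axis=1))[0]
    cols = np.where(moving.any(axis=0))[0]
    r0, r1 = max(rows[0] - pad, 0), min(rows[-1] + pad + 1, h)
    c0, c1 = max(cols[0] - pad, 0), min(cols[-1] + pad + 1, w)

    x, y = np.meshgrid(np.arange(r0, r1, dtype=float),
                       np.arange(c0, c1, dtype=float), indexing="ij")
    gx, gy = x - d[0, r0:r1, c0:c1], y - d[1, r0:r1, c0:c1]
    for _ in range(n_iter):
        du = ndimage.map_coordinates(d[0], [gx, gy], order=1, mode="nearest")
        dv = ndimage.map_coordinates(d[1], [gx, gy], order=1, mode="nearest")
        gx, gy = x - du, y - dv
    clamped = np.mean((gx < 0) | (gx > h - 1) | (gy < 0) | (gy > w - 1))
    out = frame.pixels.copy()
    out[r0:r1, c0:c1] = ndimage.map_coordinates(frame.pixels, [gx, gy], order=1,
                                                mode="nearest")
    return GrayFrame(np.clip(out, 0.0, 255.0), frame.frame_index, frame.label,
                     frame.participant_id), float(clamped)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate the reference study design: ten participants, 230 frames
    each at 1 fps under the default schedule, localized happy/sad deformation
    ramping from ``ramp[0]`` to ``ramp[1]`` pixels over each viewing block,
    additive Gaussian intensity noise (gray levels), small per-participant
    lobe jitter and amplitude multipliers, and optionally a rigid whole-frame
    jitter emulating subtle head motion.  ``n_weak`` participants respond
    with strongly attenuated amplitude (idiosyncratic low responders).
    """

    n_participants: int = 10
    frame_shape: tuple[int, int] = (200, 200)
    density: float = 0.10
    grain: float = 1.6
    schedule: StimulusSchedule = field(default_factory=default_schedule)
    ramp: tuple[float, float] = (1.0, 6.0)
    amp_range: tuple[float, float] = (0.8, 1.25)
    lobe_jitter: float = 5.0
    n_weak: int = 0
    weak_multiplier: float = 0.12
    noise_sigma: float = 2.0
    rigid_jitter: float = 0.0
    seed: int = 0


def cohort_grid(config: SyntheticCohortConfig | None = None) -> GridSpec:
    """Analysis grid proportioned to the default 200-px synthetic frames."""
    return GridSpec(subset_size=41, step=16, search_radius=12)


@dataclass(frozen=True)
class FrameTruth:
    """Analytic ground truth for one frame: template, scale and rigid offset."""

    template: DeformationTemplate | None
    scale: float
    rigid: tuple[float, float] = (0.0, 0.0)

    def at_points(self, points: np.ndarray) -> np.ndarray:
        """True (u, v) at (N, 2) pixel coordinates; shape (N, 2)."""
        pts = np.asarray(points, dtype=float)
        if self.template is None or self.scale == 0.0:
            uv = np.zeros((len(pts), 2))
        else:
            u, v = self.template.evaluate(pts[:, 0], pts[:, 1], self.scale)
            uv = np.column_stack([u, v])
        return uv + np.asarray(self.rigid)

    def dense(self, shape: tuple[int, int]) -> np.ndarray:
        if self.template is None or self.scale == 0.0:
            d = np.zeros((2, *shape))
        else:
            d = template_field(self.template, shape, self.scale)
        d[0] += self.rigid[0]
        d[1] += self.rigid[1]
        return d


@dataclass
class SyntheticSession:
    """A generated session plus per-frame analytic ground truth."""

    session: Session
    truths: dict[int, FrameTruth]
    templates: dict[str, DeformationTemplate]
    config: SyntheticCohortConfig


def _jittered_template(
    template: DeformationTemplate, jitter: float, mult: float, rng: np.random.Generator
) -> DeformationTemplate:
    lobes = []
    for lobe in template.lobes:
        cx = lobe.center[0] + rng.uniform(-jitter, jitter)
        cy = lobe.center[1] + rng.uniform(-jitter, jitter)
        lobes.append(replace(lobe, center=(cx, cy), amplitude=lobe.amplitude * mult))
    return DeformationTemplate(template.label, tuple(lobes))


def generate_session(
    participant_id: str,
    config: SyntheticCohortConfig,
    rng: np.random.Generator,
    weak: bool = False,
) -> SyntheticSession:
    """One participant's frame stack, labels and ground-truth deformations."""
    shape = config.frame_shape
    base = make_speckle(shape, config.density, config.grain, rng)
    mult = rng.uniform(*config.amp_range)
    if weak:
        mult *= config.weak_multiplier
    templates = {
        "happy": _jittered_template(happy_template(shape), config.lobe_jitter, mult, rng),
        "sad": _jittered_template(sad_template(shape), config.lobe_jitter, mult, rng),
    }

    bounds = config.schedule.block_bounds()
    frames: list[GrayFrame] = []
    block_ids: list[int] = []
    truths: dict[int, FrameTruth] = {}
    n_frames = int(np.ceil(config.schedule.total_duration))
    block_positions: dict[int, int] = {}
    block_sizes = {
        b: int(np.ceil(end)) - int(np.ceil(start))
        for b, (_, start, end) in enumerate(bounds)
    }
    for k in range(n_frames):
        b = config.schedule.block_at(float(k))
        label = bounds[b][0]
        tau = block_positions.get(b, 0)
        block_positions[b] = tau + 1

        rigid = (0.0, 0.0)
        if config.rigid_jitter > 0:
            rigid = tuple(rng.uniform(-config.rigid_jitter, config.rigid_jitter, 2))
        if label in templates:
            scale = ramp_scale(config.ramp, tau, block_sizes[b])
            truth = FrameTruth(templates[label], scale, rigid)
        else:
            truth = FrameTruth(None, 0.0, rigid)
        dense = truth.dense(shape)
        warped, _ = warp(base, dense)
        px = warped.pixels
        if config.noise_sigma > 0:
            px = px + rng.normal(0.0, config.noise_sigma, shape)
        frames.append(
            GrayFrame(np.clip(px, 0.0, 255.0), frame_index=k, label=label,
                      participant_id=participant_id)
        )
        block_ids.append(b)
        truths[k] = truth

    sess = Session(
        participant_id=participant_id,
        frames=frames,
        block_ids=block_ids,
        schedule=config.schedule,
    )
    select_baselines(sess)
    return SyntheticSession(sess, truths, templates, config)


def generate_cohort(config: SyntheticCohortConfig) -> list[SyntheticSession]:
    """All participants of a cohort, bit-reproducible under ``config.seed``.

    Each participant gets an independent child generator spawned from the
    cohort seed, so per-participant content does not depend on generation
    order.  The first ``n_weak`` participants are low responders.
    """
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_participants)
    out = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        pid = f"P{i + 1:02d}"
        out.append(generate_session(pid, config, rng, weak=i < config.n_weak))
    return out


def recovery_benchmark(
    amplitudes: Sequence[float],
    frame_shape: tuple[int, int] = (512, 512),
    sigma: float = 170.0,
    noise_sigma: float = 2.0,
    seed: int = 0,
) -> tuple[GrayFrame, list[tuple[GrayFrame, FrameTruth]]]:
    """Broad-lobe warp sweep for validating displacement recovery.

    One speckle baseline is warped by a single Gaussian lobe (diagonal
    direction) at each requested peak amplitude, with fresh intensity noise
    per frame.  The lobe scale defaults to a value large relative to the
    standard 85-px subset so the displacement is near-uniform at subset scale
    (the window-smoothing bias is about ``amplitude * (w/sigma)^2`` with
    ``w ~ subset/sqrt(12)``, i.e. a few tenths of a pixel at 20-px
    amplitude); steeper deformations are exercised by the cohort generator.
    Returns the baseline and one (warped frame, analytic truth) per amplitude.
    """
    rng = np.random.default_rng(seed)
    base = make_speckle(frame_shape, seed=rng)
    h, w = frame_shape
    d = math.hypot(0.6, 0.8)
    template = DeformationTemplate(
        "happy", (Lobe((h / 2, w / 2), sigma, (0.6 / d, 0.8 / d)),)
    )
    out = []
    for k, amp in enumerate(amplitudes):
        truth = FrameTruth(template, float(amp))
        warped, _ = warp(base, truth.dense(frame_shape))
        px = warped.pixels
        if noise_sigma > 0:
            px = np.clip(px + rng.normal(0.0, noise_sigma, frame_shape), 0.0, 255.0)
        out.append(
            (GrayFrame(px, frame_index=k + 1, label="happy"), truth)
        )
    return base, out


def region_masks(
    config: SyntheticCohortConfig,
    margin_sigmas: float = 2.0,
) -> dict[str, np.ndarray]:
    """Boolean pixel masks of the nominal mouth and brow deformation regions.

    A pixel belongs to a region if it lies within ``margin_sigmas`` lobe
    scales (plus the configured lobe jitter) of a nominal lobe center; used
    for spatial-dissociation assertions on heatmaps.
    """
    shape = config.frame_shape
    x, y = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    masks: dict[str, np.ndarray] = {}
    for name, template in (("happy", happy_template(shape)), ("sad", sad_template(shape))):
        m = np.zeros(shape, dtype=bool)
        for lobe in template.lobes:
            r = margin_sigmas * lobe.sigma + config.lobe_jitter
            m |= (x - lobe.center[0]) ** 2 + (y - lobe.center[1]) ** 2 <= r * r
        masks["mouth" if name == "happy" else "brow"] = m
    return masks
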