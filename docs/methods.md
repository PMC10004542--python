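# Methods

## The measurement problem

Emotionally triggered facial movements can be far too small to see: the
mouth corners and brow shift by fractions of a millimeter — sub-pixel to a
few pixels on a fixed camera — while the overall image looks unchanged.
`discmotion` measures these motions with digital image speckle correlation
(DISC), a displacement-tracking technique from experimental mechanics.  Skin
pores and fine texture act as a natural speckle pattern: every small
neighborhood of the face has a locally unique intensity fingerprint that can
be found again in a later frame.

## The DISC kernel

For a grid point $(x, y)$ of the baseline frame, the $N \times N$ intensity
neighborhood $I_a$ (default $N = 85$) is compared against equal-sized
neighborhoods $I_b$ centered at candidate positions $(x+u,\, y+v)$ of the
target frame using the non-centered normalized cross-correlation

$$S = \frac{\sum I_a I_b}{\sqrt{\sum I_a^2 \,\sum I_b^2}} \in [0, 1],$$

with no mean subtraction.  $S = 1$ exactly iff the neighborhoods are
positive scalar multiples of each other (Cauchy–Schwarz), so the score is
invariant to global intensity rescaling — illumination gain does not read as
motion.  The integer $(u, v)$ maximizing $S$ over an exhaustive search
window ($|u|, |v| \le$ `search_radius`, default 40 px) is the estimated
displacement; grid points are spaced `step` = 20 px apart, giving one
displacement vector per lattice point and a vector field per frame pair.

Numerical choices worth knowing:

* **Exact arithmetic at equality.** The score is computed as
  $\texttt{num}^2$ vs $\sum I_a^2 \sum I_b^2$ and returns exactly 1.0 when
  Cauchy–Schwarz equality is attained in floating point.  Self-similarity is
  therefore identically 1, and so is similarity under power-of-two intensity
  scalings — no tolerance needed at the top of the scale.
* **Batched search.** The full similarity surface per grid point is computed
  with FFT cross-correlation (numerators) plus integral images (window
  energies), batched over all lattice points of a frame pair; the reported
  peak value is then re-evaluated by direct summation, so it is exact rather
  than FFT-rounded.
* **Tie-breaking.** Equal peak scores resolve to the candidate with the
  smallest displacement magnitude, then smallest $u$, then $v$ —
  deterministic and biased toward null motion (relevant only for degenerate
  textures).
* **Sub-pixel refinement** fits an independent 1-D parabola per axis through
  the $3\times3$ directly-evaluated similarity values around the integer
  peak, clamped to $\pm 0.5$ px.  Refinement is skipped when the integer
  peak is exactly 1.0: a perfect match cannot be improved, which also makes
  the field of a frame against itself exactly zero.  Default ON for pipeline
  use; oracle tests that assert exact integer recovery run with it OFF.
* **Boundary policy.** Lattice points whose subset or search window would
  exit the image are dropped (recorded as invalid), never padded or clamped,
  so all fields from equal-sized frames share an identical lattice.  An
  all-zero subset is flagged invalid rather than producing 0/0.
* **Coordinates.** $(x, y) = (\text{row}, \text{col})$, origin top-left;
  $u$ is vertical (positive down), $v$ horizontal (positive right).  Most
  image libraries transpose this — all public APIs here use (row, col).

## Sessions, schedule and baselines

A recording follows a block schedule — by default 10 s blank (neutral),
100 s happy image viewing, 10 s blank, 100 s sad viewing, 10 s blank — and
is sampled at 1 frame per second, yielding 100 happy, 100 sad and 30 neutral
frames per participant (230 total).  Within each viewing block every frame
is tracked against the block's **first frame**: the temporally nearest
baseline minimizes misalignment from slow head drift.  Neutral frames are
referenced to the first frame of the first blank so that they, too, produce
feature fields for the classifiers.  Block intervals are half-open
$[\text{start}, \text{end})$; frame $i$ at rate $r$ sits at time $i/r$.

## Downstream analyses

* **Heatmaps** — the pointwise mean of displacement magnitude
  $\sqrt{u^2+v^2}$ over a participant's frames of one emotion; composite
  maps are the unweighted mean across participants (one participant, one
  vote; a pooled-frame weighting is equivalent when frame counts match,
  which the averaging-linearity test asserts).  Overlays bilinearly upsample
  the lattice for display only; no analysis consumes them.
* **Similarity matrices** — the frame-level similarity is the mean of the
  per-subset scores at zero offset over the co-located lattice (median and
  max aggregations available).  All pairwise scores over the happy and sad
  frames form a symmetric matrix with unit diagonal whose quadrants separate
  within- from cross-emotion comparisons.  The quadrant contrast is a
  two-sample two-tailed t-test (Welch by default) on the pooled
  within-quadrant vs cross-quadrant entries, each unordered pair counted
  once, diagonal excluded.  *Caveat:* entries sharing a frame are not
  independent, and the test ignores this.  The per-frame noise components
  cancel exactly in the within-minus-cross contrast while still inflating
  the variance estimate, so under label permutation the test is
  **conservative** (empirical size ≈ 1–2% at nominal 5% on null cohorts);
  its p-values are descriptive, and significance claims survive the
  conservatism in one direction only.
* **Embedding** — per frame, $u$ then $v$ over the lattice in row-major
  order form a feature vector (invalid points zero-imputed so dimensions
  match; magnitude-only features available).  Vectors from all participants
  and labels are pooled, centered on the cohort mean, and decomposed with
  PCA; the two leading components are reported with the full
  explained-variance spectrum.  Component signs follow a fixed convention
  (largest-magnitude loading positive).  Note that with pooled centering the
  plot origin is the cohort mean: when emotion amplitudes are large, the
  zero-motion state does *not* sit at the origin, so "neutral frames cluster
  centrally" is asserted relative to the projection of the
  zero-displacement vector, which is the invariant statement of the same
  fact.  Temporal profiles are the lattice-mean magnitude per frame within
  a block, with the cohort curve the unweighted participant mean.
* **Classifiers** — three families on participant-disjoint
  (leave-participants-out) splits:
  * *MSLR*: multinomial logistic regression with an $\ell_1$ penalty
    (sparse feature selection), features standardized on the training set
    only; the penalty strength is chosen by grid search with
    participant-grouped folds over the training participants only.
  * *MLP*: a feed-forward network, two hidden layers (128, 64) with
    rectifier activations and early stopping on a 10% train-internal
    validation split.
  * *3-D CNN*: a compact NumPy network on stacks of $k = 3$ adjacent
    displacement-magnitude lattices — two blocks of (3-D convolution with
    3×3×3 kernels, 8 then 16 channels → leaky ReLU, slope 0.01 → max
    pooling 1×2×2 → batch normalization), global average pooling, and two
    dense layers to three outputs trained with per-class binary cross
    entropy (sigmoid outputs, arg-max decision; a categorical
    cross-entropy option exists).  Adam, explicit seed, full
    forward/backward in NumPy with numeric-gradient-checked layers.
  Confusion matrices put true emotions on rows and predictions on columns;
  each row is also reported as percentages summing to 100.  Because the test
  label counts are imbalanced (100/100/30), chance level is quoted as
  **balanced accuracy** (mean per-class recall), which is exactly 1/3 in
  expectation whenever predictions are independent of the true labels.
  A chance-level caveat: shuffling training labels is not a meaningful
  control for a high-capacity model on strongly patterned inputs — it
  memorizes the per-pattern majority of the shuffled labels and the
  resulting test accuracy is a random pattern-to-class map (possibly 0 or
  1), not chance.  The generator's zero-amplitude setting is the well-posed
  control: with no label-linked signal in the frames, out-of-sample balanced
  accuracy concentrates at 1/3 for all three models.

## The synthetic cohort

The generator produces the study conditions end-to-end with known ground
truth, replacing participant videos that cannot ship with the package:

* **Texture**: band-limited speckle — random impulses (density 0.10)
  blurred at grain 1.6 px, rescaled to [20, 235]; every subset has positive
  variance, which is what makes skin-pore texture trackable.
* **Deformation**: smooth Gaussian displacement lobes, truncated to exactly
  zero beyond 3σ.  Happy = two mouth-corner lobes (σ = 0.09·frame) moving
  up-and-outward; sad = one brow lobe (σ = 0.11·frame) moving down.  The
  lobe amplitude ramps linearly from 1 px (first post-baseline frame) to
  6 px (block end), the baseline frame itself exactly zero — motion that
  builds over the viewing period.
* **Idiosyncrasy**: per-participant lobe-center jitter (±5 px), amplitude
  multiplier U(0.8, 1.25), and optionally `n_weak` low responders
  (multiplier ×0.12) for participant-separation checks.
* **Nuisance**: additive Gaussian intensity noise (σ = 2 gray levels) per
  frame; optional ±1 px rigid whole-frame jitter for head motion (off by
  default).
* **Warping** solves the inverse map of the *forward* displacement field by
  fixed-point iteration and samples bilinearly, so DISC at a lattice point
  recovers exactly the analytic truth at that point; a zero field returns
  the input bit-exactly.  Ground truth is kept analytically (template +
  scale per frame) and can be evaluated at any pixel.
* **Determinism**: one seed fixes the entire cohort bit-exactly;
  participants use independently spawned child generators so content does
  not depend on generation order.

Default sizes are chosen for desk-scale runs: 200×200-px frames with a
proportionally reduced analysis grid (subset 41, step 16, search radius 12),
ten participants, 230 frames each.  The displacement-recovery benchmark uses
512×512 frames with a broad lobe (σ = 170 px) at the full default grid
(85/20/40): recovery accuracy requires the deformation gradient to be small
at subset scale (window-smoothing bias ≈ amplitude·(w/σ)² with
w ≈ subset/√12, i.e. ≈ 0.4 px at 20-px amplitude for these sizes); the
steeper cohort lobes deliberately violate this and test pattern detection
rather than metrological accuracy.

What the generator does **not** emulate — and hence what passing tests do
not show about real recordings: nonrigid head pose changes and out-of-plane
rotation, blinking and gaze shifts, illumination drift, occlusion, camera
compression artifacts, non-Gaussian deformation profiles, and any
within-block temporal structure beyond a monotone ramp (no image-by-image
reaction spikes).  Real-data performance must be established on real data.

## Tunable parameters (defaults and units)

| parameter | default | unit | why |
|---|---|---|---|
| `subset_size` | 85 | px | neighborhood with enough texture to be unique; odd so the center is defined |
| `step` | 20 | px | lattice spacing; ~500+ dimensional feature vectors on realistic frame sizes |
| `search_radius` | 40 | px | exhaustive integer search bound; covers sub-visible motions with margin |
| subpixel | on | — | facial motions are sub-pixel; off for integer-recovery oracles |
| ramp | (1, 6) | px | amplitude at block start → end in the generator |
| noise σ | 2 | gray levels | sensor noise floor |
| CNN depth k | 3 | frames | adjacent heatmaps carrying temporal context |
| MSLR C grid | 0.1/1/10 | — | inverse ℓ1 strength, participant-grouped CV |
| seed | 20230310 | — | default for every stochastic step |

## Known limitations

* The t-test on similarity-matrix quadrants is conservative (dependence
  ignored), as discussed above.
* Integer + parabolic-refinement matching exhibits the usual peak-locking
  bias of correlation trackers (a few hundredths of a pixel here); the
  recovery tests bound total error, not bias structure.
* The pipeline assumes a fixed camera and a chinrest-stabilized face; no
  registration or pose compensation is attempted.
* Leave-participants-out accuracy on the synthetic cohort reflects the
  generator's shared deformation geometry across participants; it bounds
  nothing about human inter-individual variability.
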