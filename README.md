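# discmotion

Quantifying **sub-visible facial motion** with digital image speckle
correlation (DISC), and turning it into emotion analysis.

When a person views emotionally charged images, their face moves — but often
by amounts invisible to the naked eye: fractions of a pixel to a few pixels
on a fixed camera, building slowly over the viewing period rather than
flashing as an overt expression.  `discmotion` tracks these motions by
treating skin texture as a natural speckle pattern: every small neighborhood
of the face has a locally unique intensity fingerprint that can be located
again in a later frame.  The package is for researchers in affective
science, clinical monitoring, and biological image analysis who want an
objective, frame-to-frame measure of facial response and classifiers built
on it — plus a fully synthetic benchmark with known ground truth to validate
every step.

## The method in brief

For each point $(x,y)$ on a grid over the baseline frame (85×85-pixel
subsets, 20-pixel spacing by default), the similarity to a candidate
neighborhood at $(x^\*, y^\*) = (x+u,\, y+v)$ of a later frame is the
non-centered normalized cross-correlation of gray-scale intensities
$I \in [0, 255]$:

$$S_{x,y}(x^\*,y^\*) \;=\; \frac{\sum I(\tilde x,\tilde y)\, I(\tilde x^\*,\tilde y^\*)}
{\sqrt{\sum I^2(\tilde x,\tilde y)\; \sum I^2(\tilde x^\*,\tilde y^\*)}} \in [0,1],$$

summed over the paired neighborhoods.  The displacement
$\vec v(x,y) = (u, v)$ maximizing $S$ (exhaustive integer search, optional
sub-pixel refinement) gives a displacement vector per grid point and a
vector field per frame pair.  Downstream, the package computes:

* **heatmaps** — average displacement magnitude per point, per emotion, per
  participant, and composites across participants;
* **similarity matrices** — all pairwise frame similarities over the happy
  and sad viewing blocks, with a within- vs cross-emotion quadrant t-test;
* **embeddings** — pooled 2-D PCA of flattened displacement fields with the
  explained-variance spectrum, per-participant emotion means, and temporal
  magnitude profiles;
* **classifiers** — multiclass sparse (ℓ1) logistic regression and an MLP on
  flattened fields, and a 3-D convolutional network on stacks of adjacent
  displacement-magnitude lattices, all evaluated leave-participants-out with
  row-normalized confusion matrices;
* **synthetic cohorts** — speckle faces deformed by mouth-corner (happy) and
  brow (sad) Gaussian lobes ramping over each viewing block, with exact
  analytic ground truth and bit-reproducible seeding.

See `docs/methods.md` for the model details, parameter defaults, numerical
choices, and limitations.

## Worked example

```python
import numpy as np
from discmotion.synthetic import (SyntheticCohortConfig, generate_cohort,
                                  cohort_grid, region_masks)
from discmotion.session import StimulusSchedule, compute_session_fields
from discmotion.heatmaps import participant_heatmap, top_decile_mass_fraction
from discmotion.similarity import build_matrix, quadrant_test

schedule = StimulusSchedule(
    (("neutral", 4), ("happy", 20), ("neutral", 4), ("sad", 20), ("neutral", 4))
)
config = SyntheticCohortConfig(n_participants=2, schedule=schedule, seed=42)
syn = generate_cohort(config)[0]
grid = cohort_grid(config)
compute_session_fields(syn.session, grid, subpixel=True)
sess = syn.session

late = max(i for i in sess.fields if sess.frames[i].label == "happy")
fld = sess.fields[late]
print(f"late happy frame {late}: mean |d| = {np.nanmean(fld.magnitude):.3f} px, "
      f"max |d| = {np.nanmax(fld.magnitude):.3f} px")

truth = syn.truths[late].at_points(fld.points)
est = np.column_stack([fld.u[fld.valid], fld.v[fld.valid]])
print(f"recovery error vs ground truth: MAE = {np.abs(est - truth).mean():.3f} px")

happy = [sess.fields[i] for i in sorted(sess.fields)
         if sess.frames[i].label == "happy"]
hm = participant_heatmap(happy, "happy", sess.participant_id)
frac = top_decile_mass_fraction(hm, region_masks(config)["mouth"])
print(f"happy heatmap: {100*frac:.0f}% of top-decile mass in the mouth region")

emo = [f for f in sess.frames if f.label == "happy"] + \
      [f for f in sess.frames if f.label == "sad"]
res = quadrant_test(build_matrix(emo, grid))
print(f"similarity quadrants: within = {res.within_mean:.4f}, "
      f"cross = {res.cross_mean:.4f}, t = {res.statistic:.1f}, p = {res.pvalue:.2e}")
```

Output:

```
late happy frame 23: mean |d| = 0.836 px, max |d| = 3.615 px
recovery error vs ground truth: MAE = 0.144 px
happy heatmap: 100% of top-decile mass in the mouth region
similarity quadrants: within = 0.9965, cross = 0.9872, t = 28.6, p = 5.97e-114
```

Reading it: by the end of the happy block the face has deformed by up to
~3.6 px at the mouth corners (lattice mean 0.84 px — invisible in the raw
frames), DISC recovers the known deformation to 0.14 px mean absolute error,
the average-motion heatmap localizes entirely to the mouth region, and
frames within an emotion block are measurably more similar to each other
than to frames of the other emotion.

## Command line

The same pipeline is scriptable from a shell; stages are restartable from
each other's artifacts (PNG frame stacks, CSV manifests/fields/matrices,
JSON sidecars carrying the producing config and seed):

```bash
discmotion simulate cohort/ --seed 42 --n-participants 10
discmotion track cohort/ --subset-size 41 --step 16 --search-radius 12
discmotion heatmap cohort/ out/heatmaps
discmotion simmatrix cohort/ out/similarity
discmotion embed cohort/ out/embedding
discmotion report cohort/ out/ --models mslr,mlp,cnn3d
```

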