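# comflow

Quantitative segmental wall-motion analysis for echocardiogram-like
image sequences, built around a **c**onfidence-**o**ptimized
**m**ultiresolution optical **flow** estimator.

Echocardiography is the workhorse for assessing regional left-ventricular
function, but reading wall motion off low-quality B-mode loops is
subjective. `comflow` is aimed at researchers and engineers building
quantitative wall-motion pipelines: it estimates dense myocardial motion
between frames, decomposes it into radial and circumferential components
per wall segment, tracks each segment's region of interest (ROI) through
the cardiac cycle, and grades the resulting displacement curves on the
clinical 0–3 scale. A ground-truth phantom simulator generates all test
data, so every stage can be validated against known motion.

## The method

Two frames `I1, I2` are placed on an exponential resolution pyramid
(coarsest level 30% of the original size by default). Starting from zero
flow at the top, each level upsamples the accumulated flow `(u, v)`,
warps `I2` toward `I1` by it, solves a linearized Horn–Schunck-type
energy for the increment `(du, dv)`,

    E = Σ (Ix·du + Iy·dv + It)² + α(|∇(u+du)|² + |∇(v+dv)|²),

and accumulates the increment weighted by a per-pixel confidence map
`s ∈ [0, 1]`:

    u ← u + s⊙du,  v ← v + s⊙dv.

`s` is the min–max-normalized level-1 wavelet approximation
reconstruction of the level's first frame — a proxy for local image
information that downweights acoustic shadows and dropout, where
high-resolution corrections are unreliable, while keeping the flow
interpolated from coarser levels. Motion vectors over each wall segment
are then projected onto the segment's circumferential tangent
`t_i = (v_i−v_{i−1})/‖·‖ + (v_{i+1}−v_i)/‖·‖` (normalized) and inward
radial normal, and segment ROIs are advected frame-to-frame along the
flow so displacement is always averaged over actual myocardium.

See `docs/methods.md` for the full model description, parameter
defaults, and limitations.

## Worked example

```python
import numpy as np
from scipy import ndimage

from comflow import phantom, com_flow, rmse, angular_error
from comflow.wall_geometry import split_six, subdivide
from comflow.tracking_curves import track_sequence

# 1. simulate a contracting ventricular wall with known motion and a
#    0.8-attenuation acoustic shadow over the right limb
pair, p, _ = phantom.reference_affine_pair(shadow="comoving")

# 2. estimate dense motion with the confidence-weighted pyramid
flow = com_flow(pair.frame1, pair.frame2)

roi = ndimage.binary_erosion(pair.roi, iterations=1)
print(f"RMSE {rmse(flow, pair.gt_flow, roi):.3f} px, "
      f"AE {angular_error(flow, pair.gt_flow, roi):.3f} deg "
      f"over {roi.sum()} wall pixels")

# 3. segmental displacement curves over a simulated 12-frame cycle
contour = phantom.make_u_contour(p)
segments = subdivide(split_six(contour), contour)
seq, gt_flows = phantom.synth_cycle(p, 12, 2.0, -2.0, 1.0, mm_per_px=0.5)
curves = track_sequence(seq, segments, gt_flows)
for c in curves[:3]:
    print(f"segment {c.label}: peak {c.peak_mm:+.2f} mm -> grade {c.grade}")
```

Output:

```
RMSE 0.209 px, AE 2.589 deg over 8032 wall pixels
segment 1-upper: peak +0.99 mm -> grade 2
segment 1-lower: peak +0.99 mm -> grade 2
segment 2-upper: peak +0.99 mm -> grade 2
```

The flow recovers the prescribed (±2, +1) px wall motion to ≈0.2 px RMSE
over the wall despite the shadow; the curves peak at the prescribed 2 px
(1 mm at 0.5 mm/px — graded 2, "motion disappearance", because the
simulated excursion is far below a healthy wall's).

A command-line interface wraps the same pipeline:

```bash
comflow simulate --out-dir sim --n-frames 12 --shadow
comflow flow --frames sim/frames.tif --out est.flo
comflow evaluate --est est.flo --gt sim/gt_flow_000.flo --roi sim/wall_mask.png
comflow compare --pair-dir sim
```

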