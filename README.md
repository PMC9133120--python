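# atlasmorph

Atlas-based volumetric phenotyping at desk scale: registration of specimen
micro-CT volumes to a population atlas, propagation of landmarks and
segmentations through the recovered transforms, geometric morphometrics,
landmark quality control, neural landmark correction, and
Jacobian-determinant voxel-based morphometry.

## Who this is for

High-throughput morphometry of model organisms (the motivating case is
mouse embryo and adult cranium micro-CT) replaces manual landmarking with
*label propagation*: every specimen is registered to a stage-specific
average atlas that carries a curated dense landmark configuration and
anatomical segmentations, and those labels are mapped back through the
inverse of each specimen's transform. `atlasmorph` implements that whole
pipeline as an importable Python library, exercisable end-to-end on
synthetic phantom volumes with exact ground truth — no multi-gigabyte scan
archive required to develop, test, or teach against.

## The core machinery

- **Registration** maximizes the uncentered normalized cross-correlation
  `NCC(I, J) = Σ I·J / √(Σ I² · Σ J²)` over the voxel domain, first with a
  coarse-to-fine 12-parameter affine (Powell direction-set search), then
  with a Gaussian-regularized, compositively-accumulated NCC-gradient
  deformation field (demons-style) with per-step folding checks
  (min det J > 0).
- **Propagation**: composite transforms map atlas world coordinates to each
  specimen; landmarks go through the composite directly, label volumes are
  resampled (nearest-neighbour) through the fixed-point-inverted composite.
- **Morphometrics**: generalized Procrustes analysis, Procrustes distance,
  3-D thin-plate splines (kernel `U(r) = r`) with bending energy,
  semi-landmark patch interpolation and tangent-constrained sliding, shape
  PCA, allometry regression on log centroid size.
- **QC**: the `RMSE = √( Σ_ℓ (1/n) Σ_I ‖x_ℓ − x̂_ℓ‖² )` landmark error, a
  cubic regression of per-specimen RMSE on registration cross-correlation
  (flagging cc < 0.90), Procrustes-distance outliers by the
  `Q3 + 1.5·IQR` rule, and PC1-extreme screening.
- **Optimizer**: a residual feedforward network trained on paired
  automated/manual configurations in a shared Procrustes frame, correcting
  systematic registration bias on held-out specimens.
- **VBM**: Jacobian-determinant maps of deformation fields (det J = 1 means
  no volume change), composite-form determinants, and voxel-wise group
  tests with Benjamini–Hochberg FDR control inside an anatomical mask.

## Worked example

```python
import numpy as np
from atlasmorph.phantom import PerturbationSpec, make_population
from atlasmorph.preprocess import background_threshold, minmax_normalize
from atlasmorph.propagate import dice, propagate_landmarks, propagate_segmentation
from atlasmorph.register import register_pair

def prep(v):
    v = minmax_normalize(v)
    v, _ = background_threshold(v, dilation_radius=2)
    return v

atlas, atlas_lms, atlas_seg, specimens, _ = make_population(
    n=1, pert=PerturbationSpec(), seed=7)
sp = specimens[0]
res = register_pair(prep(sp.volume), prep(atlas), levels=3, iters_per_level=30)
lms = propagate_landmarks(atlas_lms, res.composite, sp.volume)
err = np.linalg.norm(lms.coords - sp.true_landmarks.coords, axis=1)
seg = propagate_segmentation(atlas_seg, res.composite, sp.volume)
```

Running this (it is `examples/02_register_and_propagate.py`) prints:

```
final NCC after registration: 0.9995 (1 = perfect alignment over the whole volume)
landmark recovery: median 0.50 voxels (0.050 mm), worst 1.17 voxels
Dice(head, label 1): 0.960
Dice(brain, label 2): 0.935
Dice(snout, label 3): 0.893
```

The NCC of 0.9995 says the warped specimen is almost indistinguishable from
the atlas; the propagated landmarks land within half a voxel (median) of
their known true positions; and the propagated segmentation overlaps the
true one with Dice above 0.9 for the major structures. The other scripts in
`examples/` walk through phantom generation, morphometrics, QC, the
landmark-correction network, and voxel-based morphometry the same way.

A thin CLI wraps the same functions for shell use
(`atlasmorph phantom|preprocess|atlas|register|propagate|morpho|qc|optimize|vbm|plan`);
`atlasmorph plan --stage atlas` enumerates the n·(n−1) pairwise affine
registration jobs an atlas build schedules, without executing them.

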