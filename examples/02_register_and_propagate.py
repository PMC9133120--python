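"""Register a specimen to the atlas and propagate labels back.

The pipeline core: preprocess (scale to [0,1], zero the background),
affine + demons-style non-linear registration driven by uncentered NCC,
then map atlas landmarks through the recovered composite transform and
resample the atlas segmentation through its inverse. Ground truth from the
phantom generator tells us exactly how well each step did.
"""

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
    n=1, pert=PerturbationSpec(), seed=7
)
sp = specimens[0]

res = register_pair(prep(sp.volume), prep(atlas), levels=3, iters_per_level=30)
print(f"final NCC after registration: {res.final_ncc:.4f} "
      "(1 = perfect alignment over the whole volume)")

lms = propagate_landmarks(atlas_lms, res.composite, sp.volume,
                          specimen_id=sp.specimen_id)
err = np.linalg.norm(lms.coords - sp.true_landmarks.coords, axis=1)
step = min(atlas.steps)
print(f"landmark recovery: median {np.median(err)/step:.2f} voxels "
      f"({np.median(err):.3f} mm), worst {err.max()/step:.2f} voxels")

seg = propagate_segmentation(atlas_seg, res.composite, sp.volume)
for label, name in [(1, "head"), (2, "brain"), (3, "snout")]:
    print(f"Dice({name}, label {label}): "
          f"{dice(seg, sp.segmentation, label):.3f}")
# Landmark errors well under 1.5 voxels and Dice above 0.9 for the major
# structures mean the recovered transform is accurate enough for the
# downstream morphometrics to treat propagated labels as measurements.
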