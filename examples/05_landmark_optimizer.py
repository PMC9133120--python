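"""Train the landmark-correction network on systematically biased data.

Automated landmarks inherit smooth, shape-dependent error where a specimen
deviates from the atlas. Given paired automated/manual configurations in a
shared Procrustes frame, a small residual MLP learns that bias and removes
it from held-out specimens.
"""

import numpy as np

from atlasmorph.morpho import ShapeArray
from atlasmorph.optimize import (
    apply_optimizer,
    load_model,
    prepare_training,
    save_model,
    train_optimizer,
)

rng = np.random.default_rng(11)
n, p = 400, 22
base = rng.uniform(0, 5, (p, 3))
manual = base + rng.normal(0, 0.15, (n, p, 3))
bias = 0.3 * np.stack(
    [np.sin(manual[..., 0]), np.cos(manual[..., 1]), np.sin(manual[..., 2] + 1)],
    axis=-1,
) / np.sqrt(3)
auto = manual + bias + rng.normal(0, 0.05, (n, p, 3))

ids = [f"s{i}" for i in range(n)]
labels = [f"lm{j}" for j in range(p)]
ts = prepare_training(ShapeArray(ids, labels, auto),
                      ShapeArray(ids, labels, manual),
                      opt_indices=range(p), seed=11)
model, metrics = train_optimizer(ts, seed=11)

before, after = metrics["test_rmse_before"], metrics["test_rmse_after"]
print(f"held-out RMSE before correction: {before:.5f} (GPA frame units)")
print(f"held-out RMSE after correction:  {after:.5f}")
print(f"ratio: {after / before:.3f} (smaller is better; < 0.6 means the "
      "network removed most of the removable systematic bias)")

path = save_model(model, "scratch_optimizer_model.json")
reloaded = load_model(path)
corrected = apply_optimizer(reloaded, ShapeArray(ids, labels, auto))
print(f"model round-trips through JSON; corrected stack shape "
      f"{corrected.coords.shape}")
import os

os.remove(path)
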