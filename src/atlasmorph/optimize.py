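"""Feedforward-network correction of automated landmark configurations.

Registration-derived landmarks carry systematic, shape-dependent error in
regions where a specimen deviates strongly from the atlas.  Given a set of
specimens with both automated and manual landmarks, a small feedforward
network is trained to predict the residual between them in a shared
Procrustes frame; applying the trained network to new automated
configurations moves them toward where the manual observer would have
placed them.

The network is a plain numpy MLP (residual form: output = input +
denormalized correction) trained with full-batch gradient descent with
momentum and early stopping on a validation split.  Everything is
deterministic for a given seed, and models serialize to portable JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .morpho import ShapeArray, align_to, gpa


@dataclass
class TrainingSet:
    auto: np.ndarray  # (n, d) features, d = 3 * p_opt
    manual: np.ndarray  # (n, d) targets in the same frame
    ids: list[str]
    opt_indices: list[int]
    mean_shape: np.ndarray  # manual GPA mean (full p x 3)
    norm_mean: np.ndarray  # (d,)
    norm_scale: np.ndarray  # (d,)
    train_ids: list[str]
    test_ids: list[str]


def prepare_training(
    auto: ShapeArray,
    manual: ShapeArray,
    opt_indices,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> TrainingSet:
    """GPA-align manual shapes, superimpose each auto configuration onto its
    manual counterpart, restrict to the optimizable landmark subset, and
    compute normalization statistics from the training portion only.
    """
    if auto.ids != manual.ids:
        raise ValueError("auto and manual specimen ids do not match")
    opt_indices = sorted(int(i) for i in opt_indices)
    if not opt_indices:
        raise ValueError("empty optimizable-landmark index set")
    if opt_indices[0] < 0 or opt_indices[-1] >= manual.p:
        raise ValueError("opt_indices out of range")
    pr = gpa(manual, scale=True)
    man_aligned = pr.aligned.coords
    auto_aligned = np.stack([
        align_to(man_aligned[i], auto.coords[i]) for i in range(auto.n)
    ])
    sub = np.asarray(opt_indices)
    A = auto_aligned[:, sub].reshape(auto.n, -1)
    M = man_aligned[:, sub].reshape(manual.n, -1)

    rng = np.random.default_rng(seed)
    order = rng.permutation(auto.n)
    n_train = max(1, int(round(train_fraction * auto.n)))
    train_idx, test_idx = order[:n_train], order[n_train:]
    mu = A[train_idx].mean(0)
    sd = A[train_idx].std(0)
    sd = np.where(sd < 1e-8, 1.0, sd)
    return TrainingSet(
        A, M, list(auto.ids), opt_indices, pr.mean_shape, mu, sd,
        [auto.ids[i] for i in train_idx], [auto.ids[i] for i in test_idx],
    )


@dataclass
class OptimizerModel:
    layer_sizes: list[int]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    norm_mean: np.ndarray
    norm_scale: np.ndarray
    opt_indices: list[int]
    metadata: dict = field(default_factory=dict)

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Corrected feature vectors (residual form)."""
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if X.shape[1] != self.layer_sizes[0]:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match model "
                f"input {self.layer_sizes[0]}"
            )
        h = (X - self.norm_mean) / self.norm_scale
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.tanh(h @ W + b)
        delta = h @ self.weights[-1] + self.biases[-1]
        return X + delta * self.norm_scale


def _forward(params, X):
    acts = [X]
    h = X
    weights, biases = params
    for W, b in zip(weights[:-1], biases[:-1]):
        h = np.tanh(h @ W + b)
        acts.append(h)
    out = h @ weights[-1] + biases[-1]
    return out, acts


def _backward(params, acts, grad_out):
    weights, _ = params
    gW, gb = [], []
    g = grad_out
    for li in range(len(weights) - 1, -1, -1):
        gW.insert(0, acts[li].T @ g)
        gb.insert(0, g.sum(0))
        if li > 0:
            g = (g @ weights[li].T) * (1.0 - acts[li] ** 2)
    return gW, gb


def train_optimizer(
    ts: TrainingSet,
    hidden: tuple[int, ...] = (64, 64),
    epochs: int = 2000,
    learning_rate: float = 3e-3,
    momentum: float = 0.9,
    seed: int = 0,
    patience: int = 200,
    min_pairs: int = 50,
) -> tuple[OptimizerModel, dict]:
    """Train the correction network on a prepared training set.

    Minimizes the mean squared coordinate error between corrected automated
    and manual configurations in the shared GPA frame (equivalently the
    squared Procrustes-aligned RMSE).  Early stopping monitors the loss on
    the held-out split; metrics report held-out RMSE before and after
    correction.  Deterministic given ``seed``.
    """
    tr = [ts.ids.index(i) for i in ts.train_ids]
    te = [ts.ids.index(i) for i in ts.test_ids]
    if len(tr) < min_pairs:
        raise ValueError(
            f"need at least {min_pairs} training pairs, got {len(tr)}"
        )
    Xtr = (ts.auto[tr] - ts.norm_mean) / ts.norm_scale
    Ytr = (ts.manual[tr] - ts.auto[tr]) / ts.norm_scale  # residual targets
    Xte = (ts.auto[te] - ts.norm_mean) / ts.norm_scale if te else None
    Yte = (ts.manual[te] - ts.auto[te]) / ts.norm_scale if te else None

    d = ts.auto.shape[1]
    sizes = [d, *hidden, d]
    rng = np.random.default_rng(seed)
    weights = [
        rng.normal(0, np.sqrt(1.0 / sizes[i]), (sizes[i], sizes[i + 1]))
        for i in range(len(sizes) - 1)
    ]
    weights[-1][:] = 0.0  # zero-init output layer: the net starts as identity
    biases = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
    vW = [np.zeros_like(W) for W in weights]
    vb = [np.zeros_like(b) for b in biases]

    def loss_of(X, Y):
        out, _ = _forward((weights, biases), X)
        return float(np.mean((out - Y) ** 2))

    best_val = np.inf
    best = None
    wait = 0
    curve = []
    n = len(tr)
    for epoch in range(epochs):
        out, acts = _forward((weights, biases), Xtr)
        err = out - Ytr
        loss = float(np.mean(err**2))
        if not np.isfinite(loss):
            raise RuntimeError(
                f"divergent training loss at epoch {epoch}; last finite epoch "
                f"{epoch - 1} (loss {curve[-1]:.4g} if any)"
            )
        gW, gb = _backward((weights, biases), acts, 2.0 * err / n)
        for i in range(len(weights)):
            vW[i] = momentum * vW[i] - learning_rate * gW[i]
            vb[i] = momentum * vb[i] - learning_rate * gb[i]
            weights[i] += vW[i]
            biases[i] += vb[i]
        val = loss_of(Xte, Yte) if te else loss
        curve.append(loss)
        if val < best_val - 1e-12:
            best_val = val
            best = ([W.copy() for W in weights], [b.copy() for b in biases])
            wait = 0
        else:
            wait += 1
            if wait > patience:
                break
    if best is not None:
        weights, biases = best

    model = OptimizerModel(
        sizes, weights, biases, ts.norm_mean, ts.norm_scale, list(ts.opt_indices),
        metadata={
            "seed": seed, "epochs_run": len(curve), "hidden": list(hidden),
            "learning_rate": learning_rate, "momentum": momentum,
            "train_ids": ts.train_ids, "test_ids": ts.test_ids,
            "loss_curve_tail": curve[-5:],
        },
    )

    def frame_rmse(F, A, M):
        corrected = model.predict(A)
        pre = np.sqrt(np.mean((A - M) ** 2))
        post = np.sqrt(np.mean((corrected - M) ** 2))
        return float(pre), float(post)

    metrics = {}
    metrics["train_rmse_before"], metrics["train_rmse_after"] = frame_rmse(
        None, ts.auto[tr], ts.manual[tr]
    )
    if te:
        metrics["test_rmse_before"], metrics["test_rmse_after"] = frame_rmse(
            None, ts.auto[te], ts.manual[te]
        )
    return model, metrics


def apply_optimizer(model: OptimizerModel, auto) -> np.ndarray | ShapeArray:
    """Correct automated configurations with a trained model.

    Accepts either flat feature rows (n x 3*p_opt) or a full ShapeArray,
    in the same superimposition frame used for training; non-optimizable
    landmarks pass through unchanged.
    """
    if isinstance(auto, ShapeArray):
        sub = np.asarray(model.opt_indices)
        if sub.max() >= auto.p:
            raise ValueError("shape has fewer landmarks than the model expects")
        feats = auto.coords[:, sub].reshape(auto.n, -1)
        corrected = model.predict(feats).reshape(auto.n, len(sub), 3)
        out = auto.coords.copy()
        out[:, sub] = corrected
        return ShapeArray(list(auto.ids), list(auto.labels), out)
    return model.predict(np.asarray(auto, dtype=float))


def save_model(model: OptimizerModel, path) -> Path:
    """Serialize to self-describing JSON (text, portable)."""
    path = Path(path)
    doc = {
        "format": "atlasmorph-optimizer-v1",
        "layer_sizes": model.layer_sizes,
        "weights": [W.tolist() for W in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "norm_mean": model.norm_mean.tolist(),
        "norm_scale": model.norm_scale.tolist(),
        "opt_indices": model.opt_indices,
        "metadata": model.metadata,
    }
    path.write_text(json.dumps(doc))
    return path


def load_model(path) -> OptimizerModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such model file: {path}")
    doc = json.loads(path.read_text())
    if doc.get("format") != "atlasmorph-optimizer-v1":
        raise ValueError("unrecognized model file format/version")
    sizes = doc["layer_sizes"]
    weights = [np.asarray(W) for W in doc["weights"]]
    biases = [np.asarray(b) for b in doc["biases"]]
    for i, W in enumerate(weights):
        if W.shape != (sizes[i], sizes[i + 1]):
            raise ValueError("corrupted model file: weight shapes do not "
                             "match declared layer sizes")
    return OptimizerModel(
        sizes, weights, biases, np.asarray(doc["norm_mean"]),
        np.asarray(doc["norm_scale"]), list(doc["opt_indices"]), doc["metadata"]
    )
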