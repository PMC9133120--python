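"""Intensity preprocessing and rigid initialization.

Covers the steps applied to every scan before registration: min-max
normalization, background thresholding with dilation masking, homomorphic
bias-field reduction, landmark-based rigid alignment into the atlas space,
and resampling onto a target grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter, map_coordinates
from skimage.filters import threshold_otsu
from skimage.morphology import ball

from .volio import AffineTransform, CompositeTransform, VolumeGrid


@dataclass
class RigidFit:
    """Rotation+translation least-squares fit with its RMS residual (mm)."""

    transform: AffineTransform
    rms_residual: float

    def __post_init__(self) -> None:
        r = self.transform.linear
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8) or np.linalg.det(r) < 0:
            raise ValueError("rigid fit linear block must be a proper rotation")


def minmax_normalize(v: VolumeGrid) -> VolumeGrid:
    """Scale intensities to [0, 1]: (v - min) / (max - min)."""
    lo, hi = float(v.values.min()), float(v.values.max())
    if hi <= lo:
        raise ValueError("degenerate intensity range: constant image")
    return v.like((v.values - lo) / (hi - lo))


def background_threshold(
    v: VolumeGrid, dilation_radius: int = 2, threshold: float | None = None
) -> tuple[VolumeGrid, float]:
    """Zero everything outside the dilated above-threshold anatomy mask.

    When ``threshold`` is None an Otsu estimate of the lower anatomical
    density bound is used.  Voxels above the threshold, and voxels within
    ``dilation_radius`` voxels of one (ball structuring element), keep their
    values; all others are set to exactly 0.  Returns the masked volume and
    the threshold used.
    """
    if dilation_radius < 0:
        raise ValueError("dilation radius must be >= 0")
    thr = float(threshold) if threshold is not None else float(threshold_otsu(v.values))
    fg = v.values > thr
    if not np.any(fg):
        raise ValueError(f"empty foreground: threshold {thr} exceeds the image maximum")
    if dilation_radius > 0:
        fg = binary_dilation(fg, structure=ball(dilation_radius))
    out = np.where(fg, v.values, 0.0)
    return v.like(out), thr


def bias_correct(v: VolumeGrid, smoothing_scale: float = 2.0) -> VolumeGrid:
    """Homomorphic reduction of multiplicative low-frequency inhomogeneity.

    Divides the image by a Gaussian low-pass estimate of the bias surface at
    ``smoothing_scale`` (mm) and rescales to preserve the foreground mean.
    This is a deliberately simple stand-in for full N3-style correction: it
    removes slowly-varying gain, which is what the downstream NCC-driven
    registration needs, and nothing else.
    """
    if smoothing_scale <= 0:
        raise ValueError("smoothing_scale must be positive (mm)")
    vals = v.values.astype(float)
    offset = 0.0
    mn = vals.min()
    if mn <= 0:
        offset = -mn + 1e-3 * max(float(np.ptp(vals)), 1.0)
        vals = vals + offset
    sigma_vox = [smoothing_scale / s for s in v.steps]
    low = gaussian_filter(vals, sigma_vox)
    corrected = vals / np.maximum(low, 1e-12)
    corrected *= vals.mean() / corrected.mean()
    return v.like(corrected - offset)


def rigid_from_landmarks(moving, fixed) -> RigidFit:
    """Least-squares rigid (rotation+translation) alignment of paired points.

    The closed-form orthogonal-Procrustes (Kabsch) solution with a
    determinant correction forbidding reflections.  Accepts LandmarkSets or
    plain p x 3 arrays; minimizes sum ||T(moving_i) - fixed_i||^2.
    """
    A = np.asarray(getattr(moving, "coords", moving), dtype=float)
    B = np.asarray(getattr(fixed, "coords", fixed), dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("moving and fixed must be matched p x 3 configurations")
    p = A.shape[0]
    if p < 3:
        raise ValueError("rigid fit needs at least 3 landmark pairs")
    ca, cb = A.mean(0), B.mean(0)
    A0, B0 = A - ca, B - cb
    # collinear points leave a rotation axis unconstrained
    if np.linalg.matrix_rank(A0, tol=1e-9 * max(1.0, np.abs(A0).max())) < 2:
        raise ValueError("degenerate configuration: landmarks are collinear")
    H = A0.T @ B0
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    T = AffineTransform.from_linear(R, t)
    resid = T.apply(A) - B
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return RigidFit(T, rms)


def resample_to_grid(
    v: VolumeGrid,
    target: VolumeGrid,
    T: AffineTransform | CompositeTransform | None = None,
    interpolation: str = "trilinear",
) -> VolumeGrid:
    """Sample ``v`` on the target grid, pulling values through ``T``.

    For each target voxel center x the output takes ``v(T(x))`` — i.e. ``T``
    maps target-space world points into the source volume's world space
    (pass ``T.inverse()`` / an inverted composite if you hold the forward
    map).  ``interpolation`` is "trilinear" for images and "nearest" for
    label volumes.
    """
    if interpolation not in ("trilinear", "nearest"):
        raise ValueError(f"unsupported interpolation {interpolation!r}")
    xs, ys, zs = target.world_coords()
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    if T is not None:
        pts = T.apply(pts)
    idx = (pts - np.asarray(v.starts)) / np.asarray(v.steps)
    order = 1 if interpolation == "trilinear" else 0
    vals = map_coordinates(
        v.values.astype(float), idx.T, order=order, mode="constant", cval=0.0
    )
    out = vals.reshape(target.lengths)
    if interpolation == "nearest" and np.issubdtype(v.values.dtype, np.integer):
        out = np.rint(out).astype(v.values.dtype)
    return VolumeGrid(out, target.steps, target.starts)
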