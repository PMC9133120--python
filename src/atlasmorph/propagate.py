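"""Transform composition/inversion and atlas label propagation.

Direction contract: registration stores transforms mapping *atlas* world
coordinates to *specimen* world coordinates.  Landmark propagation applies
them directly to atlas landmark coordinates; volume propagation onto the
specimen grid pulls values back through the inverted composite.
"""

from __future__ import annotations

import numpy as np

from .preprocess import resample_to_grid
from .volio import (
    AffineTransform,
    CompositeTransform,
    DeformationField,
    LandmarkSet,
    VolumeGrid,
)


def invert_field(f: DeformationField, tol: float = 0.01, max_iter: int = 50) -> DeformationField:
    """Fixed-point inverse of a diffeomorphic displacement field.

    Solves v(x) = -u(x + v(x)) by damped iteration; the damping factor is
    set adaptively from the field's maximum displacement-gradient norm so
    the scheme stays contractive for steep (but still fold-free) fields.
    After convergence, composing the field with its inverse moves interior
    points by less than ``tol`` mm.  Raises on non-convergence.
    """
    grad_norm = 0.0
    for d in range(3):
        g = np.gradient(f.displacements[..., d], *f.steps)
        grad_norm = max(grad_norm, float(np.max(np.sqrt(sum(gg**2 for gg in g)))))
    alpha = min(1.0, 1.0 / (1.0 + grad_norm))
    xs, ys, zs = np.meshgrid(
        *(f.starts[a] + np.arange(f.lengths[a]) * f.steps[a] for a in range(3)),
        indexing="ij",
    )
    pts = np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()])
    v = np.zeros_like(pts)
    for _ in range(max_iter):
        v_new = -f.sample(pts + v)
        delta = np.max(np.linalg.norm(v_new - v, axis=1))
        v = v + alpha * (v_new - v)
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"field inversion did not converge within {max_iter} iterations "
            f"(last update {delta:.4g} mm, tol {tol} mm, damping {alpha:.2f})"
        )
    return DeformationField(v.reshape(f.lengths + (3,)), f.steps, f.starts)


def invert_composite(T: CompositeTransform, tol: float = 0.01,
                     max_iter: int = 50) -> CompositeTransform:
    """Invert a composite: reversed stage order, each stage inverted."""
    inv_stages = []
    for stage in reversed(T.stages):
        if isinstance(stage, AffineTransform):
            inv_stages.append(stage.inverse())
        else:
            inv_stages.append(invert_field(stage, tol, max_iter))
    direction = (
        "specimen_to_atlas" if T.direction == "atlas_to_specimen" else "atlas_to_specimen"
    )
    return CompositeTransform(inv_stages, direction)


def compose(stages, direction: str = "atlas_to_specimen") -> CompositeTransform:
    """Build a CompositeTransform from an ordered stage list."""
    flat = []
    for s in stages:
        if isinstance(s, CompositeTransform):
            flat.extend(s.stages)
        else:
            flat.append(s)
    return CompositeTransform(flat, direction)


def apply_to_points(T, points: np.ndarray) -> np.ndarray:
    """Map world points through an affine, field, or composite transform."""
    return T.apply(np.asarray(points, dtype=float))


def apply_to_volume(T, v: VolumeGrid, target: VolumeGrid,
                    interpolation: str = "trilinear") -> VolumeGrid:
    """Resample ``v`` on ``target``'s grid, reading ``v(T(x))`` at each
    target voxel center x.  ``T`` must map target-space points into ``v``'s
    space (for atlas->specimen composites, pass the inverted composite when
    resampling atlas labels onto the specimen grid)."""
    return resample_to_grid(v, target, T, interpolation)


def propagate_landmarks(atlas_lms: LandmarkSet, T,
                        specimen_grid: VolumeGrid | None = None,
                        specimen_id: str | None = None) -> LandmarkSet:
    """Map atlas landmarks into the specimen's rigid space.

    Landmarks falling outside the specimen grid bounding box (when given)
    are kept but flagged in ``result.flags['out_of_bounds']`` so downstream
    QC can see them.
    """
    coords = apply_to_points(T, atlas_lms.coords)
    out = LandmarkSet(
        specimen_id or atlas_lms.specimen_id, list(atlas_lms.labels), coords
    )
    if specimen_grid is not None:
        lo = np.asarray(specimen_grid.starts)
        hi = specimen_grid.extent
        oob = np.any((coords < lo) | (coords > hi), axis=1)
        if np.any(oob):
            out.flags["out_of_bounds"] = [
                l for l, bad in zip(out.labels, oob) if bad
            ]
    return out


def propagate_segmentation(atlas_seg: VolumeGrid, T, target: VolumeGrid,
                           tol: float = 0.01, max_iter: int = 100) -> VolumeGrid:
    """Propagate an integer atlas label volume to the specimen grid.

    Nearest-neighbour resampling through the inverted atlas->specimen
    composite; output labels are a subset of the input labels plus 0.
    """
    if not np.allclose(atlas_seg.values, np.rint(atlas_seg.values)):
        raise ValueError("atlas segmentation must be integer-valued")
    seg = VolumeGrid(np.rint(atlas_seg.values).astype(int),
                     atlas_seg.steps, atlas_seg.starts)
    if isinstance(T, AffineTransform):
        T_inv = T.inverse()
    elif isinstance(T, CompositeTransform):
        T_inv = invert_composite(T, tol=tol, max_iter=max_iter)
    elif isinstance(T, DeformationField):
        T_inv = invert_field(T, tol=tol, max_iter=max_iter)
    else:
        raise TypeError(f"unsupported transform type: {type(T).__name__}")
    return apply_to_volume(T_inv, seg, target, "nearest")


def dice(a: VolumeGrid, b: VolumeGrid, label: int) -> float:
    """Dice overlap of one integer label between two label volumes."""
    ma, mb = a.values == label, b.values == label
    denom = ma.sum() + mb.sum()
    if denom == 0:
        return float("nan")
    return 2.0 * np.logical_and(ma, mb).sum() / denom


def select_label(seg: VolumeGrid, label: int) -> VolumeGrid:
    """Binary mask volume of one rendering label (1=keep, 0=drop)."""
    return seg.like((seg.values == label).astype(int))
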