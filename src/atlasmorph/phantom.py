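"""Synthetic atlas and specimen populations with known ground truth.

The phantoms emulate stained micro-CT heads at desk scale: a handful of
smooth ellipsoidal components ("head", "brain", "snout") on a faint
background, with named landmarks at component surface poles and an integer
segmentation per component.  Specimens are derived from the atlas by a known
rigid mis-orientation composed with a smooth diffeomorphic warp, plus a
multiplicative low-frequency intensity bias and additive noise — the
acquisition nuisances the registration pipeline is built to undo.

Every specimen carries its exact ground-truth landmark positions and the
exact atlas-to-specimen composite transform, so downstream registration,
propagation, morphometrics and QC can all be validated without external
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .volio import (
    AffineTransform,
    CompositeTransform,
    DeformationField,
    LandmarkSet,
    VolumeGrid,
    write_landmark_csv,
    write_tag,
    write_volume,
    write_composite,
)


@dataclass
class Component:
    """One ellipsoidal phantom component."""

    name: str
    center: tuple[float, float, float]  # world mm
    radii: tuple[float, float, float]  # world mm
    intensity: float
    label: int  # positive segmentation integer

    def __post_init__(self) -> None:
        if self.label < 1:
            raise ValueError("segmentation labels must be positive integers")


@dataclass
class PhantomSpec:
    lengths: tuple[int, int, int] = (48, 48, 48)
    steps: tuple[float, float, float] = (0.1, 0.1, 0.1)
    starts: tuple[float, float, float] = (0.0, 0.0, 0.0)
    components: list[Component] = field(default_factory=list)
    anchors: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    background: float = 0.05
    edge_sigma_vox: float = 0.8  # smooth component edges so NCC gradients exist


@dataclass
class PerturbationSpec:
    """Ranges for the random specimen-generating perturbation."""

    rotation_deg: float = 6.0
    translation_mm: float = 0.2
    warp_amplitude_mm: float = 0.4
    warp_length_mm: float = 1.2
    bias_amplitude: float = 0.15
    noise_sd: float = 0.02
    background: float = 0.0  # additive offset emulating staining medium

    def __post_init__(self) -> None:
        for name in ("rotation_deg", "translation_mm", "warp_amplitude_mm",
                     "bias_amplitude", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def default_head_spec(lengths=(48, 48, 48), steps=(0.1, 0.1, 0.1)) -> PhantomSpec:
    """The default desk-scale "head" phantom: head + brain + snout."""
    ext = tuple((l - 1) * s for l, s in zip(lengths, steps))
    c = tuple(e / 2 for e in ext)
    head_r = (0.42 * ext[0], 0.36 * ext[1], 0.34 * ext[2])
    brain_c = (c[0] - 0.08 * ext[0], c[1], c[2] + 0.08 * ext[2])
    brain_r = (0.18 * ext[0], 0.16 * ext[1], 0.14 * ext[2])
    snout_c = (c[0] + 0.34 * ext[0], c[1], c[2] - 0.06 * ext[2])
    snout_r = (0.14 * ext[0], 0.10 * ext[1], 0.09 * ext[2])
    comps = [
        Component("head", c, head_r, 0.55, 1),
        Component("brain", brain_c, brain_r, 0.9, 2),
        Component("snout", snout_c, snout_r, 0.8, 3),
    ]
    anchors = {}
    # landmarks at the six poles of head and brain, plus the snout tip:
    for comp in comps[:2]:
        for ax, nm in enumerate("xyz"):
            for sgn, side in ((1, "plus"), (-1, "minus")):
                pt = list(comp.center)
                pt[ax] += sgn * comp.radii[ax]
                anchors[f"{comp.name}_{nm}_{side}"] = tuple(pt)
    tip = list(snout_c)
    tip[0] += snout_r[0]
    anchors["snout_tip"] = tuple(tip)
    return PhantomSpec(lengths, steps, (0.0, 0.0, 0.0), comps, anchors)


def _ellipsoid_distance(grid_coords, comp: Component) -> np.ndarray:
    """Normalized ellipsoid coordinate: <=1 inside."""
    xs, ys, zs = grid_coords
    q = np.zeros((len(xs), len(ys), len(zs)))
    for ax, coords in enumerate((xs, ys, zs)):
        shape = [1, 1, 1]
        shape[ax] = -1
        q = q + (((coords - comp.center[ax]) / comp.radii[ax]) ** 2).reshape(shape)
    return np.sqrt(q)


def make_atlas_phantom(spec: PhantomSpec) -> tuple[VolumeGrid, LandmarkSet, VolumeGrid]:
    """Render the phantom: intensity volume, landmarks, integer segmentation."""
    if not spec.components:
        raise ValueError("phantom spec has no components")
    probe = VolumeGrid(np.zeros(spec.lengths), spec.steps, spec.starts)
    lo, hi = np.asarray(spec.starts), probe.extent
    for comp in spec.components:
        cl = np.asarray(comp.center) - np.asarray(comp.radii)
        ch = np.asarray(comp.center) + np.asarray(comp.radii)
        if np.any(cl < lo - 1e-9) or np.any(ch > hi + 1e-9):
            raise ValueError(f"component {comp.name!r} extends outside the grid")
    coords = probe.world_coords()
    vol = np.full(spec.lengths, float(spec.background))
    seg = np.zeros(spec.lengths, dtype=int)
    for comp in spec.components:
        inside = _ellipsoid_distance(coords, comp) <= 1.0
        vol[inside] = comp.intensity
        seg[inside] = comp.label
    if spec.edge_sigma_vox > 0:
        vol = gaussian_filter(vol, spec.edge_sigma_vox)
    vol = (vol - vol.min()) / (vol.max() - vol.min())
    labels = sorted(spec.anchors)
    lms = LandmarkSet("atlas", labels, np.asarray([spec.anchors[l] for l in labels]))
    return probe.like(vol), lms, VolumeGrid(seg, spec.steps, spec.starts)


# ---------------------------------------------------------------------------
# perturbation
# ---------------------------------------------------------------------------

def _random_rigid(rng: np.random.Generator, pert: PerturbationSpec,
                  center: np.ndarray) -> AffineTransform:
    angles = np.deg2rad(rng.uniform(-pert.rotation_deg, pert.rotation_deg, 3))
    cx, cy, cz = np.cos(angles)
    sx, sy, sz = np.sin(angles)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    r = rz @ ry @ rx
    t = rng.uniform(-pert.translation_mm, pert.translation_mm, 3)
    # rotate about the grid center so the object stays inside the volume
    full_t = center - r @ center + t
    return AffineTransform.from_linear(r, full_t)


def _smooth_field(rng: np.random.Generator, grid: VolumeGrid,
                  amplitude_mm: float, length_mm: float,
                  max_halvings: int = 10) -> DeformationField:
    """Gaussian-filtered white-noise displacements scaled to a target
    amplitude, with the amplitude halved until min det J > 0.05."""
    from .vbm import jacobian_determinant

    sigma_vox = np.asarray([length_mm / s for s in grid.steps])
    if np.any(sigma_vox < 2.0):
        raise ValueError("warp correlation length must exceed 2 voxel steps")
    disp = np.empty(grid.lengths + (3,))
    for d in range(3):
        noise = rng.standard_normal(grid.lengths)
        disp[..., d] = gaussian_filter(noise, sigma_vox)
    peak = np.max(np.abs(disp))
    if peak > 0:
        disp *= amplitude_mm / peak
    field = DeformationField(disp, grid.steps, grid.starts)
    for _ in range(max_halvings):
        if amplitude_mm == 0 or jacobian_determinant(field).values.values.min() > 0.05:
            return field
        disp = disp / 2.0
        field = DeformationField(disp, grid.steps, grid.starts)
    raise RuntimeError("could not generate a fold-free warp after maximum rescaling")


def perturb_specimen(
    atlas: VolumeGrid,
    atlas_lms: LandmarkSet,
    atlas_seg: VolumeGrid,
    pert: PerturbationSpec,
    seed: int,
    specimen_id: str = "specimen",
) -> tuple[VolumeGrid, LandmarkSet, CompositeTransform, VolumeGrid]:
    """Generate one specimen: warped/biased/noisy volume plus ground truth.

    The true atlas-to-specimen mapping is ``T(x) = R(x + u(x))`` with R the
    random rigid transform and u the smooth random warp; landmarks are mapped
    exactly through T, while the image and segmentation are pulled back
    through the numerically inverted T.
    """
    from .propagate import apply_to_volume, invert_composite

    rng = np.random.default_rng(seed)
    center = (np.asarray(atlas.starts) + atlas.extent) / 2.0
    rigid = _random_rigid(rng, pert, center)
    warp = _smooth_field(rng, atlas, pert.warp_amplitude_mm, pert.warp_length_mm)
    T = CompositeTransform([warp, rigid], "atlas_to_specimen")

    true_lms = LandmarkSet(specimen_id, list(atlas_lms.labels), T.apply(atlas_lms.coords))

    if pert.warp_amplitude_mm == 0 and pert.rotation_deg == 0 and pert.translation_mm == 0:
        vol_vals = atlas.values.copy()
        seg_vals = atlas_seg.values.copy()
    else:
        T_inv = invert_composite(T, tol=1e-3, max_iter=100)
        vol_vals = apply_to_volume(T_inv, atlas, atlas, "trilinear").values
        seg_vals = apply_to_volume(T_inv, atlas_seg, atlas, "nearest").values

    if pert.bias_amplitude > 0:
        bias = _smooth_field(rng, atlas, 1.0, max(pert.warp_length_mm * 3, 1.0)
                             ).displacements[..., 0]
        bias = bias / max(np.max(np.abs(bias)), 1e-12)
        vol_vals = vol_vals * (1.0 + pert.bias_amplitude * bias)
    if pert.background > 0:
        vol_vals = vol_vals + pert.background
    if pert.noise_sd > 0:
        vol_vals = vol_vals + rng.normal(0, pert.noise_sd, vol_vals.shape)

    specimen = atlas.like(vol_vals)
    seg = VolumeGrid(np.rint(seg_vals).astype(int), atlas.steps, atlas.starts)
    return specimen, true_lms, T, seg


@dataclass
class Specimen:
    specimen_id: str
    volume: VolumeGrid
    true_landmarks: LandmarkSet
    true_transform: CompositeTransform
    segmentation: VolumeGrid
    group: str = "control"
    sex: str = "NA"


def make_population(
    n: int,
    pert: PerturbationSpec,
    seed: int,
    spec: PhantomSpec | None = None,
    group_effect: tuple[str, float] | None = None,
    mutant_fraction: float = 0.5,
) -> tuple[VolumeGrid, LandmarkSet, VolumeGrid, list[Specimen], pd.DataFrame]:
    """Generate an atlas plus ``n`` perturbed specimens with metadata.

    ``group_effect=(component_name, f)`` scales the radii of one component by
    ``f`` for the "mutant" half of the population (e.g. a 0.8x brain
    shrinkage), giving voxel-based and morphometric analyses a localized
    known signal.  Per-specimen seeds are derived deterministically from
    ``seed``.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    spec = spec or default_head_spec()
    atlas, atlas_lms, atlas_seg = make_atlas_phantom(spec)

    mutant_spec = None
    if group_effect is not None:
        comp_name, f = group_effect
        comps = []
        found = False
        for c in spec.components:
            if c.name == comp_name:
                comps.append(Component(c.name, c.center,
                                       tuple(r * f for r in c.radii), c.intensity, c.label))
                found = True
            else:
                comps.append(c)
        if not found:
            raise ValueError(f"no component named {comp_name!r}")
        anchors = dict(spec.anchors)
        for key in list(anchors):
            if key.startswith(comp_name + "_") or key == f"{comp_name}_tip":
                c = next(c for c in comps if c.name == comp_name)
                # recompute pole anchors for the scaled component
                for ax, nm in enumerate("xyz"):
                    for sgn, side in ((1, "plus"), (-1, "minus")):
                        k = f"{comp_name}_{nm}_{side}"
                        if k in anchors:
                            pt = list(c.center)
                            pt[ax] += sgn * c.radii[ax]
                            anchors[k] = tuple(pt)
        mutant_spec = PhantomSpec(spec.lengths, spec.steps, spec.starts, comps,
                                  anchors, spec.background, spec.edge_sigma_vox)

    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    specimens: list[Specimen] = []
    rows = []
    for i in range(n):
        sid = f"phantom_{i + 1:03d}"
        mutant = (
            group_effect is not None and n > 1 and i >= n - int(round(n * mutant_fraction))
        )
        if mutant:
            src_atlas, src_lms, src_seg = make_atlas_phantom(mutant_spec)
            group = "mutant"
        else:
            src_atlas, src_lms, src_seg = atlas, atlas_lms, atlas_seg
            group = "control"
        vol, lms, T, seg = perturb_specimen(
            src_atlas, src_lms, src_seg, pert, int(child_seeds[i]), sid
        )
        sex = "F" if (child_seeds[i] % 2) else "M"
        specimens.append(Specimen(sid, vol, lms, T, seg, group, sex))
        rows.append({
            "Biosample": sid,
            "Genotype": "mut/mut" if group == "mutant" else "+/+",
            "Experimental Group": group,
            "Sex": sex,
            "Stage": "synthetic",
        })
    meta = pd.DataFrame(rows)
    return atlas, atlas_lms, atlas_seg, specimens, meta


def write_population(outdir, atlas, atlas_lms, atlas_seg, specimens, meta) -> None:
    """Write a generated population using the pipeline naming conventions."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_volume(atlas, outdir / "Synthetic_Atlas.nii.gz")
    write_volume(atlas_seg, outdir / "Synthetic_Atlas_Segs.nii.gz", dtype=np.int16)
    write_tag(atlas_lms, outdir / "Synthetic_Atlas_Landmarks.tag")
    for sp in specimens:
        write_volume(sp.volume, outdir / f"{sp.specimen_id}.nii.gz")
        write_volume(sp.segmentation, outdir / f"{sp.specimen_id}_Segs.nii.gz", dtype=np.int16)
        write_tag(sp.true_landmarks, outdir / f"{sp.specimen_id}_Head_Landmarks.tag")
        write_composite(sp.true_transform, outdir / f"{sp.specimen_id}_true")
    meta.to_csv(outdir / "metadata.csv", index=False)
    write_landmark_csv([sp.true_landmarks for sp in specimens], outdir / "true_landmarks.csv")
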