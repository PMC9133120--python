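"""Volume, transform, and landmark containers plus file I/O.

Conventions
-----------
* Grids are axis-aligned: world = start + index * step per axis, with 0-based
  voxel indices addressing voxel *centers*.  Headers carrying a non-identity
  direction/orientation matrix are rejected.
* All world coordinates are millimetres.  Arrays are stored in (x, y, z)
  index order, so ``values[i, j, k]`` sits at world point
  ``starts + (i, j, k) * steps``.
* Supported on-disk formats: NIfTI-1 (``.nii``/``.nii.gz``), NRRD
  (``.nrrd``), the ASCII MNI tag dialect (``.tag``), and a wide CSV landmark
  table.  MINC (``.mnc``) is deliberately not supported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk

AXIS_NAMES = ("xspace", "yspace", "zspace")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class VolumeGrid:
    """Axis-aligned 3-D scalar image with world-coordinate metadata."""

    values: np.ndarray
    steps: tuple[float, float, float]
    starts: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_names: tuple[str, str, str] = AXIS_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(
                f"unsupported dimensionality: expected 3 axes, got {self.values.ndim}"
            )
        self.steps = tuple(float(s) for s in self.steps)
        self.starts = tuple(float(s) for s in self.starts)
        if any(s <= 0 for s in self.steps):
            raise ValueError("all grid steps must be positive")

    @property
    def lengths(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def extent(self) -> np.ndarray:
        """World extent per axis: start + (length - 1) * step."""
        return np.asarray(self.starts) + (np.asarray(self.lengths) - 1) * np.asarray(self.steps)

    def like(self, values: np.ndarray) -> "VolumeGrid":
        """New grid with the same geometry and different values."""
        return VolumeGrid(values, self.steps, self.starts, self.axis_names)

    def meta_equal(self, other: "VolumeGrid", tol: float = 1e-9) -> bool:
        return (
            self.lengths == other.lengths
            and np.allclose(self.steps, other.steps, atol=tol)
            and np.allclose(self.starts, other.starts, atol=tol)
        )

    def world_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinate vectors."""
        return tuple(
            self.starts[a] + np.arange(self.lengths[a]) * self.steps[a] for a in range(3)
        )  # type: ignore[return-value]


@dataclass
class AffineTransform:
    """Homogeneous 4x4 world-coordinate (mm) affine mapping."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("affine matrix must be 4x4")
        if not np.allclose(self.matrix[3], (0.0, 0.0, 0.0, 1.0), atol=1e-10):
            raise ValueError("last row of a homogeneous affine must be (0, 0, 0, 1)")
        if abs(np.linalg.det(self.matrix[:3, :3])) <= 1e-12:
            raise ValueError("linear block of affine is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    @classmethod
    def from_linear(cls, linear: np.ndarray, translation: Sequence[float] = (0, 0, 0)) -> "AffineTransform":
        m = np.eye(4)
        m[:3, :3] = linear
        m[:3, 3] = translation
        return cls(m)

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.linear.T + self.translation
        return out if np.asarray(points).ndim == 2 else out[0]

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def compose_with(self, other: "AffineTransform") -> "AffineTransform":
        """Transform applying ``self`` first, then ``other``."""
        return AffineTransform(other.matrix @ self.matrix)


@dataclass
class DeformationField:
    """Dense per-voxel displacement field u(x) in world mm on a VolumeGrid.

    The field defines the mapping ``x -> x + u(x)``; displacements between
    voxel centers are obtained by trilinear interpolation with edge clamping.
    """

    displacements: np.ndarray  # (nx, ny, nz, 3)
    steps: tuple[float, float, float]
    starts: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.displacements.ndim != 4 or self.displacements.shape[3] != 3:
            raise ValueError("displacements must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.displacements)):
            raise ValueError("displacement field contains non-finite values")
        self.steps = tuple(float(s) for s in self.steps)
        self.starts = tuple(float(s) for s in self.starts)
        if any(s <= 0 for s in self.steps):
            raise ValueError("all grid steps must be positive")

    @property
    def lengths(self) -> tuple[int, int, int]:
        return self.displacements.shape[:3]  # type: ignore[return-value]

    @property
    def grid(self) -> VolumeGrid:
        """Grid metadata (x-component carried as values for convenience)."""
        return VolumeGrid(self.displacements[..., 0], self.steps, self.starts)

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Interpolate u at world points (trilinear, edge-clamped)."""
        from scipy.ndimage import map_coordinates

        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = (pts - np.asarray(self.starts)) / np.asarray(self.steps)
        coords = idx.T  # (3, m)
        out = np.empty_like(pts)
        for d in range(3):
            out[:, d] = map_coordinates(
                self.displacements[..., d], coords, order=1, mode="nearest"
            )
        return out if np.asarray(points).ndim == 2 else out[0]

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) + self.sample(points)


@dataclass
class CompositeTransform:
    """Ordered chain of affine / deformation stages in world mm.

    ``apply(p)`` applies stages in list order.  ``direction`` documents which
    way the mapping goes ("atlas_to_specimen" or "specimen_to_atlas").
    """

    stages: list
    direction: str = "atlas_to_specimen"

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("empty composition")
        for s in self.stages:
            if not isinstance(s, (AffineTransform, DeformationField)):
                raise TypeError(f"unsupported stage type: {type(s).__name__}")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        for stage in self.stages:
            pts = stage.apply(pts)
        return pts


@dataclass
class LandmarkSet:
    """Named p x 3 landmark configuration in world mm."""

    specimen_id: str
    labels: list[str]
    coords: np.ndarray
    header: list[str] = field(default_factory=list)  # preserved .tag header lines
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("expected 3-D point rows (p x 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("landmark set must contain at least one point")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("landmark coordinates must be finite")
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != self.coords.shape[0]:
            raise ValueError("label count does not match coordinate rows")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("landmark labels must be unique")

    @property
    def p(self) -> int:
        return self.coords.shape[0]

    def with_coords(self, coords: np.ndarray) -> "LandmarkSet":
        return LandmarkSet(self.specimen_id, list(self.labels), coords, list(self.header))


# ---------------------------------------------------------------------------
# volume I/O
# ---------------------------------------------------------------------------

def _check_axis_aligned(mat: np.ndarray, what: str) -> None:
    off = mat - np.diag(np.diag(mat))
    if np.max(np.abs(off)) > 1e-6 * max(1.0, np.max(np.abs(mat))):
        raise ValueError(
            f"{what} has a non-identity orientation; only axis-aligned grids are supported"
        )


def read_volume(path, format: str = "auto") -> VolumeGrid:
    """Read a NIfTI or NRRD volume into a VolumeGrid.

    ``format`` may be "nifti", "nrrd", or "auto" (sniff from the suffix).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    if format == "auto":
        name = path.name.lower()
        if name.endswith((".nii", ".nii.gz")):
            format = "nifti"
        elif name.endswith(".nrrd"):
            format = "nrrd"
        elif name.endswith(".mnc"):
            raise ValueError(
                "MINC (.mnc) is not supported; use NIfTI (.nii/.nii.gz) or NRRD (.nrrd)"
            )
        else:
            raise ValueError(f"cannot infer volume format from name: {path.name}")
    if format == "nifti":
        img = nib.load(str(path))
        if img.ndim != 3:
            raise ValueError(f"unsupported dimensionality: expected 3 axes, got {img.ndim}")
        aff = np.asarray(img.affine, dtype=float)
        _check_axis_aligned(aff[:3, :3], "NIfTI affine")
        steps = np.diag(aff[:3, :3])
        if np.any(steps <= 0):
            raise ValueError("NIfTI affine must have positive axis-aligned steps")
        data = np.asarray(img.dataobj, dtype=float)
        return VolumeGrid(data, tuple(steps), tuple(aff[:3, 3]))
    if format == "nrrd":
        img = sitk.ReadImage(str(path))
        if img.GetDimension() != 3:
            raise ValueError(
                f"unsupported dimensionality: expected 3 axes, got {img.GetDimension()}"
            )
        _check_axis_aligned(np.asarray(img.GetDirection()).reshape(3, 3), "NRRD direction")
        data = sitk.GetArrayFromImage(img).astype(float).transpose(2, 1, 0)  # zyx -> xyz
        return VolumeGrid(data, tuple(img.GetSpacing()), tuple(img.GetOrigin()))
    raise ValueError(f"unsupported format: {format!r}")


def write_volume(v: VolumeGrid, path, dtype=None) -> Path:
    """Write a VolumeGrid as NIfTI or NRRD depending on the suffix."""
    path = Path(path)
    data = v.values if dtype is None else v.values.astype(dtype)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        aff = np.eye(4)
        aff[:3, :3] = np.diag(v.steps)
        aff[:3, 3] = v.starts
        nib.save(nib.Nifti1Image(np.asarray(data), aff), str(path))
    elif name.endswith(".nrrd"):
        img = sitk.GetImageFromArray(np.ascontiguousarray(np.asarray(data).transpose(2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in v.steps))
        img.SetOrigin(tuple(float(s) for s in v.starts))
        sitk.WriteImage(img, str(path))
    elif name.endswith(".mnc"):
        raise ValueError("MINC (.mnc) is not supported; use NIfTI or NRRD")
    else:
        raise ValueError(f"cannot infer volume format from name: {path.name}")
    return path


def read_field(path) -> DeformationField:
    """Read a dense displacement field stored as a 4-D (x,y,z,3) NIfTI."""
    img = nib.load(str(path))
    if img.ndim != 4 or img.shape[3] != 3:
        raise ValueError("deformation field file must be 4-D with 3 vector components")
    aff = np.asarray(img.affine, dtype=float)
    _check_axis_aligned(aff[:3, :3], "field affine")
    return DeformationField(
        np.asarray(img.dataobj, dtype=float), tuple(np.diag(aff[:3, :3])), tuple(aff[:3, 3])
    )


def write_field(f: DeformationField, path) -> Path:
    path = Path(path)
    aff = np.eye(4)
    aff[:3, :3] = np.diag(f.steps)
    aff[:3, 3] = f.starts
    nib.save(nib.Nifti1Image(f.displacements, aff), str(path))
    return path


def write_composite(T: CompositeTransform, stem) -> list[Path]:
    """Serialize a composite as paired text affine(s) and field volume(s).

    ``<stem>_stage<i>_affine.txt`` holds a 4x4 matrix; ``<stem>_stage<i>_grid.nii.gz``
    holds a displacement field.  A ``<stem>_composite.txt`` manifest records
    stage order and the direction tag.
    """
    stem = Path(stem)
    written: list[Path] = []
    manifest = [f"direction {T.direction}"]
    for i, stage in enumerate(T.stages):
        if isinstance(stage, AffineTransform):
            p = stem.parent / f"{stem.name}_stage{i}_affine.txt"
            np.savetxt(p, stage.matrix)
            manifest.append(f"stage{i} affine {p.name}")
        else:
            p = stem.parent / f"{stem.name}_stage{i}_grid.nii.gz"
            write_field(stage, p)
            manifest.append(f"stage{i} field {p.name}")
        written.append(p)
    mpath = stem.parent / f"{stem.name}_composite.txt"
    mpath.write_text("\n".join(manifest) + "\n")
    written.append(mpath)
    return written


def read_composite(manifest_path) -> CompositeTransform:
    manifest_path = Path(manifest_path)
    lines = [l.split() for l in manifest_path.read_text().splitlines() if l.strip()]
    direction = lines[0][1]
    stages: list = []
    for row in lines[1:]:
        kind, fname = row[1], row[2]
        p = manifest_path.parent / fname
        if kind == "affine":
            stages.append(AffineTransform(np.loadtxt(p)))
        else:
            stages.append(read_field(p))
    return CompositeTransform(stages, direction)


# ---------------------------------------------------------------------------
# MNI .tag dialect
# ---------------------------------------------------------------------------

_NUM = r"[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?"
_POINT_RE = re.compile(
    rf"^\s*({_NUM})\s+({_NUM})\s+({_NUM})\s*(?:\"([^\"]*)\")?\s*;?\s*$"
)


def read_tag(path) -> LandmarkSet:
    """Parse an ASCII MNI tag file into a LandmarkSet.

    The reader is permissive: header lines up to and including ``Points =``
    are preserved verbatim, each following row is an ``x y z`` triple with an
    optional quoted trailing label, and a terminating ``;`` is tolerated.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such tag file: {path}")
    lines = path.read_text().splitlines()
    header: list[str] = []
    body_start = None
    for i, line in enumerate(lines):
        header.append(line)
        if line.strip().startswith("Points"):
            body_start = i + 1
            break
    if body_start is None:
        raise ValueError(f"malformed tag header: no 'Points =' line in {path.name}")
    coords: list[tuple[float, float, float]] = []
    labels: list[str] = []
    for line in lines[body_start:]:
        stripped = line.strip().rstrip(";").strip()
        if not stripped:
            continue
        m = _POINT_RE.match(line)
        if m is None:
            ntok = len(stripped.replace('"', " ").split())
            if 0 < ntok < 3:
                raise ValueError(f"expected 3-D point, got {ntok} coordinates: {line!r}")
            raise ValueError(f"cannot parse tag point row: {line!r}")
        coords.append((float(m.group(1)), float(m.group(2)), float(m.group(3))))
        labels.append(m.group(4) if m.group(4) is not None else f"lm{len(coords)}")
    if not coords:
        raise ValueError(f"tag file {path.name} contains no points")
    return LandmarkSet(path.stem, labels, np.asarray(coords), header)


def write_tag(lms: LandmarkSet, path) -> Path:
    """Write a canonical single-volume MNI tag file."""
    path = Path(path)
    if lms.header and any(h.strip().startswith("Points") for h in lms.header):
        header = list(lms.header)
    else:
        header = [
            "MNI Tag Point File",
            "Volumes = 1;",
            f"% written by atlasmorph for {lms.specimen_id}",
            "",
            "Points =",
        ]
    rows = [
        f" {x:.10g} {y:.10g} {z:.10g} \"{label}\""
        for (x, y, z), label in zip(lms.coords, lms.labels)
    ]
    rows[-1] += ";"
    path.write_text("\n".join(header + rows) + "\n")
    return path


# ---------------------------------------------------------------------------
# wide landmark table
# ---------------------------------------------------------------------------

def landmark_table(sets: Iterable[LandmarkSet]) -> pd.DataFrame:
    """Stack LandmarkSets into the wide n x (p*3) table.

    Columns are ordered ``x1, y1, z1, ..., xp, yp, zp`` (per-landmark triples);
    the index is the specimen id.
    """
    sets = list(sets)
    if not sets:
        raise ValueError("no landmark sets given")
    ref = sets[0]
    ids = [s.specimen_id for s in sets]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate specimen_id in landmark table input")
    for s in sets[1:]:
        if s.p != ref.p or s.labels != ref.labels:
            raise ValueError(
                f"inconsistent landmark count/order: {s.specimen_id} has p={s.p}, "
                f"expected p={ref.p}"
            )
    cols = []
    for i in range(ref.p):
        cols += [f"x{i + 1}", f"y{i + 1}", f"z{i + 1}"]
    data = np.stack([s.coords.reshape(-1) for s in sets])
    df = pd.DataFrame(data, index=pd.Index(ids, name="specimen_id"), columns=cols)
    df.attrs["labels"] = list(ref.labels)
    return df


def table_to_landmarks(df: pd.DataFrame, labels: Sequence[str] | None = None) -> list[LandmarkSet]:
    """Inverse of :func:`landmark_table`."""
    if df.shape[1] % 3:
        raise ValueError("wide landmark table must have a multiple of 3 columns")
    p = df.shape[1] // 3
    if labels is None:
        labels = df.attrs.get("labels") or [f"lm{i + 1}" for i in range(p)]
    return [
        LandmarkSet(str(idx), list(labels), row.to_numpy(dtype=float).reshape(p, 3))
        for idx, row in df.iterrows()
    ]


def write_landmark_csv(sets: Iterable[LandmarkSet], path) -> Path:
    path = Path(path)
    landmark_table(sets).to_csv(path)
    return path


def read_landmark_csv(path) -> list[LandmarkSet]:
    df = pd.read_csv(path, index_col=0)
    return table_to_landmarks(df)


# ---------------------------------------------------------------------------
# voxel <-> world
# ---------------------------------------------------------------------------

def voxel_to_world(v, g: VolumeGrid) -> np.ndarray:
    """World mm point(s) of (possibly fractional) voxel index triple(s)."""
    return np.asarray(g.starts) + np.asarray(v, dtype=float) * np.asarray(g.steps)


def world_to_voxel(w, g: VolumeGrid) -> np.ndarray:
    """Exact inverse of :func:`voxel_to_world`."""
    return (np.asarray(w, dtype=float) - np.asarray(g.starts)) / np.asarray(g.steps)
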