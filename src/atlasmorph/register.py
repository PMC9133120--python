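"""NCC-driven affine and non-linear pairwise registration, plus iterative
population-template (atlas) construction.

The similarity metric throughout is the uncentered normalized
cross-correlation NCC(I, J) = sum(I*J) / sqrt(sum(I^2) * sum(J^2)) over a
voxel domain.  The affine stage is a coarse-to-fine direction-set (Powell)
search over 12 world-space parameters; the non-linear stage is a
multi-resolution, Gaussian-regularized greedy NCC-gradient update
(demons-style) with compositive field accumulation and per-step folding
checks.  Neither stage uses randomness: results are deterministic for a
given configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import expm, logm
from scipy.ndimage import gaussian_filter, map_coordinates

from .volio import AffineTransform, CompositeTransform, DeformationField, VolumeGrid


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------

def ncc(i: VolumeGrid, j: VolumeGrid, domain: np.ndarray | None = None) -> float:
    """Uncentered normalized cross-correlation over a voxel domain.

    For nonnegative images the value lies in [0, 1], with 1 meaning perfect
    alignment over the domain.  ``domain`` is an optional boolean mask on
    the shared grid.
    """
    if i.lengths != j.lengths:
        raise ValueError("NCC requires identical grids")
    a, b = i.values, j.values
    if domain is not None:
        a, b = a[domain], b[domain]
    num = float(np.sum(a * b))
    den = float(np.sqrt(np.sum(a * a) * np.sum(b * b)))
    if den == 0.0:
        raise ValueError("NCC undefined: an image is all-zero over the domain")
    return num / den


def _ncc_arrays(a: np.ndarray, b: np.ndarray) -> float:
    den = np.sqrt(np.sum(a * a) * np.sum(b * b))
    if den == 0:
        return 0.0
    return float(np.sum(a * b) / den)


# ---------------------------------------------------------------------------
# pyramids
# ---------------------------------------------------------------------------

def _downsample(v: VolumeGrid, factor: int) -> VolumeGrid:
    """Anti-aliased integer-factor downsampling (grid metadata updated)."""
    if factor == 1:
        return v
    sm = gaussian_filter(v.values.astype(float), sigma=0.5 * factor)
    vals = sm[::factor, ::factor, ::factor]
    steps = tuple(s * factor for s in v.steps)
    return VolumeGrid(vals, steps, v.starts)


def _pyramid(v: VolumeGrid, levels: int) -> list[VolumeGrid]:
    """Coarse-to-fine pyramid with 2x downsampling per level."""
    factors = [2 ** (levels - 1 - k) for k in range(levels)]
    out = []
    for f in factors:
        while f > 1 and min(v.lengths) // f < 6:
            f //= 2
        out.append(_downsample(v, f))
    return out


# ---------------------------------------------------------------------------
# affine registration
# ---------------------------------------------------------------------------

@dataclass
class RegistrationResult:
    affine: AffineTransform
    field: DeformationField | None
    final_ncc: float
    level_log: list[float] = field(default_factory=list)

    @property
    def composite(self) -> CompositeTransform:
        stages = ([self.field] if self.field is not None else []) + [self.affine]
        return CompositeTransform(stages, "atlas_to_specimen")


def _params_to_affine(params: np.ndarray, center: np.ndarray) -> AffineTransform:
    """12 parameters -> world affine about ``center``.

    Layout: translation (3, mm), rotation (3, rad, x-y-z order), log-scale
    (3), shear (3: xy, xz, yz).
    """
    t = params[0:3]
    ax, ay, az = params[3:6]
    rx = np.array([[1, 0, 0], [0, np.cos(ax), -np.sin(ax)], [0, np.sin(ax), np.cos(ax)]])
    ry = np.array([[np.cos(ay), 0, np.sin(ay)], [0, 1, 0], [-np.sin(ay), 0, np.cos(ay)]])
    rz = np.array([[np.cos(az), -np.sin(az), 0], [np.sin(az), np.cos(az), 0], [0, 0, 1]])
    S = np.diag(np.exp(params[6:9]))
    Sh = np.eye(3)
    Sh[0, 1], Sh[0, 2], Sh[1, 2] = params[9:12]
    L = rz @ ry @ rx @ Sh @ S
    trans = center - L @ center + t
    return AffineTransform.from_linear(L, trans)


def _sample_through_affine(moving: VolumeGrid, fixed: VolumeGrid,
                           A: AffineTransform) -> np.ndarray:
    xs, ys, zs = fixed.world_coords()
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    mapped = A.apply(pts)
    idx = (mapped - np.asarray(moving.starts)) / np.asarray(moving.steps)
    vals = map_coordinates(moving.values.astype(float), idx.T, order=1,
                           mode="constant", cval=0.0)
    return vals.reshape(fixed.lengths)


def _center_of_mass(v: VolumeGrid) -> np.ndarray:
    w = np.clip(v.values, 0, None).astype(float)
    tot = w.sum()
    if tot == 0:
        return (np.asarray(v.starts) + v.extent) / 2
    xs, ys, zs = v.world_coords()
    cx = np.sum(w.sum(axis=(1, 2)) * xs) / tot
    cy = np.sum(w.sum(axis=(0, 2)) * ys) / tot
    cz = np.sum(w.sum(axis=(0, 1)) * zs) / tot
    return np.array([cx, cy, cz])


def affine_register(
    moving: VolumeGrid,
    fixed: VolumeGrid,
    levels: int = 4,
    init: AffineTransform | None = None,
    maxfev_per_level: int = 2000,
) -> tuple[AffineTransform, list[float]]:
    """Coarse-to-fine 12-parameter affine maximizing NCC.

    Returns the world-space affine mapping fixed (atlas) coordinates into
    the moving image, and the per-level full-resolution NCC trace.  If the
    coarsest level cannot improve on the initialization at all, a warning
    is issued and the initialization returned.
    """
    fix_pyr = _pyramid(fixed, levels)
    mov_pyr = _pyramid(moving, levels)
    center = (np.asarray(fixed.starts) + fixed.extent) / 2

    params = np.zeros(12)
    if init is None:
        params[0:3] = _center_of_mass(moving) - _center_of_mass(fixed)
    init_matrix = init.matrix if init is not None else _params_to_affine(params, center).matrix

    # per-parameter natural scales for the direction-set search
    step = min(fixed.steps)
    scales = np.array([step * 2] * 3 + [0.02] * 3 + [0.02] * 3 + [0.02] * 3)

    def make_cost(mv, fx, base: np.ndarray | None):
        fxv = fx.values.astype(float)

        def cost(q):
            A = _params_to_affine(q * scales, center)
            if base is not None:
                A = AffineTransform(base @ A.matrix)  # refine about the init
            w = _sample_through_affine(mv, fx, A)
            return -_ncc_arrays(fxv, w)

        return cost

    base = init.matrix if init is not None else None
    if init is None:
        q = params / scales
    else:
        q = np.zeros(12)

    trace: list[float] = []
    first_level = True
    for mv, fx in zip(mov_pyr, fix_pyr):
        cost = make_cost(mv, fx, base)
        f0 = cost(q)
        res = optimize.minimize(
            cost, q, method="Powell",
            options=dict(xtol=1e-3, ftol=1e-7, maxfev=maxfev_per_level),
        )
        if res.fun <= f0:
            q = res.x
        elif first_level:
            warnings.warn("affine optimizer failed to improve on the "
                          "initialization at the coarsest level; returning init")
            A0 = AffineTransform(init_matrix)
            return A0, [ncc(fixed, fixed.like(_sample_through_affine(moving, fixed, A0)))]
        A_cur = _params_to_affine(q * scales, center)
        if base is not None:
            A_cur = AffineTransform(base @ A_cur.matrix)
        trace.append(ncc(fixed, fixed.like(_sample_through_affine(moving, fixed, A_cur))))
        first_level = False

    A_final = _params_to_affine(q * scales, center)
    if base is not None:
        A_final = AffineTransform(base @ A_final.matrix)
    return A_final, trace


# ---------------------------------------------------------------------------
# non-linear registration
# ---------------------------------------------------------------------------

def _field_min_detj(disp: np.ndarray, steps) -> float:
    from .vbm import jacobian_determinant

    f = DeformationField(disp, steps)
    return float(jacobian_determinant(f).values.values.min())


def _warp_moving(moving: VolumeGrid, grid: VolumeGrid, disp: np.ndarray) -> np.ndarray:
    xs, ys, zs = grid.world_coords()
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]) + disp.reshape(-1, 3)
    idx = (pts - np.asarray(moving.starts)) / np.asarray(moving.steps)
    vals = map_coordinates(moving.values.astype(float), idx.T, order=1,
                           mode="constant", cval=0.0)
    return vals.reshape(grid.lengths)


def _resample_disp(disp: np.ndarray, src: VolumeGrid, dst: VolumeGrid) -> np.ndarray:
    xs, ys, zs = dst.world_coords()
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    idx = (pts - np.asarray(src.starts)) / np.asarray(src.steps)
    out = np.empty(dst.lengths + (3,))
    for d in range(3):
        out[..., d] = map_coordinates(disp[..., d], idx.T, order=1,
                                      mode="nearest").reshape(dst.lengths)
    return out


def nonlinear_register(
    moving: VolumeGrid,
    fixed: VolumeGrid,
    levels: int = 3,
    reg_sigma: float = 0.2,
    step_size: float = 1.0,
    iters_per_level: int = 30,
) -> tuple[DeformationField, float]:
    """Demons-style NCC-driven deformable registration.

    Inputs must be affine-aligned on a common grid.  The displacement field
    u lives on the fixed (atlas) grid and maps fixed coordinates toward the
    moving image: warped(x) = moving(x + u(x)).  Updates follow the exact
    gradient of the uncentered NCC with Gaussian (fluid) regularization at
    scale ``reg_sigma`` (mm) and compositive accumulation; any update that
    would fold the field triggers step-size halving, and a fold at the final
    level that survives halving raises.

    Returns the field and the final full-resolution NCC.
    """
    if moving.lengths != fixed.lengths:
        raise ValueError("non-linear registration requires a common grid")
    fix_pyr = _pyramid(fixed, levels)
    mov_pyr = _pyramid(moving, levels)

    disp: np.ndarray | None = None
    for li, (mv, fx) in enumerate(zip(mov_pyr, fix_pyr)):
        final_level = li == levels - 1
        if disp is None:
            disp = np.zeros(fx.lengths + (3,))
        else:
            disp = _resample_disp(disp, fix_pyr[li - 1], fx)
        sigma_vox = [max(reg_sigma / s, 0.5) for s in fx.steps]
        fxv = fx.values.astype(float)
        step = step_size
        best_disp = disp.copy()
        warped = _warp_moving(mv, fx, disp)
        best_ncc = _ncc_arrays(fxv, warped)
        stall = 0
        for _ in range(iters_per_level):
            # exact gradient of uncentered NCC wrt warped intensities
            B = np.sum(fxv * fxv)
            C = np.sum(warped * warped)
            A = np.sum(fxv * warped)
            if B == 0 or C == 0:
                break
            dN = fxv / np.sqrt(B * C) - (A / np.sqrt(B * C)) * warped / C
            grads = np.gradient(warped, *fx.steps)
            force = np.stack([dN * g for g in grads], axis=-1)
            for d in range(3):
                force[..., d] = gaussian_filter(force[..., d], sigma_vox)
            peak = np.max(np.linalg.norm(force, axis=-1))
            if peak < 1e-15:
                break
            # scale so the largest per-iteration motion is step * voxel size
            upd = force * (step * min(fx.steps) / peak)
            # compositive accumulation: u_new(x) = d(x) + u(x + d(x))
            grid_pts = np.stack(
                np.meshgrid(*fx.world_coords(), indexing="ij"), axis=-1
            )
            probe = (grid_pts + upd - np.asarray(fx.starts)) / np.asarray(fx.steps)
            comp = np.empty_like(disp)
            flat = probe.reshape(-1, 3).T
            for d in range(3):
                comp[..., d] = map_coordinates(
                    disp[..., d], flat, order=1, mode="nearest"
                ).reshape(fx.lengths)
            cand = upd + comp
            if _field_min_detj(cand, fx.steps) <= 0:
                step /= 2
                if step < 1e-3:
                    if final_level:
                        raise RuntimeError(
                            "non-linear registration folded at the final level "
                            f"despite step-size reduction (ncc={best_ncc:.4f})"
                        )
                    break
                continue
            disp = cand
            warped = _warp_moving(mv, fx, disp)
            cur = _ncc_arrays(fxv, warped)
            if cur > best_ncc + 1e-7:
                best_ncc = cur
                best_disp = disp.copy()
                stall = 0
            else:
                stall += 1
                if stall >= 4:
                    break
        disp = best_disp

    field = DeformationField(_resample_disp(disp, fix_pyr[-1], fixed),
                             fixed.steps, fixed.starts)
    final = ncc(fixed, fixed.like(_warp_moving(moving, fixed, field.displacements)))
    return field, final


def register_pair(
    moving: VolumeGrid,
    fixed: VolumeGrid,
    levels: int = 3,
    reg_sigma: float = 0.2,
    step_size: float = 1.0,
    iters_per_level: int = 30,
    init: AffineTransform | None = None,
) -> RegistrationResult:
    """Full pairwise registration: affine then non-linear refinement.

    The returned composite maps atlas (fixed) world coordinates to the
    moving specimen: ``specimen(A(x + u(x))) ~= atlas(x)``.
    """
    A, trace = affine_register(moving, fixed, levels=levels, init=init)
    aligned = fixed.like(_sample_through_affine(moving, fixed, A))
    fld, final = nonlinear_register(
        aligned, fixed, levels=levels, reg_sigma=reg_sigma,
        step_size=step_size, iters_per_level=iters_per_level,
    )
    return RegistrationResult(A, fld, final, trace + [final])


# ---------------------------------------------------------------------------
# affine averaging and atlas construction
# ---------------------------------------------------------------------------

def average_affines(transforms: list[AffineTransform]) -> AffineTransform:
    """Log-Euclidean mean of homogeneous affines: expm(mean(logm(M_i)))."""
    if not transforms:
        raise ValueError("cannot average an empty transform list")
    logs = []
    for T in transforms:
        L = logm(T.matrix)
        if np.max(np.abs(L.imag)) > 1e-8:
            raise ValueError("matrix log failure: transform too far from identity "
                             "(rotation near or beyond pi)")
        logs.append(L.real)
    M = expm(np.mean(logs, axis=0))
    M[3] = (0, 0, 0, 1)
    return AffineTransform(M)


@dataclass
class AtlasBuild:
    template: VolumeGrid
    results: dict[str, RegistrationResult]
    iteration_ncc: list[float]  # mean template NCC per non-linear iteration


def build_atlas(
    volumes: dict[str, VolumeGrid],
    levels: int = 3,
    nl_iterations: int = 4,
    reg_sigma: float = 0.2,
    iters_per_level: int = 20,
    progress=None,
) -> AtlasBuild:
    """Iterative population-average template construction.

    Stage 1: every ordered pair of the n inputs is affinely registered
    (n*(n-1) jobs, deterministic order by sorted id), each specimen's
    transforms are log-Euclidean averaged, the specimens are resampled
    through their averaged affines, and the voxel-wise mean forms the
    affine template.  Stage 2: ``nl_iterations`` rounds (coarse to fine)
    non-linearly deform every specimen to the evolving template and
    re-average.
    """
    ids = sorted(volumes)
    n = len(ids)
    if n < 2:
        raise ValueError("atlas construction needs at least 2 volumes")
    ref = volumes[ids[0]]

    # stage 1: all ordered pairwise affine registrations
    pair_affines: dict[str, list[AffineTransform]] = {i: [] for i in ids}
    for mid in ids:
        for fid in ids:
            if mid == fid:
                continue
            try:
                A, _ = affine_register(volumes[mid], volumes[fid], levels=levels)
            except Exception as exc:  # noqa: BLE001
                raise RuntimeError(
                    f"stage-1 affine registration failed for pair "
                    f"(moving={mid}, fixed={fid}): {exc}"
                ) from exc
            pair_affines[mid].append(A)
            if progress:
                progress(f"affine {mid}->{fid}")
    avg_aff = {i: average_affines(pair_affines[i]) for i in ids}
    # resample each specimen through its averaged affine onto the reference grid
    resampled = {
        i: ref.like(_sample_through_affine(volumes[i], ref, avg_aff[i])) for i in ids
    }
    template = ref.like(np.mean([resampled[i].values for i in ids], axis=0))

    # stage 2: evolving non-linear template, coarse to fine
    iteration_ncc: list[float] = []
    results: dict[str, RegistrationResult] = {}
    for it in range(nl_iterations):
        lv = min(levels, 1 + it * max(1, levels - 1) // max(1, nl_iterations - 1)) \
            if nl_iterations > 1 else levels
        warped = {}
        nccs = []
        for i in ids:
            fld, fin = nonlinear_register(
                resampled[i], template, levels=lv, reg_sigma=reg_sigma,
                iters_per_level=iters_per_level,
            )
            warped[i] = template.like(_warp_moving(resampled[i], template,
                                                   fld.displacements))
            nccs.append(fin)
            results[i] = RegistrationResult(avg_aff[i], fld, fin)
            if progress:
                progress(f"nonlinear it{it + 1} {i} ncc={fin:.4f}")
        iteration_ncc.append(float(np.mean(nccs)))
        template = ref.like(np.mean([warped[i].values for i in ids], axis=0))

    return AtlasBuild(template, results, iteration_ncc)
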