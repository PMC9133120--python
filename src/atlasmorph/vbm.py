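"""Deformation-field analytics: Jacobian determinant maps and voxel-wise
statistics (statistical parametric mapping with FDR control).

A Jacobian determinant of 1 means no local volume change; values above 1
mark expansion and values in (0, 1) shrinkage of the specimen relative to
the atlas.  Determinant maps from a population can be compared voxel-by-
voxel with a linear model and a Benjamini-Hochberg false-discovery-rate
correction across the anatomical mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .volio import AffineTransform, DeformationField, VolumeGrid


@dataclass
class DeterminantMap:
    values: VolumeGrid
    source_id: str = ""
    boundary_handling: str = "one-sided differences at grid boundaries"
    negative_fraction: float = 0.0  # reported, never clipped


def jacobian_determinant(f: DeformationField, source_id: str = "") -> DeterminantMap:
    """det J of the mapping x -> x + u(x), per voxel.

    Spatial derivatives use central differences at interior voxels and
    one-sided differences at the boundary, with world-step (mm) spacing.
    """
    if min(f.lengths) < 2:
        raise ValueError("grid with a singleton axis has no spatial derivatives")
    jac = np.empty(f.lengths + (3, 3))
    for d in range(3):  # component u_d
        grads = np.gradient(f.displacements[..., d], *f.steps)
        for ax in range(3):  # derivative axis
            jac[..., d, ax] = grads[ax] + (1.0 if d == ax else 0.0)
    det = np.linalg.det(jac)
    neg = float(np.mean(det <= 0))
    return DeterminantMap(
        VolumeGrid(det, f.steps, f.starts), source_id, negative_fraction=neg
    )


def composite_determinant(f: DeformationField, a: AffineTransform,
                          source_id: str = "") -> DeterminantMap:
    """Determinant of the composite: field det scaled by det of the affine's
    linear block (constant over the grid)."""
    det_a = float(np.linalg.det(a.linear))
    if abs(det_a) <= 1e-12:
        raise ValueError("singular affine")
    base = jacobian_determinant(f, source_id)
    vals = base.values.like(base.values.values * det_a)
    return DeterminantMap(vals, source_id, base.boundary_handling,
                          float(np.mean(vals.values <= 0)))


@dataclass
class VoxelStatsResult:
    statistic: VolumeGrid  # t (2 groups) or F (k groups)
    p: VolumeGrid
    q: VolumeGrid
    mask: VolumeGrid
    model: str
    group_variance: dict[str, VolumeGrid] = field(default_factory=dict)
    stat_name: str = "t"


def voxelwise_test(
    maps: list[DeterminantMap],
    groups: list[str],
    mask: VolumeGrid,
    covariates: np.ndarray | None = None,
    log_transform: bool = True,
    q_level: float = 0.05,
) -> VoxelStatsResult:
    """Per-voxel group comparison of determinant maps within a mask.

    Two groups give a two-sided t statistic, k > 2 groups an F statistic,
    both from an OLS fit per voxel (optionally with covariate columns).
    p-values are Benjamini-Hochberg adjusted across masked voxels.  The
    response defaults to log det for symmetric treatment of expansion and
    shrinkage.
    """
    if len(maps) != len(groups):
        raise ValueError("one group label per determinant map required")
    uniq = sorted(set(groups))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    counts = {g: groups.count(g) for g in uniq}
    if min(counts.values()) < 2:
        raise ValueError("each group needs n >= 2")
    grid = maps[0].values
    for m in maps[1:]:
        if not m.values.meta_equal(grid):
            raise ValueError("determinant maps must share one grid")
    mvox = mask.values > 0
    if not np.any(mvox):
        raise ValueError("empty mask")

    Y = np.stack([m.values.values[mvox] for m in maps])  # (n, v)
    if log_transform:
        if np.any(Y <= 0):
            raise ValueError("log transform requires strictly positive determinants")
        Y = np.log(Y)
    n, v = Y.shape

    # design: intercept + group indicators (+ covariates); F-test on group cols
    G = np.zeros((n, len(uniq) - 1))
    for i, g in enumerate(groups):
        j = uniq.index(g)
        if j > 0:
            G[i, j - 1] = 1.0
    X_full = np.column_stack([np.ones(n), G])
    X_null = np.ones((n, 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        X_full = np.column_stack([X_full, C])
        X_null = np.column_stack([X_null, C])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("singular design matrix")

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        return np.sum(resid**2, axis=0), beta

    rss_full, beta_full = rss(X_full)
    rss_null, _ = rss(X_null)
    df_num = X_full.shape[1] - X_null.shape[1]
    df_den = n - X_full.shape[1]
    if df_den < 1:
        raise ValueError("not enough residual degrees of freedom")
    # voxels with (numerically) zero residual variance carry no evidence
    zero_var = rss_full <= 1e-18 * max(1.0, float(np.sum(Y**2)) / v)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss_null - rss_full) / df_num) / (rss_full / df_den)
    F = np.where(np.isfinite(F) & ~zero_var, F, 0.0)
    p = stats.f.sf(F, df_num, df_den)

    if len(uniq) == 2:
        sigma2 = rss_full / df_den
        xtx_inv = np.linalg.inv(X_full.T @ X_full)
        se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 1e-300))
        with np.errstate(divide="ignore", invalid="ignore"):
            stat_flat = np.where(zero_var, 0.0, beta_full[1] / se)
        stat_name = "t"
        p = 2.0 * stats.t.sf(np.abs(stat_flat), df_den)
    else:
        stat_flat = F
        stat_name = "F"
    p = np.where(zero_var, 1.0, p)

    q = multipletests(p, alpha=q_level, method="fdr_bh")[1]

    def to_vol(flat, fill=0.0):
        out = np.full(grid.lengths, fill)
        out[mvox] = flat
        return grid.like(out)

    gvar = {}
    for g in uniq:
        sel = [i for i, gg in enumerate(groups) if gg == g]
        gvar[g] = to_vol(np.var(Y[sel], axis=0, ddof=1))

    model = (
        f"{stat_name}-test on {'log ' if log_transform else ''}det J, "
        f"groups={uniq}, n={counts}, BH FDR across {v} masked voxels"
    )
    return VoxelStatsResult(to_vol(stat_flat), to_vol(p, 1.0), to_vol(q, 1.0),
                            mask, model, gvar, stat_name)
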