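"""Geometric morphometrics: GPA, Procrustes distance, thin-plate splines,
semi-landmark patch interpolation and sliding, shape PCA, allometry, and
mesh deformation heatmaps.

Shapes are handled as n x p x 3 stacks (``ShapeArray``).  Generalized
Procrustes analysis removes position, orientation and (optionally) scale;
the resulting aligned coordinates feed PCA, allometry regression, QC
distance distributions and the landmark-correction network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volio import LandmarkSet


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ShapeArray:
    ids: list[str]
    labels: list[str]
    coords: np.ndarray  # (n, p, 3)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n, p, 3)")
        if len(self.ids) != self.coords.shape[0]:
            raise ValueError("one id per configuration required")
        if len(self.labels) != self.coords.shape[1]:
            raise ValueError("one label per landmark required")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("shape coordinates must be finite")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def p(self) -> int:
        return self.coords.shape[1]

    @classmethod
    def from_landmark_sets(cls, sets) -> "ShapeArray":
        sets = list(sets)
        ref = sets[0]
        for s in sets[1:]:
            if s.labels != ref.labels:
                raise ValueError("landmark sets disagree on labels/order")
        return cls([s.specimen_id for s in sets], list(ref.labels),
                   np.stack([s.coords for s in sets]))

    def to_landmark_sets(self) -> list[LandmarkSet]:
        return [LandmarkSet(i, list(self.labels), c) for i, c in zip(self.ids, self.coords)]


@dataclass
class ProcrustesResult:
    aligned: ShapeArray
    mean_shape: np.ndarray  # (p, 3)
    centroid_sizes: np.ndarray  # (n,)
    scaled: bool
    tangent_projected: bool = False


@dataclass
class SemiLandmarkScheme:
    """Fixed anchors, sliding curve chains, and surface patches.

    ``curves`` are ordered landmark-index lists (endpoints anchored);
    ``patches`` are (corner_labels, (u, v)) entries: four anchor labels in
    ring order and the grid density of the interpolated patch.
    """

    fixed: list[int] = field(default_factory=list)
    curves: list[list[int]] = field(default_factory=list)
    surfaces: list[int] = field(default_factory=list)
    patches: list[tuple[list[str], tuple[int, int]]] = field(default_factory=list)

    def validate(self, p: int) -> None:
        curve_sliders = {i for c in self.curves for i in c[1:-1]}
        surf = set(self.surfaces)
        fixed = set(self.fixed)
        if (curve_sliders & surf) or (curve_sliders & fixed) or (surf & fixed):
            raise ValueError("fixed/curve/surface index sets must be disjoint")
        for idx in fixed | curve_sliders | surf | {i for c in self.curves for i in c}:
            if not 0 <= idx < p:
                raise ValueError(f"scheme index {idx} out of range for p={p}")


# ---------------------------------------------------------------------------
# superimposition
# ---------------------------------------------------------------------------

def centroid_size(x: np.ndarray) -> float:
    """Square-root of summed squared distances to the centroid."""
    c = x - x.mean(0)
    return float(np.sqrt(np.sum(c**2)))


def _optimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation R (no reflection) minimizing ||a R - b||_F for centered a, b."""
    H = a.T @ b
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    return U @ D @ Vt


def gpa(shapes: ShapeArray, scale: bool = True, tol: float = 1e-10,
        max_iter: int = 100) -> ProcrustesResult:
    """Generalized Procrustes analysis.

    Iteratively centers, optionally scales to unit centroid size, and
    rotates every configuration to the evolving mean until the summed
    Procrustes distance changes by less than ``tol``.  Reflections are
    never used.
    """
    if shapes.n < 2:
        raise ValueError("GPA needs at least 2 configurations")
    if shapes.p < 3:
        raise ValueError("GPA needs at least 3 landmarks")
    X = shapes.coords.copy()
    sizes = np.empty(shapes.n)
    for i in range(shapes.n):
        X[i] -= X[i].mean(0)
        s = np.sqrt(np.sum(X[i] ** 2))
        if s < 1e-12:
            raise ValueError(f"degenerate (zero-size) configuration: {shapes.ids[i]}")
        sizes[i] = s
        if scale:
            X[i] /= s
    mean = X[0].copy()
    mean /= np.sqrt(np.sum(mean**2)) if scale else 1.0
    for _ in range(max_iter):
        for i in range(shapes.n):
            X[i] = X[i] @ _optimal_rotation(X[i], mean)
        new_mean = X.mean(0)
        if scale:
            nm = np.sqrt(np.sum(new_mean**2))
            if nm > 0:
                new_mean = new_mean / nm
        shift = float(np.max(np.abs(new_mean - mean)))
        mean = new_mean
        if shift < tol:
            break
    aligned = ShapeArray(list(shapes.ids), list(shapes.labels), X)
    return ProcrustesResult(aligned, mean, sizes, scale)


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Shape-space distance: RMS-style residual after full superimposition.

    Both configurations are centered and scaled to unit centroid size, b is
    rotated onto a, and the square root of the summed squared coordinate
    differences is returned.  Symmetric; 0 iff same shape.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("configurations must share p")
    a0 = a - a.mean(0)
    b0 = b - b.mean(0)
    sa, sb = np.sqrt(np.sum(a0**2)), np.sqrt(np.sum(b0**2))
    if sa < 1e-12 or sb < 1e-12:
        raise ValueError("degenerate configuration")
    a0, b0 = a0 / sa, b0 / sb
    b0 = b0 @ _optimal_rotation(b0, a0)
    return float(np.sqrt(np.sum((a0 - b0) ** 2)))


def align_to(target: np.ndarray, x: np.ndarray, scale: bool = True) -> np.ndarray:
    """Ordinary Procrustes superimposition of x onto a target frame."""
    t0 = target - target.mean(0)
    x0 = x - x.mean(0)
    if scale:
        x0 = x0 / np.sqrt(np.sum(x0**2)) * np.sqrt(np.sum(t0**2))
    R = _optimal_rotation(x0, t0)
    return x0 @ R + target.mean(0)


# ---------------------------------------------------------------------------
# thin-plate splines
# ---------------------------------------------------------------------------

@dataclass
class TPSModel:
    source: np.ndarray  # (p, 3) control points
    affine: np.ndarray  # (4, 3)
    weights: np.ndarray  # (p, 3)
    bending_energy: float


def _tps_kernel(r: np.ndarray) -> np.ndarray:
    # 3-D kernel U(r) = r (triharmonic-consistent choice)
    return r


def tps_fit(source: np.ndarray, target: np.ndarray, reg: float = 0.0) -> TPSModel:
    """Fit a 3-D thin-plate spline interpolating source -> target.

    Exact at the control points; the bending energy is the quadratic form
    w^T K w summed over output dimensions and is zero iff the mapping is
    affine.
    """
    X = np.asarray(source, dtype=float)
    Y = np.asarray(target, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("source and target must be matched p x 3 arrays")
    p = X.shape[0]
    if p < 4:
        raise ValueError("TPS needs at least 4 control points")
    if np.linalg.matrix_rank(X - X.mean(0), tol=1e-9 * max(1.0, np.abs(X).max())) < 3:
        raise ValueError("degenerate source: control points are coplanar")
    K = _tps_kernel(np.linalg.norm(X[:, None] - X[None], axis=2))
    if reg > 0:
        K = K + reg * np.eye(p)
    P = np.column_stack([np.ones(p), X])
    L = np.zeros((p + 4, p + 4))
    L[:p, :p] = K
    L[:p, p:] = P
    L[p:, :p] = P.T
    rhs = np.zeros((p + 4, 3))
    rhs[:p] = Y
    try:
        sol = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular TPS system (degenerate source points)") from exc
    w, a = sol[:p], sol[p:]
    # U(r) = r is conditionally negative definite, so the energy is -w'Kw
    be = float(-np.sum(w * (K @ w)))
    return TPSModel(X, a, w, max(be, 0.0))


def tps_apply(model: TPSModel, pts: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    U = _tps_kernel(np.linalg.norm(pts[:, None] - model.source[None], axis=2))
    out = (np.column_stack([np.ones(len(pts)), pts]) @ model.affine) + U @ model.weights
    return out


def bending_energy_matrix(source: np.ndarray) -> np.ndarray:
    """The p x p bending-energy quadratic form of a TPS anchored at
    ``source`` (the upper-left block of L^{-1}); annihilates affine maps."""
    X = np.asarray(source, dtype=float)
    p = X.shape[0]
    K = _tps_kernel(np.linalg.norm(X[:, None] - X[None], axis=2))
    P = np.column_stack([np.ones(p), X])
    L = np.zeros((p + 4, p + 4))
    L[:p, :p] = K
    L[:p, p:] = P
    L[p:, :p] = P.T
    Linv = np.linalg.inv(L)
    # with U(r) = r the energy of targets y is -y' E y, so negate for a PSD form
    E = -Linv[:p, :p]
    return (E + E.T) / 2


# ---------------------------------------------------------------------------
# semi-landmark patches
# ---------------------------------------------------------------------------

def interpolate_patches(
    sparse: LandmarkSet,
    scheme: SemiLandmarkScheme,
    template_dense: LandmarkSet | None = None,
    template_sparse: LandmarkSet | None = None,
) -> LandmarkSet:
    """Densify a sparse configuration with semi-landmark patches.

    Without a template, each patch is filled with a u x v bilinear grid
    spanned by its four corner anchors.  With ``template_dense`` (and the
    matching ``template_sparse`` anchors), dense points are transported
    from the template by the TPS defined on the sparse anchors, which
    reproduces the template dense points exactly when the sparse anchors
    coincide.  Output order: sparse landmarks first, then patch-major,
    row-major semi-landmarks.
    """
    for corners, (u, v) in scheme.patches:
        if u < 2 or v < 2:
            raise ValueError("patch density must be at least 2 x 2")
        for c in corners:
            if c not in sparse.labels:
                raise ValueError(f"missing patch anchor landmark: {c!r}")
    coords = [sparse.coords]
    labels = list(sparse.labels)
    if template_dense is not None:
        src = template_sparse.coords if template_sparse is not None else None
        if src is None:
            raise ValueError("template_dense requires template_sparse anchors")
        model = tps_fit(src, sparse.coords)
        dense = tps_apply(model, template_dense.coords)
        coords.append(dense)
        labels += [f"semi_{l}" for l in template_dense.labels]
    else:
        for pi, (corners, (u, v)) in enumerate(scheme.patches):
            c = np.stack([sparse.coords[sparse.labels.index(l)] for l in corners])
            us = np.linspace(0, 1, u)
            vs = np.linspace(0, 1, v)
            for a in us:
                for b in vs:
                    pt = ((1 - a) * (1 - b) * c[0] + a * (1 - b) * c[1]
                          + a * b * c[2] + (1 - a) * b * c[3])
                    coords.append(pt[None])
                    labels.append(f"patch{pi}_{len(labels)}")
    return LandmarkSet(sparse.specimen_id, labels, np.vstack(coords))


# ---------------------------------------------------------------------------
# sliding
# ---------------------------------------------------------------------------

def _tangent_bases(x: np.ndarray, scheme: SemiLandmarkScheme,
                   k_neighbors: int = 8) -> dict[int, np.ndarray]:
    """Tangent directions per sliding landmark: (1,3) for curve points
    (central differences along the chain), (2,3) for surface points (local
    PCA of the k nearest scheme neighbors)."""
    bases: dict[int, np.ndarray] = {}
    for chain in scheme.curves:
        for j in range(1, len(chain) - 1):
            t = x[chain[j + 1]] - x[chain[j - 1]]
            nrm = np.linalg.norm(t)
            if nrm > 1e-12:
                bases[chain[j]] = (t / nrm)[None]
    if scheme.surfaces:
        surf = np.asarray(scheme.surfaces)
        pool = x[surf]
        for idx in scheme.surfaces:
            d = np.linalg.norm(pool - x[idx], axis=1)
            near = pool[np.argsort(d)[1:k_neighbors + 1]]
            if len(near) < 3:
                continue
            c = near - near.mean(0)
            _, _, Vt = np.linalg.svd(c, full_matrices=False)
            bases[idx] = Vt[:2]
    return bases


def _total_bending_energy(X: np.ndarray, mean: np.ndarray) -> float:
    E = bending_energy_matrix(mean)
    return float(sum(X[i].T @ E @ X[i] for i in range(X.shape[0])).trace())


def slide_semilandmarks(
    shapes: ShapeArray,
    scheme: SemiLandmarkScheme,
    mode: str = "bending_energy",
    iters: int = 3,
) -> ShapeArray:
    """Slide semi-landmarks along their tangents against the sample mean.

    Curve points move along their tangent line, surface points within their
    tangent plane; fixed landmarks never move.  ``mode`` selects the
    objective: "bending_energy" minimizes the TPS bending energy of the
    mean-to-specimen deformation (closed-form solve in the sliding
    parameters), "procrustes" minimizes the summed squared distance to the
    mean (tangent projection of the residual).  The objective is
    non-increasing over iterations; the mean is re-estimated between
    iterations.
    """
    if mode not in ("bending_energy", "procrustes"):
        raise ValueError(f"unknown sliding mode {mode!r}")
    scheme.validate(shapes.p)
    X = shapes.coords.copy()
    fixed = set(scheme.fixed)
    for it in range(iters):
        mean = X.mean(0)
        E = bending_energy_matrix(mean) if mode == "bending_energy" else None
        for i in range(shapes.n):
            bases = _tangent_bases(X[i], scheme)
            movers = [j for j in bases if j not in fixed]
            if not movers:
                continue
            if mode == "procrustes":
                for j in movers:
                    B = bases[j]  # (d, 3)
                    resid = mean[j] - X[i, j]
                    X[i, j] += B.T @ (B @ resid)
            else:
                # quadratic solve: columns of the dof matrix are tangent dirs
                dof_dirs = [(j, B[d]) for j in movers for B in [bases[j]]
                            for d in range(B.shape[0])]
                m = len(dof_dirs)
                rows = np.asarray([j for j, _ in dof_dirs])
                dirs = np.stack([v for _, v in dof_dirs])  # (m, 3)
                # objective: tr((X+Δ)ᵀ E (X+Δ)), Δ_row(j) += t_k d_k
                # grad_k = 2 d_kᵀ (E X)_{row k};  H_{kl} = 2 (d_k·d_l) E_{jk,jl}
                EX = E @ X[i]
                g = 2.0 * np.sum(dirs * EX[rows], axis=1)
                H = 2.0 * (dirs @ dirs.T) * E[np.ix_(rows, rows)]
                try:
                    t = np.linalg.solve(H + 1e-12 * np.eye(m), -g)
                except np.linalg.LinAlgError:
                    t = np.linalg.lstsq(H, -g, rcond=None)[0]
                before = float(np.trace(X[i].T @ E @ X[i]))
                cand = X[i].copy()
                np.add.at(cand, rows, t[:, None] * dirs)
                after = float(np.trace(cand.T @ E @ cand))
                if after <= before:
                    X[i] = cand
    return ShapeArray(list(shapes.ids), list(shapes.labels), X)


# ---------------------------------------------------------------------------
# shape PCA
# ---------------------------------------------------------------------------

@dataclass
class ShapePCA:
    scores: np.ndarray  # (n, m)
    loadings: np.ndarray  # (m, 3p) rows are unit PCs
    variances: np.ndarray  # (m,)
    mean_shape: np.ndarray  # (p, 3)
    ids: list[str]
    tangent_projected: bool


def shape_pca(pr: ProcrustesResult, tangent_projection: bool = True) -> ShapePCA:
    """PCA of aligned-coordinate deviations from the mean shape.

    With ``tangent_projection`` (default) deviations are orthogonally
    projected onto the tangent space at the mean (the component along the
    vectorized mean is removed) before decomposition.  The PC variances sum
    to the total (projected) Procrustes variance.
    """
    X = pr.aligned.coords
    n, p, _ = X.shape
    if n < 3:
        raise ValueError("shape PCA needs at least 3 specimens")
    mean_v = pr.mean_shape.reshape(-1)
    dev = X.reshape(n, -1) - mean_v
    if tangent_projection:
        m = mean_v / np.linalg.norm(mean_v)
        dev = dev - np.outer(dev @ m, m)
    U, S, Vt = np.linalg.svd(dev, full_matrices=False)
    variances = S**2 / (n - 1)
    keep = S > 1e-12 * max(S[0], 1.0)
    scores = (U * S)[:, keep]
    return ShapePCA(scores, Vt[keep], variances[keep], pr.mean_shape,
                    list(pr.aligned.ids), tangent_projection)


def morph_along_pc(pca: ShapePCA, pc: int, score: float) -> np.ndarray:
    """Mean shape displaced by ``score`` along one PC, as p x 3."""
    if not 1 <= pc <= pca.loadings.shape[0]:
        raise ValueError(f"pc index {pc} out of range")
    v = pca.mean_shape.reshape(-1) + score * pca.loadings[pc - 1]
    return v.reshape(pca.mean_shape.shape)


def project_and_correlate(auto: ShapeArray, manual_pca: ShapePCA) -> np.ndarray:
    """Correlate automated configurations against a manual PC basis.

    The automated deviations from the *manual* mean are projected onto the
    manual loadings without centering ("uncentered scores"), and the
    per-PC Pearson correlation between automated and manual score vectors
    is returned.
    """
    if auto.p * 3 != manual_pca.loadings.shape[1]:
        raise ValueError("shape dimension does not match the PC basis")
    dev = auto.coords.reshape(auto.n, -1) - manual_pca.mean_shape.reshape(-1)
    if manual_pca.tangent_projected:
        m = manual_pca.mean_shape.reshape(-1)
        m = m / np.linalg.norm(m)
        dev = dev - np.outer(dev @ m, m)
    auto_scores = dev @ manual_pca.loadings.T
    if auto_scores.shape != manual_pca.scores.shape:
        raise ValueError("auto and manual samples must match in size")
    out = np.empty(auto_scores.shape[1])
    for k in range(auto_scores.shape[1]):
        a, b = auto_scores[:, k], manual_pca.scores[:, k]
        sa, sb = a.std(), b.std()
        out[k] = np.corrcoef(a, b)[0, 1] if sa > 0 and sb > 0 else np.nan
    return out


# ---------------------------------------------------------------------------
# heatmaps and allometry
# ---------------------------------------------------------------------------

def vertex_heatmap(mesh_vertices: np.ndarray, tps: TPSModel) -> dict:
    """Per-vertex displacement magnitude of a mesh under a fitted TPS."""
    verts = np.asarray(mesh_vertices, dtype=float)
    if verts.size == 0:
        raise ValueError("empty mesh")
    warped = tps_apply(tps, verts)
    mags = np.linalg.norm(warped - verts, axis=1)
    return {
        "magnitudes": mags,
        "mean": float(mags.mean()),
        "max": float(mags.max()),
        "argmax_vertex": int(np.argmax(mags)),
    }


@dataclass
class AllometryResult:
    intercept: np.ndarray  # (p*3,)
    slope: np.ndarray  # (p*3,) shape change per unit log centroid size
    r_squared: float  # fraction of total Procrustes variance explained
    predicted: np.ndarray  # (n, p, 3)
    degenerate: bool = False  # True when there is no shape variance


def allometry_regress(pr: ProcrustesResult) -> AllometryResult:
    """Multivariate regression of aligned shape on log centroid size."""
    if not pr.scaled:
        raise ValueError("allometry regression expects a scaled GPA "
                         "(centroid sizes stored separately)")
    X = pr.aligned.coords
    n = X.shape[0]
    if n <= 2:
        raise ValueError("allometry regression needs n > 2")
    logs = np.log(pr.centroid_sizes)
    if np.ptp(logs) < 1e-12:
        raise ValueError("zero variance in centroid size")
    Y = X.reshape(n, -1)
    A = np.column_stack([np.ones(n), logs])
    beta, *_ = np.linalg.lstsq(A, Y, rcond=None)
    pred = A @ beta
    ss_tot = float(np.sum((Y - Y.mean(0)) ** 2))
    if ss_tot < 1e-24:
        return AllometryResult(beta[0], beta[1], 0.0,
                               pred.reshape(X.shape), degenerate=True)
    ss_res = float(np.sum((Y - pred) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return AllometryResult(beta[0], beta[1], r2, pred.reshape(X.shape))


def ellipsoid_mesh(center, radii, n_theta: int = 12, n_phi: int = 24) -> np.ndarray:
    """Vertices of an analytic ellipsoid surface (synthetic test mesh)."""
    th = np.linspace(0, np.pi, n_theta)
    ph = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
    T, P = np.meshgrid(th, ph, indexing="ij")
    c = np.asarray(center, dtype=float)
    r = np.asarray(radii, dtype=float)
    x = c[0] + r[0] * np.sin(T) * np.cos(P)
    y = c[1] + r[1] * np.sin(T) * np.sin(P)
    z = c[2] + r[2] * np.cos(T)
    return np.column_stack([x.ravel(), y.ravel(), z.ravel()])
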