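import numpy as np
import pytest

from atlasmorph.morpho import (
    SemiLandmarkScheme,
    ShapeArray,
    allometry_regress,
    bending_energy_matrix,
    ellipsoid_mesh,
    gpa,
    interpolate_patches,
    morph_along_pc,
    procrustes_distance,
    project_and_correlate,
    shape_pca,
    slide_semilandmarks,
    tps_apply,
    tps_fit,
    vertex_heatmap,
)
from atlasmorph.volio import LandmarkSet


def _random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(0, 1, (3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _shapes(rng, n=6, p=10, sd=0.0):
    base = rng.uniform(0, 5, (p, 3))
    out = []
    for _ in range(n):
        x = base + rng.normal(0, sd, (p, 3))
        x = (x @ _random_rotation(rng).T) * rng.uniform(0.5, 2) + rng.uniform(-3, 3, 3)
        out.append(x)
    return ShapeArray([f"s{i}" for i in range(n)], [f"l{j}" for j in range(p)],
                      np.stack(out))


class TestGPA:
    def test_invariance_to_similarity_transforms(self, rng):
        shapes = _shapes(rng, n=8, sd=0.0)
        pr = gpa(shapes)
        spread = np.max(np.abs(pr.aligned.coords - pr.aligned.coords[0]))
        assert spread < 1e-8
        for i in range(shapes.n):
            for j in range(i + 1, shapes.n):
                assert procrustes_distance(pr.aligned.coords[i],
                                           pr.aligned.coords[j]) < 1e-8

    def test_mean_matches_alternating_least_squares_oracle(self, rng):
        shapes = _shapes(rng, n=3, p=6, sd=0.3)
        pr = gpa(shapes)

        # independent brute-force: alternate OPA-align-to-mean / re-average
        def opa(x, target):
            x0 = x - x.mean(0)
            x0 = x0 / np.sqrt(np.sum(x0**2))
            H = x0.T @ target
            U, _, Vt = np.linalg.svd(H)
            D = np.diag([1, 1, np.sign(np.linalg.det(U @ Vt))])
            return x0 @ (U @ D @ Vt)

        X = [c.copy() for c in shapes.coords]
        mean = X[0] - X[0].mean(0)
        mean = mean / np.sqrt(np.sum(mean**2))
        for _ in range(2000):
            X = [opa(x, mean) for x in X]
            new = np.mean(X, axis=0)
            new = new / np.sqrt(np.sum(new**2))
            if np.max(np.abs(new - mean)) < 1e-14:
                break
            mean = new
        assert procrustes_distance(pr.mean_shape, mean) < 1e-6

    def test_zero_size_configuration_rejected(self, rng):
        coords = np.zeros((2, 4, 3))
        coords[1] = rng.normal(0, 1, (4, 3))
        with pytest.raises(ValueError, match="degenerate"):
            gpa(ShapeArray(["a", "b"], list("wxyz"), coords))


class TestProcrustesDistance:
    def test_identity_and_symmetry(self, rng):
        for _ in range(50):
            a = rng.normal(0, 1, (7, 3))
            b = rng.normal(0, 1, (7, 3))
            assert procrustes_distance(a, a) < 1e-12
            assert abs(procrustes_distance(a, b) - procrustes_distance(b, a)) < 1e-10

    def test_matches_rotation_grid_search(self):
        # planar square vs stretched rectangle: 2-D problem, 1-D rotation search
        sq = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
        rect = sq * np.array([1.2, 1.0, 1.0])
        d = procrustes_distance(sq, rect)

        a0 = sq - sq.mean(0)
        a0 /= np.sqrt(np.sum(a0**2))
        b0 = rect - rect.mean(0)
        b0 /= np.sqrt(np.sum(b0**2))
        best = np.inf
        for th in np.arange(0, 2 * np.pi, 1e-4):
            R = np.array([[np.cos(th), -np.sin(th), 0],
                          [np.sin(th), np.cos(th), 0], [0, 0, 1]])
            best = min(best, np.sqrt(np.sum((a0 - b0 @ R.T) ** 2)))
        assert d == pytest.approx(best, abs=1e-3)


class TestTPS:
    def test_identity_mapping(self, rng):
        src = rng.normal(0, 2, (8, 3))
        m = tps_fit(src, src)
        assert m.bending_energy < 1e-10
        pts = rng.normal(0, 2, (20, 3))
        assert np.max(np.abs(tps_apply(m, pts) - pts)) < 1e-8

    def test_affine_target_reproduced_with_zero_bending(self, rng):
        src = rng.normal(0, 2, (8, 3))
        A = np.diag([1.2, 0.8, 1.1])
        t = np.array([0.5, -1, 2])
        m = tps_fit(src, src @ A.T + t)
        assert m.bending_energy < 1e-10
        pts = rng.normal(0, 2, (20, 3))
        assert np.max(np.abs(tps_apply(m, pts) - (pts @ A.T + t))) < 1e-6

    def test_exact_at_controls(self, rng):
        src = rng.normal(0, 2, (10, 3))
        tgt = src + rng.normal(0, 0.3, (10, 3))
        m = tps_fit(src, tgt)
        assert np.max(np.abs(tps_apply(m, src) - tgt)) < 1e-8
        assert m.bending_energy > 0

    def test_single_bump_nonaffine_influence_decays(self, rng):
        # the kernel (non-affine) part of a one-point bump decays with
        # distance; the induced affine trend is subtracted first
        src = rng.normal(0, 1, (9, 3))
        tgt = src.copy()
        tgt[0] += np.array([0.5, 0, 0])
        m = tps_fit(src, tgt)
        mags = []
        for rad in (2.0, 6.0, 18.0):
            probe = (src[0] + np.array([0, rad, 0]))[None]
            aff = np.column_stack([np.ones(1), probe]) @ m.affine
            mags.append(np.linalg.norm(tps_apply(m, probe) - aff))
        assert mags[0] > mags[1] > mags[2]

    def test_coplanar_source_rejected(self, rng):
        src = rng.normal(0, 1, (6, 3))
        src[:, 2] = 0.0
        with pytest.raises(ValueError, match="coplanar|degenerate"):
            tps_fit(src, src + 0.1)


class TestPatches:
    def test_bilinear_square_patch(self):
        sq = LandmarkSet("s", ["a", "b", "c", "d", "e"], np.array(
            [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0], [5, 5, 5.0]]
        ))
        scheme = SemiLandmarkScheme(patches=[(["a", "b", "c", "d"], (3, 3))])
        dense = interpolate_patches(sq, scheme)
        assert dense.p == 5 + 9
        patch = dense.coords[5:]
        assert np.allclose(patch.mean(0), [0.5, 0.5, 0])
        assert np.allclose(patch[:, 2], 0)

    def test_template_transport_identity(self, rng):
        src = rng.normal(0, 2, (6, 3))
        dense_pts = rng.normal(0, 2, (15, 3))
        sparse = LandmarkSet("s", [f"a{i}" for i in range(6)], src)
        template_sparse = LandmarkSet("t", [f"a{i}" for i in range(6)], src.copy())
        template_dense = LandmarkSet("td", [f"d{i}" for i in range(15)], dense_pts)
        out = interpolate_patches(sparse, SemiLandmarkScheme(),
                                  template_dense, template_sparse)
        assert np.max(np.abs(out.coords[6:] - dense_pts)) < 1e-8

    def test_embryo_style_count(self, rng):
        # 22 sparse anchors + patch densities -> p = 22 + sum(u*v)
        labels = [f"lm{i}" for i in range(22)]
        sparse = LandmarkSet("s", labels, rng.normal(0, 3, (22, 3)))
        scheme = SemiLandmarkScheme(patches=[
            (labels[:4], (3, 4)), (labels[4:8], (5, 5)), (labels[8:12], (2, 6)),
        ])
        dense = interpolate_patches(sparse, scheme)
        assert dense.p == 22 + 12 + 25 + 12

    def test_missing_anchor_rejected(self, rng):
        sparse = LandmarkSet("s", ["a", "b", "c", "d"], rng.normal(0, 1, (4, 3)))
        scheme = SemiLandmarkScheme(patches=[(["a", "b", "c", "missing"], (2, 2))])
        with pytest.raises(ValueError, match="anchor"):
            interpolate_patches(sparse, scheme)

    def test_density_below_2x2_rejected(self, rng):
        sparse = LandmarkSet("s", ["a", "b", "c", "d"], rng.normal(0, 1, (4, 3)))
        scheme = SemiLandmarkScheme(patches=[(["a", "b", "c", "d"], (1, 3))])
        with pytest.raises(ValueError, match="density"):
            interpolate_patches(sparse, scheme)


def _sliding_population(rng, n=5):
    """Anchored 3-D configs with a noisy curve and surface patch."""
    p_fixed = 6
    fixed_pts = rng.normal(0, 2, (p_fixed, 3))
    curve = np.linspace(fixed_pts[0], fixed_pts[1], 7)  # indices 6..12
    grid_u, grid_v = np.meshgrid(np.linspace(0, 1, 3), np.linspace(0, 1, 3))
    surf = (fixed_pts[2][None] + np.outer(grid_u.ravel(), fixed_pts[3] - fixed_pts[2])
            + np.outer(grid_v.ravel(), fixed_pts[4] - fixed_pts[2]))  # 13..21
    base = np.vstack([fixed_pts, curve[1:-1], surf])
    p = base.shape[0]
    shapes = np.stack([base + rng.normal(0, 0.05, (p, 3)) for _ in range(n)])
    scheme = SemiLandmarkScheme(
        fixed=list(range(p_fixed)),
        curves=[[0, *range(6, 11), 1]],
        surfaces=list(range(11, p)),
    )
    return ShapeArray([f"s{i}" for i in range(n)], [f"l{j}" for j in range(p)],
                      shapes), scheme


class TestSliding:
    def test_identical_population_unchanged(self, rng):
        shapes, scheme = _sliding_population(rng)
        same = ShapeArray(shapes.ids, shapes.labels,
                          np.repeat(shapes.coords[:1], shapes.n, axis=0))
        out = slide_semilandmarks(same, scheme, iters=2)
        assert np.max(np.abs(out.coords - same.coords)) < 1e-8

    def test_fixed_landmarks_immutable(self, rng):
        shapes, scheme = _sliding_population(rng)
        out = slide_semilandmarks(shapes, scheme, mode="bending_energy", iters=2)
        assert np.array_equal(out.coords[:, scheme.fixed], shapes.coords[:, scheme.fixed])

    @pytest.mark.parametrize("mode", ["bending_energy", "procrustes"])
    def test_objective_non_increasing(self, rng, mode):
        shapes, scheme = _sliding_population(rng)
        out = slide_semilandmarks(shapes, scheme, mode=mode, iters=1)

        mean = shapes.coords.mean(0)
        if mode == "bending_energy":
            E = bending_energy_matrix(mean)

            def obj(X):
                return sum(float(np.trace(x.T @ E @ x)) for x in X)
        else:

            def obj(X):
                return float(np.sum((X - mean) ** 2))

        assert obj(out.coords) <= obj(shapes.coords) + 1e-10
        assert obj(out.coords) < obj(shapes.coords)


class TestShapePCA:
    def test_morph_at_zero_is_mean(self, rng):
        pr = gpa(_shapes(rng, n=8, sd=0.2))
        pca = shape_pca(pr)
        assert np.allclose(morph_along_pc(pca, 1, 0.0), pr.mean_shape)

    def test_variance_conservation(self, rng):
        pr = gpa(_shapes(rng, n=10, sd=0.2))
        pca = shape_pca(pr, tangent_projection=False)
        dev = pr.aligned.coords.reshape(10, -1) - pr.mean_shape.reshape(-1)
        total = np.sum(dev**2) / 9
        assert np.isclose(pca.variances.sum(), total, atol=1e-10)

    def test_rank_bound(self, rng):
        n, p = 6, 12
        pr = gpa(_shapes(rng, n=n, p=p, sd=0.3))
        pca = shape_pca(pr)
        assert np.sum(pca.variances > 1e-12) <= min(n - 1, 3 * p - 7)

    def test_too_few_specimens_rejected(self, rng):
        pr = gpa(_shapes(rng, n=2, sd=0.1))
        with pytest.raises(ValueError):
            shape_pca(pr)


class TestProjectAndCorrelate:
    def test_self_projection_perfect_correlation(self, rng):
        pr = gpa(_shapes(rng, n=10, sd=0.3))
        pca = shape_pca(pr)
        r = project_and_correlate(pr.aligned, pca)
        assert np.allclose(r[pca.variances > 1e-10], 1.0, atol=1e-8)

    def test_noise_degrades_correlation_monotonically(self, rng):
        pr = gpa(_shapes(rng, n=12, sd=0.3))
        pca = shape_pca(pr)
        noise = np.random.default_rng(7).normal(0, 1, pr.aligned.coords.shape)
        means = []
        for sd in (0.001, 0.01, 0.1):
            noisy = ShapeArray(pr.aligned.ids, pr.aligned.labels,
                               pr.aligned.coords + sd * noise)
            r = project_and_correlate(noisy, pca)
            means.append(np.nanmean(r[:3]))
        assert means[0] > means[1] > means[2]

    def test_negated_pc1_scores(self, rng):
        pr = gpa(_shapes(rng, n=8, sd=0.3))
        pca = shape_pca(pr)
        dev = pr.aligned.coords.reshape(8, -1) - pr.mean_shape.reshape(-1)
        flipped = dev - 2 * np.outer(dev @ pca.loadings[0], pca.loadings[0])
        arr = ShapeArray(pr.aligned.ids, pr.aligned.labels,
                         (flipped + pr.mean_shape.reshape(-1)).reshape(8, -1, 3))
        r = project_and_correlate(arr, pca)
        assert r[0] == pytest.approx(-1.0, abs=1e-8)
        assert np.all(r[1:4] > 0.99)


class TestVertexHeatmap:
    def test_identity_tps_zero_magnitudes(self, rng):
        src = rng.normal(0, 2, (8, 3))
        m = tps_fit(src, src)
        verts = ellipsoid_mesh((0, 0, 0), (1, 1, 1))
        hm = vertex_heatmap(verts, m)
        assert hm["max"] < 1e-8

    def test_uniform_translation(self, rng):
        src = rng.normal(0, 2, (8, 3))
        t = np.array([0.3, -0.1, 0.2])
        m = tps_fit(src, src + t)
        hm = vertex_heatmap(ellipsoid_mesh((0, 0, 0), (1, 1, 1)), m)
        assert np.allclose(hm["magnitudes"], np.linalg.norm(t), atol=1e-8)

    def test_bump_localized(self, rng):
        src = rng.uniform(-2, 2, (12, 3))
        tgt = src.copy()
        tgt[0] += np.array([0.8, 0, 0])
        m = tps_fit(src, tgt)
        verts = ellipsoid_mesh(src[0], (0.5, 0.5, 0.5))
        far = ellipsoid_mesh(src.mean(0), (4.0, 4.0, 4.0))
        hm = vertex_heatmap(np.vstack([verts, far]), m)
        assert hm["argmax_vertex"] < len(verts)

    def test_empty_mesh_rejected(self, rng):
        m = tps_fit(rng.normal(0, 1, (5, 3)), rng.normal(0, 1, (5, 3)))
        with pytest.raises(ValueError, match="empty"):
            vertex_heatmap(np.empty((0, 3)), m)


class TestAllometry:
    def test_pure_size_signal_recovered(self, rng):
        base = rng.uniform(0, 5, (8, 3))
        beta = rng.normal(0, 0.02, (8, 3))
        shapes = []
        sizes = np.linspace(1, 3, 10)
        for s in sizes:
            shapes.append((base + beta * np.log(s)) * s)
        sa = ShapeArray([f"s{i}" for i in range(10)], [f"l{j}" for j in range(8)],
                        np.stack(shapes))
        pr = gpa(sa)
        res = allometry_regress(pr)
        assert res.r_squared > 0.99

    def test_no_shape_variance_gives_zero_r2(self, rng):
        base = rng.uniform(0, 5, (8, 3))
        shapes = np.stack([base * s for s in np.linspace(1, 2, 6)])
        sa = ShapeArray([f"s{i}" for i in range(6)], [f"l{j}" for j in range(8)], shapes)
        pr = gpa(sa)
        res = allometry_regress(pr)
        assert res.degenerate or res.r_squared < 1e-6

    def test_constant_size_rejected(self, rng):
        sa = _shapes(rng, n=5, sd=0.2)
        pr = gpa(sa)
        pr.centroid_sizes = np.ones(5)
        with pytest.raises(ValueError, match="size"):
            allometry_regress(pr)
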