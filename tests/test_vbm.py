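import numpy as np
import pytest

from atlasmorph.phantom import PerturbationSpec, make_population
from atlasmorph.vbm import (
    composite_determinant,
    jacobian_determinant,
    voxelwise_test,
)
from atlasmorph.volio import AffineTransform, DeformationField, VolumeGrid


def _zero_field(shape=(16, 16, 16), step=0.1):
    return DeformationField(np.zeros(shape + (3,)), (step,) * 3)


class TestJacobianDeterminant:
    def test_zero_field_is_unity_everywhere(self):
        det = jacobian_determinant(_zero_field())
        assert np.allclose(det.values.values, 1.0, atol=1e-15)
        assert det.negative_fraction == 0.0

    def test_uniform_dilation_analytic_value(self):
        # u(x) = 0.1 x -> det(1.1 I) = 1.331 at interior voxels
        f = _zero_field()
        xs = np.arange(16) * 0.1
        for d, coord in enumerate(np.meshgrid(xs, xs, xs, indexing="ij")):
            f.displacements[..., d] = 0.1 * coord
        det = jacobian_determinant(f)
        interior = det.values.values[1:-1, 1:-1, 1:-1]
        assert np.allclose(interior, 1.1**3, atol=1e-9)

    def test_matches_half_spacing_refinement_oracle(self, rng):
        # smooth random field evaluated analytically on grids at h and h/2
        from numpy import sin, cos

        def u(x, y, z):
            return np.stack([
                0.05 * sin(x) * cos(y),
                0.04 * cos(y) * sin(z),
                0.03 * sin(x + z),
            ], axis=-1)

        def field_on(n, step):
            xs = np.arange(n) * step
            gx, gy, gz = np.meshgrid(xs, xs, xs, indexing="ij")
            return DeformationField(u(gx, gy, gz), (step,) * 3)

        coarse = jacobian_determinant(field_on(12, 0.2)).values.values
        fine = jacobian_determinant(field_on(23, 0.1)).values.values
        # compare at shared voxel centers, interior only
        c = coarse[2:-2, 2:-2, 2:-2]
        f = fine[4:-4:2, 4:-4:2, 4:-4:2]
        assert np.max(np.abs(c - f) / np.abs(f)) < 0.01

    def test_singleton_axis_rejected(self):
        with pytest.raises(ValueError, match="singleton"):
            jacobian_determinant(DeformationField(np.zeros((1, 5, 5, 3)), (1, 1, 1)))


class TestCompositeDeterminant:
    def test_isotropic_scale_cubes(self):
        a = AffineTransform.from_linear(np.eye(3) * 1.2)
        det = composite_determinant(_zero_field(), a)
        assert np.allclose(det.values.values, 1.728, atol=1e-12)

    def test_identity_affine_reduces_to_field_det(self, rng):
        f = _zero_field()
        f.displacements[...] = rng.normal(0, 0.01, f.displacements.shape)
        base = jacobian_determinant(f).values.values
        comp = composite_determinant(f, AffineTransform.identity()).values.values
        assert np.array_equal(base, comp)

    def test_rotation_affine_preserves_det(self, rng):
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        f = _zero_field()
        f.displacements[...] = rng.normal(0, 0.01, f.displacements.shape)
        base = jacobian_determinant(f).values.values
        comp = composite_determinant(f, AffineTransform.from_linear(R)).values.values
        assert np.max(np.abs(base - comp)) < 1e-12


def _det_maps_from_population(n, seed, group_effect=None):
    atlas, _, seg, specimens, meta = make_population(
        n, PerturbationSpec(bias_amplitude=0, noise_sd=0.01), seed,
        group_effect=group_effect,
    )
    maps, groups = [], []
    for sp in specimens:
        field = sp.true_transform.stages[0]
        maps.append(jacobian_determinant(field, sp.specimen_id))
        groups.append(sp.group)
    return atlas, seg, maps, groups


class TestVoxelwiseTest:
    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(0)
        grid = VolumeGrid(np.ones((8, 8, 8)), (0.1,) * 3)
        maps = []
        base = rng.normal(1.0, 0.05, (8, 8, 8))
        from atlasmorph.vbm import DeterminantMap

        for i in range(8):
            maps.append(DeterminantMap(grid.like(base.copy())))
        res = voxelwise_test(maps, ["a"] * 4 + ["b"] * 4, grid)
        assert not np.any(res.q.values < 0.05)

    def test_seeded_shrinkage_localized_to_component(self):
        # mutants carry a 0.8x-scaled brain: group difference in det J must
        # peak inside the brain's atlas label
        atlas, seg, _, _ = _det_maps_from_population(4, 5)
        rng = np.random.default_rng(3)
        from atlasmorph.vbm import DeterminantMap
        from scipy.ndimage import gaussian_filter

        brain = seg.values == 2
        maps, groups = [], []
        for i in range(12):
            noise = gaussian_filter(rng.normal(0, 0.5, seg.lengths), 2)
            det = 1.0 + noise
            if i >= 6:
                det = det - 0.4 * brain  # mutant local shrinkage
            maps.append(DeterminantMap(seg.like(det)))
            groups.append("mutant" if i >= 6 else "control")
        mask = seg.like((seg.values > 0).astype(int))
        res = voxelwise_test(maps, groups, mask, log_transform=False)
        qv = res.q.values.copy()
        qv[mask.values == 0] = 2.0
        best = np.unravel_index(np.argmin(qv), qv.shape)
        assert brain[best]

    def test_fdr_control_under_null(self):
        rng = np.random.default_rng(3)
        grid = VolumeGrid(np.ones((200, 1, 2)), (1, 1, 1))
        # 200-voxel mask on a synthetic grid; 100 null replicates
        from atlasmorph.vbm import DeterminantMap

        mask3 = VolumeGrid(np.zeros((200, 2, 2)), (1, 1, 1))
        mask3.values[:, 0, :] = 1
        rates = []
        for _ in range(100):
            maps = [
                DeterminantMap(mask3.like(np.exp(rng.normal(0, 0.05, (200, 2, 2)))))
                for _ in range(10)
            ]
            res = voxelwise_test(maps, ["a"] * 5 + ["b"] * 5, mask3)
            rates.append(np.mean(res.q.values[mask3.values > 0] < 0.05))
        mc_sd = np.std(rates) / np.sqrt(len(rates))
        assert np.mean(rates) <= 0.05 + 2 * mc_sd

    def test_bh_adjustment_monotone_and_bounded(self, rng):
        grid = VolumeGrid(np.ones((6, 6, 6)), (1, 1, 1))
        from atlasmorph.vbm import DeterminantMap

        maps = [DeterminantMap(grid.like(np.exp(rng.normal(0, 0.1, (6, 6, 6)))))
                for _ in range(8)]
        res = voxelwise_test(maps, ["a"] * 4 + ["b"] * 4, grid)
        p = res.p.values.ravel()
        q = res.q.values.ravel()
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1 + 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_variance_maps_present_per_group(self, rng):
        grid = VolumeGrid(np.ones((5, 5, 5)), (1, 1, 1))
        from atlasmorph.vbm import DeterminantMap

        maps = [DeterminantMap(grid.like(np.exp(rng.normal(0, 0.1, (5, 5, 5)))))
                for _ in range(6)]
        res = voxelwise_test(maps, ["wt"] * 3 + ["mut"] * 3, grid)
        assert set(res.group_variance) == {"wt", "mut"}
        assert res.stat_name == "t"

    def test_singular_design_rejected(self, rng):
        grid = VolumeGrid(np.ones((4, 4, 4)), (1, 1, 1))
        from atlasmorph.vbm import DeterminantMap

        maps = [DeterminantMap(grid.like(np.ones((4, 4, 4)))) for _ in range(4)]
        with pytest.raises(ValueError, match="groups"):
            voxelwise_test(maps, ["a"] * 4, grid)
        cov = np.array([[1.0, 0], [1, 0], [1, 0], [1, 0]])  # rank-deficient
        with pytest.raises(ValueError, match="singular|design"):
            voxelwise_test(maps, ["a", "a", "b", "b"], grid, covariates=cov)
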