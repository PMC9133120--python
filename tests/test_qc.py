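import numpy as np
import pytest

from atlasmorph.morpho import ShapeArray, gpa, shape_pca
from atlasmorph.qc import (
    fit_quality_model,
    flag_low_quality,
    outlier_shapes,
    pc_extreme_screen,
    qc_report,
    rmse,
)


def _pair(rng, n=5, p=4, sd=0.0):
    labels = [f"l{j}" for j in range(p)]
    ids = [f"s{i}" for i in range(n)]
    manual = rng.normal(0, 2, (n, p, 3))
    auto = manual + rng.normal(0, sd, (n, p, 3))
    return (ShapeArray(ids, labels, manual), ShapeArray(ids, labels, auto))


class TestRMSE:
    def test_zero_in_every_mode(self, rng):
        m, _ = _pair(rng)
        for per in ("overall", "specimen", "landmark"):
            assert np.all(np.asarray(rmse(m, m, per)) == 0)

    def test_single_point_345_triangle(self):
        m = ShapeArray(["s"], ["l"], np.zeros((1, 1, 3)))
        a = ShapeArray(["s"], ["l"], np.array([[[0.3, 0.0, 0.4]]]))
        assert rmse(m, a) == pytest.approx(0.5, abs=1e-12)

    def test_overall_matches_printed_formula_loop_oracle(self, rng):
        m, a = _pair(rng, n=5, p=4, sd=0.7)
        total = 0.0
        for l in range(4):
            acc = 0.0
            for i in range(5):
                acc += np.sum((m.coords[i, l] - a.coords[i, l]) ** 2)
            total += acc / 5
        assert rmse(m, a) == pytest.approx(np.sqrt(total), abs=1e-12)

    def test_per_specimen_and_per_landmark_shapes(self, rng):
        m, a = _pair(rng, n=6, p=3, sd=0.2)
        assert rmse(m, a, "specimen").shape == (6,)
        assert rmse(m, a, "landmark").shape == (3,)

    def test_id_mismatch_rejected(self, rng):
        m, a = _pair(rng)
        b = ShapeArray([i + "_x" for i in a.ids], a.labels, a.coords)
        with pytest.raises(ValueError, match="ids"):
            rmse(m, b)


class TestQualityModel:
    def test_exact_cubic_recovered(self, rng):
        cc = rng.uniform(0.5, 1.0, 20)
        coef = np.array([2.0, -1.5, 0.7, 3.1])
        y = coef[0] + coef[1] * cc + coef[2] * cc**2 + coef[3] * cc**3
        model = fit_quality_model(y, cc)
        assert np.allclose(model.coefficients, coef, atol=1e-8)
        assert model.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_constant_cc_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_quality_model(np.arange(6.0), np.full(6, 0.9))

    def test_simulated_generator_recovered_at_85(self):
        # rmse = 0.2 + 5 * (0.95 - cc)^3 + N(0, 0.01), n = 500
        r = np.random.default_rng(7)
        cc = r.uniform(0.7, 1.0, 500)
        y = 0.2 + 5 * (0.95 - cc) ** 3 + r.normal(0, 0.01, 500)
        model = fit_quality_model(y, cc)
        truth = 0.2 + 5 * (0.95 - 0.85) ** 3
        assert model.predict(0.85) == pytest.approx(truth, rel=0.15)

    def test_residuals_orthogonal_to_design(self, rng):
        cc = rng.uniform(0.6, 1.0, 50)
        y = 0.3 + rng.normal(0, 0.05, 50)
        model = fit_quality_model(y, cc)
        resid = y - model.predict(cc)
        X = np.column_stack([np.ones_like(cc), cc, cc**2, cc**3])
        assert np.max(np.abs(X.T @ resid)) < 1e-8


class TestFlagLowQuality:
    @pytest.fixture()
    def model(self, rng):
        cc = rng.uniform(0.6, 1.0, 30)
        return fit_quality_model(0.2 + (1 - cc) ** 3 + rng.normal(0, 0.01, 30), cc)

    def test_all_good_no_flags(self, model):
        df = flag_low_quality(np.full(5, 0.95), model)
        assert not df["flagged"].any()

    def test_below_090_flagged(self, model):
        df = flag_low_quality(np.array([0.95, 0.85]), model)
        assert list(df["flagged"]) == [False, True]

    def test_empty_vector(self, model):
        assert len(flag_low_quality(np.array([]), model)) == 0

    def test_stage_summary_format(self, model):
        df = flag_low_quality(np.array([0.94, 0.92, 0.96, 0.91]), model,
                              stages=["E15.5", "E15.5", "adult", "adult"])
        assert set(df.attrs["stage_summary"]) == {"E15.5", "adult"}
        assert "±" in df.attrs["stage_summary"]["adult"]


class TestOutlierShapes:
    def test_identical_shapes_no_flags(self, rng):
        shapes = np.repeat(rng.normal(0, 1, (1, 8, 3)), 6, axis=0)
        pr = gpa(ShapeArray([f"s{i}" for i in range(6)],
                            [f"l{j}" for j in range(8)], shapes))
        rep = outlier_shapes(pr)
        assert np.allclose(rep.distances, 0, atol=1e-8)
        assert rep.iqr == pytest.approx(0, abs=1e-12)
        assert rep.flagged == []

    def test_hand_computed_quartile_rule(self):
        # distances {1..9, 100}: Q1 = 3.25, Q3 = 7.75, IQR = 4.5, thr = 14.5
        from atlasmorph.qc import iqr_outlier_rule

        d = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 100], dtype=float)
        q1, q3, iqr, thr, mask = iqr_outlier_rule(d)
        assert q1 == pytest.approx(3.25, abs=1e-12)
        assert q3 == pytest.approx(7.75, abs=1e-12)
        assert iqr == pytest.approx(4.5, abs=1e-12)
        assert thr == pytest.approx(14.5, abs=1e-12)
        assert list(np.nonzero(mask)[0]) == [9]

    def test_gross_corruption_flagged(self, rng):
        base = rng.normal(0, 2, (10, 3))
        coords = np.stack([base + rng.normal(0, 0.02, (10, 3)) for _ in range(21)])
        coords[7, 0] += 4.0  # one landmark displaced ~10x the field amplitude
        sa = ShapeArray([f"s{i}" for i in range(21)], [f"l{j}" for j in range(10)], coords)
        rep = outlier_shapes(gpa(sa))
        assert rep.flagged == ["s7"]

    def test_minimum_sample_size(self, rng):
        sa = ShapeArray(["a", "b", "c"], ["x", "y", "z", "w"],
                        rng.normal(0, 1, (3, 4, 3)))
        with pytest.raises(ValueError):
            outlier_shapes(gpa(sa))


class TestPCExtremeScreen:
    def test_symmetric_scores_give_equidistant_morphs(self, rng):
        from atlasmorph.morpho import ProcrustesResult

        base = rng.normal(0, 1, (12, 3))
        base -= base.mean(0)
        d = rng.normal(0, 0.1, (12, 3))
        d -= d.mean(0)
        shapes = np.stack([base - d, base, base + d])
        sa = ShapeArray(["lo", "mid", "hi"], [f"l{j}" for j in range(12)], shapes)
        pr = ProcrustesResult(sa, shapes.mean(0), np.ones(3), scaled=False)
        pca = shape_pca(pr, tangent_projection=False)
        rep = pc_extreme_screen(pca, 1)
        mean = pca.mean_shape
        dlo = np.linalg.norm(rep.min_morph - mean)
        dhi = np.linalg.norm(rep.max_morph - mean)
        assert dlo == pytest.approx(dhi, abs=1e-9)
        assert {rep.min_id, rep.max_id} == {"lo", "hi"}

    def test_corrupted_specimen_attains_extreme(self, rng):
        base = rng.normal(0, 2, (10, 3))
        coords = np.stack([base + rng.normal(0, 0.02, (10, 3)) for _ in range(15)])
        coords[4, 0] += 3.0
        sa = ShapeArray([f"s{i}" for i in range(15)], [f"l{j}" for j in range(10)], coords)
        pca = shape_pca(gpa(sa))
        rep = pc_extreme_screen(pca, 1)
        assert "s4" in (rep.min_id, rep.max_id)
        assert rep.ranked_ids[0] == "s4"

    def test_out_of_range_pc_rejected(self, rng):
        sa = ShapeArray([f"s{i}" for i in range(5)], [f"l{j}" for j in range(6)],
                        rng.normal(0, 1, (5, 6, 3)))
        pca = shape_pca(gpa(sa))
        for bad in (0, 99):
            with pytest.raises(ValueError):
                pc_extreme_screen(pca, bad)


def test_qc_report_merges_all_screens(rng):
    coords = np.stack([rng.normal(0, 1, (6, 3)) + rng.normal(0, 0.05, (6, 3))
                       for _ in range(8)])
    sa = ShapeArray([f"s{i}" for i in range(8)], [f"l{j}" for j in range(6)], coords)
    rep = outlier_shapes(gpa(sa))
    cc = rng.uniform(0.85, 1.0, 8)
    model = fit_quality_model(rng.uniform(0.1, 0.3, 8), rng.uniform(0.7, 1.0, 8))
    df = qc_report(rep.ids, cc, model, rep)
    assert {"id", "cc", "predicted_rmse", "procrustes_distance"} <= set(df.columns)
    assert len(df) == 8
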