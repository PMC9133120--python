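"""Registration and landmark quality control.

Three complementary screens, mirroring the pipeline's validation loop:

* an NCC audit with a cubic cross-correlation -> RMSE quality model
  (registrations with cc below 0.90 are flagged for review);
* Procrustes-distance outlier detection against the sample mean with the
  Q3 + 1.5 * IQR rule;
* PC1-extreme screening, morphing the mean shape to the observed extremes
  of a chosen principal component to expose localized landmark errors.

Flagged specimens are written to a review list; removal is never automatic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .morpho import (
    ProcrustesResult,
    ShapeArray,
    ShapePCA,
    morph_along_pc,
    procrustes_distance,
)


# ---------------------------------------------------------------------------
# RMSE
# ---------------------------------------------------------------------------

def rmse(manual: ShapeArray, auto: ShapeArray, per: str = "overall"):
    """Root mean squared landmark error between matched shape stacks.

    ``per="overall"`` evaluates sqrt( sum_l (1/n) sum_I ||x_l^I - xhat_l^I||^2 )
    — a sum over landmarks of per-landmark mean squared deviations, with no
    1/p factor inside the root.  ``per="specimen"`` returns, for each
    specimen, sqrt of the mean (over landmarks) squared deviation;
    ``per="landmark"`` is the transposed summary.
    """
    if manual.ids != auto.ids:
        raise ValueError("specimen ids do not match")
    if manual.p != auto.p:
        raise ValueError("landmark counts do not match")
    d2 = np.sum((manual.coords - auto.coords) ** 2, axis=2)  # (n, p)
    if per == "overall":
        return float(np.sqrt(np.sum(d2.mean(axis=0))))
    if per == "specimen":
        return np.sqrt(d2.mean(axis=1))
    if per == "landmark":
        return np.sqrt(d2.mean(axis=0))
    raise ValueError(f"unknown mode {per!r}")


# ---------------------------------------------------------------------------
# quality model
# ---------------------------------------------------------------------------

@dataclass
class QualityModel:
    coefficients: np.ndarray  # intercept, cc, cc^2, cc^3
    r_squared: float
    n: int
    flag_threshold_cc: float = 0.90

    def predict(self, cc):
        scalar = np.isscalar(cc) or np.ndim(cc) == 0
        cc = np.atleast_1d(np.asarray(cc, dtype=float))
        X = np.column_stack([np.ones_like(cc), cc, cc**2, cc**3])
        out = X @ self.coefficients
        return float(out[0]) if scalar else out


def fit_quality_model(
    rmse_per_specimen: np.ndarray,
    cc: np.ndarray,
    flag_threshold_cc: float = 0.90,
) -> QualityModel:
    """OLS of per-specimen RMSE on cc with linear, squared and cubic terms."""
    y = np.asarray(rmse_per_specimen, dtype=float)
    x = np.asarray(cc, dtype=float)
    if y.shape != x.shape:
        raise ValueError("rmse and cc vectors must have equal length")
    if len(y) < 5:
        raise ValueError("quality model needs at least 5 specimens")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("cc values must lie in [0, 1]")
    X = np.column_stack([np.ones_like(x), x, x**2, x**3])
    if np.linalg.matrix_rank(X) < 4:
        raise ValueError("degenerate design: cc values do not span a cubic")
    fit = sm.OLS(y, X).fit()
    return QualityModel(np.asarray(fit.params), float(fit.rsquared), len(y),
                        flag_threshold_cc)


def flag_low_quality(cc: np.ndarray, model: QualityModel,
                     ids: list[str] | None = None,
                     stages: list[str] | None = None) -> pd.DataFrame:
    """Flag specimens whose registration cc falls below the model threshold.

    Returns a table (id, cc, predicted_rmse, flagged); when ``stages`` is
    given a per-stage "mean ± sd" cc summary is attached as
    ``df.attrs["stage_summary"]``.
    """
    cc = np.asarray(cc, dtype=float)
    if cc.size and np.any((cc < 0) | (cc > 1)):
        raise ValueError("cc values must lie in [0, 1]")
    ids = ids if ids is not None else [f"specimen_{i + 1}" for i in range(len(cc))]
    df = pd.DataFrame({
        "id": ids,
        "cc": cc,
        "predicted_rmse": model.predict(cc) if cc.size else np.array([]),
        "flagged": cc < model.flag_threshold_cc,
    })
    if stages is not None and cc.size:
        summ = (
            pd.DataFrame({"stage": stages, "cc": cc})
            .groupby("stage")["cc"]
            .agg(["mean", "std"])
        )
        df.attrs["stage_summary"] = {
            s: f"{r['mean']:.2f} ± {0.0 if np.isnan(r['std']) else r['std']:.2f}"
            for s, r in summ.iterrows()
        }
    return df


# ---------------------------------------------------------------------------
# shape outliers
# ---------------------------------------------------------------------------

@dataclass
class OutlierReport:
    ids: list[str]
    distances: np.ndarray
    q1: float
    q3: float
    iqr: float
    threshold: float
    flagged: list[str]


def iqr_outlier_rule(distances: np.ndarray) -> tuple[float, float, float, float, np.ndarray]:
    """Q3 + 1.5*IQR rule on a distance vector.

    Quartiles use linear interpolation of order statistics; returns
    (q1, q3, iqr, threshold, flag_mask) with strict-inequality flagging.
    """
    d = np.asarray(distances, dtype=float)
    q1, q3 = np.percentile(d, [25, 75])
    iqr = q3 - q1
    thr = q3 + 1.5 * iqr
    return float(q1), float(q3), float(iqr), float(thr), d > thr


def outlier_shapes(pr: ProcrustesResult) -> OutlierReport:
    """Procrustes-distance outliers against the mean shape.

    Distances d_i between the mean and every configuration; quartiles by
    linear interpolation of order statistics; specimens with
    d_i > Q3 + 1.5 * IQR are flagged (strict inequality, so a degenerate
    zero-IQR sample flags nothing unless a distance exceeds Q3).
    """
    n = pr.aligned.n
    if n < 4:
        raise ValueError("outlier screen needs at least 4 configurations")
    d = np.array([
        procrustes_distance(pr.mean_shape, pr.aligned.coords[i]) for i in range(n)
    ])
    q1, q3, iqr, thr, mask = iqr_outlier_rule(d)
    flagged = [pr.aligned.ids[i] for i in range(n) if mask[i]]
    return OutlierReport(list(pr.aligned.ids), d, q1, q3, iqr, thr, flagged)


# ---------------------------------------------------------------------------
# PC-extreme screening
# ---------------------------------------------------------------------------

@dataclass
class PCExtremeReport:
    pc: int
    min_morph: np.ndarray  # (p, 3)
    max_morph: np.ndarray
    min_id: str
    max_id: str
    ranked_ids: list[str]  # by |score| on the chosen PC, most extreme first


def pc_extreme_screen(pca: ShapePCA, pc: int = 1) -> PCExtremeReport:
    """Morph the mean to the observed extremes of one PC for visual review."""
    if not 1 <= pc <= pca.scores.shape[1]:
        raise ValueError(f"pc index {pc} out of range (1..{pca.scores.shape[1]})")
    s = pca.scores[:, pc - 1]
    imin, imax = int(np.argmin(s)), int(np.argmax(s))
    order = np.argsort(-np.abs(s))
    return PCExtremeReport(
        pc,
        morph_along_pc(pca, pc, float(s[imin])),
        morph_along_pc(pca, pc, float(s[imax])),
        pca.ids[imin],
        pca.ids[imax],
        [pca.ids[i] for i in order],
    )


def qc_report(
    ids: list[str],
    cc: np.ndarray | None = None,
    model: QualityModel | None = None,
    outliers: OutlierReport | None = None,
) -> pd.DataFrame:
    """Combined review table: cc, predicted RMSE, Procrustes distance, flags."""
    df = pd.DataFrame({"id": ids})
    if cc is not None and model is not None:
        sub = flag_low_quality(np.asarray(cc), model, ids)
        df = df.merge(sub.rename(columns={"flagged": "low_cc"}), on="id", how="left")
    if outliers is not None:
        od = pd.DataFrame({
            "id": outliers.ids,
            "procrustes_distance": outliers.distances,
            "shape_outlier": [i in outliers.flagged for i in outliers.ids],
        })
        df = df.merge(od, on="id", how="left")
    return df
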