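"""High-level fusion of per-sensor predictions and end-to-end orchestration.

The fused prediction of a sample is the weighted sum of the individual
sensors' predictions,

    y_p(x) = sum_i y_i(x) w_i(x),

with per-sample weights from the reciprocal-Mahalanobis-distance rule.
Because every weight row is a convex combination, each fused value lies
between that sample's per-sensor predictions, and the fused absolute error
never exceeds the worst sensor's absolute error for that sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataio import ReferenceValues, SpectraTable, align_reference
from .mdweight import (
    MDProfile,
    WeightMatrix,
    assign_weights,
    compute_threshold,
    mahalanobis_distances,
)
from .plsmodel import (
    PLSCalibration,
    fit_pls,
    mc_outlier_detect,
    predict,
    project_scores,
    select_lv,
)


@dataclass
class EvaluationMetrics:
    """RMSEP (% w/w), predicted-vs-actual OLS slope, and mean bias (% w/w)."""

    rmsep: float
    slope: float
    bias: float


@dataclass
class PipelineConfig:
    max_lv: int = 15
    cv_folds: int = 5
    weight_power: float = 1.0
    lv_parsimony_tol: float = 0.0
    outlier_check: bool = False
    outlier_runs: int = 1000
    seed: int = 1


@dataclass
class FusionResult:
    sensor_names: list[str]
    per_sensor_predictions: np.ndarray  # n_v x L, % w/w
    fused_predictions: np.ndarray  # n_v, % w/w
    weights: WeightMatrix
    md_profiles: list[MDProfile]
    models: list[PLSCalibration]
    metrics_per_sensor: list[EvaluationMetrics]
    metrics_fused: EvaluationMetrics
    y_val: np.ndarray
    log: dict = field(default_factory=dict)


def fuse(Y: np.ndarray, W: WeightMatrix | np.ndarray) -> np.ndarray:
    """Row-wise weighted sum of per-sensor predictions."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    weights = W.weights if isinstance(W, WeightMatrix) else np.atleast_2d(np.asarray(W, dtype=float))
    if Y.shape != weights.shape:
        raise ValueError(f"prediction shape {Y.shape} != weight shape {weights.shape}")
    if not np.allclose(weights.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("weight rows must sum to 1")
    return np.einsum("ij,ij->i", Y, weights)


def evaluate(y_true: np.ndarray, y_pred: np.ndarray) -> EvaluationMetrics:
    """RMSEP, bias and predicted-vs-actual slope of a validation set."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size or y_true.size < 2:
        raise ValueError("y_true and y_pred must have equal length >= 2")
    if np.std(y_true) == 0:
        raise ValueError("y_true has zero variance; slope undefined")
    err = y_pred - y_true
    rmsep = float(np.sqrt(np.mean(err**2)))
    bias = float(np.mean(err))
    slope = float(stats.linregress(y_true, y_pred).slope)
    return EvaluationMetrics(rmsep=rmsep, slope=slope, bias=bias)


def _as_vector(y, table: SpectraTable) -> np.ndarray:
    if isinstance(y, ReferenceValues):
        return align_reference(table, y)
    return np.asarray(y, dtype=float).ravel()


def run_mdw_pipeline(
    sensors: list[tuple[SpectraTable, SpectraTable]],
    y_cal,
    y_val,
    config: PipelineConfig | None = None,
) -> FusionResult:
    """Execute the full distance-weighted fusion workflow.

    Per sensor: autoscale, choose the LV count by k-fold cross-validation,
    fit PLS, predict the validation set, project scores and compute
    Mahalanobis distances and the 3x-mean threshold. Then assign per-sample
    weights, fuse, and evaluate each sensor and the fused output.

    ``sensors`` is a list of (calibration, validation) spectra-table pairs,
    one per sensor; sample ids must agree across sensors within each set.
    ``y_cal`` / ``y_val`` may be ReferenceValues (matched by id) or plain
    vectors in table order.
    """
    if config is None:
        config = PipelineConfig()
    if len(sensors) < 2:
        raise ValueError("high-level fusion needs at least 2 sensors")
    cal0, val0 = sensors[0]
    for cal_t, val_t in sensors[1:]:
        for ref_t, t, which in ((cal0, cal_t, "calibration"), (val0, val_t, "validation")):
            if t.sample_ids != ref_t.sample_ids:
                diff = sorted(set(t.sample_ids) ^ set(ref_t.sample_ids))
                raise ValueError(
                    f"{which} sample ids differ between sensors "
                    f"{ref_t.sensor_name!r} and {t.sensor_name!r}: {diff or 'order mismatch'}"
                )
    yc = _as_vector(y_cal, cal0)
    yv = _as_vector(y_val, val0)

    names, models, profiles = [], [], []
    preds = np.empty((val0.n_samples, len(sensors)))
    D = np.empty_like(preds)
    thresholds = np.empty(len(sensors))
    log: dict = {"seed": config.seed, "sensors": {}}
    for i, (cal_t, val_t) in enumerate(sensors):
        if not np.array_equal(cal_t.wavenumbers, val_t.wavenumbers):
            raise ValueError(
                f"sensor {cal_t.sensor_name!r}: calibration and validation "
                "wavenumber grids differ"
            )
        name = cal_t.sensor_name or f"sensor{i + 1}"
        n_lv, curve = select_lv(
            cal_t.absorbance, yc, config.max_lv, config.cv_folds, config.lv_parsimony_tol
        )
        model = fit_pls(cal_t.absorbance, yc, n_lv, rmsecv_curve=curve, sensor_name=name)
        sensor_log = {"n_lv": n_lv, "rmsecv_min": float(curve[n_lv - 1])}
        if config.outlier_check:
            report = mc_outlier_detect(
                cal_t.absorbance, yc, n_lv=n_lv,
                n_runs=config.outlier_runs, seed=config.seed,
            )
            sensor_log["outlier_flags"] = int(report.flags.sum())
        preds[:, i] = predict(model, val_t.absorbance)
        d_cal = mahalanobis_distances(model.cal_scores, model.cal_scores)
        d_val = mahalanobis_distances(model.cal_scores, project_scores(model, val_t.absorbance))
        thr = compute_threshold(d_cal)
        D[:, i] = d_val
        thresholds[i] = thr
        sensor_log["threshold"] = thr
        names.append(name)
        models.append(model)
        profiles.append(MDProfile(name, d_cal, d_val, thr))
        log["sensors"][name] = sensor_log

    W = assign_weights(D, thresholds, config.weight_power)
    fused = fuse(preds, W)
    # convexity: fused value lies within the span of per-sensor predictions
    assert np.all(fused >= preds.min(axis=1) - 1e-9)
    assert np.all(fused <= preds.max(axis=1) + 1e-9)

    metrics = [evaluate(yv, preds[:, i]) for i in range(len(sensors))]
    fused_metrics = evaluate(yv, fused)
    log["n_excluded_sensor_entries"] = int(np.sum((D > thresholds[None, :])))
    log["n_extrapolation_samples"] = int(W.extrapolation_flags.sum())
    return FusionResult(
        sensor_names=names,
        per_sensor_predictions=preds,
        fused_predictions=fused,
        weights=W,
        md_profiles=profiles,
        models=models,
        metrics_per_sensor=metrics,
        metrics_fused=fused_metrics,
        y_val=yv,
        log=log,
    )
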