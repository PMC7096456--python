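"""Mahalanobis distances in score space, the 3x-mean threshold, and fusion weights.

The Mahalanobis distance (MD) of a sample from the calibration distribution
is the covariance-normalized distance in the model's latent-variable score
space — a multivariate leverage measure. Working in score space rather than
wavenumber space sidesteps the collinearity that would make the covariance
of raw spectra singular.

A sensor's applicability threshold is three times the mean MD of its own
calibration samples. Per validation sample, each sensor within its
threshold receives a raw weight equal to the reciprocal of its MD
(closer-to-calibration sensors count more); sensors beyond the threshold
get weight zero; the surviving weights are normalized to sum to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

_EPS = 1e-12  # reciprocal cap: a zero-MD sensor dominates with weight ~1


@dataclass
class MDProfile:
    """Per-sensor Mahalanobis distances and applicability threshold."""

    sensor_name: str
    distances_cal: np.ndarray
    distances_new: np.ndarray
    threshold: float


@dataclass
class WeightMatrix:
    """n_v x L fusion weights; rows sum to 1.

    ``extrapolation_flags[i]`` is True when every sensor exceeded its
    threshold for sample i; the row then falls back to normalized
    reciprocal distances over all sensors rather than refusing to predict.
    """

    weights: np.ndarray
    extrapolation_flags: np.ndarray


def mahalanobis_distances(S_cal: np.ndarray, S_query: np.ndarray) -> np.ndarray:
    """MD of each query row from the calibration score distribution.

    D(x) = sqrt((s - s_bar)' C^-1 (s - s_bar)) with s_bar and C the mean and
    (n-1)-denominator covariance of ``S_cal``. Returns the non-squared
    distance. A singular covariance falls back to the pseudo-inverse with a
    warning.
    """
    S_cal = np.atleast_2d(np.asarray(S_cal, dtype=float))
    S_query = np.atleast_2d(np.asarray(S_query, dtype=float))
    n_cal, d = S_cal.shape
    if S_query.shape[1] != d:
        raise ValueError("query and calibration score dimensions differ")
    if n_cal <= d:
        raise ValueError(
            f"need more calibration samples ({n_cal}) than score dimensions ({d})"
        )
    center = S_cal.mean(axis=0)
    cov = np.atleast_2d(np.cov(S_cal, rowvar=False, ddof=1))
    diff = S_query - center
    cond = np.linalg.cond(cov)
    if np.isfinite(cond) and cond < 1e12:
        solved = cho_solve(cho_factor(cov), diff.T)
    else:
        warnings.warn(
            "singular score covariance; falling back to pseudo-inverse",
            UserWarning,
            stacklevel=2,
        )
        solved = np.linalg.pinv(cov) @ diff.T
    d2 = np.einsum("ij,ji->i", diff, solved)
    return np.sqrt(np.maximum(d2, 0.0))


def compute_threshold(distances_cal: np.ndarray) -> float:
    """Applicability threshold: three times the calibration-group mean MD."""
    d = np.asarray(distances_cal, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance vector")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    return 3.0 * float(d.mean())


def assign_weights(
    D: np.ndarray,
    thresholds: np.ndarray,
    weight_power: float = 1.0,
) -> WeightMatrix:
    """Reciprocal-MD fusion weights with threshold exclusion.

    Per row: sensors with D <= threshold (inclusive — only strict
    exceedance excludes) get raw weight 1 / max(D, 1e-12)**weight_power;
    the rest get 0; raw weights are normalized to sum to 1. If every sensor
    exceeds its threshold the row is flagged as extrapolation and the
    weights fall back to normalized reciprocal distances over all sensors.
    """
    D = np.atleast_2d(np.asarray(D, dtype=float))
    thresholds = np.asarray(thresholds, dtype=float).ravel()
    if D.shape[1] != thresholds.size:
        raise ValueError("one threshold per sensor column required")
    if np.any(D < 0):
        raise ValueError("negative Mahalanobis distance")
    if np.any(thresholds < 0):
        raise ValueError("negative threshold")
    raw_all = 1.0 / np.maximum(D, _EPS) ** weight_power
    inside = D <= thresholds[None, :]
    raw = np.where(inside, raw_all, 0.0)
    row_sums = raw.sum(axis=1)
    flags = row_sums == 0.0
    raw[flags] = raw_all[flags]
    weights = raw / raw.sum(axis=1, keepdims=True)
    return WeightMatrix(weights=weights, extrapolation_flags=flags)
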