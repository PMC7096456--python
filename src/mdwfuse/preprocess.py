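"""Autoscaling and the concentration-ordered calibration/validation split.

Autoscaling standardizes every wavenumber column to zero mean and unit
variance so all variables carry the same weight in the regression,
regardless of absolute absorbance. The split orders samples by
concentration and draws validation samples systematically across that
ordering, so both sets span the calibrated range and the validation
extrema stay strictly inside the calibration extrema.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Scaler:
    """Per-column mean/SD of a calibration matrix (SD denominator n-1)."""

    column_means: np.ndarray
    column_sds: np.ndarray

    def __post_init__(self) -> None:
        self.column_means = np.asarray(self.column_means, dtype=float)
        self.column_sds = np.asarray(self.column_sds, dtype=float)
        if self.column_means.shape != self.column_sds.shape:
            raise ValueError("mean and sd vectors must have equal length")


@dataclass
class SplitPlan:
    """Disjoint calibration/validation sample sets."""

    calibration_ids: list
    validation_ids: list
    calibration_indices: np.ndarray
    validation_indices: np.ndarray


def autoscale_fit(X: np.ndarray) -> Scaler:
    """Fit per-column mean and sample standard deviation.

    A zero-variance column makes autoscaling undefined and is a hard error
    (silent flooring would distort the PLS weights); drop such columns
    beforehand with :func:`drop_constant_columns` if that is intended.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("autoscale_fit needs a 2-D matrix with at least 2 rows")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        raise ValueError(
            f"zero-variance column(s) {zero.tolist()}: autoscaling undefined"
        )
    return Scaler(column_means=means, column_sds=sds)


def autoscale_apply(scaler: Scaler, X: np.ndarray) -> np.ndarray:
    """Apply calibration column statistics: (x - mean) / sd, columnwise."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != scaler.column_means.size:
        raise ValueError(
            f"matrix has {X.shape[1]} columns, scaler expects {scaler.column_means.size}"
        )
    return (X - scaler.column_means) / scaler.column_sds


def drop_constant_columns(X: np.ndarray, wavenumbers: np.ndarray | None = None):
    """Remove zero-variance columns; returns (X_kept, kept_mask)."""
    X = np.asarray(X, dtype=float)
    keep = X.std(axis=0, ddof=1) > 0
    return X[:, keep], keep


def rank_split(
    y: np.ndarray,
    validation_fraction: float,
    sample_ids: list | None = None,
) -> SplitPlan:
    """Systematic calibration/validation split over the concentration ranking.

    Samples are sorted by concentration from high to low (stable sort, so
    ties keep original order). ``n_val = round(n * validation_fraction)``
    validation samples are taken at the centered systematic positions
    ``floor((j + 0.5) * n / n_val)`` of the sorted list, which keeps the
    validation extrema strictly inside the calibration extrema. Fully
    deterministic: the same y always yields the same plan.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 5:
        raise ValueError("need at least 5 samples to split")
    if not 0.0 < validation_fraction < 0.5:
        raise ValueError("validation_fraction must lie in (0, 0.5)")
    if sample_ids is None:
        sample_ids = list(range(n))
    elif len(sample_ids) != n:
        raise ValueError("sample_ids length must match y")
    n_val = int(round(n * validation_fraction))
    if n_val < 1:
        raise ValueError("validation_fraction too small: zero validation samples")
    order = np.argsort(-y, kind="stable")  # high to low concentration
    positions = np.floor((np.arange(n_val) + 0.5) * n / n_val).astype(int)
    val_idx = np.sort(order[positions])
    mask = np.zeros(n, dtype=bool)
    mask[val_idx] = True
    cal_idx = np.flatnonzero(~mask)
    return SplitPlan(
        calibration_ids=[sample_ids[i] for i in cal_idx],
        validation_ids=[sample_ids[i] for i in val_idx],
        calibration_indices=cal_idx,
        validation_indices=val_idx,
    )
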