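"""PLS1 regression with latent-variable selection and Monte-Carlo outlier screening.

The regression core is NIPALS PLS1 with deflation of X only. That choice is
deliberate: the algorithm is deterministic, the calibration score matrix T
falls out directly (it is the space in which Mahalanobis distances are
computed downstream), and with all components retained it reproduces the
least-squares solution, which the tests exploit as an oracle.

Spectra are autoscaled inside :func:`fit_pls` using calibration statistics;
the response is mean-centered. The number of latent variables (LVs) — the
key complexity parameter — is chosen by k-fold cross-validation with a
deterministic venetian-blind fold assignment over the concentration-ordered
calibration set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import Scaler, autoscale_apply, autoscale_fit

# relative tolerance below which a NIPALS weight/score is treated as rank-exhausted
_RANK_TOL = 1e-12


@dataclass
class PLSCalibration:
    """A fitted per-sensor PLS1 calibration.

    ``cal_scores`` (n_cal x n_lv) are the calibration samples' coordinates
    in latent-variable space; their columns are mutually orthogonal.
    ``coefficients`` live on the autoscaled-X / centered-y scale.
    """

    scaler: Scaler
    x_mean: np.ndarray
    x_weights: np.ndarray
    x_loadings: np.ndarray
    x_rotations: np.ndarray
    y_loadings: np.ndarray
    coefficients: np.ndarray
    y_center: float
    n_lv: int
    cal_scores: np.ndarray
    rmsecv_curve: np.ndarray | None = None
    sensor_name: str = ""


@dataclass
class OutlierReport:
    """Per-sample held-out residual statistics from Monte-Carlo resampling."""

    mean_residual: np.ndarray
    sd_residual: np.ndarray
    flags: np.ndarray
    n_runs: int
    threshold_multiplier: float = 3.0


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_lv: int):
    """NIPALS PLS1, X-deflation only.

    Returns (W, P, q, T, n_found). Stops early when the residual X carries
    no covariance with y left (rank exhausted); callers decide whether that
    is an error or acceptable truncation.
    """
    n, p = Xc.shape
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    Xa = Xc.copy()
    ref_w = None
    ref_t = None
    found = 0
    for a in range(n_lv):
        w = Xa.T @ yc
        nw = np.linalg.norm(w)
        if ref_w is None:
            ref_w = nw
        if nw <= _RANK_TOL * max(ref_w, 1.0):
            break
        w /= nw
        t = Xa @ w
        tt = float(t @ t)
        if ref_t is None:
            ref_t = tt
        if tt <= _RANK_TOL * max(ref_t, 1.0):
            break
        pa = Xa.T @ t / tt
        qa = float(yc @ t) / tt
        Xa -= np.outer(t, pa)
        W[:, a], P[:, a], q[a], T[:, a] = w, pa, qa, t
        found = a + 1
    return W[:, :found], P[:, :found], q[:found], T[:, :found], found


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    rmsecv_curve: np.ndarray | None = None,
    sensor_name: str = "",
) -> PLSCalibration:
    """Fit a PLS1 calibration with ``n_lv`` latent variables.

    X may be raw absorbance; autoscaling is fitted and applied internally,
    and y is mean-centered. Refitting on identical input yields identical
    coefficients (the algorithm has no random element).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X rows and y length differ")
    n, p = X.shape
    if not 1 <= n_lv <= min(n - 1, p):
        raise ValueError(f"n_lv={n_lv} outside feasible range 1..{min(n - 1, p)}")
    if np.std(y) == 0:
        raise ValueError("y has zero variance; calibration is undefined")
    scaler = autoscale_fit(X)
    Xs = autoscale_apply(scaler, X)
    x_mean = Xs.mean(axis=0)
    y_center = float(y.mean())
    W, P, q, T, found = _nipals_pls1(Xs - x_mean, y - y_center, n_lv)
    if found < n_lv:
        raise ValueError(
            f"X rank exhausted after {found} components; cannot extract n_lv={n_lv}"
        )
    # rotations R satisfy T = Xc @ R; P'W is upper triangular
    R = W @ np.linalg.inv(P.T @ W)
    coef = R @ q
    return PLSCalibration(
        scaler=scaler,
        x_mean=x_mean,
        x_weights=W,
        x_loadings=P,
        x_rotations=R,
        y_loadings=q,
        coefficients=coef,
        y_center=y_center,
        n_lv=n_lv,
        cal_scores=T,
        rmsecv_curve=rmsecv_curve,
        sensor_name=sensor_name,
    )


def _preprocessed(model: PLSCalibration, X_new: np.ndarray) -> np.ndarray:
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.coefficients.size:
        raise ValueError(
            f"X has {X_new.shape[1]} columns, model expects {model.coefficients.size}"
        )
    return autoscale_apply(model.scaler, X_new) - model.x_mean


def predict(model: PLSCalibration, X_new: np.ndarray) -> np.ndarray:
    """Predict concentrations (% w/w) for new spectra."""
    return _preprocessed(model, X_new) @ model.coefficients + model.y_center


def project_scores(model: PLSCalibration, X_new: np.ndarray) -> np.ndarray:
    """Project new spectra into the model's latent-variable (score) space."""
    return _preprocessed(model, X_new) @ model.x_rotations


def select_lv(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int,
    folds: int = 5,
    parsimony_tol: float = 0.0,
):
    """Choose the LV count by k-fold cross-validation.

    Folds are venetian blinds over the concentration-ordered samples
    (position i of the sorted list goes to fold i mod folds), which is
    deterministic and stratifies concentration across folds. RMSECV(k) =
    sqrt(sum of held-out squared errors / n). Ties (within 1e-12 of the
    minimum) resolve to the smallest LV count; ``parsimony_tol`` > 0
    additionally accepts the smallest k with RMSECV(k) <=
    (1 + parsimony_tol) * min.

    Returns ``(n_lv, rmsecv_curve)`` with the curve indexed by k-1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if folds < 2 or folds > n:
        raise ValueError("folds must be in 2..n")
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    order = np.argsort(-y, kind="stable")
    fold_of = np.empty(n, dtype=int)
    fold_of[order] = np.arange(n) % folds
    min_train = min(int(np.sum(fold_of != f)) for f in range(folds))
    kmax = min(max_lv, min_train - 1, p)
    if kmax < max_lv:
        warnings.warn(
            f"max_lv={max_lv} exceeds the feasible component count; truncated to {kmax}",
            UserWarning,
            stacklevel=2,
        )
    sse = np.zeros(kmax)
    for f in range(folds):
        tr = fold_of != f
        te = ~tr
        scaler = autoscale_fit(X[tr])
        Xs = autoscale_apply(scaler, X[tr])
        x_mean = Xs.mean(axis=0)
        y_center = float(y[tr].mean())
        W, P, q, T, found = _nipals_pls1(Xs - x_mean, y[tr] - y_center, kmax)
        R = W @ np.linalg.inv(P.T @ W)
        Xte = autoscale_apply(scaler, X[te]) - x_mean
        scores_te = Xte @ R  # n_te x found
        # cumulative prediction over components; pad past rank with the last
        contrib = scores_te * q
        cum = np.cumsum(contrib, axis=1)
        for k in range(kmax):
            kk = min(k, found - 1)
            pred = cum[:, kk] + y_center
            sse[k] += float(np.sum((pred - y[te]) ** 2))
    curve = np.sqrt(sse / n)
    best = float(curve.min())
    tol = best + 1e-12
    if parsimony_tol > 0:
        tol = max(tol, (1.0 + parsimony_tol) * best)
    n_lv = int(np.flatnonzero(curve <= tol)[0]) + 1
    return n_lv, curve


def mc_outlier_detect(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    n_runs: int = 1000,
    holdout_fraction: float = 0.2,
    seed: int = 1,
    threshold_multiplier: float = 3.0,
) -> OutlierReport:
    """Monte-Carlo outlier screening by repeated random hold-out.

    Each run holds out ``holdout_fraction`` of the samples, fits PLS on the
    rest, and records the held-out absolute residuals. Per sample the mean
    and SD of its residual distribution are reported; flagging is driven by
    the mean (a response outlier is consistently mispredicted by a large,
    near-constant offset, so its residual SD is small — an SD condition
    would mask exactly that case). Because residual means are strongly
    right-skewed, the test runs on the log scale, where they are close to
    normal: sample i is flagged iff log(mean_i) exceeds the mean +
    ``threshold_multiplier`` * SD of the other samples' log-means
    (jackknifed, so a gross outlier cannot inflate its own cut).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n_runs < 100:
        raise ValueError("n_runs must be >= 100 for stable residual statistics")
    if not 0.0 < holdout_fraction < 0.5:
        raise ValueError("holdout_fraction must lie in (0, 0.5)")
    m = max(1, int(round(holdout_fraction * n)))
    rng = np.random.default_rng(seed)
    residuals: list[list[float]] = [[] for _ in range(n)]
    for _ in range(n_runs):
        held = rng.choice(n, size=m, replace=False)
        mask = np.ones(n, dtype=bool)
        mask[held] = False
        model = fit_pls(X[mask], y[mask], n_lv=n_lv)
        pred = predict(model, X[held])
        for i, r in zip(held, np.abs(pred - y[held])):
            residuals[int(i)].append(float(r))
    counts = np.array([len(r) for r in residuals])
    if np.any(counts < 2):
        short = np.flatnonzero(counts < 2).tolist()
        raise RuntimeError(
            f"samples {short} held out fewer than twice in {n_runs} runs; "
            "increase n_runs"
        )
    means = np.array([np.mean(r) for r in residuals])
    sds = np.array([np.std(r, ddof=1) for r in residuals])
    log_means = np.log(np.maximum(means, 1e-300))
    flags = np.zeros(n, dtype=bool)
    for i in range(n):
        rest = np.delete(log_means, i)
        flags[i] = log_means[i] > rest.mean() + threshold_multiplier * rest.std(ddof=1)
    return OutlierReport(
        mean_residual=means,
        sd_residual=sds,
        flags=flags,
        n_runs=n_runs,
        threshold_multiplier=threshold_multiplier,
    )
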