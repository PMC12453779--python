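"""Regression evaluation metrics for affinity prediction.

Concordance index (CI): over all observation pairs with distinct true
affinities, the fraction predicted in the correct relative order, with
ties in the predictions counted as 1/2.  R^2 is the ordinary coefficient
of determination.  rm^2 is Roy's modified squared correlation,
r^2 * (1 - sqrt(|r^2 - r0^2|)), where r^2 is the squared Pearson
correlation and r0^2 the coefficient of determination of the
through-origin regression of the observations on the predictions; it
penalizes divergence between the free-intercept and through-origin fits.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import mean_squared_error as _sk_mse
from sklearn.metrics import r2_score as _sk_r2

from .exceptions import UndefinedMetricError

__all__ = ["concordance_index", "mse", "r2_score", "rm2_score", "evaluate_all"]


def _validate(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    if y_true.size < 2:
        raise UndefinedMetricError("need at least 2 observations")
    return y_true, y_pred


def concordance_index(y_true, y_pred) -> float:
    """CI in [0, 1]; 1 = perfect ranking, 0.5 = random, 0 = reversed."""
    y_true, y_pred = _validate(y_true, y_pred)
    # vectorized over all ordered pairs with y_true_i > y_true_j
    diff_true = y_true[:, None] - y_true[None, :]
    gt = diff_true > 0
    n_pairs = int(gt.sum())
    if n_pairs == 0:
        raise UndefinedMetricError("all true values tied; CI undefined")
    diff_pred = y_pred[:, None] - y_pred[None, :]
    score = np.where(diff_pred > 0, 1.0, np.where(diff_pred == 0, 0.5, 0.0))
    return float(score[gt].sum() / n_pairs)


def mse(y_true, y_pred) -> float:
    y_true, y_pred = _validate(y_true, y_pred)
    return float(_sk_mse(y_true, y_pred))


def r2_score(y_true, y_pred) -> float:
    """R^2 = 1 - SS_res / SS_tot (undefined for zero-variance y_true)."""
    y_true, y_pred = _validate(y_true, y_pred)
    if np.var(y_true) == 0:
        raise UndefinedMetricError("zero variance in y_true; R^2 undefined")
    return float(_sk_r2(y_true, y_pred))


def rm2_score(y_true, y_pred) -> float:
    """Roy's rm^2 = r^2 * (1 - sqrt(|r^2 - r0^2|))."""
    y_true, y_pred = _validate(y_true, y_pred)
    if np.var(y_true) == 0 or np.var(y_pred) == 0:
        raise UndefinedMetricError("zero variance; rm^2 undefined")
    r = np.corrcoef(y_true, y_pred)[0, 1]
    r2 = r * r
    k = float(np.sum(y_true * y_pred) / np.sum(y_pred * y_pred))
    ss_res0 = float(np.sum((y_true - k * y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r02 = 1.0 - ss_res0 / ss_tot
    return float(r2 * (1.0 - np.sqrt(abs(r2 - r02))))


def evaluate_all(y_true, y_pred) -> dict[str, float]:
    """All four metrics on one prediction vector."""
    return {
        "mse": mse(y_true, y_pred),
        "ci": concordance_index(y_true, y_pred),
        "r2": r2_score(y_true, y_pred),
        "rm2": rm2_score(y_true, y_pred),
    }
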