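"""Evaluation metrics for affinity regression: CI, MSE, r²m.

Concordance index (CI) follows the convention of the affinity-prediction
literature: pairs with tied true affinities are excluded from the comparable
set; on comparable pairs a correctly ordered prediction earns 1, a tied
prediction earns 0.5.  r²m is the modified external-validation statistic
``r² · (1 − sqrt(|r² − r₀²|))`` where r² is the squared Pearson correlation
(with intercept) and r₀² the squared correlation through the origin.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .errors import InputError, UndefinedMetricError

__all__ = ["EvalResult", "concordance_index", "mse_metric", "rm2_metric", "evaluate"]


@dataclass
class EvalResult:
    ci: float
    mse: float
    rm2: float
    n_pairs_compared: int

    def to_dict(self) -> dict:
        return asdict(self)


def _check_pair(y_true, y_pred, min_len: int = 1):
    y_true = np.asarray(y_true, dtype=np.float64).ravel()
    y_pred = np.asarray(y_pred, dtype=np.float64).ravel()
    if y_true.shape != y_pred.shape:
        raise InputError("y_true and y_pred must have equal length")
    if y_true.size < min_len:
        raise InputError(f"need at least {min_len} observations")
    return y_true, y_pred


def concordance_index(y_true, y_pred) -> float:
    """Fraction of correctly ordered comparable pairs (ties earn 0.5).

    Raises :class:`UndefinedMetricError` when all true values are tied
    (no comparable pairs).
    """
    y_true, y_pred = _check_pair(y_true, y_pred, min_len=2)
    # ordered pairs (i, j) with y_true[i] > y_true[j]; each unordered
    # comparable pair appears exactly once
    greater = y_true[:, None] > y_true[None, :]
    n_comparable = int(greater.sum())
    if n_comparable == 0:
        raise UndefinedMetricError("all true affinities tied: CI undefined")
    pred_diff = y_pred[:, None] - y_pred[None, :]
    credit = np.where(pred_diff > 0, 1.0, np.where(pred_diff == 0, 0.5, 0.0))
    return float(credit[greater].sum() / n_comparable)


def mse_metric(y_true, y_pred) -> float:
    """Mean squared error ``(1/n) Σ (Yᵢ − yᵢ)²``."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    return float(np.mean((y_true - y_pred) ** 2))


def rm2_metric(y_true, y_pred) -> float:
    """Modified r²m: ``r²·(1 − sqrt(|r² − r₀²|))``.

    r₀² is the determination coefficient of the best through-origin fit
    ŷ → k·ŷ of the observations, with k = Σ(y·ŷ)/Σ(ŷ²), measured against
    the intercept-including total sum of squares.
    """
    y_true, y_pred = _check_pair(y_true, y_pred, min_len=3)
    if np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        raise UndefinedMetricError("zero variance: r²m undefined")
    r = np.corrcoef(y_true, y_pred)[0, 1]
    r2 = r * r
    k = float(np.sum(y_true * y_pred) / np.sum(y_pred**2))
    ss_res0 = float(np.sum((y_true - k * y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r02 = 1.0 - ss_res0 / ss_tot
    return float(r2 * (1.0 - np.sqrt(abs(r2 - r02))))


def evaluate(y_true, y_pred) -> EvalResult:
    """Compute the full metric suite on one labeled prediction set.

    Unlike the individual metric functions, an undefined component (e.g.
    r²m for a constant predictor) is reported as NaN rather than raising,
    so the defined metrics are still returned.
    """
    y_true, y_pred = _check_pair(y_true, y_pred, min_len=2)
    greater = y_true[:, None] > y_true[None, :]
    try:
        ci = concordance_index(y_true, y_pred)
    except UndefinedMetricError:
        ci = float("nan")
    try:
        rm2 = rm2_metric(y_true, y_pred)
    except UndefinedMetricError:
        rm2 = float("nan")
    return EvalResult(
        ci=ci,
        mse=mse_metric(y_true, y_pred),
        rm2=rm2,
        n_pairs_compared=int(greater.sum()),
    )
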