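"""Comparator fit metrics for binary-outcome predictions.

The alternatives the IMV is contrasted against: the Brier-skill-style R²
(1 minus the ratio of squared prediction error to squared error of the
training prevalence), the Mann–Whitney AUC, the F1 score, the AIC/BIC
information criteria, and the RMSE of estimated versus true probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .core import _as_outcomes, _as_probs, mean_log_likelihood

__all__ = [
    "MetricsBundle",
    "r2_brier",
    "auc",
    "f1",
    "aic_bic",
    "rmse_probabilities",
    "metrics_bundle",
]


def r2_brier(p, y, ybar: float) -> float:
    """R² as one minus squared error relative to a supplied prevalence.

    ``1 - sum((y - p)^2) / sum((y - ybar)^2)`` with ``ybar`` the *training*
    prevalence (supplied, not recomputed from ``y``), so out-of-sample skill
    is judged against the constant base-rate predictor.
    """
    y = _as_outcomes(y)
    p = _as_probs(p, y.size)
    ybar = float(ybar)
    if not 0.0 < ybar < 1.0:
        raise ValueError(f"prevalence must lie in (0, 1), got {ybar}")
    denom = float(np.sum((y - ybar) ** 2))
    return 1.0 - float(np.sum((y - p) ** 2)) / denom


def auc(p, y) -> float:
    """Area under the ROC curve, Mann–Whitney form.

    The fraction of (positive, negative) pairs in which the positive
    observation receives the higher prediction, with ties counted 1/2;
    a constant prediction therefore scores exactly 0.5.
    """
    y = _as_outcomes(y)
    p = np.asarray(p, dtype=float)
    if p.size != y.size:
        raise ValueError("length mismatch between predictions and outcomes")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: outcomes contain a single class")
    ranks = rankdata(p)  # average ranks give ties half credit
    return float(
        (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


def f1(p, y, threshold: float = 0.5) -> float:
    """F1 score (harmonic mean of precision and recall) at a hard threshold.

    Predictions at or above ``threshold`` are classified positive.  Returns
    0 when there are no predicted positives or no true positives.
    """
    y = _as_outcomes(y)
    p = np.asarray(p, dtype=float)
    if p.size != y.size:
        raise ValueError("length mismatch between predictions and outcomes")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    yhat = (p >= threshold).astype(float)
    tp = float(np.sum((yhat == 1) & (y == 1)))
    if yhat.sum() == 0 or y.sum() == 0 or tp == 0:
        return 0.0
    precision = tp / yhat.sum()
    recall = tp / y.sum()
    return float(2.0 * precision * recall / (precision + recall))


def aic_bic(loglik_total: float, n_params: int, n_obs: int) -> tuple[float, float]:
    """AIC and BIC from a total log-likelihood and a parameter count."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    aic_ = 2.0 * n_params - 2.0 * loglik_total
    bic_ = n_params * float(np.log(n_obs)) - 2.0 * loglik_total
    return float(aic_), float(bic_)


def rmse_probabilities(p_hat, p_true) -> float:
    """Root-mean-square error of estimated probabilities against true ones."""
    p_hat = np.asarray(p_hat, dtype=float)
    p_true = np.asarray(p_true, dtype=float)
    if p_hat.shape != p_true.shape:
        raise ValueError("length mismatch between probability vectors")
    return float(np.sqrt(np.mean((p_hat - p_true) ** 2)))


@dataclass(frozen=True)
class MetricsBundle:
    r2: float
    auc: float
    f1: float
    aic: float
    bic: float
    rmse_p: float


def metrics_bundle(
    p,
    y,
    ybar: float,
    n_params: int,
    p_true=None,
    threshold: float = 0.5,
) -> MetricsBundle:
    """All comparator metrics for one prediction set, side by side.

    ``rmse_p`` is NaN unless the true generating probabilities are supplied.
    """
    y = _as_outcomes(y)
    p = _as_probs(p, y.size)
    ll_total = mean_log_likelihood(p, y) * y.size
    aic_, bic_ = aic_bic(ll_total, n_params, y.size)
    rmse = rmse_probabilities(p, p_true) if p_true is not None else float("nan")
    return MetricsBundle(
        r2=r2_brier(p, y, ybar),
        auc=auc(p, y),
        f1=f1(p, y, threshold),
        aic=aic_,
        bic=bic_,
        rmse_p=rmse,
    )
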