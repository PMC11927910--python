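"""Core InterModel Vigorish (IMV) algebra.

The IMV compares two probabilistic predictive systems for a binary outcome
by translating each system's per-observation (geometric-mean) likelihood
into the weight of a single biased coin with the same expected
log-likelihood per toss, and then asking what a bookmaker would expect to
win per unit wagered if odds were set from the baseline coin while outcomes
actually followed the enhanced coin:

    omega = (w1 - w0) / w0

where ``w0``, ``w1`` in [1/2, 1) are the entropy-matched coin weights of the
baseline and enhanced predictions.  The quantity is portable across
outcomes with different prevalences because every predictive system is
reduced to the same physical reference (a weighted coin) before comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "NoMatchingCoinError",
    "DegeneratePrevalenceError",
    "ImvResult",
    "mean_log_likelihood",
    "geometric_mean_likelihood",
    "coin_entropy",
    "weight_from_mean_log_likelihood",
    "weight_from_predictions",
    "fair_odds",
    "imv_from_weights",
    "imv",
    "prevalence_predictions",
]

LOG2 = float(np.log(2.0))

# clipping bound for saturated probabilities when clip=True
CLIP_EPS = 1e-12

# largest representable weight; coin_entropy(_W_MAX) ~ -2.9e-11
_W_MAX = 1.0 - 1e-12

# slack below -log 2 treated as the w = 1/2 boundary (pure rounding noise)
_BOUNDARY_TOL = 1e-12


class NoMatchingCoinError(ValueError):
    """Mean log-likelihood below -log 2: no coin weight in [1/2, 1) matches.

    Predictions this poor are, on average, less informative than any single
    weighted coin can be; the entropy-matching equation has no solution with
    w >= 1/2.
    """


class DegeneratePrevalenceError(ValueError):
    """Constant training outcomes cannot form an interior prevalence."""


def _as_outcomes(y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 1:
        raise ValueError("outcomes must be a non-empty 1-d sequence")
    if not np.all((y == 0.0) | (y == 1.0)):
        raise ValueError("outcomes must be exactly 0 or 1")
    return y


def _as_probs(p, n: int, clip: bool = False) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("predictions must be a 1-d sequence")
    if p.size != n:
        raise ValueError(
            f"length mismatch: {p.size} predictions vs {n} outcomes"
        )
    if clip:
        p = np.clip(p, CLIP_EPS, 1.0 - CLIP_EPS)
    if np.any(p <= 0.0) or np.any(p >= 1.0) or not np.all(np.isfinite(p)):
        raise ValueError(
            "predictions must lie strictly in (0, 1); pass clip=True to map "
            "saturated values to [1e-12, 1 - 1e-12]"
        )
    return p


def mean_log_likelihood(p, y, clip: bool = False) -> float:
    """Average log-likelihood (nats per observation) of predictions ``p`` on ``y``.

    Returns (1/n) * sum_i [y_i log p_i + (1 - y_i) log(1 - p_i)], which is
    always negative for interior probabilities.
    """
    y = _as_outcomes(y)
    p = _as_probs(p, y.size, clip=clip)
    return float(np.mean(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def geometric_mean_likelihood(p, y, clip: bool = False) -> float:
    """Geometric mean of the per-observation likelihoods, A(p; y) in (0, 1).

    Equals the n-th root of the full likelihood, so systems evaluated on
    samples of different size are put on a common per-observation scale.
    """
    return float(np.exp(mean_log_likelihood(p, y, clip=clip)))


def coin_entropy(w) -> float:
    """Expected log-likelihood of one toss of a coin with heads-probability ``w``.

    ``w log w + (1 - w) log(1 - w)``: the negative Shannon entropy in nats.
    Strictly increasing on [1/2, 1) from -log 2 towards 0.
    """
    w = float(w)
    if not 0.0 < w < 1.0:
        raise ValueError(f"coin weight must lie in (0, 1), got {w}")
    return w * np.log(w) + (1.0 - w) * np.log1p(-w)


def weight_from_mean_log_likelihood(
    ll: float, on_subcoin: str = "raise"
) -> float:
    """Invert the coin-entropy equation: the unique w in [1/2, 1) with
    ``coin_entropy(w) == ll``.

    Parameters
    ----------
    ll
        Mean log-likelihood in nats; must satisfy ``ll >= -log 2`` for a
        solution to exist.
    on_subcoin
        What to do when ``ll < -log 2``: ``"raise"`` (default) raises
        :class:`NoMatchingCoinError`; ``"clamp"`` returns the boundary 0.5,
        matching the behaviour of boundary-constrained optimisation.
    """
    ll = float(ll)
    if not np.isfinite(ll) or ll >= 0.0:
        raise ValueError(f"mean log-likelihood must be finite and < 0, got {ll}")
    if ll <= -LOG2:
        if ll >= -LOG2 - _BOUNDARY_TOL:
            return 0.5
        if on_subcoin == "clamp":
            return 0.5
        raise NoMatchingCoinError(
            f"mean log-likelihood {ll:.6f} < -log 2 = {-LOG2:.6f}: predictions "
            "are on average worse than any single weighted coin; no matching "
            "weight exists in [1/2, 1)"
        )
    if ll >= coin_entropy(_W_MAX):
        return _W_MAX
    w = brentq(lambda v: coin_entropy(v) - ll, 0.5, _W_MAX, xtol=1e-15)
    assert abs(coin_entropy(w) - ll) < 1e-10
    return float(w)


def weight_from_predictions(p, y, clip: bool = False, on_subcoin: str = "raise") -> float:
    """Entropy-matched coin weight w(p; y) of predictions ``p`` on outcomes ``y``."""
    return weight_from_mean_log_likelihood(
        mean_log_likelihood(p, y, clip=clip), on_subcoin=on_subcoin
    )


def fair_odds(w) -> float:
    """Odds ratio O(w) = w / (1 - w) at which a bet on the outcome is fair."""
    w = float(w)
    if w >= 1.0:
        raise ValueError("fair odds are infinite at w = 1")
    if w <= 0.0:
        raise ValueError(f"coin weight must be positive, got {w}")
    return w / (1.0 - w)


def imv_from_weights(w0, w1) -> float:
    """House edge (w1 - w0) / w0 when odds come from w0 but outcomes follow w1.

    This is the expected profit per unit wagered of the side information in
    the enhanced coin; over w0, w1 in [1/2, 1) it ranges over [-1/2, 1].
    """
    w0, w1 = float(w0), float(w1)
    for w in (w0, w1):
        if not 0.5 <= w < 1.0:
            raise ValueError(f"coin weights must lie in [1/2, 1), got {w}")
    return (w1 - w0) / w0


@dataclass(frozen=True)
class ImvResult:
    """One baseline/enhanced comparison.

    Attributes
    ----------
    w0, w1 : entropy-matched coin weights of baseline and enhanced predictions
    omega : the IMV, (w1 - w0) / w0
    a0, a1 : geometric-mean likelihoods of the two systems
    n : number of observations
    """

    w0: float
    w1: float
    omega: float
    a0: float
    a1: float
    n: int


def imv(p0, p1, y, clip: bool = False, on_subcoin: str = "raise") -> ImvResult:
    """InterModel Vigorish of enhanced predictions ``p1`` over baseline ``p0``.

    The argument order matters: the metric is asymmetric.  ``omega > 0``
    means ``p1`` carries monetisable information beyond ``p0`` on ``y``.
    """
    y = _as_outcomes(y)
    p0 = _as_probs(p0, y.size, clip=clip)
    p1 = _as_probs(p1, y.size, clip=clip)
    ll0 = mean_log_likelihood(p0, y)
    ll1 = mean_log_likelihood(p1, y)
    w0 = weight_from_mean_log_likelihood(ll0, on_subcoin=on_subcoin)
    w1 = weight_from_mean_log_likelihood(ll1, on_subcoin=on_subcoin)
    return ImvResult(
        w0=w0,
        w1=w1,
        omega=imv_from_weights(w0, w1),
        a0=float(np.exp(ll0)),
        a1=float(np.exp(ll1)),
        n=int(y.size),
    )


def prevalence_predictions(y_train, n_out: int) -> np.ndarray:
    """Constant predictions equal to the training prevalence (base rate).

    The simplest baseline predictive system: predict mean(y_train) for
    every one of ``n_out`` observations.
    """
    y_train = _as_outcomes(y_train)
    m = float(y_train.mean())
    if m <= 0.0 or m >= 1.0:
        raise DegeneratePrevalenceError(
            "training outcomes are constant; prevalence is not an interior "
            "probability"
        )
    if n_out < 1:
        raise ValueError("n_out must be >= 1")
    return np.full(int(n_out), m)
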