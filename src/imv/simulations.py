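"""Simulation studies contrasting the IMV with comparator metrics.

Four configurable, seeded experiments, each emitting a tidy table of raw
draws (no smoothing):

1. Oracle/Overfit behaviour of a slope-only logistic model across sample
   sizes and effect sizes.
2. A psi-noise study in which true probabilities drawn from a rescaled Beta
   distribution are perturbed by +/- psi, tracing each metric's sensitivity
   to estimation error of controlled magnitude.
3. A prevalence/effect-size trade-off: the slope beta1 required to hold the
   population IMV constant while the intercept beta0 (hence prevalence)
   grows, contrasted with R².
4. A misspecification study comparing the IMV with AIC/BIC across three
   wrong models (quadratic overfit, noisy covariate, cloglog link).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import brentq
from scipy.special import expit, xlogy

from .core import (
    CLIP_EPS,
    LOG2,
    imv,
    prevalence_predictions,
    weight_from_mean_log_likelihood,
)
from .metrics import auc, f1, r2_brier, rmse_probabilities
from .resampling import oracle_overfit_study

__all__ = [
    "LogisticSimConfig",
    "BetaNoiseConfig",
    "OmegaTargetConfig",
    "MisspecSimConfig",
    "simulate_logistic",
    "run_oracle_overfit_grid",
    "run_oracle_overfit_cells",
    "simulate_beta_noise",
    "rescaled_beta_variance",
    "break_even_psi",
    "run_psi_sweep",
    "population_omega",
    "find_beta1_for_omega",
    "run_prevalence_tradeoff",
    "run_misspecification_study",
    "first_negative_crossing",
]

_MAX_SEED = 2**31 - 1


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, _MAX_SEED, size=n)


# ---------------------------------------------------------------------------
# logistic DGP and the oracle/overfit study grid


@dataclass(frozen=True)
class LogisticSimConfig:
    """Bernoulli outcomes from p = sigmoid(beta0 + beta1 * x), x ~ Normal(0,1)."""

    beta1: float
    n: int
    beta0: float = 0.0
    seed: int = 0


def simulate_logistic(cfg: LogisticSimConfig):
    """Draw (x, p_true, y, y_star): two outcome sets sharing x and p_true.

    ``y`` plays the role of training outcomes and ``y_star`` of fresh test
    outcomes generated from the same probabilities.
    """
    rng = np.random.default_rng(cfg.seed)
    x = rng.standard_normal(cfg.n)
    p = expit(cfg.beta0 + cfg.beta1 * x)
    y = rng.binomial(1, p).astype(float)
    y_star = rng.binomial(1, p).astype(float)
    return x, p, y, y_star


def run_oracle_overfit_grid(
    beta1_set=(0.01, 0.1, 0.5),
    n_draws: int = 5000,
    seed: int = 0,
    log10_n_range: tuple[float, float] = (np.log10(50), np.log10(10000)),
) -> pd.DataFrame:
    """Oracle/Overfit study over a log-uniform sample-size grid.

    For each beta1 and each draw, N = round(10^u) with u uniform on the
    stated log10 range; one row per successful draw with columns
    (beta1, n, omega0, oracle, overfit).  Fit failures are logged and skipped.
    """
    rows = []
    for beta1 in beta1_set:
        rng = np.random.default_rng([int(seed), int(round(beta1 * 1000))])
        seeds = rng.integers(0, _MAX_SEED, size=n_draws)
        us = rng.uniform(*log10_n_range, size=n_draws)
        for u, s in zip(us, seeds):
            n = int(round(10.0**u))
            try:
                rep = oracle_overfit_study(n, beta1, int(s))
            except RuntimeError as exc:
                warnings.warn(f"draw skipped (beta1={beta1}, n={n}): {exc}")
                continue
            rows.append((beta1, n, rep.omega0, rep.oracle, rep.overfit))
    return pd.DataFrame(
        rows, columns=["beta1", "n", "omega0", "oracle", "overfit"]
    )


def run_oracle_overfit_cells(
    beta1_values, n_values, n_reps: int, seed: int = 0
) -> pd.DataFrame:
    """Oracle/Overfit study on a fixed (beta1, N) design with replicates."""
    rows = []
    for beta1 in beta1_values:
        for n in n_values:
            seeds = _child_seeds(
                np.random.default_rng(
                    [int(seed), int(round(beta1 * 1000)), int(n)]
                ).integers(0, _MAX_SEED),
                n_reps,
            )
            for rep_i, s in enumerate(seeds):
                try:
                    rep = oracle_overfit_study(int(n), beta1, int(s))
                except RuntimeError as exc:
                    warnings.warn(f"replicate skipped (beta1={beta1}, n={n}): {exc}")
                    continue
                rows.append(
                    (beta1, int(n), rep_i, rep.omega0, rep.oracle, rep.overfit)
                )
    return pd.DataFrame(
        rows, columns=["beta1", "n", "rep", "omega0", "oracle", "overfit"]
    )


# ---------------------------------------------------------------------------
# rescaled-Beta psi-noise study


@dataclass(frozen=True)
class BetaNoiseConfig:
    """True probabilities from Beta(a, b) rescaled to (Psi, 1 - Psi), then
    perturbed by +/- psi with independent equiprobable signs."""

    n: int = 1000
    a: float = 1.0
    b: float = 1.0
    Psi: float = 0.2
    psi: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.Psi < 0.5:
            raise ValueError("Psi must lie in [0, 0.5)")
        if not 0.0 <= self.psi <= self.Psi:
            raise ValueError("psi must lie in [0, Psi]")


def simulate_beta_noise(cfg: BetaNoiseConfig):
    """Draw (p, p1, ybar_train, y_test) for one psi-noise replicate.

    Two outcome sets are drawn from Bernoulli(p): the first only supplies
    the training prevalence ybar, the second is the test set on which
    metrics are evaluated.  p1 = p +/- psi emulates an estimate of p whose
    error magnitude is exactly psi.
    """
    rng = np.random.default_rng(cfg.seed)
    raw = rng.beta(cfg.a, cfg.b, size=cfg.n)
    p = cfg.Psi + (1.0 - 2.0 * cfg.Psi) * raw
    y_train = rng.binomial(1, p).astype(float)
    y_test = rng.binomial(1, p).astype(float)
    signs = rng.choice([-1.0, 1.0], size=cfg.n)
    p1 = p + signs * cfg.psi
    assert np.all((p1 > 0.0) & (p1 < 1.0)), "perturbed probabilities left (0,1)"
    return p, p1, float(y_train.mean()), y_test


def rescaled_beta_variance(a: float, b: float, Psi: float) -> float:
    """Closed-form variance of Beta(a, b) linearly rescaled to (Psi, 1 - Psi)."""
    var_beta = a * b / ((a + b) ** 2 * (a + b + 1.0))
    return float((1.0 - 2.0 * Psi) ** 2 * var_beta)


def break_even_psi(a: float = 1.0, b: float = 1.0, Psi: float = 0.2) -> float:
    """Perturbation magnitude at which psi^2 equals V(p): the point where the
    perturbed estimate's expected squared error matches the prevalence's."""
    return float(np.sqrt(rescaled_beta_variance(a, b, Psi)))


def run_psi_sweep(
    n_samples: int = 2000,
    n: int = 1000,
    a: float = 1.0,
    b: float = 1.0,
    Psi: float = 0.2,
    seed: int = 0,
    f1_threshold: float = 0.5,
) -> pd.DataFrame:
    """Sweep psi ~ Uniform(0, Psi) and record every metric per draw.

    Each row compares both the perturbed estimate p1 and the truth p against
    the training prevalence on the test outcomes.  Raw draws only; any
    smoothing is left to the consumer.
    """
    master = np.random.default_rng(seed)
    psis = master.uniform(0.0, Psi, size=n_samples)
    seeds = master.integers(0, _MAX_SEED, size=n_samples)
    rows = []
    for psi, s in zip(psis, seeds):
        cfg = BetaNoiseConfig(n=n, a=a, b=b, Psi=Psi, psi=float(psi), seed=int(s))
        p, p1, ybar, y_test = simulate_beta_noise(cfg)
        p0 = np.full(n, ybar)
        rows.append(
            (
                psi,
                imv(p0, p1, y_test, on_subcoin="clamp").omega,
                imv(p0, p, y_test, on_subcoin="clamp").omega,
                r2_brier(p1, y_test, ybar),
                r2_brier(p, y_test, ybar),
                auc(p1, y_test),
                auc(p, y_test),
                f1(p1, y_test, f1_threshold),
                f1(p, y_test, f1_threshold),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "psi",
            "omega_p1",
            "omega_truth",
            "r2_p1",
            "r2_truth",
            "auc_p1",
            "auc_truth",
            "f1_p1",
            "f1_truth",
        ],
    )


def first_negative_crossing(psi, values, window: int = 201) -> float:
    """Smallest psi at which the running mean of ``values`` (ordered by psi)
    turns negative; NaN if it never does.

    A centred moving average of width ``window`` stands in for presentation
    smoothing; the crossing is the psi at the first negative window centre.
    """
    psi = np.asarray(psi, dtype=float)
    values = np.asarray(values, dtype=float)
    order = np.argsort(psi)
    psi, values = psi[order], values[order]
    if window >= psi.size:
        raise ValueError("window must be smaller than the number of draws")
    kernel = np.ones(window) / window
    smooth = np.convolve(values, kernel, mode="valid")
    centers = psi[window // 2 : window // 2 + smooth.size]
    neg = np.nonzero(smooth < 0.0)[0]
    return float(centers[neg[0]]) if neg.size else float("nan")


# ---------------------------------------------------------------------------
# prevalence / effect-size trade-off at constant population IMV


def _hermite_nodes(n_nodes: int):
    t, w = np.polynomial.hermite_e.hermegauss(n_nodes)
    return t, w / np.sqrt(2.0 * np.pi)


def population_omega(beta0: float, beta1: float, n_nodes: int = 128) -> float:
    """Population IMV of p = sigmoid(beta0 + beta1*x) over the prevalence baseline.

    Expectations over x ~ Normal(0, 1) are computed by Gauss-Hermite
    quadrature.  The baseline predicts the DGP-implied prevalence
    ybar = E[p]; its expected log-likelihood is the negative entropy of
    Bernoulli(ybar), while the enhanced side scores E[p log p +
    (1-p) log(1-p)].  Both are inverted to coin weights and combined.
    """
    x, wq = _hermite_nodes(n_nodes)
    p = expit(beta0 + beta1 * x)
    ybar = float(wq @ p)
    # xlogy keeps nodes where p saturates in float from poisoning the sum
    ll1 = float(wq @ (xlogy(p, p) + xlogy(1.0 - p, 1.0 - p)))
    ll0 = ybar * np.log(ybar) + (1.0 - ybar) * np.log1p(-ybar)
    w0 = weight_from_mean_log_likelihood(ll0)
    w1 = weight_from_mean_log_likelihood(ll1)
    return (w1 - w0) / w0


def find_beta1_for_omega(
    beta0: float,
    omega_target: float,
    beta1_max: float = 50.0,
    tol: float = 1e-6,
    n_nodes: int = 128,
) -> float:
    """Slope beta1 at which the population IMV over prevalence hits the target.

    The population IMV is strictly increasing in beta1 at fixed beta0, so a
    bracketed root search suffices.
    """
    if omega_target <= 0.0:
        raise ValueError("omega_target must be positive")

    def gap(b1):
        return population_omega(beta0, b1, n_nodes) - omega_target

    hi = 1.0
    while gap(hi) < 0.0:
        hi *= 2.0
        if hi > beta1_max:
            raise RuntimeError(
                f"omega target {omega_target} unreachable with beta1 <= {beta1_max}"
            )
    b1 = brentq(gap, 0.0, hi, xtol=1e-12)
    if abs(gap(b1)) > tol:
        raise RuntimeError("beta1 search did not meet the omega tolerance")
    return float(b1)


@dataclass(frozen=True)
class OmegaTargetConfig:
    """Grid study: solve beta1 for each (beta0, omega target), then simulate."""

    beta0_grid: tuple = tuple(np.linspace(0.0, 0.5, 11))
    omega_targets: tuple = (0.01, 0.1)
    n: int = 100_000
    n_reps: int = 1
    seed: int = 0


def run_prevalence_tradeoff(cfg: OmegaTargetConfig) -> pd.DataFrame:
    """Trace the beta1 needed to hold the population IMV constant as beta0 grows.

    For each grid cell the solved beta1 is used to simulate (x, y, y*) at
    cfg.n; R² is computed with the true probabilities against the sigma(beta0)
    constant, and the sample IMV of truth over the training prevalence is
    recomputed on the fresh outcomes.  One row per (beta0, target, replicate).
    """
    rows = []
    for target in cfg.omega_targets:
        for beta0 in cfg.beta0_grid:
            beta1 = find_beta1_for_omega(beta0, target)
            cell_seed = np.random.default_rng(
                [cfg.seed, int(round(beta0 * 1e6)), int(round(target * 1e6))]
            ).integers(0, _MAX_SEED)
            for rep_i, s in enumerate(_child_seeds(int(cell_seed), cfg.n_reps)):
                x, p, y, y_star = simulate_logistic(
                    LogisticSimConfig(beta0=beta0, beta1=beta1, n=cfg.n, seed=int(s))
                )
                base = expit(beta0)
                r2 = 1.0 - float(np.sum((y - p) ** 2)) / float(
                    np.sum((y - base) ** 2)
                )
                p0 = prevalence_predictions(y, cfg.n)
                omega_sample = imv(p0, p, y_star, on_subcoin="clamp").omega
                rows.append((beta0, target, beta1, rep_i, r2, omega_sample))
    return pd.DataFrame(
        rows,
        columns=["beta0", "omega_target", "beta1", "rep", "r2", "omega_sample"],
    )


# ---------------------------------------------------------------------------
# misspecification study: IMV versus information criteria


@dataclass(frozen=True)
class MisspecSimConfig:
    """Misspecification study settings.

    ``intercept=True`` fits every model with an intercept term even though
    the generating process has none — the convention of standard GLM
    software.  Without it the complementary log-log fit is forced through
    p = 1 - 1/e at x = 0 and its misfit is dominated by that artefact
    rather than by the link's shape.
    """

    beta: float = 0.5
    noise_sd: float = 0.3
    intercept: bool = True
    seed: int = 0
    log10_n_range: tuple[float, float] = (np.log10(50), np.log10(25000))


_ALTERNATIVES = ("quadratic", "noisy_x", "cloglog")


def _glm_fit(y, exog, link=None):
    family = sm.families.Binomial() if link is None else sm.families.Binomial(link=link)
    res = sm.GLM(y, exog, family=family).fit()
    if not np.all(np.isfinite(res.params)):
        raise ValueError("non-finite GLM parameters")
    p = np.clip(np.asarray(res.fittedvalues), CLIP_EPS, 1.0 - CLIP_EPS)
    return p, float(res.llf), len(res.params)


def run_misspecification_study(
    cfg: MisspecSimConfig, n_draws: int = 5000
) -> pd.DataFrame:
    """Contrast the out-of-sample IMV with Delta-AIC/BIC under misspecification.

    Per draw: N = round(10^u), u uniform on cfg.log10_n_range; outcomes from
    the slope-only logistic DGP with slope cfg.beta; four slope-only fits on
    the training outcomes (true logistic, quadratic logistic, logistic on
    x + Normal(0, noise_sd²) noise, complementary log-log link).  Each
    alternative is compared to the true-specification fit: the IMV of the
    correct fit over the alternative on the fresh outcomes, the in-sample
    Delta-AIC/BIC (alternative minus true), and each fit's probability RMSE
    against the generating probabilities.  One row per (draw, alternative).
    """
    master = np.random.default_rng(cfg.seed)
    us = master.uniform(*cfg.log10_n_range, size=n_draws)
    seeds = master.integers(0, _MAX_SEED, size=n_draws)
    rows = []
    for draw, (u, s) in enumerate(zip(us, seeds)):
        n = int(round(10.0**u))
        rng = np.random.default_rng(int(s))
        x = rng.standard_normal(n)
        p = expit(cfg.beta * x)
        y = rng.binomial(1, p).astype(float)
        y_star = rng.binomial(1, p).astype(float)
        x_noisy = x + rng.normal(0.0, cfg.noise_sd, size=n)

        def design(*cols):
            mat = np.column_stack(cols)
            return sm.add_constant(mat) if cfg.intercept else mat

        try:
            p_true_hat, ll_true, k_true = _glm_fit(y, design(x))
            fits = {
                "quadratic": _glm_fit(y, design(x, x**2)),
                "noisy_x": _glm_fit(y, design(x_noisy)),
                "cloglog": _glm_fit(y, design(x), link=sm.families.links.CLogLog()),
            }
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"draw {draw} skipped (n={n}): {exc}")
            continue
        aic_true = 2.0 * k_true - 2.0 * ll_true
        bic_true = k_true * np.log(n) - 2.0 * ll_true
        rmse_true = rmse_probabilities(p_true_hat, p)
        for alt in _ALTERNATIVES:
            p_alt, ll_alt, k_alt = fits[alt]
            omega = imv(p_alt, p_true_hat, y_star, on_subcoin="clamp").omega
            rows.append(
                (
                    draw,
                    n,
                    alt,
                    omega,
                    (2.0 * k_alt - 2.0 * ll_alt) - aic_true,
                    (k_alt * np.log(n) - 2.0 * ll_alt) - bic_true,
                    rmse_probabilities(p_alt, p),
                    rmse_true,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "draw",
            "n",
            "alternative",
            "omega",
            "delta_aic",
            "delta_bic",
            "rmse_alt",
            "rmse_true",
        ],
    )
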