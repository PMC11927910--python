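# Methods

## The model

A predictive system for a binary outcome assigns each observation `i` a
probability `pᵢ ∈ (0,1)` that `yᵢ = 1`. Its quality on data `y` is summarised
by the mean log-likelihood `ℓ̄ = (1/n) Σ [yᵢ log pᵢ + (1−yᵢ) log(1−pᵢ)]`
(natural logarithm throughout), or equivalently the geometric-mean
likelihood `A = exp(ℓ̄)`. The entropy-matched coin weight `w(p; y)` is the
unique `w ∈ [½, 1)` solving

    w log w + (1−w) log(1−w) = ℓ̄ ,

i.e. the bias of the single weighted coin whose expected log-likelihood per
toss equals the system's mean log-likelihood — the system's equivalent in a
physical reference process. Comparing a baseline and an enhanced system
through their weights gives the InterModel Vigorish
`ω = (w₁ − w₀)/w₀`: the expected profit per unit wagered when fair odds
`O = w₀/(1−w₀)` are offered but the outcome truly follows `w₁`. Over
`w₀, w₁ ∈ [½, 1)` the quantity ranges over `[−½, 1]`; it is asymmetric in
its arguments by construction (the reverse comparison is `(w₀−w₁)/w₁`, not
`−ω`).

Assumptions worth keeping in mind: predictions are strictly interior
probabilities; observations enter exchangeably (only the mean log-likelihood
matters); and the comparison prices *average* per-observation information,
so heterogeneous subgroups are blended exactly as a bankroll blends bets.

## Numerical choices

- **Weight inversion.** The negative entropy is strictly increasing on
  `[½, 1)`, so the equation is solved by bracketed root finding (Brent's
  method on `[0.5, 1 − 1e−12]`, residual checked `< 1e−10`). A dense-grid
  search is kept in the tests as an independent oracle.
- **The `−log 2` floor.** If `ℓ̄ < −log 2`, no coin in `[½, 1)` matches:
  the system is, on average, less informative than a fair coin. The core
  API raises a descriptive `NoMatchingCoinError` (silently clamping would
  report losses as break-even). Analyses that aggregate many draws —
  cross-validation and all simulation studies — instead clamp the weight at
  ½ (`on_subcoin="clamp"`), because out-of-sample mean log-likelihoods sit
  marginally below the floor on a large fraction of draws whenever a
  near-0.5-prevalence baseline is evaluated on fresh outcomes; discarding
  those draws would bias the aggregate. Values within `1e−12` of the floor
  are treated as the boundary and return exactly ½.
- **Saturated predictions.** `p ∈ {0,1}` is rejected by default; `clip=True`
  maps values into `[1e−12, 1 − 1e−12]` for model outputs that saturate in
  floating point.
- **Degenerate outcomes.** A constant training outcome has no interior
  prevalence; the prevalence baseline raises `DegeneratePrevalenceError`.
  The IMV itself still computes for interior predictions.
- **Boundary behaviour to know about.** The entropy inverse behaves like
  `½ + sqrt((ℓ̄ + log 2)/2)` near the floor, so ω estimates are noisy and
  slightly biased (upward in each weight, in opposite directions in ω) when
  a system sits at the maximum-entropy point. Two documented consequences:
  a no-signal enhanced model scores a small *negative* CV ω (≈ −0.02 at
  n = 5000, k = 10), not zero — fitting noise has a real price; and the
  Oracle diagnostic is not sign-guaranteed when the truth itself is nearly
  uninformative (see below).

## Cross-validation

`kfold_imv` assigns observations to k folds independently and uniformly
(multinomial fold sizes — the literal contract; `balanced=True` gives
near-equal folds via a permutation). For each fold both models are fitted
on the complement; the training-fold prevalence is used for the baseline,
never the held-out fold. The fold mean and sample SD (k−1 denominator) of ω
are reported; folds where the comparison is undefined are skipped, warned
about, and counted. Assignments are reproducible from the seed; an empty
fold triggers a logged redraw with seed+1.

## Oracle and Overfit diagnostics

On the slope-only logistic process `p = σ(β₁x)`, `x ~ Normal(0,1)`, with two
independent outcome sets `y` (training) and `y*` (test) sharing `x`:

- `ω₀ = IMV(ȳ, p̂; y*)` — standalone value of the fitted model over the
  training prevalence;
- `Overfit = IMV(p̂, p_true; y)` — always ≤ 0, because the in-sample MLE
  dominates the truth within its own family;
- `Oracle = IMV(p̂, p_true; y*)` — the residual value of knowing the truth.

Fits are slope-only to match the generating process (`intercept=True`
available). Perfect separation or constant outcomes trigger a reseeded
retry (up to 10, then an error). Limitation: for a near-null effect
(β₁ ≈ 0) the truth sits at the `w = ½` floor, so the Oracle can be negative
but essentially never positive; its mean is measurably below zero at small
N (≈ −0.017 at β₁ = 0.01, N = 50). The Oracle's usual positive sign is a
property of detectable effects, not of the construction.

## The simulation studies

**Psi-noise study.** True probabilities are Beta(a,b) draws linearly
rescaled to `(Ψ, 1−Ψ)`; estimates are `p₁ = p ± ψ` with equiprobable signs.
Defaults follow the study conditions: `N = 1000`, `a = b = 1`, `Ψ = 0.2`,
2000 draws of `ψ ~ Uniform(0, Ψ)`. The rescaled variance is
`V(p) = (1−2Ψ)²/12 = 0.03`, so squared-error parity with the prevalence
baseline occurs at `ψ = √0.03 ≈ 0.173`; the IMV's own parity point (equal
mean log-likelihood) is slightly lower, ≈ 0.154, and the empirical
running-mean crossing (window 201) lands between the two. Tables carry raw
draws; any smoothing is the consumer's choice.

**Prevalence trade-off.** For intercepts `β₀` on an 11-point grid over
`[0, 0.5]` and targets `ω ∈ {0.01, 0.1}`, the slope `β₁` achieving the
target *population* IMV is solved by bracketed bisection on a Gauss–Hermite
quadrature (128 nodes) of the population quantities: baseline
`ℓ̄₀ = −H(E[p])` with `E[p]` the DGP-implied prevalence, enhanced
`ℓ̄₁ = E[p log p + (1−p) log(1−p)]`. The σ(β₀)-baseline variant is a
switch. Simulation at N = 100,000 by default (20,000 in the scaled
acceptance test, 6 replicates per cell) confirms the solved targets.

**Misspecification study.** Outcomes from `p = σ(0.5x)`; alternatives are a
quadratic logistic, a logistic on `x + Normal(0, 0.3²)` noise, and a
complementary log-log link, compared with the correctly specified logistic
fit via out-of-sample IMV, in-sample ΔAIC/ΔBIC, and probability RMSE, with
`N = round(10^u)`, `u ~ Uniform(log₁₀ 50, log₁₀ 25000)`. All models include
an intercept by default, the convention of standard GLM software, even
though the generating process has none: a slope-only cloglog fit is forced
through `p = 1 − 1/e` at `x = 0` and its misfit would be dominated by that
artefact rather than by the link's shape (`intercept=False` restores
slope-only fits throughout).

## Comparator metrics

`r2_brier` is one minus the ratio of squared prediction error to the
squared error of a *supplied* prevalence (the training base rate), the
Brier-skill convention; AUC is the Mann–Whitney pair statistic with
half-credit ties (constant predictions score exactly 0.5); F1 thresholds at
0.5 by default and returns 0 with no predicted or true positives; AIC/BIC
are `2k − 2ℓ` and `k log n − 2ℓ`. These are authored here because their
exact conventions are part of the comparison being studied; tests
cross-check them against scikit-learn.

## What the generators emulate — and what they do not

The synthetic processes cover controlled effect sizes, prevalences,
estimation-error magnitudes and misspecification types, which is what the
contrasts require. They do not emulate covariate dependence structures,
measurement error in outcomes, class imbalance beyond `σ(0.5)` ≈ 0.62
prevalence, or model families beyond single-index binomial GLMs — so
passing tests certify the metric's algebra and its documented contrasts,
not performance of any applied model on real data.

## Scales used by the checked studies

Unit and property tests run in seconds. The heavier study checks use 2000
psi draws at N = 1000; 500 Oracle/Overfit replicates per (β₁, N) cell on
{50, 500, 5000}; 300 misspecification draws; and 6 replicates per
prevalence-trade-off cell at N = 20,000 — sizes at which every asserted
contrast is several Monte-Carlo standard errors wide, as the assertions
themselves verify.
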