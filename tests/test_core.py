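"""Core likelihood-to-coin-weight mapping and IMV algebra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imv import (
    DegeneratePrevalenceError,
    NoMatchingCoinError,
    coin_entropy,
    fair_odds,
    geometric_mean_likelihood,
    imv,
    imv_from_weights,
    mean_log_likelihood,
    prevalence_predictions,
    weight_from_mean_log_likelihood,
    weight_from_predictions,
)

LOG2 = np.log(2.0)

# frozen from direct high-precision summation of the toy data
TOY_LL0 = (33 * np.log(0.55) + 7 * np.log(0.45)) / 40
TOY_LL1 = (14 * np.log(0.5) + 6 * np.log(0.5) + 19 * np.log(0.9) + np.log(0.1)) / 40


class TestMeanLogLikelihood:
    def test_constant_half_gives_entropy_of_fair_coin(self):
        y = np.array([0.0, 1.0, 1.0, 0.0])
        assert mean_log_likelihood(np.full(4, 0.5), y) == pytest.approx(-LOG2)

    def test_toy_baseline_matches_direct_summation(self, toy):
        assert mean_log_likelihood(toy.p0, toy.y) == pytest.approx(
            TOY_LL0, abs=1e-14
        )
        assert TOY_LL0 == pytest.approx(-0.63295, abs=5e-5)

    def test_two_symmetric_correct_predictions(self):
        ll = mean_log_likelihood(np.array([0.9, 0.1]), np.array([1.0, 0.0]))
        assert ll == pytest.approx(np.log(0.9))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length mismatch"):
            mean_log_likelihood(np.array([0.5, 0.5]), np.array([1.0]))

    def test_boundary_probability_rejected_unless_clipped(self):
        y = np.array([1.0, 0.0])
        p = np.array([1.0, 0.5])
        with pytest.raises(ValueError, match="strictly in"):
            mean_log_likelihood(p, y)
        assert mean_log_likelihood(p, y, clip=True) < 0.0

    def test_non_binary_outcome_rejected(self):
        with pytest.raises(ValueError, match="exactly 0 or 1"):
            mean_log_likelihood(np.array([0.5, 0.5]), np.array([1.0, 2.0]))


class TestGeometricMeanLikelihood:
    def test_constant_half_is_exactly_half(self):
        y = np.array([1.0, 0.0, 1.0])
        assert geometric_mean_likelihood(np.full(3, 0.5), y) == pytest.approx(
            0.5, abs=1e-15
        )

    @pytest.mark.parametrize(
        "which,expected", [("p0", 0.53), ("p1", 0.63)]
    )
    def test_toy_values_at_two_decimals(self, toy, which, expected):
        a = geometric_mean_likelihood(getattr(toy, which), toy.y)
        assert round(a, 2) == expected


class TestCoinEntropy:
    def test_fair_coin_is_minus_log_two(self):
        assert coin_entropy(0.5) == pytest.approx(-LOG2)

    def test_matches_direct_evaluation_at_toy_weight(self):
        assert coin_entropy(0.67) == pytest.approx(-0.6342, abs=5e-5)

    def test_deterministic_limit_approaches_zero(self):
        assert -1e-8 < coin_entropy(1 - 1e-10) < 0.0

    def test_monotone_increasing_on_upper_half(self):
        ws = np.linspace(0.5, 0.999, 200)
        vals = [coin_entropy(w) for w in ws]
        assert np.all(np.diff(vals) > 0)

    @pytest.mark.parametrize("w", [0.0, 1.0, -0.1, 1.5])
    def test_domain_error(self, w):
        with pytest.raises(ValueError):
            coin_entropy(w)


class TestWeightInversion:
    def test_toy_weights_at_two_decimals(self, toy):
        assert round(weight_from_predictions(toy.p0, toy.y), 2) == 0.67
        assert round(weight_from_predictions(toy.p1, toy.y), 2) == 0.83

    def test_constant_half_maps_to_exactly_half(self):
        y = np.array([1.0, 0.0, 0.0])
        assert weight_from_predictions(np.full(3, 0.5), y) == 0.5

    def test_round_trip_over_the_entropy_range(self, rng):
        lls = rng.uniform(-LOG2 + 1e-9, -1e-9, size=1000)
        for ll in lls:
            w = weight_from_mean_log_likelihood(ll)
            assert abs(coin_entropy(w) - ll) < 1e-8

    def test_monotone_in_mean_log_likelihood(self, rng):
        lls = np.sort(rng.uniform(-LOG2 + 1e-6, -1e-6, size=200))
        ws = [weight_from_mean_log_likelihood(ll) for ll in lls]
        assert np.all(np.diff(ws) > 0)

    def test_worse_than_any_coin_raises(self):
        # confident and wrong on every observation
        y = np.array([1.0, 0.0])
        p = np.array([0.1, 0.9])
        with pytest.raises(NoMatchingCoinError):
            weight_from_predictions(p, y)

    def test_clamp_mode_returns_boundary(self):
        assert weight_from_mean_log_likelihood(-1.5, on_subcoin="clamp") == 0.5

    def test_solver_agrees_with_grid_search_oracle(self, rng):
        grid = np.arange(0.5, 1.0 - 1e-6, 1e-6)
        grid_entropy = grid * np.log(grid) + (1 - grid) * np.log1p(-grid)
        for _ in range(100):
            n = rng.integers(5, 51)
            y = (rng.random(n) < 0.5).astype(float)
            p = rng.uniform(0.35, 0.97, size=n)
            ll = mean_log_likelihood(p, y)
            if ll < -LOG2:
                continue
            w = weight_from_mean_log_likelihood(ll)
            w_grid = grid[np.argmin(np.abs(grid_entropy - ll))]
            assert abs(w - w_grid) < 1e-5


class TestFairOdds:
    @pytest.mark.parametrize("w,odds", [(0.5, 1.0), (2 / 3, 2.0), (0.8, 4.0)])
    def test_algebraic_identities(self, w, odds):
        assert fair_odds(w) == pytest.approx(odds)
        # zero expected profit at the fair odds
        assert w * (1.0 / fair_odds(w)) - (1.0 - w) == pytest.approx(0.0)

    def test_degenerate_weight(self):
        with pytest.raises(ValueError):
            fair_odds(1.0)


class TestImv:
    def test_equal_weights_give_zero(self):
        assert imv_from_weights(0.7, 0.7) == 0.0

    def test_toy_vigorish_at_two_decimals(self, toy):
        assert round(imv_from_weights(0.67172, 0.83107), 2) == 0.24
        assert round(imv(toy.p0, toy.p1, toy.y).omega, 2) == 0.24

    def test_maximal_vigorish_approaches_one(self):
        assert imv_from_weights(0.5, 1 - 1e-12) == pytest.approx(1.0)

    def test_monotone_in_each_weight(self):
        assert imv_from_weights(0.6, 0.8) > imv_from_weights(0.6, 0.7)
        assert imv_from_weights(0.7, 0.8) < imv_from_weights(0.6, 0.8)

    def test_range_over_random_weight_pairs(self, rng):
        w = rng.uniform(0.5, 1.0 - 1e-9, size=(10_000, 2))
        omegas = (w[:, 1] - w[:, 0]) / w[:, 0]
        vals = [imv_from_weights(a, b) for a, b in w[:100]]
        assert np.all(omegas >= -0.5) and np.all(omegas <= 1.0)
        assert np.all(np.asarray(vals) >= -0.5) and np.all(np.asarray(vals) <= 1.0)

    def test_self_comparison_is_exactly_zero(self, rng):
        y = (rng.random(30) < 0.6).astype(float)
        # informative predictions keep the mean log-likelihood above -log 2
        p = np.where(y == 1, rng.uniform(0.6, 0.9, 30), rng.uniform(0.1, 0.4, 30))
        assert imv(p, p, y).omega == 0.0

    def test_asymmetry_on_toy_data(self, toy):
        forward = imv(toy.p0, toy.p1, toy.y)
        reverse = imv(toy.p1, toy.p0, toy.y)
        assert reverse.omega == pytest.approx(
            (forward.w0 - forward.w1) / forward.w1
        )
        assert reverse.omega == pytest.approx(-0.1917, abs=5e-4)
        assert reverse.omega != pytest.approx(-forward.omega, abs=1e-3)

    def test_permutation_invariance(self, toy, rng):
        perm = rng.permutation(toy.y.size)
        base = imv(toy.p0, toy.p1, toy.y)
        shuf = imv(toy.p0[perm], toy.p1[perm], toy.y[perm])
        assert shuf.omega == pytest.approx(base.omega, abs=1e-12)
        assert shuf.w0 == pytest.approx(base.w0, abs=1e-12)

    def test_result_is_consistent_triple(self, toy):
        res = imv(toy.p0, toy.p1, toy.y)
        assert res.omega == pytest.approx((res.w1 - res.w0) / res.w0, abs=1e-12)
        assert res.n == 40
        assert np.exp(mean_log_likelihood(toy.p0, toy.y)) == pytest.approx(res.a0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    data=st.lists(
        st.tuples(st.integers(0, 1), st.floats(0.02, 0.98)),
        min_size=2,
        max_size=60,
    )
)
def test_weight_round_trip_property(data):
    """Any admissible prediction/outcome pair round-trips through the
    entropy-matched weight, or is explicitly below the fair-coin floor."""
    y = np.array([d[0] for d in data], dtype=float)
    p = np.array([d[1] for d in data], dtype=float)
    ll = mean_log_likelihood(p, y)
    if ll < -LOG2:
        with pytest.raises(NoMatchingCoinError):
            weight_from_mean_log_likelihood(ll)
    else:
        w = weight_from_mean_log_likelihood(ll)
        assert 0.5 <= w < 1.0
        assert coin_entropy(w) == pytest.approx(ll, abs=1e-8)


class TestPrevalencePredictions:
    def test_mean_is_broadcast(self):
        out = prevalence_predictions(np.array([1.0, 0.0, 1.0, 1.0]), 6)
        assert out.shape == (6,)
        assert np.all(out == 0.75)

    def test_toy_prevalence(self, toy):
        assert prevalence_predictions(toy.y, 5)[0] == pytest.approx(0.825)

    @pytest.mark.parametrize("y", [np.ones(4), np.zeros(4)])
    def test_degenerate_training_outcomes(self, y):
        with pytest.raises(DegeneratePrevalenceError):
            prevalence_predictions(y, 3)
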