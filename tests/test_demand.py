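"""Purchase-task capping, observed metrics, and exponentiated demand fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eftrial.demand import (DEFAULT_PRICES, DemandObservationSet,
                            cap_overconsumption, exponentiated_demand,
                            fit_exponentiated, fitted_pmax, observed_metrics,
                            shared_k_span)


class TestCapping:
    @pytest.mark.parametrize("raw,capped,flags", [
        ((60,), (50,), (True,)),
        ((50,), (50,), (False,)),
        ((0, 10, 80), (0, 10, 50), (False, False, True)),
    ])
    def test_elementwise_rule(self, raw, capped, flags):
        q, f = cap_overconsumption(raw, 50)
        assert tuple(q) == capped and tuple(f) == flags

    def test_negative_quantity_rejected(self):
        with pytest.raises(ValueError):
            cap_overconsumption((-1,), 50)

    @given(st.lists(st.integers(min_value=0, max_value=200), min_size=1,
                    max_size=13))
    @settings(derandomize=True, max_examples=50)
    def test_idempotent(self, raw):
        once, _ = cap_overconsumption(raw, 50)
        twice, flags = cap_overconsumption(once, 50)
        assert np.array_equal(once, twice) and not flags.any()


class TestObservedMetrics:
    def _obs(self, prices, q):
        return DemandObservationSet(tuple(prices), tuple(q))

    def test_basic(self):
        i, o, p = observed_metrics(self._obs((0, 1, 2, 4), (10, 8, 5, 2)))
        assert (i, o, p) == (10, 10.0, 2.0)

    def test_all_zero(self):
        i, o, p = observed_metrics(self._obs((0, 1, 2), (0, 0, 0)))
        assert (i, o, p) == (0, 0.0, 0.0)

    def test_tie_takes_lowest_price(self):
        i, o, p = observed_metrics(self._obs((0, 1, 2), (6, 4, 2)))
        assert (i, o, p) == (6, 4.0, 1.0)


class TestKSpan:
    def test_full_range(self):
        assert shared_k_span([list(range(1, 51))]) == \
            pytest.approx(math.log10(50) + 0.5)

    def test_zero_range(self):
        assert shared_k_span([(10, 10), (10,)]) == pytest.approx(0.5)

    def test_formula(self):
        assert shared_k_span([(2, 20), (0,)]) == pytest.approx(1.5)

    def test_all_zero_is_estimation_error(self):
        with pytest.raises(ValueError):
            shared_k_span([(0, 0), (0,)])


class TestExponentiatedFit:
    def test_value_at_zero_price_is_q0(self):
        for q0, a, k in [(10, 0.003, 2), (3, 0.1, 1.5), (50, 1e-4, 3)]:
            assert exponentiated_demand(0.0, q0, a, k) == pytest.approx(q0)

    def test_curve_nonincreasing_in_price(self):
        c = np.linspace(0, 100, 400)
        q = exponentiated_demand(c, 12.0, 0.005, 2.2)
        assert np.all(np.diff(q) <= 1e-12)

    def test_noiseless_recovery(self):
        q = exponentiated_demand(DEFAULT_PRICES, 10.0, 0.003, 2.0)
        obs = DemandObservationSet(DEFAULT_PRICES, tuple(q))
        fit = fit_exponentiated(obs, 2.0)
        assert fit.converged
        assert abs(fit.Q0 - 10) / 10 <= 1e-4
        assert abs(fit.alpha - 0.003) / 0.003 <= 1e-4

    def test_noiseless_recovery_matches_grid_oracle(self):
        """The optimizer lands on (within grid spacing of) the dense 2-D
        grid-search optimum."""
        q = np.asarray(exponentiated_demand(DEFAULT_PRICES, 10.0, 0.003, 2.0))
        q0s = np.linspace(5, 15, 201)
        alphas = np.geomspace(1e-4, 1e-2, 201)
        pred = q0s[:, None, None] * 10.0 ** (
            2.0 * (np.exp(-alphas[None, :, None] * q0s[:, None, None]
                          * np.asarray(DEFAULT_PRICES)[None, None, :]) - 1))
        sse = ((pred - q[None, None, :]) ** 2).sum(axis=2)
        i, j = np.unravel_index(sse.argmin(), sse.shape)
        fit = fit_exponentiated(DemandObservationSet(DEFAULT_PRICES, tuple(q)),
                                2.0)
        assert abs(fit.Q0 - q0s[i]) <= q0s[1] - q0s[0]
        assert fit.sse <= sse[i, j] + 1e-9

    def test_sse_dominates_grid_on_noisy_sets(self):
        rng = np.random.default_rng(5)
        prices = np.asarray(DEFAULT_PRICES)
        q0s = np.linspace(1, 60, 120)
        alphas = np.geomspace(1e-6, 1.0, 240)
        pred = q0s[:, None, None] * 10.0 ** (
            2.19 * (np.exp(-alphas[None, :, None] * q0s[:, None, None]
                           * prices[None, None, :]) - 1))
        for _ in range(20):
            q0 = rng.uniform(3, 30)
            a = math.exp(rng.uniform(math.log(5e-4), math.log(5e-2)))
            q = exponentiated_demand(prices, q0, a, 2.19)
            q = np.minimum(np.rint(q * 10 ** rng.normal(0, 0.1, prices.size)), 50)
            fit = fit_exponentiated(
                DemandObservationSet(DEFAULT_PRICES, tuple(int(x) for x in q)),
                2.19)
            grid_best = ((pred - q[None, None, :]) ** 2).sum(axis=2).min()
            assert fit.converged
            assert fit.sse <= grid_best + 1e-9

    def test_price_scale_invariance(self):
        """Multiplying prices by c and alpha by 1/c leaves Q unchanged."""
        c = np.asarray(DEFAULT_PRICES)
        q1 = exponentiated_demand(c, 10, 0.003, 2.0)
        q2 = exponentiated_demand(c * 4.0, 10, 0.003 / 4.0, 2.0)
        assert np.allclose(q1, q2)

    def test_all_zero_returns_nonconverged(self):
        obs = DemandObservationSet(DEFAULT_PRICES, (0,) * 13)
        fit = fit_exponentiated(obs, 2.0)
        assert not fit.converged

    def test_invalid_observation_sets(self):
        with pytest.raises(ValueError):
            DemandObservationSet((0.5, 1.0), (5, 4))   # first price not 0
        with pytest.raises(ValueError):
            DemandObservationSet((0, 1, 1), (5, 4, 3))  # not ascending
        with pytest.raises(ValueError):
            DemandObservationSet((0, 1), (5, -1))


class TestFittedPmax:
    def _fit(self, q0=10.0, alpha=0.003, k=2.0):
        q = exponentiated_demand(DEFAULT_PRICES, q0, alpha, k)
        return fit_exponentiated(
            DemandObservationSet(DEFAULT_PRICES, tuple(q)), k)

    def test_matches_fine_grid_maximizer(self):
        fit = self._fit()
        upper = 10 * fit.pmax_obs + 1
        grid = np.linspace(0, upper, 10 ** 6)
        expenditure = grid * exponentiated_demand(grid, fit.Q0, fit.alpha,
                                                  fit.k_span)
        assert abs(fitted_pmax(fit) - grid[expenditure.argmax()]) <= \
            upper / 10 ** 6 * 2

    def test_doubling_alpha_halves_pmax(self):
        p1 = fitted_pmax(self._fit(alpha=0.003))
        p2 = fitted_pmax(self._fit(alpha=0.006))
        assert p1 / p2 == pytest.approx(2.0, rel=1e-6)

    def test_monotone_decreasing_in_alpha(self):
        vals = [fitted_pmax(self._fit(alpha=a))
                for a in (0.001, 0.003, 0.01, 0.03, 0.1)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1.0  # large alpha drives Pmax toward 0

    def test_unavailable_for_nonconverged_fit(self):
        fit = fit_exponentiated(
            DemandObservationSet(DEFAULT_PRICES, (0,) * 13), 2.0)
        with pytest.raises(ValueError):
            fitted_pmax(fit)
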