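"""Titration engine, systematicity screening, and hyperbolic fitting."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eftrial.discounting import (DEFAULT_DELAYS_DAYS, IndifferenceCurve,
                                 ProtocolError, TitrationSchedule,
                                 fit_hyperbolic, johnson_bickel_screen,
                                 run_titration)
from eftrial.synthetic import simulated_chooser

from oracles import titration_binary_search

SCHEDULE = TitrationSchedule()


def constant_chooser(choice):
    return lambda ss, ll, d: choice


class TestTitration:
    def test_always_ll_sequence_and_endpoint(self):
        presented = []

        def chooser(ss, ll, d):
            if d == 1:
                presented.append(ss)
            return "LL"

        curve = run_titration(chooser, SCHEDULE)
        assert presented == [500, 750, 875, 937.5, 968.75, 984.375]
        assert curve.values == (992.1875,) * 7

    def test_always_ss_endpoint(self):
        curve = run_titration(constant_chooser("SS"), SCHEDULE)
        assert curve.values == (7.8125,) * 7

    def test_all_64_choice_paths_match_binary_search_oracle(self):
        """Exhaustive check of every possible 6-trial choice sequence."""
        one_delay = TitrationSchedule(delays_days=(30.0,))
        for path in itertools.product("SL", repeat=6):
            seq = ["SS" if c == "S" else "LL" for c in path]
            it = iter(seq)
            curve = run_titration(lambda ss, ll, d: next(it), one_delay)
            assert curve.values[0] == titration_binary_search(seq)

    def test_deterministic_hyperbolic_chooser_hits_closed_form(self):
        chooser = simulated_chooser(math.log(0.01), temperature=0.0)
        sched = TitrationSchedule(delays_days=(100.0,))
        curve = run_titration(chooser, sched)
        assert abs(curve.values[0] - 1000 / (1 + 0.01 * 100)) <= sched.resolution

    def test_invalid_choice_raises_protocol_error(self):
        with pytest.raises(ProtocolError, match="delay 1.0 trial 1"):
            run_titration(lambda ss, ll, d: "maybe", SCHEDULE)

    @given(st.lists(st.sampled_from(["SS", "LL"]), min_size=6, max_size=6))
    @settings(derandomize=True, max_examples=64)
    def test_output_within_reachable_band(self, seq):
        it = iter(seq)
        curve = run_titration(lambda ss, ll, d: next(it),
                              TitrationSchedule(delays_days=(10.0,)))
        res = SCHEDULE.resolution
        assert res <= curve.values[0] <= 1000 - res

    @given(st.floats(min_value=20.0, max_value=980.0))
    @settings(derandomize=True, max_examples=40)
    def test_threshold_chooser_converges_to_threshold(self, threshold):
        """A monotone chooser (take SS iff SS > threshold) is located to
        within one resolution step: the engine is a binary search."""
        chooser = lambda ss, ll, d: "SS" if ss > threshold else "LL"
        curve = run_titration(chooser, TitrationSchedule(delays_days=(5.0,)))
        assert abs(curve.values[0] - threshold) <= SCHEDULE.resolution

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            TitrationSchedule(delays_days=(5.0, 5.0))
        with pytest.raises(ValueError):
            TitrationSchedule(ll_amount=-1)
        with pytest.raises(ValueError):
            TitrationSchedule(trials_per_delay=0)


class TestJohnsonBickel:
    A = 1000.0

    @pytest.mark.parametrize("points,expect", [
        ((990, 900, 700, 500, 300, 150, 80), (True, True)),
        ((990, 900, 700, 950, 300, 150, 80), (False, True)),   # 700->950 rise
        ((950, 940, 930, 920, 910, 900, 880), (True, False)),  # drop only 70
    ])
    def test_reference_curves(self, points, expect):
        curve = IndifferenceCurve("s", DEFAULT_DELAYS_DAYS, points)
        assert johnson_bickel_screen(curve, self.A) == expect

    def test_rise_exactly_at_threshold_passes(self):
        # criterion 1 fails only for rises strictly greater than 0.20 * A
        curve = IndifferenceCurve("s", (1, 14, 30), (500, 700, 100))
        assert johnson_bickel_screen(curve, self.A)[0] is True

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            johnson_bickel_screen(IndifferenceCurve("s", (1,), (500,)), self.A)


class TestHyperbolicFit:
    def test_noiseless_recovery(self):
        k = 0.01
        v = tuple(1000 / (1 + k * d) for d in DEFAULT_DELAYS_DAYS)
        fit = fit_hyperbolic(IndifferenceCurve("s", DEFAULT_DELAYS_DAYS, v),
                             schedule=SCHEDULE)
        assert abs(fit.k - k) / k <= 1e-6
        assert abs(fit.ln_k - math.log(0.01)) < 1e-5
        assert not fit.boundary_flag

    def test_flat_curve_pins_lower_bound(self):
        v = (1000.0,) * 7
        fit = fit_hyperbolic(IndifferenceCurve("s", DEFAULT_DELAYS_DAYS, v),
                             schedule=SCHEDULE)
        assert fit.boundary_flag and fit.k == pytest.approx(1e-10)

    def test_zero_curve_pins_upper_bound(self):
        v = (0.0,) * 7
        fit = fit_hyperbolic(IndifferenceCurve("s", DEFAULT_DELAYS_DAYS, v),
                             schedule=SCHEDULE)
        assert fit.boundary_flag and fit.k == pytest.approx(1e3)

    def test_dominates_dense_log_grid_oracle(self):
        """Returned SSE never exceeds the best point of a 10^6-point grid."""
        rng = np.random.default_rng(42)
        delays = np.asarray(DEFAULT_DELAYS_DAYS)
        grid_k = np.exp(np.linspace(math.log(1e-10), math.log(1e3), 10 ** 6))
        for _ in range(20):
            k = math.exp(rng.uniform(-9, -1))
            v = 1000 / (1 + k * delays) + rng.normal(0, 50, size=7)
            v = np.clip(v, 0, 1000)
            curve = IndifferenceCurve("s", DEFAULT_DELAYS_DAYS, tuple(v))
            fit = fit_hyperbolic(curve, schedule=SCHEDULE)
            # oracle evaluated in manageable chunks
            best = math.inf
            for chunk in np.array_split(grid_k, 50):
                pred = 1000 / (1 + chunk[:, None] * delays[None, :])
                sse = ((v[None, :] - pred) ** 2).sum(axis=1).min()
                best = min(best, sse)
            assert fit.sse <= best + 1e-9

    def test_invariant_to_common_rescaling(self):
        k = 0.02
        v = np.asarray([1000 / (1 + k * d) for d in DEFAULT_DELAYS_DAYS])
        f1 = fit_hyperbolic(
            IndifferenceCurve("s", DEFAULT_DELAYS_DAYS, tuple(v)),
            ll_amount=1000.0)
        f2 = fit_hyperbolic(
            IndifferenceCurve("s", DEFAULT_DELAYS_DAYS, tuple(v * 3.5)),
            ll_amount=3500.0)
        assert f1.ln_k == pytest.approx(f2.ln_k, abs=1e-6)
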