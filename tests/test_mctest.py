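"""Tests for the Markov-chain randomization engine."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import lamstats as ls
from lamstats.climate import ClimateLabel, ClimateSeries
from lamstats.mctest import TWO_SIDED, ONE_SIDED, TransitionProbs
from conftest import make_series

from _oracles import enumerate_null, exact_p_two_sided


def states_of(flags, ages=None):
    flags = list(flags)
    ages = np.arange(len(flags), dtype=float) if ages is None else ages
    return ls.StateSeries(ages=ages, laminated=flags)


class TestEstimateTransitions:
    @pytest.mark.parametrize(
        "flags, p_NL, p_LN",
        [
            ([0, 0, 1, 1, 0], 0.5, 0.5),
            ([1, 0, 1, 0], 1.0, 1.0),
            ([0, 1, 1, 1, 0, 0], 1.0 / 2.0, 1.0 / 3.0),
        ],
    )
    def test_hand_counts(self, flags, p_NL, p_LN):
        tp = ls.estimate_transitions(states_of([bool(f) for f in flags]))
        assert tp.p_NL == pytest.approx(p_NL)
        assert tp.p_LN == pytest.approx(p_LN)

    def test_unobserved_source_state_warns(self):
        with pytest.warns(UserWarning, match="laminated"):
            tp = ls.estimate_transitions(states_of([False] * 5))
        assert tp.p_NL == 0.0 and tp.p_LN == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ls.estimate_transitions(states_of([True]))

    @given(st.lists(st.booleans(), min_size=2, max_size=40))
    def test_matches_direct_counting(self, flags):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tp = ls.estimate_transitions(states_of(flags))
        nNL = sum(1 for a, b in zip(flags, flags[1:]) if not a and b)
        nLN = sum(1 for a, b in zip(flags, flags[1:]) if a and not b)
        fromN = sum(1 for a in flags[:-1] if not a)
        fromL = sum(1 for a in flags[:-1] if a)
        assert tp.p_NL == (nNL / fromN if fromN else 0.0)
        assert tp.p_LN == (nLN / fromL if fromL else 0.0)


class TestSimulateStates:
    def test_absorbing_chain(self):
        out = ls.simulate_states(50, TransitionProbs(0.0, 0.0),
                                 initial_laminated=False, rng_seed=1)
        assert not out.laminated.any()

    def test_strict_alternation(self):
        out = ls.simulate_states(50, TransitionProbs(1.0, 1.0),
                                 initial_laminated=False, rng_seed=1)
        assert out.laminated.tolist() == [bool(i % 2) for i in range(50)]

    def test_reproducible(self):
        p = TransitionProbs(0.3, 0.4)
        a = ls.simulate_states(200, p, rng_seed=99)
        b = ls.simulate_states(200, p, rng_seed=99)
        assert np.array_equal(a.laminated, b.laminated)

    def test_stationary_fraction(self):
        # long-run laminated fraction 0.05/(0.05+0.10) = 1/3; the chain is
        # autocorrelated, so the standard error of the fraction carries the
        # factor sqrt((1+rho)/(1-rho)) with rho = 1 - p_NL - p_LN
        n = 100_000
        p_NL, p_LN = 0.05, 0.10
        out = ls.simulate_states(n, TransitionProbs(p_NL, p_LN), rng_seed=7)
        pi = p_NL / (p_NL + p_LN)
        rho = 1 - p_NL - p_LN
        se = np.sqrt(pi * (1 - pi) / n * (1 + rho) / (1 - rho))
        assert abs(out.laminated.mean() - pi) < 3 * se

    def test_transition_frequencies_converge(self):
        p = TransitionProbs(0.2, 0.35)
        out = ls.simulate_states(60_000, p, rng_seed=5)
        tp = ls.estimate_transitions(out)
        assert abs(tp.p_NL - 0.2) < 3 * np.sqrt(0.2 * 0.8 / tp.n_transitions_from_N)
        assert abs(tp.p_LN - 0.35) < 3 * np.sqrt(0.35 * 0.65 / tp.n_transitions_from_L)


class TestPValue:
    @pytest.mark.parametrize(
        "observed, null, sidedness, expected",
        [
            (5.0, [1.0, 2.0, 3.0], TWO_SIDED, 0.0),
            (2.0, [1.0, 2.0, 3.0], TWO_SIDED, 1.0),   # observed at null mean
            (3.0, [1.0, 2.0, 3.0], TWO_SIDED, 2.0 / 3.0),
            (3.0, [1.0, 2.0, 3.0], ONE_SIDED, 1.0 / 3.0),
            (1.0, [1.0, 2.0, 3.0], ONE_SIDED, 1.0 / 3.0),  # low tail, tie at 1
        ],
    )
    def test_examples(self, observed, null, sidedness, expected):
        assert ls.p_value(observed, null, sidedness) == pytest.approx(expected)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            ls.p_value(1.0, [])

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=50),
           st.floats(-200, 200))
    def test_bounds_and_permutation_invariance(self, null, observed):
        p = ls.p_value(observed, null)
        assert 0.0 <= p <= 1.0
        assert p == ls.p_value(observed, list(reversed(null)))

    def test_monotone_in_deviation(self, rng):
        null = rng.standard_normal(500)
        m = null.mean()
        ps = [ls.p_value(m + d, null) for d in np.linspace(0, 4, 15)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestMeanDifference:
    def test_planted_shift_detected(self, rng):
        st_ = ls.simulate_states(800, TransitionProbs(0.05, 0.2), rng_seed=3)
        vals = rng.standard_normal(800) + 2.0 * st_.laminated
        res = ls.mc_test_mean_difference(
            make_series(vals), st_, n_iter=500, seed=4)
        assert res.p_value <= 0.05
        assert res.observed == pytest.approx(2.0, abs=0.5)

    def test_one_state_observed_record_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            ls.mc_test_mean_difference(make_series([1.0, 2.0]),
                                       states_of([True, True]), n_iter=10)

    def test_degenerate_chain_flagged_invalid(self):
        # with switching probabilities forced to zero every simulated
        # labelling stays in the initial state, so no iteration yields a
        # defined difference
        st_ = states_of([True, True, False, False])
        with pytest.warns(UserWarning, match="discarded"):
            res = ls.mc_test_mean_difference(
                make_series([1.0, 2.0, 3.0, 4.0]), st_, n_iter=50, seed=0,
                probs=TransitionProbs(0.0, 0.0))
        assert res.n_valid == 0 and not res.valid
        assert np.isnan(res.p_value)

    def test_discarded_iterations_reported(self):
        # tiny record where a simulated chain can fail to ever enter the
        # laminated state; such labellings must be discarded, not imputed
        st_ = states_of([False, False, True, True, False, False])
        with pytest.warns(UserWarning, match="discarded"):
            res = ls.mc_test_mean_difference(
                make_series([1.0, 5.0, 2.0, 6.0, 1.5, 5.5]), st_,
                n_iter=2000, seed=8)
        assert 0 < res.n_valid < 2000
        assert len(res.null_stats) == res.n_valid


class TestMeanDuringEvents:
    def test_constant_values_give_p_one(self):
        st_ = states_of([False, True, True, False, True])
        res = ls.mc_test_mean_during_events(
            make_series([3.0] * 5), st_, n_iter=200, seed=1)
        assert res.observed == 3.0
        assert (res.null_stats == 3.0).all()
        assert res.p_value == 1.0

    def test_single_laminated_sample_statistic(self):
        st_ = states_of([False, True, False, False])
        res = ls.mc_test_mean_during_events(
            make_series([1.0, 42.0, 2.0, 3.0]), st_, n_iter=100, seed=1)
        assert res.observed == 42.0


class TestStateProportion:
    def _climate(self, labels):
        labs = tuple(ClimateLabel(x) for x in labels)
        n = len(labs)
        return ClimateSeries(ages=np.arange(n, dtype=float), labels=labs,
                             d18O=np.zeros(n), baseline_mean=np.zeros(n),
                             baseline_sd=np.ones(n))

    def test_all_target_gives_p_one(self):
        cs = self._climate(["Glacial"] * 6)
        st_ = states_of([True, False, True, False, True, False])
        res = ls.mc_test_state_proportion(cs, st_, ClimateLabel.GLACIAL,
                                          n_iter=300, seed=2)
        assert res.observed == 1.0 and (res.null_stats == 1.0).all()
        assert res.p_value == 1.0

    def test_absent_target_well_defined(self):
        cs = self._climate(["Intermediate"] * 6)
        st_ = states_of([True, False, True, False, True, False])
        res = ls.mc_test_state_proportion(cs, st_, ClimateLabel.GLACIAL,
                                          n_iter=300, seed=2)
        assert res.observed == 0.0 and res.p_value == 1.0

    def test_no_laminated_samples_rejected(self):
        cs = self._climate(["Glacial"] * 3)
        with pytest.raises(ValueError, match="laminated"):
            ls.mc_test_state_proportion(cs, states_of([False] * 3),
                                        ClimateLabel.GLACIAL, n_iter=10)

    def test_enumeration_agreement_eight_samples(self):
        # exact null by summing all 2^7 chains from the observed start
        labels = ["Glacial", "Glacial", "Intermediate", "Interglacial",
                  "Glacial", "Intermediate", "Interglacial", "Glacial"]
        cs = self._climate(labels)
        flags = [False, True, True, False, False, True, False, False]
        st_ = states_of(flags)
        res = ls.mc_test_state_proportion(cs, st_, ClimateLabel.GLACIAL,
                                          n_iter=10_000, seed=5)
        tp = ls.estimate_transitions(st_)
        ind = [1.0 if x == "Glacial" else 0.0 for x in labels]
        enum = enumerate_null(ind, flags[0], tp.p_NL, tp.p_LN,
                              "proportion", target_indicator=ind)
        exact = exact_p_two_sided(enum, res.observed)
        se = np.sqrt(max(exact * (1 - exact), 1e-12) / res.n_valid)
        assert abs(res.p_value - exact) <= 3 * se + 1e-9


class TestResultObject:
    def test_p_zero_displayed_as_bound(self, rng):
        st_ = ls.simulate_states(600, TransitionProbs(0.05, 0.2), rng_seed=11)
        vals = rng.standard_normal(600) + 5.0 * st_.laminated
        res = ls.mc_test_mean_difference(make_series(vals), st_,
                                         n_iter=400, seed=12)
        assert res.p_value == 0.0
        assert res.p_value_display().startswith("<")

    def test_seed_recorded_and_reproducible(self, rng):
        st_ = ls.simulate_states(300, TransitionProbs(0.1, 0.2), rng_seed=21)
        vals = rng.standard_normal(300)
        v = make_series(vals)
        a = ls.mc_test_mean_difference(v, st_, n_iter=200, seed=77)
        b = ls.mc_test_mean_difference(v, st_, n_iter=200, seed=77)
        assert a.seed == 77
        np.testing.assert_array_equal(a.null_stats, b.null_stats)
        assert a.p_value == b.p_value
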