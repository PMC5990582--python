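import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igtbayes import (
    PVLDeltaParams,
    choice_probabilities,
    log_likelihood,
    sensitivity,
    simulate_agent,
    update_expectancies,
    utility,
)
from igtbayes.pvl_delta import ExpectancyState

from conftest import oracle_loglik, random_instance


class TestUtility:
    def test_zero_outcome(self):
        assert utility(0.0, A=0.5, w=2.0) == 0.0
        assert utility(0.0, A=0.0, w=5.0) == 0.0  # 0**0 edge

    def test_identity_at_unit_params(self):
        assert utility(100.0, 1.0, 1.0) == 100.0
        assert utility(-100.0, 1.0, 1.0) == -100.0

    def test_loss_aversion_scaling(self):
        assert utility(-100.0, 0.5, 2.0) == pytest.approx(-20.0)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            utility(1.0, A=1.5, w=1.0)
        with pytest.raises(ValueError):
            utility(1.0, A=0.5, w=6.0)

    @given(x=st.floats(-20, 20), A=st.floats(0, 1), w=st.floats(0, 5))
    def test_sign_structure(self, x, A, w):
        u = utility(x, A, w)
        if x > 0:
            assert u > 0
        elif x < 0:
            assert u <= 0  # w = 0 neutralizes losses


class TestUpdateExpectancies:
    def test_single_deck_updated(self):
        state = ExpectancyState()
        new = update_expectancies(state, 1, u=1.0, a=0.3)
        assert new.Ev.tolist() == [0.3, 0.0, 0.0, 0.0]
        assert state.Ev.tolist() == [0.0] * 4  # input untouched

    def test_zero_rate_freezes(self):
        state = ExpectancyState(Ev=np.array([0.5, -0.1, 0.0, 0.2]))
        new = update_expectancies(state, 2, u=9.9, a=0.0)
        assert new.Ev.tolist() == state.Ev.tolist()

    def test_full_replacement(self):
        state = ExpectancyState(Ev=np.array([0.5, 0.0, 0.0, 0.0]))
        new = update_expectancies(state, 1, u=-0.2, a=1.0)
        assert new.Ev[0] == pytest.approx(-0.2)


class TestSensitivity:
    @pytest.mark.parametrize("c,theta", [(0, 0), (1, 2), (5, 242)])
    def test_values(self, c, theta):
        assert sensitivity(c) == theta

    def test_monotone(self):
        cs = np.linspace(0, 5, 50)
        thetas = [sensitivity(c) for c in cs]
        assert np.all(np.diff(thetas) > 0)

    def test_range(self):
        with pytest.raises(ValueError):
            sensitivity(5.1)


class TestChoiceProbabilities:
    def test_uniform_at_c_zero(self):
        p = choice_probabilities(np.array([3.0, -1.0, 0.0, 2.0]), c=0.0)
        assert p.tolist() == [0.25] * 4

    def test_uniform_for_equal_ev(self):
        p = choice_probabilities(np.full(4, 1.7), c=3.0)
        assert np.allclose(p, 0.25)

    def test_direct_evaluation(self):
        # e^2 / (e^2 + 3) for Ev = (1,0,0,0), theta = 2
        p = choice_probabilities(np.array([1.0, 0.0, 0.0, 0.0]), c=1.0)
        expected = math.exp(2) / (math.exp(2) + 3)
        assert p[0] == pytest.approx(expected, abs=1e-12)

    def test_no_overflow_at_extremes(self):
        p = choice_probabilities(np.array([62.5, -62.5, 0.0, 10.0]), c=5.0)
        assert np.all(np.isfinite(p))
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            choice_probabilities(np.array([np.nan, 0, 0, 0]), 1.0)

    @given(
        ev=st.lists(st.floats(-60, 60), min_size=4, max_size=4),
        c=st.floats(0, 5),
    )
    @settings(max_examples=200)
    def test_sums_to_one(self, ev, c):
        p = choice_probabilities(np.array(ev), c)
        assert abs(p.sum() - 1.0) < 1e-12

    @given(ev=st.lists(st.floats(-5, 5), min_size=4, max_size=4))
    def test_consistency_monotone_in_argmax(self, ev):
        ev = np.array(ev)
        k = int(np.argmax(ev))
        probs = [choice_probabilities(ev, c)[k] for c in (0.5, 1.0, 2.0, 4.0)]
        assert all(b >= a - 1e-12 for a, b in zip(probs, probs[1:]))


class TestLogLikelihood:
    def test_single_trial_uniform(self, example_agent):
        p, params = example_agent
        one = type(p)(p.participant_id, p.trials[:1])
        assert log_likelihood(one, params) == pytest.approx(math.log(0.25))

    def test_c_zero_gives_uniform_every_trial(self, example_agent):
        p, _ = example_agent
        params = PVLDeltaParams(0.5, 1.0, 0.5, 0.0)
        assert log_likelihood(p, params) == pytest.approx(
            len(p.trials) * math.log(0.25)
        )

    def test_oracle_equivalence_100_instances(self, rng):
        for _ in range(100):
            params, choices, nets = random_instance(rng)
            from igtbayes._kernels import loglik_one

            got = loglik_one(
                np.asarray(choices) - 1, np.asarray(nets), len(choices),
                params.A, params.w, params.a, params.c,
            )
            want = oracle_loglik(
                choices.tolist(), nets.tolist(),
                params.A, params.w, params.a, params.c,
            )
            assert got == pytest.approx(want, abs=1e-10)

    def test_finite_across_parameter_grid(self, example_agent):
        p, _ = example_agent
        for A in (0.0, 0.5, 1.0):
            for w in (0.0, 5.0):
                for a in (0.0, 1.0):
                    for c in (0.0, 5.0):
                        ll = log_likelihood(p, PVLDeltaParams(A, w, a, c))
                        assert np.isfinite(ll)

    def test_empty_sequence(self):
        from igtbayes import ParticipantData

        with pytest.raises(ValueError):
            log_likelihood(ParticipantData("x", []),
                           PVLDeltaParams(0.5, 1, 0.5, 1))


class TestSimulateAgent:
    def test_reproducible(self, scheme):
        params = PVLDeltaParams(0.4, 1.0, 0.3, 1.5)
        a = simulate_agent(params, scheme, 50, seed=5)
        b = simulate_agent(params, scheme, 50, seed=5)
        assert a.trials == b.trials

    def test_c_zero_uniform_frequencies(self, scheme):
        params = PVLDeltaParams(0.5, 1.0, 0.5, 0.0)
        p = simulate_agent(params, scheme, 10_000, seed=11)
        freqs = np.bincount(p.choices, minlength=5)[1:] / 10_000
        assert np.all(np.abs(freqs - 0.25) < 0.02)

    def test_a_zero_keeps_choices_uniform(self, scheme):
        params = PVLDeltaParams(0.9, 4.0, 0.0, 5.0)
        p = simulate_agent(params, scheme, 4000, seed=13)
        freqs = np.bincount(p.choices, minlength=5)[1:] / 4000
        assert np.all(np.abs(freqs - 0.25) < 0.05)

    def test_forced_deck_d_block_net(self, scheme):
        params = PVLDeltaParams(0.5, 1.0, 0.3, 1.0)
        p = simulate_agent(params, scheme, 10, seed=1,
                           forced_choices=[4] * 10)
        assert p.net_outcomes.sum() == 250

    def test_loglik_invariant_to_loss_sign_storage(self, scheme):
        # the likelihood sees net outcomes only, so storing a loss as part
        # of the reward column must not change it
        from igtbayes import ParticipantData, TrialRecord

        params = PVLDeltaParams(0.6, 1.2, 0.4, 1.0)
        p = simulate_agent(params, scheme, 30, seed=3)
        merged = ParticipantData(
            "alt",
            [TrialRecord(t.trial_index, t.deck, t.reward + t.loss, 0.0)
             if t.reward + t.loss >= 0 else
             TrialRecord(t.trial_index, t.deck, 0.0, t.reward + t.loss)
             for t in p.trials],
        )
        assert log_likelihood(merged, params) == pytest.approx(
            log_likelihood(p, params), abs=1e-12
        )
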