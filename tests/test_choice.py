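"""Prospect-theory valuation, choice rule, affective modulation, simulation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from affectrisk.affect import AffectParams
from affectrisk.choice import (
    AffectRegressionWeights,
    ChoiceParams,
    gamble_value,
    loglik_choice,
    modulate_params,
    p_accept,
    simulate_choices,
    utility,
)
from affectrisk.gambles import Gamble, GambleConfig, compute_ev, generate_session


def _gamble(outcomes, probs=(0.25, 0.25, 0.25, 0.25)):
    return Gamble(tuple(outcomes), tuple(probs))


@pytest.mark.parametrize(
    "x,lam,rho,expected",
    [
        (10, 3.0, 1.0, 10.0),
        (-10, 2.0, 1.0, -20.0),
        (4, 1.0, 0.5, 2.0),
        (-9, 2.0, 0.5, -6.0),
    ],
)
def test_utility_values(x, lam, rho, expected):
    assert utility(x, lam, rho) == pytest.approx(expected, abs=1e-12)


def test_utility_rejects_zero_outcome():
    with pytest.raises(ValueError):
        utility(0, 1.0, 1.0)


def test_gamble_value_reduces_to_ev_when_risk_neutral(rng):
    for _ in range(50):
        g = generate_session(rng, 1)[0]
        assert gamble_value(g, 1.0, 1.0).v == pytest.approx(compute_ev(g), abs=1e-10)


def test_gamble_value_hand_case_and_lam_monotonicity():
    g = _gamble((10, -10, 20, -20))
    assert gamble_value(g, 2.0, 1.0).v == pytest.approx(-7.5, abs=1e-12)
    values = [gamble_value(g, lam, 1.0).v for lam in (0.5, 1.0, 2.0, 4.0)]
    assert values == sorted(values, reverse=True)


def test_gamble_value_matches_brute_force(rng):
    for _ in range(100):
        g = generate_session(rng, 1)[0]
        lam, rho = rng.uniform(0.2, 3), rng.uniform(0.3, 1.5)
        expected = sum(
            (x**rho if x > 0 else -lam * (-x) ** rho) * p
            for x, p in zip(g.outcomes, g.probabilities)
        )
        assert gamble_value(g, lam, rho).v == pytest.approx(expected, abs=1e-12)


def test_p_accept_closed_forms():
    assert p_accept(3.7, 0.0) == pytest.approx(0.5)
    assert p_accept(0.0, 7.0) == pytest.approx(0.5)
    assert p_accept(np.log(3.0), 1.0) == pytest.approx(0.75, abs=1e-12)
    with pytest.raises(ValueError):
        p_accept(1.0, 25.0)


@given(st.floats(-50, 50), st.floats(0, 20))
def test_p_accept_symmetry(v, c):
    assert p_accept(v, c) + p_accept(-v, c) == pytest.approx(1.0, abs=1e-12)


def test_modulation_zero_regressors_returns_base():
    base = ChoiceParams(lam=1.5, rho=0.7, c=2.0)
    w = AffectRegressionWeights(beta_a_lam=0.04, beta_a_rho=-0.1, beta_a_c=0.4)
    tp = modulate_params(base, w, valence_prev=0.0, arousal_prev=0.0)
    assert (tp.lam, tp.rho, tp.c) == (base.lam, base.rho, base.c)


def test_modulation_shifts_and_direction():
    base = ChoiceParams(lam=1.0, rho=0.6, c=2.0)
    w = AffectRegressionWeights(beta_a_lam=0.04, beta_a_rho=-0.1, beta_a_c=0.4)
    tp = modulate_params(base, w, arousal_prev=1.0)
    assert tp.lam == pytest.approx(1.04)
    # the empirical direction: arousal raises lam and c, lowers rho
    assert tp.c > base.c and tp.rho < base.rho


def test_modulation_clips_to_admissible_ranges():
    base = ChoiceParams(lam=0.1, rho=0.5, c=19.0)
    w = AffectRegressionWeights(beta_a_lam=-1.0, beta_a_rho=-2.0, beta_a_c=5.0)
    tp = modulate_params(base, w, arousal_prev=1.0)
    assert tp.lam == 0.0 and tp.rho == 0.0 and tp.c == 20.0


def test_choice_loglik_closed_form_and_oracle(rng):
    session = generate_session(rng, 12)
    choices = rng.integers(0, 2, size=12)

    random_tp = [modulate_params(ChoiceParams(1.0, 1.0, 0.0), AffectRegressionWeights())] * 12
    assert loglik_choice(random_tp, session, choices) == pytest.approx(12 * np.log(0.5), abs=1e-10)

    tps = [
        modulate_params(
            ChoiceParams(rng.uniform(0.5, 2), rng.uniform(0.4, 1.2), rng.uniform(0.5, 5)),
            AffectRegressionWeights(),
        )
        for _ in range(12)
    ]
    expected = 0.0
    for tp, g, ch in zip(tps, session, choices):
        p = p_accept(gamble_value(g, tp.lam, tp.rho).v, tp.c)
        expected += np.log(p if ch else 1 - p)
    assert loglik_choice(tps, session, choices) == pytest.approx(expected, abs=1e-10)

    with pytest.raises(ValueError):
        loglik_choice(tps[:-1], session, choices)


def _null_affect():
    return AffectParams(sigma=0.8, gamma=0.3)


def test_simulation_ev_maximizer_limit():
    """With c=20, lam=rho=1 and no modulation the agent is a near-deterministic
    EV maximizer: every trial with non-negligible |EV| matches sign(EV)."""
    rng = np.random.default_rng(11)
    session = generate_session(rng, 200)
    sim = simulate_choices(
        rng,
        ChoiceParams(lam=1.0, rho=1.0, c=20.0),
        AffectRegressionWeights(),
        session,
        _null_affect(),
        _null_affect(),
    )
    clear = np.abs(sim.ev) >= 1.0
    np.testing.assert_array_equal(sim.choices[clear], (sim.ev[clear] > 0).astype(int))


def test_simulation_is_deterministic_given_seed():
    session = generate_session(np.random.default_rng(3), 30)
    base = ChoiceParams(lam=1.2, rho=0.6, c=2.0)
    w = AffectRegressionWeights(beta_a_lam=0.05, beta_a_c=0.3)
    s1 = simulate_choices(np.random.default_rng(5), base, w, session, _null_affect(), _null_affect())
    s2 = simulate_choices(np.random.default_rng(5), base, w, session, _null_affect(), _null_affect())
    np.testing.assert_array_equal(s1.choices, s2.choices)
    np.testing.assert_array_equal(s1.outcomes, s2.outcomes)
    np.testing.assert_array_equal(s1.valence, s2.valence)


def test_acceptance_rate_increases_with_mean_gamble_ev():
    base = ChoiceParams(lam=1.0, rho=0.7, c=2.0)
    rates = []
    for shift in (-6.0, 0.0, 6.0):
        rng = np.random.default_rng(17)
        cfg = GambleConfig(outcome_mean=shift, ev_cap=40.0)
        session = generate_session(rng, 400, cfg)
        sim = simulate_choices(
            rng, base, AffectRegressionWeights(), session, _null_affect(), _null_affect()
        )
        rates.append(sim.choices.mean())
    assert rates[0] < rates[1] < rates[2]


def test_rejected_trials_have_zero_outcome_and_pe():
    rng = np.random.default_rng(23)
    session = generate_session(rng, 80)
    sim = simulate_choices(
        rng, ChoiceParams(1.0, 0.6, 1.5), AffectRegressionWeights(), session, _null_affect(), _null_affect()
    )
    rejected = sim.choices == 0
    assert rejected.any()
    assert np.all(sim.outcomes[rejected] == 0.0)
    assert np.all(sim.pe[rejected] == 0.0)
    accepted = ~rejected
    np.testing.assert_allclose(sim.pe[accepted], sim.outcomes[accepted] - sim.ev[accepted], atol=1e-12)


def test_own_params_beat_wrong_loss_aversion_on_long_run():
    """Self-consistency: the generating parameters have a higher likelihood
    than a badly mis-specified loss aversion on a long simulated session."""
    rng = np.random.default_rng(31)
    session = generate_session(rng, 600)
    truth = ChoiceParams(lam=2.0, rho=0.8, c=2.0)
    sim = simulate_choices(
        rng, truth, AffectRegressionWeights(), session, _null_affect(), _null_affect()
    )
    tp_true = [modulate_params(truth, AffectRegressionWeights())] * 600
    wrong = ChoiceParams(lam=0.2, rho=0.8, c=2.0)
    tp_wrong = [modulate_params(wrong, AffectRegressionWeights())] * 600
    assert loglik_choice(tp_true, session, sim.choices) > loglik_choice(
        tp_wrong, session, sim.choices
    )


def test_choice_params_validation():
    with pytest.raises(ValueError):
        ChoiceParams(lam=-0.1, rho=1.0, c=1.0)
    with pytest.raises(ValueError):
        ChoiceParams(lam=1.0, rho=1.0, c=21.0)
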