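"""ORL and VSE update rules, choice probabilities, simulation, likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from igtlab.models import (
    ORLParams,
    ORLState,
    VSEParams,
    VSEState,
    TrialSequence,
    log_likelihood,
    orl_choice_probs,
    orl_update,
    simulate_agent,
    simulate_batch,
    vse_choice_probs,
    vse_update,
    vse_utility,
)
from igtlab.task import Outcome, build_standard_schedule


# ---------------------------------------------------------------------------
# ORL


def test_orl_decay_transform_range():
    assert ORLParams(0.5, 0.5, 5.0, 0, 0).K == 242
    assert ORLParams(0.5, 0.5, 0.0, 0, 0).K == 0


def test_orl_param_validation():
    with pytest.raises(ValueError):
        ORLParams(1.5, 0.5, 1, 0, 0)
    with pytest.raises(ValueError):
        ORLParams(0.5, 0.5, 6, 0, 0)


def test_orl_zero_net_zero_decay():
    # sgn(0) = 0 and K = 0: only the perseverance reset acts
    p = ORLParams(0.3, 0.3, 0.0, 1.0, 1.0)
    s = orl_update(ORLState(), p, "A", Outcome(50, 50))
    assert np.allclose(s.ev, 0) and np.allclose(s.ef, 0)
    assert np.allclose(s.ps, [1, 0, 0, 0])


def test_orl_one_step_hand_computed():
    # scaled net +1.0 from zero state
    p = ORLParams(0.5, 0.2, 1.0, 0.0, 0.0)
    s = orl_update(ORLState(), p, "B", Outcome(100, 0), outcome_scale=0.01)
    assert s.ev[1] == pytest.approx(0.5)
    assert s.ef[1] == pytest.approx(0.5)
    for d in (0, 2, 3):
        assert s.ef[d] == pytest.approx(-1 / 6)
    assert s.ps[1] == pytest.approx(1 / 3)  # K = 2


def test_orl_punishment_learning_step():
    # EV 0.5, A_pun 0.2, scaled net -1.5 -> 0.5 + 0.2(-1.5 - 0.5) = 0.1
    st0 = ORLState(ev=np.array([0.5, 0, 0, 0.0]))
    p = ORLParams(0.9, 0.2, 0.0, 0.0, 0.0)
    s = orl_update(st0, p, "A", Outcome(100, 250), outcome_scale=0.01)
    assert s.ev[0] == pytest.approx(0.1)


def test_orl_unchosen_ev_unchanged():
    st0 = ORLState(ev=np.array([0.1, 0.2, 0.3, 0.4]))
    s = orl_update(st0, ORLParams(0.5, 0.5, 1, 0, 0), "A", Outcome(100, 0))
    assert np.allclose(s.ev[1:], [0.2, 0.3, 0.4])


def test_orl_choice_probs_closed_form():
    p = ORLParams(0.5, 0.5, 0, 0.0, 0.0)
    s = ORLState(ev=np.array([1.0, 0, 0, 0]))
    probs = orl_choice_probs(s, p)
    assert probs[0] == pytest.approx(np.e / (np.e + 3), abs=1e-12)
    assert probs.sum() == pytest.approx(1.0, abs=1e-12)
    uniform = orl_choice_probs(ORLState(), p)
    assert np.allclose(uniform, 0.25)


def test_orl_value_signal_reduces_to_ev_without_weights():
    s = ORLState(
        ev=np.array([0.5, 0, 0, 0]),
        ef=np.array([0.9, -0.9, 0.3, 0.1]),
        ps=np.array([1.0, 0, 0, 0]),
    )
    p0 = ORLParams(0.5, 0.5, 0, 0.0, 0.0)
    assert np.allclose(s.value_signal(p0), s.ev)


def test_orl_nonfinite_rejected():
    s = ORLState(ev=np.array([np.nan, 0, 0, 0]))
    with pytest.raises(FloatingPointError):
        orl_update(s, ORLParams(0.5, 0.5, 1, 0, 0), "A", Outcome(100, 0))


@settings(deadline=None, derandomize=True)
@given(a=st.floats(0.05, 0.95), x=st.floats(-2, 2), n=st.integers(1, 60))
def test_orl_ev_geometric_convergence(a, x, n):
    """Repeated identical net outcomes drive EV to x at rate (1-a)."""
    p = ORLParams(a, a, 0.0, 0.0, 0.0)
    s = ORLState()
    gain, loss = (100 * x, 0) if x >= 0 else (0, -100 * x)
    for _ in range(n):
        s = orl_update(s, p, "C", Outcome(gain, loss), outcome_scale=0.01)
    assert s.ev[2] == pytest.approx(x * (1 - (1 - a) ** n), rel=1e-9, abs=1e-9)


# ---------------------------------------------------------------------------
# VSE


def test_vse_consistency_transform():
    assert VSEParams(0.5, 0.5, 0.5, 0, 5.0).c == 242
    assert VSEParams(0.5, 0.5, 0.5, 0, 0.0).c == 0


def test_vse_utility_values():
    assert vse_utility(100, 0, 1.0) == 100
    assert vse_utility(100, 50, 0.5) == pytest.approx(10 - np.sqrt(50), abs=1e-9)
    assert vse_utility(70, 70, 0.37) == 0
    with pytest.raises(ValueError):
        vse_utility(-1, 0, 0.5)


def test_vse_update_identity_when_no_decay_no_outcome():
    p = VSEParams(1.0, 1.0, 0.0, 0.0, 1.0)
    s0 = VSEState(exploit=np.array([1.0, 2, 3, 4]))
    s = vse_update(s0, p, "A", Outcome(50, 50))  # v = 0 at theta = 1
    assert np.allclose(s.exploit, s0.exploit)


def test_vse_explore_delta_step():
    p = VSEParams(0.5, 1.0, 0.5, 2.0, 1.0)
    s = vse_update(VSEState(), p, "A", Outcome(50, 50))
    assert np.allclose(s.explore[1:], 1.0)  # 0 + 0.5 (2 - 0)
    assert s.explore[0] == 0.0  # chosen deck always reset


def test_vse_chosen_explore_zero_any_state(rng):
    s0 = VSEState(explore=rng.normal(size=4), exploit=rng.normal(size=4))
    p = VSEParams(0.5, 0.9, 0.3, -1.0, 2.0)
    s = vse_update(s0, p, "D", Outcome(50, 0))
    assert s.explore[3] == 0.0


def test_vse_choice_probs():
    state = VSEState(exploit=np.array([1.0, 0, 0, 0]))
    random_p = VSEParams(0.5, 0.5, 0.5, 0.5, 0.0)
    assert np.allclose(vse_choice_probs(state, random_p), 0.25)
    beta1 = VSEParams(0.5, 0.5, 0.5, 0.5, 1.0)  # c = 2
    probs = vse_choice_probs(state, beta1)
    assert probs[0] == pytest.approx(np.e ** 2 / (np.e ** 2 + 3), abs=1e-12)


@settings(deadline=None, derandomize=True)
@given(alpha=st.floats(0.05, 0.95), phi=st.floats(-3, 3), n=st.integers(1, 50))
def test_vse_explore_converges_to_phi(alpha, phi, n):
    p = VSEParams(0.5, 0.5, alpha, phi, 1.0)
    s = VSEState()
    for _ in range(n):
        s = vse_update(s, p, "A", Outcome(50, 0))
    expected = phi * (1 - (1 - alpha) ** n)
    assert s.explore[1] == pytest.approx(expected, rel=1e-9, abs=1e-9)


def test_vse_exploit_decays_geometrically():
    p = VSEParams(0.0, 0.5, 0.0, 0.0, 1.0)  # theta 0 -> v = 0 on loss trials
    s = VSEState(exploit=np.array([0.0, 8.0, 0, 0]))
    for _ in range(3):
        s = vse_update(s, p, "A", Outcome(100, 50))
    assert s.exploit[1] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# simulation and likelihood


def test_simulate_conservation_and_determinism(schedule):
    p = ORLParams(0.3, 0.2, 1.0, 1.0, 0.5)
    seq1 = simulate_agent("ORL", p, schedule, seed=9)
    seq2 = simulate_agent("ORL", p, schedule, seed=9)
    assert seq1.n_trials == 100
    assert np.bincount(seq1.choices, minlength=4).sum() == 100
    assert np.array_equal(seq1.choices, seq2.choices)
    assert np.array_equal(seq1.gains, seq2.gains)
    seq3 = simulate_agent("ORL", p, schedule, seed=10)
    assert not np.array_equal(seq1.choices, seq3.choices)


def test_vse_beta0_choices_near_uniform():
    """beta = 0 is the random-exploration limit: a binomial CI check."""
    params = np.tile([[0.5, 0.5, 0.5, 0.5, 0.0]], (40, 1))
    choices, _, _ = simulate_batch("VSE", params, 100, seed=2)
    counts = np.bincount(choices.ravel(), minlength=4)
    n = counts.sum()
    # each deck ~ Binomial(n, 1/4); +/- 5 sigma band
    sd = np.sqrt(n * 0.25 * 0.75)
    assert all(abs(c - n / 4) < 5 * sd for c in counts)


def test_simulate_batch_matches_probs_at_fixed_state():
    """Choice frequencies from many simulated first trials match the
    uniform initial distribution within multinomial tolerance."""
    params = np.tile([[0.3, 0.3, 1.0, 1.0, 1.0]], (4000, 1))
    choices, _, _ = simulate_batch("ORL", params, 1, seed=3)
    counts = np.bincount(choices[:, 0], minlength=4)
    sd = np.sqrt(4000 * 0.25 * 0.75)
    assert all(abs(c - 1000) < 5 * sd for c in counts)


def test_unknown_model_rejected(schedule):
    with pytest.raises(ValueError):
        simulate_agent("EVX", np.zeros(5), schedule)
    with pytest.raises(ValueError):
        simulate_batch("EVX", np.zeros((1, 5)), 10, 0)


def test_loglik_uniform_limits(schedule):
    p = VSEParams(0.5, 0.5, 0.5, 0.5, 0.0)
    seq = simulate_agent("VSE", p, schedule, seed=1)
    ll = log_likelihood("VSE", p, seq)
    assert ll == pytest.approx(100 * np.log(0.25), abs=1e-9)
    one = TrialSequence([0], [100.0], [0.0])
    assert log_likelihood("ORL", ORLParams(0.5, 0.5, 1, 1, 1), one) == (
        pytest.approx(np.log(0.25))
    )


def test_loglik_pointwise_bounds(schedule):
    p = ORLParams(0.4, 0.1, 1.0, 2.0, 1.0)
    seq = simulate_agent("ORL", p, schedule, seed=4)
    pw = log_likelihood("ORL", p, seq, pointwise=True)
    assert pw.shape == (100,)
    assert (pw <= 0).all() and (np.exp(pw) > 0).all()
    assert log_likelihood("ORL", p, seq) == pytest.approx(pw.sum())


@pytest.mark.parametrize("model,params", [
    ("ORL", ORLParams(0.4, 0.15, 1.5, 1.0, 0.8)),
    ("VSE", VSEParams(0.4, 0.7, 0.3, 0.6, 1.2)),
])
def test_loglik_kernel_matches_scalar_reference(model, params, schedule):
    """Dual route: the numba likelihood kernel must equal a teacher-forced
    replay through the pure-python single-step updates."""
    from igtlab.models import (
        orl_choice_probs, orl_update, vse_choice_probs, vse_update,
    )

    seq = simulate_agent(model, params, schedule, seed=6)
    pw = log_likelihood(model, params, seq, pointwise=True)
    state = ORLState() if model == "ORL" else VSEState()
    expected = []
    for t in range(seq.n_trials):
        if model == "ORL":
            probs = orl_choice_probs(state, params)
        else:
            probs = vse_choice_probs(state, params)
        expected.append(np.log(probs[seq.choices[t]]))
        out = Outcome(seq.gains[t], seq.losses[t])
        if model == "ORL":
            state = orl_update(state, params, int(seq.choices[t]), out)
        else:
            state = vse_update(state, params, int(seq.choices[t]), out)
    assert np.allclose(pw, expected, atol=1e-10)


def test_parameter_recovery_smoke():
    """Average log-likelihood over simulated subjects peaks near the
    generating parameters relative to a perturbed set."""
    true = ORLParams(0.4, 0.15, 1.0, 1.5, 1.0)
    perturbed = ORLParams(0.9, 0.6, 4.0, -1.5, -1.0)
    params = np.tile(true.as_array(), (50, 1))
    choices, gains, losses = simulate_batch("ORL", params, 100, seed=8)
    ll_true = ll_pert = 0.0
    for i in range(50):
        seq = TrialSequence(choices[i], gains[i], losses[i])
        ll_true += log_likelihood("ORL", true, seq)
        ll_pert += log_likelihood("ORL", perturbed, seq)
    assert ll_true > ll_pert


def test_trial_sequence_validation_and_frame():
    with pytest.raises(ValueError):
        TrialSequence([0, 1], [100.0], [0.0])
    seq = TrialSequence([0, 3], [100, 50], [0, 250], "s1")
    df = seq.to_frame()
    assert list(df["deck"]) == ["A", "D"]
    assert list(df["trial"]) == [1, 2]
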