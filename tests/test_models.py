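"""Observer models: step algebra, likelihoods, simulators, filter theory."""

import numpy as np
import pytest
from scipy import optimize

from painseq.models import (RLParams, ERLParams, KFParams, EKFParams,
                            RandomParams, BeliefState, confidence_noise_scale,
                            rl_step, kf_step, trial_loglik, run_model,
                            simulate_responses)
from painseq.sequences import generate_schedule


# ---------------------------------------------------------------- noise scale

def test_confidence_noise_scale_limits():
    assert confidence_noise_scale(10.0, 5.0, 1.0) == pytest.approx(10.0)
    assert confidence_noise_scale(10.0, 1.0, 0.0) == pytest.approx(10.0 * np.e)
    assert confidence_noise_scale(10.0, 1e6, 0.0) == pytest.approx(10.0, rel=1e-5)


def test_confidence_noise_scale_monotone_in_confidence():
    c = np.linspace(0, 1, 11)
    sd = confidence_noise_scale(5.0, 2.0, c)
    assert np.all(np.diff(sd) < 0)


def test_confidence_out_of_range_rejected():
    with pytest.raises(ValueError):
        confidence_noise_scale(10.0, 1.0, 1.5)
    with pytest.raises(ValueError):
        confidence_noise_scale(-1.0, 1.0, 0.5)


# ---------------------------------------------------------------- RL algebra

@pytest.mark.parametrize("alpha,expected_E", [(0.0, 40.0), (1.0, 60.0)])
def test_rl_step_learning_rate_extremes(alpha, expected_E):
    p = RLParams(alpha, 8.0, 40.0, 2.0)
    percept, state = rl_step(BeliefState(expectation=40.0), 60.0, p)
    assert percept == 60.0          # RL perception reports the input
    assert state.expectation == pytest.approx(expected_E)


def test_erl_reduces_to_rl_at_gamma_zero(rng):
    inputs = rng.uniform(0, 100, 50)
    rl = RLParams(0.35, 8.0, 45.0, 2.0)
    erl = ERLParams(0.35, 8.0, 45.0, 2.0, perception_weight=0.0)
    s_rl, s_erl = BeliefState(expectation=45.0), BeliefState(expectation=45.0)
    for x in inputs:
        p1, s_rl = rl_step(s_rl, x, rl)
        p2, s_erl = rl_step(s_erl, x, erl)
        assert p1 == pytest.approx(p2, abs=1e-12)
        assert s_rl.expectation == pytest.approx(s_erl.expectation, abs=1e-12)


def test_erl_perception_is_convex_blend(rng):
    p = ERLParams(0.3, 8.0, 40.0, 2.0, perception_weight=0.6)
    percept, _ = rl_step(BeliefState(expectation=40.0), 60.0, p)
    assert percept == pytest.approx(0.4 * 60.0 + 0.6 * 40.0)
    assert min(40.0, 60.0) <= percept <= max(40.0, 60.0)


# ---------------------------------------------------------------- KF algebra

def test_kf_gain_half_when_uncertainty_equals_noise():
    p = KFParams(stochasticity=4.0, volatility=1.0, response_noise=8.0,
                 initial_expectation=50.0, initial_uncertainty=10.0,
                 confidence_scaling=2.0)
    state = BeliefState(expectation=50.0, uncertainty=16.0)   # w^2 = s^2
    _, nxt = kf_step(state, 60.0, p)
    # m' = m + 0.5 (N - m)
    assert nxt.expectation == pytest.approx(55.0)


def test_ekf_reduces_to_kf_at_zero_subjective_noise(rng):
    inputs = rng.uniform(0, 100, 60)
    kf = KFParams(6.0, 2.0, 8.0, 50.0, 9.0, 2.0)
    ekf = EKFParams(6.0, 2.0, 8.0, 50.0, 9.0, 2.0, subjective_noise=0.0)
    s1 = BeliefState(expectation=50.0, uncertainty=81.0)
    s2 = BeliefState(expectation=50.0, uncertainty=81.0)
    for x in inputs:
        p1, s1 = kf_step(s1, x, kf)
        p2, s2 = kf_step(s2, x, ekf)
        assert p1 == pytest.approx(p2, abs=1e-12)
        assert s1.expectation == pytest.approx(s2.expectation, abs=1e-12)
        assert s1.uncertainty == pytest.approx(s2.uncertainty, abs=1e-12)


def test_kf_without_drift_matches_conjugate_posterior(rng):
    """With v = 0 the filter must reproduce the closed-form batch posterior
    of a Gaussian mean with known variance (conjugate updating)."""
    s, E0, w0 = 3.0, 50.0, 12.0
    p = KFParams(s, 0.0, 8.0, E0, w0, 2.0)
    data = rng.normal(55.0, s, 40)
    state = BeliefState(expectation=E0, uncertainty=w0 ** 2)
    for x in data:
        _, state = kf_step(state, x, p)
    post_prec = 1.0 / w0 ** 2 + len(data) / s ** 2
    post_mean = (E0 / w0 ** 2 + data.sum() / s ** 2) / post_prec
    assert state.expectation == pytest.approx(post_mean, abs=1e-10)
    assert state.uncertainty == pytest.approx(1.0 / post_prec, abs=1e-10)


def test_kf_uncertainty_converges_to_fixed_point():
    """w^2 tends to the fixed point of w^2 -> w^2 s^2/(w^2+s^2) + v^2."""
    s, v = 5.0, 2.0
    p = KFParams(s, v, 8.0, 50.0, 20.0, 2.0)
    state = BeliefState(expectation=50.0, uncertainty=400.0)
    for _ in range(200):
        _, state = kf_step(state, 50.0, p)
    wstar = optimize.brentq(lambda w2: w2 * s**2 / (w2 + s**2) + v**2 - w2,
                            1e-6, 1e6)
    assert state.uncertainty == pytest.approx(wstar, rel=1e-9)


def test_kf_gain_in_unit_interval(rng):
    p = KFParams(4.0, 3.0, 8.0, 50.0, 6.0, 2.0)
    state = BeliefState(expectation=50.0, uncertainty=36.0)
    for x in rng.uniform(0, 100, 50):
        prev = state
        _, state = kf_step(prev, x, p)
        gain = (state.expectation - prev.expectation) / (x - prev.expectation)
        assert 0.0 < gain < 1.0


def test_ekf_weight_monotonicity():
    """gamma_t = eps^2/(eps^2+s^2+w^2) rises with eps, falls with s and w."""
    def gamma(eps, s, w2):
        return eps**2 / (eps**2 + s**2 + w2)
    assert gamma(0.0, 3.0, 9.0) == 0.0
    eps_grid = np.linspace(0.1, 20, 30)
    assert np.all(np.diff([gamma(e, 3.0, 9.0) for e in eps_grid]) > 0)
    s_grid = np.linspace(0.1, 20, 30)
    assert np.all(np.diff([gamma(5.0, s, 9.0) for s in s_grid]) < 0)
    assert np.all(gamma(5.0, 3.0, np.linspace(1, 400, 30)) < 1.0)


def test_ekf_perception_is_convex_blend(rng):
    p = EKFParams(4.0, 2.0, 8.0, 40.0, 6.0, 2.0, subjective_noise=7.0)
    percept, _ = kf_step(BeliefState(expectation=40.0, uncertainty=36.0), 70.0, p)
    assert 40.0 <= percept <= 70.0


def test_kf_requires_positive_uncertainty():
    p = KFParams(4.0, 2.0, 8.0, 50.0, 6.0, 2.0)
    with pytest.raises(ValueError):
        kf_step(BeliefState(expectation=50.0), 60.0, p)


# ---------------------------------------------------------------- likelihood

def test_loglik_at_mode_and_formula(rng):
    for _ in range(20):
        y, mu = rng.uniform(0, 100, 2)
        xi, C, c = rng.uniform(1, 20), rng.uniform(0.5, 5), rng.uniform(0, 1)
        sd = xi * np.exp((1 - c) / C)
        expected = -np.log(sd * np.sqrt(2 * np.pi)) - 0.5 * ((y - mu) / sd) ** 2
        assert trial_loglik(y, mu, xi, C, c) == pytest.approx(expected, abs=1e-12)
    # at the mode, doubling sd lowers the log-density by log 2
    at_mode = trial_loglik(50.0, 50.0, 5.0, 1e9, 1.0)
    doubled = trial_loglik(50.0, 50.0, 10.0, 1e9, 1.0)
    assert at_mode - doubled == pytest.approx(np.log(2.0), rel=1e-6)


def test_missing_response_contributes_zero():
    assert trial_loglik(np.nan, 50.0, 5.0, 1.0, 0.5) == 0.0


# ---------------------------------------------------------------- run_model

def _setup(n=40, seed=0):
    rng = np.random.default_rng(seed)
    inputs = rng.uniform(20, 80, n)
    sched = generate_schedule(n, seed=seed)
    conf = rng.uniform(0, 1, n)
    return inputs, sched, conf


def test_random_model_mean_is_constant():
    inputs, sched, conf = _setup()
    p = RandomParams(constant_response=62.0, response_noise=5.0,
                     confidence_scaling=2.0)
    out = run_model("random", p, inputs, sched, conf)
    assert np.all(out["response_mean"] == 62.0)


def test_total_loglik_is_sum_of_pointwise(rng):
    inputs, sched, conf = _setup()
    resp = rng.uniform(0, 100, 40)
    p = RLParams(0.3, 8.0, 50.0, 2.0)
    out = run_model("rl", p, inputs, sched, conf, resp)
    assert out["total_loglik"] == pytest.approx(out["loglik"].sum())


def test_rl_no_learning_predicts_initial_expectation():
    inputs, sched, conf = _setup()
    p = RLParams(0.0, 8.0, 47.0, 2.0)
    out = run_model("rl", p, inputs, sched, conf)
    assert np.all(out["prediction_mean"] == 47.0)


def test_belief_updates_despite_missing_responses(rng):
    inputs, sched, conf = _setup()
    resp = rng.uniform(0, 100, 40)
    resp_missing = resp.copy()
    resp_missing[5:15] = np.nan
    p = RLParams(0.4, 8.0, 50.0, 2.0)
    full = run_model("rl", p, inputs, sched, conf, resp)
    part = run_model("rl", p, inputs, sched, conf, resp_missing)
    # trajectories identical; missing trials contribute zero likelihood
    assert np.allclose(full["prediction_mean"], part["prediction_mean"])
    assert np.all(part["loglik"][5:15] == 0.0)
    assert part["total_loglik"] == pytest.approx(
        full["total_loglik"] - full["loglik"][5:15].sum())


def test_length_mismatch_rejected():
    inputs, sched, conf = _setup()
    p = RLParams(0.3, 8.0, 50.0, 2.0)
    with pytest.raises(ValueError):
        run_model("rl", p, inputs[:-1], sched, conf)


# ------------------------------------------------------------- simulation

def test_noise_free_simulation_returns_means():
    inputs, sched, conf = _setup()
    p = RandomParams(55.0, 1e-9, 2.0)
    out = simulate_responses("random", p, inputs, sched, conf, seed=1)
    assert np.allclose(out["response"], 55.0, atol=1e-6)
    q = RLParams(0.3, 1e-9, 50.0, 2.0)
    out = simulate_responses("rl", q, inputs, sched, conf, seed=1)
    assert np.allclose(out["response"], out["response_mean"], atol=1e-6)


def test_simulated_response_sd_matches_noise_scale():
    n = 10_000
    conf = np.full(n, 0.25)
    inputs = np.full(n, 50.0)
    sched = ["perception"] * n
    p = RandomParams(50.0, 6.0, 1.5)
    out = simulate_responses("random", p, inputs, sched, conf, seed=2)
    expected_sd = confidence_noise_scale(6.0, 1.5, 0.25)
    assert out["response"].std() == pytest.approx(expected_sd, rel=0.03)


def test_generating_model_fits_its_own_data_best(rng):
    """Smoke recovery check: loglik of simulated data is higher under the
    generating model than under a mismatched one at true parameters."""
    inputs, sched, conf = _setup(n=80, seed=4)
    rl = RLParams(0.5, 3.0, 50.0, 2.0)
    rnd = RandomParams(50.0, 3.0, 2.0)
    diffs = []
    for seed in range(5):
        sim = simulate_responses("rl", rl, inputs, sched, conf, seed=seed)
        out_rl = run_model("rl", rl, inputs, sched, conf, sim["response"])
        out_rnd = run_model("random", rnd, inputs, sched, conf, sim["response"])
        diffs.append(out_rl["total_loglik"] - out_rnd["total_loglik"])
    assert np.mean(diffs) > 0


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        RLParams(1.2, 8.0, 50.0, 2.0)
    with pytest.raises(ValueError):
        RLParams(0.5, -1.0, 50.0, 2.0)
    with pytest.raises(ValueError):
        EKFParams(4.0, 2.0, 8.0, 50.0, 6.0, 2.0, subjective_noise=-0.1)
    with pytest.raises(ValueError):
        RandomParams(50.0, 5.0, 0.0)
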