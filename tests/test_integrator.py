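import math

import numpy as np
import pytest

from bdchain.coefficients import constant
from bdchain.integrate import (
    IntegrationError,
    SimulationConfig,
    generate_brownian,
    milstein_step,
    simulate,
    simulate_pair,
)
from bdchain.oracle import LogisticSpec, logistic_embedding
from bdchain.presets import preset


def test_brownian_determinism_and_coarsening():
    a = generate_brownian(1000, 0.01, seed=5)
    b = generate_brownian(1000, 0.01, seed=5)
    np.testing.assert_array_equal(a.increments, b.increments)
    c = a.coarsen(10)
    assert c.n_steps == 100 and c.dt == pytest.approx(0.1)
    np.testing.assert_allclose(
        c.increments.sum(axis=1), a.increments.sum(axis=1), rtol=1e-12
    )


def test_brownian_moments():
    """Mean within the 4-sigma CLT band, variance within 1% (1e6 draws)."""
    dt = 0.01
    path = generate_brownian(333_334, dt, seed=42)
    draws = path.increments.ravel()
    assert abs(draws.mean()) < 4.0 * math.sqrt(dt / draws.size)
    assert draws.var() == pytest.approx(dt, rel=0.01)


def _unit_logistic_params(a, b, alpha):
    return logistic_embedding(LogisticSpec.make(a, b, alpha, 1.0))


def test_milstein_step_hand_value():
    """x=1, f=1, sigma=0.5, dt=0.01, dB=0.2 gives
    1 + 0.01 + 0.1 + 0.5*0.25*(0.04-0.01) = 1.11375."""
    params = _unit_logistic_params(a=2.0, b=1.0, alpha=0.5)  # f = x(2 - x) = 1 at x=1
    x = np.ones(3)
    out = milstein_step(0.0, x, x, x, np.array([0.2, 0.0, 0.0]), 0.01, params)
    assert out[0] == pytest.approx(1.11375, abs=1e-12)


def test_milstein_reduces_to_euler_when_db2_equals_dt():
    params = _unit_logistic_params(2.0, 1.0, 0.5)
    x = np.array([1.0, 0.5, 0.25])
    dB = np.full(3, math.sqrt(0.01))
    mil = milstein_step(0.0, x, x, x, dB, 0.01, params, scheme="milstein")
    eul = milstein_step(0.0, x, x, x, dB, 0.01, params, scheme="euler")
    np.testing.assert_allclose(mil, eul, rtol=1e-14)


def test_zero_noise_zero_drift_is_identity():
    # equilibrium x=a/b with alpha=0: drift and diffusion both vanish
    params = _unit_logistic_params(1.0, 1.0, 0.0)
    x = np.array([1.0, 1e-6, 1e-6])
    out = milstein_step(0.0, x, x, x, np.zeros(3), 0.01, params)
    assert out[0] == pytest.approx(1.0, abs=1e-15)


def test_single_step_bookkeeping(model33):
    cfg = SimulationConfig(dt=0.01, horizon=0.01, seed=1)
    traj = simulate(model33.params, model33.history, cfg)
    assert traj.times.size == 2
    assert traj.states.shape == (3, 2)
    np.testing.assert_array_equal(traj.states[:, 0], [0.5, 0.5, 0.5])


def test_zero_noise_run_is_seed_independent(model33):
    params = model33.params.with_zero_noise()
    runs = [
        simulate(params, model33.history, SimulationConfig(dt=0.01, horizon=5.0, seed=s))
        for s in (1, 999)
    ]
    np.testing.assert_array_equal(runs[0].states, runs[1].states)


@pytest.mark.parametrize("name", ["model33", "model35", "model36"])
def test_no_positivity_interventions_on_presets(name):
    p = preset(name)
    cfg = SimulationConfig(dt=0.01, horizon=50.0, seed=0)
    traj = simulate(p.params, p.history, cfg)
    assert traj.clamp_count == 0
    assert traj.states.min() >= cfg.clamp_floor


def test_delay_alignment_enforced(model33):
    params = model33.params.replace(tau1=6.005)
    cfg = SimulationConfig(dt=0.01, horizon=1.0, seed=0)
    with pytest.raises(ValueError, match="integer multiple"):
        simulate(params, model33.history, cfg)
    # interpolation mode accepts the misaligned delay
    cfg_i = SimulationConfig(dt=0.01, horizon=1.0, seed=0, delay_interpolation=True)
    traj = simulate(params, model33.history, cfg_i)
    assert np.all(np.isfinite(traj.states))


def test_pair_with_identical_histories_coincides(model33):
    cfg = SimulationConfig(dt=0.01, horizon=2.0, seed=3)
    a, b = simulate_pair(model33.params, (0.5, 0.5, 0.5), (0.5, 0.5, 0.5), cfg)
    np.testing.assert_array_equal(a.states, b.states)


def test_reject_policy_aborts_on_overshoot():
    """Huge noise with a coarse step overshoots zero; reject must raise."""
    params = _unit_logistic_params(1.0, 1.0, alpha=3.0)
    cfg = SimulationConfig(
        dt=0.5, horizon=50.0, seed=2, scheme="euler", positivity_policy="reject"
    )
    with pytest.raises(IntegrationError):
        simulate(params, (1.0, 1.0, 1.0), cfg)
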