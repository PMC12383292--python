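import numpy as np
import pytest

from bdchain.coefficients import Coefficient, constant
from bdchain.model import (
    bd_term,
    diffusion,
    drift,
    validate_params,
)
from bdchain.oracle import LogisticSpec, logistic_embedding


def test_validate_presets_clean(model33, model35, model36):
    for p in (model33, model35, model36):
        assert validate_params(p.params) == []


def test_validate_reports_violations(model33):
    bad_a11 = Coefficient(kind="sine", midline=0.5, amplitude=1.0, name="a11")
    params = model33.params.replace(a11=bad_a11, tau1=-1.0)
    problems = validate_params(params)
    assert any("a11 not strictly positive" in msg for msg in problems)
    assert "tau1 negative" in problems


def test_drift_baseline_hand_value(model33):
    """At t=0 with all densities 1 the prey rate is
    1*(5.5 - 1.2 - 0.062/(1 + 0.5 + 0.11))."""
    x = np.ones(3)
    f = drift(0.0, x, x, x, model33.params)
    assert f[0] == pytest.approx(5.5 - 1.2 - 0.062 / 1.61, abs=1e-9)


def test_drift_vanishes_with_density(model33):
    """Each component carries an overall x_i factor (multiplicative structure)."""
    base = np.array([1.3, 0.7, 0.4])
    for i in range(3):
        x = base.copy()
        x[i] = 1e-12
        f = drift(0.3, x, base, base, model33.params)
        assert abs(f[i]) < 1e-10


def test_drift_decouples_without_interactions():
    spec = LogisticSpec.make(a=2.0, b=1.5, alpha=0.0, N0=1.0)
    params = logistic_embedding(spec)  # a12=a21=a23=a32=0
    x = np.array([0.8, 0.6, 0.4])
    f = drift(0.0, x, x, x, params)
    assert f[0] == pytest.approx(0.8 * (2.0 - 1.5 * 0.8), abs=1e-14)
    assert f[1] == pytest.approx(0.6 * (-1.0 - 1.0 * 0.6), abs=1e-14)
    assert f[2] == pytest.approx(0.4 * (-1.0 - 1.0 * 0.4), abs=1e-14)


def test_drift_rejects_nonpositive_state(model33):
    x = np.ones(3)
    with pytest.raises(ValueError, match="positive"):
        drift(0.0, np.array([1.0, 0.0, 1.0]), x, x, model33.params)


def test_diffusion_values_and_linearity(model33):
    x = np.ones(3)
    np.testing.assert_allclose(
        diffusion(0.5, x, model33.params), [0.6, 0.3, 0.225], atol=1e-12
    )
    np.testing.assert_allclose(
        diffusion(0.5, 2 * x, model33.params),
        2 * diffusion(0.5, x, model33.params),
        rtol=1e-14,
    )
    zero = model33.params.with_zero_noise()
    np.testing.assert_array_equal(diffusion(0.5, x, zero), np.zeros(3))


def test_bd_response_bounded(model33):
    """a*u/(1+beta*u+gamma*v) <= a/beta and the cross form <= a/gamma,
    the inequalities the persistence proof rests on."""
    rng = np.random.default_rng(11)
    p = model33.params
    for _ in range(10_000):
        t = rng.uniform(0.0, 50.0)
        u, v = rng.lognormal(0.0, 2.0, size=2)
        a12, b1, g1 = p.a12(t), p.beta1(t), p.gamma1(t)
        a21 = p.a21(t)
        assert bd_term(a12, g1, b1, v, u) <= a12 / g1 + 1e-12  # predation per prey
        assert bd_term(a21, b1, g1, u, v) <= a21 / b1 + 1e-12  # intake per predator


def test_drift_consistent_with_bd_term(model33):
    """The inlined kernel and the standalone BD helper agree."""
    p = model33.params
    rng = np.random.default_rng(3)
    for _ in range(50):
        t = rng.uniform(0.0, 10.0)
        x = rng.lognormal(0.0, 1.0, size=3)
        d1 = rng.lognormal(0.0, 1.0, size=3)
        d2 = rng.lognormal(0.0, 1.0, size=3)
        f = drift(t, x, d1, d2, p)
        expect3 = x[2] * (
            -p.r3(t)
            + bd_term(p.a32(t), p.beta2(t), p.gamma2(t), d2[1], d2[2])
            - p.a33(t) * x[2]
        )
        assert f[2] == pytest.approx(expect3, rel=1e-12)


def test_params_hash_distinguishes_presets(model33, model35):
    assert model33.params.params_hash() != model35.params.params_hash()
    assert model33.params.params_hash() == model33.params.params_hash()
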