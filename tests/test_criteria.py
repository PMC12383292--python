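import numpy as np
import pytest

from bdchain.coefficients import constant
from bdchain.criteria import (
    attractivity_coefficients,
    check_conditions,
    moment_bounds,
    persistence_bounds,
    search_weights,
)
from bdchain.integrate import SimulationConfig, simulate
from bdchain.oracle import LogisticSpec, logistic_embedding
from bdchain.presets import random_model

from _reference_formulas import reference_all


def test_baseline_bounds_exact_arithmetic(model33):
    b = persistence_bounds(model33.params)
    assert b.m1 == pytest.approx(4.195 / 2.2, abs=1e-12)
    assert b.M1 == pytest.approx((6.0 - 0.5 * 0.4**2) / 0.2, abs=1e-12)
    assert b.M2 == pytest.approx((6.0 / 0.4 - 0.004 - 0.005) / 2.5, abs=1e-12)
    assert b.warnings == ()


def test_logistic_carrying_capacity_collapses_bounds():
    """No noise, no interactions, constant rates: M1 = m1 = r1/a11."""
    params = logistic_embedding(LogisticSpec.make(a=2.0, b=0.5, alpha=0.0, N0=1.0))
    b = persistence_bounds(params)
    assert b.M1 == pytest.approx(4.0, abs=1e-14)
    assert b.m1 == pytest.approx(4.0, abs=1e-14)


def test_condition_profile_of_presets(model33, model35):
    """Under the literal sup/inf reading the baseline satisfies H1-H5 while
    H6 narrowly fails (the exact M1 inflates its denominator); the reduced
    a32 variant breaks H3 by about -2.66e-3."""
    r33 = check_conditions(model33.params)
    for name in ("H1", "H2", "H3", "H4", "H5"):
        assert r33[name].satisfied, name
    assert not r33["H6"].satisfied
    r35 = check_conditions(model35.params)
    assert not r35["H3"].satisfied
    assert r35["H3"].margin == pytest.approx(0.0015 / 1.3 - 0.0038125, abs=1e-12)


def test_h1_failure_forces_nonpositive_M1():
    params = logistic_embedding(LogisticSpec.make(a=0.1, b=1.0, alpha=0.5, N0=1.0))
    report = check_conditions(params)
    assert not report["H1"].satisfied
    assert persistence_bounds(params).M1 <= 0.0
    assert persistence_bounds(params).warnings  # non-positive bounds flagged


def test_noise_monotonically_erodes_margins(model33):
    """Raising the sigma1 midline lowers the H1 and H4 margins."""
    margins = []
    for mid in (0.5, 0.6, 0.7):
        params = model33.params.replace(sigma1=constant(mid, name="sigma1"))
        r = check_conditions(params)
        margins.append((r["H1"].margin, r["H4"].margin))
    assert margins[0][0] > margins[1][0] > margins[2][0]
    assert margins[0][1] > margins[1][1] > margins[2][1]


def test_sigma_convention_only_moves_m3(model33):
    printed = persistence_bounds(model33.params, "printed")
    sup = persistence_bounds(model33.params, "sup")
    for name in ("M1", "M2", "M3", "m1", "m2"):
        assert getattr(printed, name) == getattr(sup, name)
    shift = 0.5 * (0.225**2 - 0.075**2) / 4.45  # (sigma3^m)^2 vs (sigma3^l)^2 over a33^m
    assert printed.m3 - sup.m3 == pytest.approx(shift, abs=1e-12)


def test_attractivity_decoupled_and_homogeneous():
    params = logistic_embedding(LogisticSpec.make(a=2.0, b=0.5, alpha=0.1, N0=1.0))
    c1 = attractivity_coefficients(params, weights=(1.0, 2.0, 3.0))
    assert c1.A == pytest.approx(0.5, abs=1e-14)       # lambda1 * a11^l
    assert c1.B == pytest.approx(2.0, abs=1e-14)       # lambda2 * a22^l
    assert c1.C == pytest.approx(3.0, abs=1e-14)       # lambda3 * a33^l
    assert c1.satisfied
    c2 = attractivity_coefficients(params, weights=(2.0, 4.0, 6.0))
    assert (c2.A, c2.B, c2.C) == pytest.approx((2 * c1.A, 2 * c1.B, 2 * c1.C))


def test_attractivity_baseline_negative_under_exact_reading(model33):
    c = attractivity_coefficients(model33.params)
    assert c.A == pytest.approx(-3.1802, abs=2e-3)
    assert not c.satisfied


def test_search_weights(model33, model36):
    params = logistic_embedding(LogisticSpec.make(a=2.0, b=0.5, alpha=0.1, N0=1.0))
    res = search_weights(params)
    assert res.h7_found
    # degenerate one-point grid reproduces the direct evaluation
    one = search_weights(model33.params, lambda2_grid=[1.0], lambda3_grid=[1.0])
    direct = attractivity_coefficients(model33.params)
    assert (one.coefficients.A, one.coefficients.B, one.coefficients.C) == (
        direct.A, direct.B, direct.C,
    )
    assert not search_weights(model36.params).h7_found


def test_moment_bounds_values_and_domain(model33):
    mb = moment_bounds(model33.params, 2.0)
    assert mb.L1 == pytest.approx(13.72**3 / (27 * 0.04), rel=1e-12)
    assert mb.L == pytest.approx(1.5 * mb.L1)
    near_one = moment_bounds(model33.params, 1.0001)
    assert np.isfinite([near_one.L1, near_one.G1, near_one.F1]).all()
    with pytest.raises(ValueError):
        moment_bounds(model33.params, 1.0)


def test_second_moment_bound_holds_empirically(model33):
    """Monte-Carlo sanity: the long-run mean of x1^2 stays below 1.5*L1(2)."""
    bound = moment_bounds(model33.params, 2.0).L
    finals = []
    for s in range(40):
        cfg = SimulationConfig(dt=0.01, horizon=20.0, seed=1000 + s)
        traj = simulate(model33.params, model33.history, cfg)
        finals.append(traj.species(0)[-1] ** 2)
    assert np.mean(finals) < bound


@pytest.mark.parametrize("seed", range(100))
def test_formulas_match_independent_transcription(seed):
    """Every bound, margin, Lyapunov coefficient and moment bound agrees
    with a separately written straight-line transcription to 1e-12."""
    params = random_model(seed, "unconstrained")
    ref = reference_all(params, p=2.0)
    b = persistence_bounds(params)
    for name, val in ref["bounds"].items():
        assert getattr(b, name) == pytest.approx(val, rel=1e-12, abs=1e-12), name
    report = check_conditions(params)
    for name, margin in ref["margins"].items():
        assert report[name].margin == pytest.approx(margin, rel=1e-12, abs=1e-12), name
    c = attractivity_coefficients(params)
    for name in ("A", "B", "C"):
        assert getattr(c, name) == pytest.approx(
            ref["attractivity"][name], rel=1e-12, abs=1e-12
        ), name
    mb = moment_bounds(params, 2.0)
    for name in ("L1", "G1", "F1"):
        assert getattr(mb, name) == pytest.approx(
            ref["moments"][name], rel=1e-12, abs=1e-12
        ), name
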