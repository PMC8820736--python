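"""Tests of the 2D Jacobian, characteristic function and fixed points."""

import numpy as np
import pytest
from scipy.optimize import fsolve

from ntanet.params import EnsembleWeights, GainParams, ParameterError, RateParams
from ntanet.rate import simulate_ensemble
from ntanet.stability import (
    characteristic_function,
    critical_input,
    find_fixed_points,
    isn_index_2d,
    jacobian_2d,
    stability_conditions_2d,
)


def _self_consistent_drives(w, gain, r_e, r_i):
    """Choose (gE, gI) so that (r_e, r_i) is a fixed point."""
    g_e = r_e ** (1 / gain.alpha_e) - w.jee * r_e + w.jei * r_i
    g_i = r_i ** (1 / gain.alpha_i) - w.jie * r_e + w.jii * r_i
    return g_e, g_i


def test_jacobian_matches_finite_differences_at_fixed_point(weights, rate_params, gain):
    r_e, r_i = 1.3, 0.7
    g_e, g_i = _self_consistent_drives(weights, gain, r_e, r_i)

    def field(s):
        re, ri = s
        ze = weights.jee * re - weights.jei * ri + g_e
        zi = weights.jie * re - weights.jii * ri + g_i
        return np.array(
            [
                (-re + max(ze, 0.0) ** gain.alpha_e) / rate_params.tau_e,
                (-ri + max(zi, 0.0) ** gain.alpha_i) / rate_params.tau_i,
            ]
        )

    h = 1e-6
    fd = np.column_stack(
        [
            (field(np.array([r_e, r_i]) + h * e) - field(np.array([r_e, r_i]) - h * e))
            / (2 * h)
            for e in np.eye(2)
        ]
    )
    jac = jacobian_2d(weights, rate_params, gain, r_e, r_i).entries
    assert np.abs(fd - jac).max() < 1e-4 * np.abs(jac).max()


def test_jacobian_at_origin_is_pure_leak(weights, rate_params, gain):
    jac = jacobian_2d(weights, rate_params, gain, 0.0, 0.0).entries
    expected = np.diag([-1 / rate_params.tau_e, -1 / rate_params.tau_i])
    assert np.allclose(jac, expected)


def test_jacobian_rejects_negative_rates(weights, rate_params, gain):
    with pytest.raises(ParameterError):
        jacobian_2d(weights, rate_params, gain, -1.0, 0.0)


def test_linear_gain_verdict_is_input_independent(weights, rate_params):
    lin = GainParams(alpha_e=1.0, alpha_i=1.0)
    verdicts = {
        tuple(stability_conditions_2d(weights, rate_params, lin, re, ri).items())
        for re, ri in [(0.1, 0.1), (3.0, 1.0), (50.0, 80.0)]
    }
    assert len(verdicts) == 1


def test_stability_verdict_agrees_with_eigensolver(rng):
    for _ in range(300):
        w = EnsembleWeights(*rng.uniform(0, 3, 4))
        rp = RateParams(tau_e=rng.uniform(0.005, 0.05), tau_i=rng.uniform(0.005, 0.05))
        g = GainParams(alpha_e=rng.uniform(0.5, 3), alpha_i=rng.uniform(0.5, 3))
        r_e, r_i = rng.uniform(0, 10, 2)
        jac = jacobian_2d(w, rp, g, r_e, r_i)
        verdict = stability_conditions_2d(w, rp, g, r_e, r_i)
        lead = jac.eigenvalues.real.max()
        if abs(lead) > 1e-9:
            assert verdict["stable"] == (lead < 0)


def test_isn_index_closed_form(weights, rate_params, gain):
    # index vanishes exactly where JEE * alphaE * sqrt(rE) = 1
    r_zero = (1.0 / (weights.jee * gain.alpha_e)) ** 2
    assert isn_index_2d(weights, rate_params, gain, r_zero) == pytest.approx(0.0, abs=1e-12)
    assert isn_index_2d(weights, rate_params, gain, 0.0) == pytest.approx(-1 / rate_params.tau_e)
    # linear gain: index independent of the rate
    lin = GainParams(alpha_e=1.0, alpha_i=1.0)
    vals = {isn_index_2d(weights, rate_params, lin, r) for r in (0.0, 1.0, 10.0)}
    assert len({round(v, 12) for v in vals}) == 1


def test_characteristic_function_reference_value(weights, rate_params, gain):
    # direct evaluation at z=0 for the canonical baseline drives
    curve = characteristic_function(weights, rate_params, gain, 1.55, 2.0, np.array([0.0]))
    assert curve.f[0] == pytest.approx(0.4051, abs=1e-12)


def test_characteristic_function_monotone_in_drive(weights, rate_params, gain):
    z = np.linspace(-2, 30, 300)
    f1 = characteristic_function(weights, rate_params, gain, 1.55, 2.0, z).f
    f2 = characteristic_function(weights, rate_params, gain, 1.75, 2.0, z).f
    assert np.all(f2 > f1)


def test_characteristic_function_equal_increments_with_large_jii(rate_params, gain):
    # when JII > JEI, raising both drives by the same amount still lifts F
    w = EnsembleWeights(jee=1.8, jei=1.0, jie=0.45, jii=1.5)
    z = np.linspace(-2, 30, 300)
    f1 = characteristic_function(w, rate_params, gain, 1.55, 2.0, z).f
    f2 = characteristic_function(w, rate_params, gain, 1.85, 2.3, z).f
    assert np.all(f2 > f1)


def test_characteristic_function_requires_jei(rate_params, gain):
    w = EnsembleWeights(1.8, 0.0, 1.0, 0.6)
    with pytest.raises(ParameterError):
        characteristic_function(w, rate_params, gain, 1.55, 2.0, np.array([0.0, 1.0]))


def test_fixed_points_baseline_and_stimulated(weights, rate_params, gain):
    rep = find_fixed_points(weights, rate_params, gain, g_e=1.55)
    assert rep.n_points == 2
    kinds = sorted(p.stability for p in rep.points)
    assert kinds == ["saddle", "stable"]
    saddle = [p for p in rep.points if p.stability == "saddle"][0]
    assert saddle.dF_dz > 0
    assert find_fixed_points(weights, rate_params, gain, g_e=3.0).n_points == 0


def test_stable_fixed_point_matches_long_time_simulation(weights, rate_params, gain):
    rep = find_fixed_points(weights, rate_params, gain, g_e=1.55)
    stable = rep.stable_points[0]
    traj = simulate_ensemble(
        weights,
        rate_params,
        gain,
        duration=4.0,
        init=(stable.r_e * 1.2, stable.r_i * 1.2, None),
    )
    assert abs(traj.r_e[-1] - stable.r_e) < 1e-4
    assert abs(traj.r_i[-1] - stable.r_i) < 1e-4


def test_roots_match_direct_newton_on_random_stable_draws(rng):
    gain = GainParams()
    rp = RateParams(g_i=2.0)
    checked = 0
    for _ in range(200):
        w = EnsembleWeights(*rng.uniform(0.2, 2.0, 4))
        g_e = float(rng.uniform(0.2, 2.0))
        rep = find_fixed_points(w, rp, gain, g_e=g_e)
        for p in rep.points:
            def eqs(s):
                re, ri = s
                return [
                    -re + max(w.jee * re - w.jei * ri + g_e, 0) ** 2,
                    -ri + max(w.jie * re - w.jii * ri + rp.g_i, 0) ** 2,
                ]

            sol, info, ier, _ = fsolve(eqs, [p.r_e, p.r_i], full_output=True)
            if ier == 1:
                assert np.abs(eqs(sol)).max() < 1e-8
                assert np.allclose(sol, [p.r_e, p.r_i], atol=1e-7, rtol=1e-7)
                checked += 1
    assert checked > 100


def test_critical_input_brackets_and_definition(weights, rate_params, gain):
    crit = critical_input(weights, rate_params, gain)
    assert 1.55 < crit < 3.0
    assert find_fixed_points(weights, rate_params, gain, g_e=crit - 1e-3).n_points >= 1
    assert find_fixed_points(weights, rate_params, gain, g_e=crit + 1e-3).n_points == 0


def test_critical_input_decreases_with_jee(rate_params, gain):
    crits = []
    for jee in (1.8, 2.0, 2.4, 2.8):  # det(J) < 0 throughout
        w = EnsembleWeights(jee, 1.0, 1.0, 0.6)
        crits.append(critical_input(w, rate_params, gain))
    assert np.all(np.diff(crits) < 0)


def test_no_threshold_for_positive_determinant(rate_params, gain):
    w = EnsembleWeights(jee=1.0, jei=1.0, jie=0.5, jii=1.0)  # det = -1+0.5 < 0? no: -1*1+0.5*1=-0.5
    w = EnsembleWeights(jee=0.5, jei=1.0, jie=1.0, jii=1.0)  # det = -0.5+1 = 0.5 > 0
    assert w.det > 0
    assert critical_input(w, rate_params, gain) is None
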