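"""Tests of the short-term-plasticity analysis."""

import numpy as np
import pytest

from ntanet import presets as P
from ntanet.params import (
    EnsembleWeights,
    FreezeInhibition,
    GainParams,
    InjectToI,
    Mechanism,
    ParameterError,
    PerturbRate,
    RateParams,
    StimulusProtocol,
)
from ntanet.rate import simulate_ensemble
from ntanet.stability import characteristic_function
from ntanet.stp import (
    characteristic_function_std,
    det_j_std,
    find_fixed_points_std,
    inhibitory_steady_rate,
    isn_index_std,
    isn_paradox_analysis_std,
    isn_trajectory_index,
    jacobian_std_3d,
    paradox_threshold_std,
    std_characteristic_poly,
    std_regime_map,
    stp_steady_state,
)


@pytest.mark.parametrize(
    "variant,rate,expected",
    [
        ("std", 20.0, 0.2),
        ("std", 0.0, 1.0),
        ("stf", 20.0, 5.0),
        ("stf", 0.0, 1.0),
    ],
)
def test_steady_state_closed_forms(variant, rate, expected):
    mech = P.default_std() if variant == "std" else P.default_stf()
    assert stp_steady_state(mech, rate) == pytest.approx(expected)


def test_jacobian_3d_matches_finite_differences(weights, rate_params, gain, std):
    r_e = 1.3
    x = stp_steady_state(std, r_e)
    r_i = inhibitory_steady_rate(weights, gain, rate_params.g_i, r_e)
    g_e = r_e ** (1 / gain.alpha_e) - x * weights.jee * r_e + weights.jei * r_i
    g_i = r_i ** (1 / gain.alpha_i) - weights.jie * r_e + weights.jii * r_i

    def field(s):
        re, ri, xx = s
        ze = xx * weights.jee * re - weights.jei * ri + g_e
        zi = weights.jie * re - weights.jii * ri + g_i
        return np.array(
            [
                (-re + max(ze, 0) ** 2) / rate_params.tau_e,
                (-ri + max(zi, 0) ** 2) / rate_params.tau_i,
                (1 - xx) / std.tau_x - std.u_d * xx * re,
            ]
        )

    s0 = np.array([r_e, r_i, x])
    h = 1e-6
    fd = np.column_stack([(field(s0 + h * e) - field(s0 - h * e)) / (2 * h) for e in np.eye(3)])
    jac = jacobian_std_3d(weights, rate_params, gain, std, r_e, r_i, x).entries
    assert np.abs(fd - jac).max() < 1e-4


def test_high_rate_limit_is_stabilized(weights, rate_params, gain, std):
    """At very high rates with x at its steady state, all cubic coefficient
    signs preclude positive roots: depression stabilizes the runaway."""
    r_e = 1e4
    x = stp_steady_state(std, r_e)
    r_i = inhibitory_steady_rate(weights, gain, rate_params.g_i, r_e)
    coeffs = std_characteristic_poly(weights, rate_params, gain, std, r_e, r_i, x)
    # coefficients of lambda^3 - tr l^2 + cof l - det: all positive => no
    # positive real roots (Descartes)
    assert np.all(coeffs > 0)
    jac = jacobian_std_3d(weights, rate_params, gain, std, r_e, r_i, x)
    assert jac.eigenvalues.real.max() < 0


def test_depressed_characteristic_function_identity_and_bending(weights, rate_params, gain):
    z = np.linspace(-2.0, 60.0, 800)
    plain = characteristic_function(weights, rate_params, gain, 1.55, 2.0, z).f
    depressed_full = characteristic_function_std(weights, rate_params, gain, 1.55, 2.0, 1.0, z).f
    assert np.allclose(plain, depressed_full)
    assert det_j_std(weights, 0.5) == pytest.approx(0.46)
    # det > 0 flips the curvature: F bends downward at large z
    f_half = characteristic_function_std(weights, rate_params, gain, 3.0, 2.0, 0.5, z).f
    assert f_half[-1] < f_half[-100] and plain[-1] > plain[-100]


def test_depressed_fixed_points_explain_restabilization(weights, rate_params, gain, std):
    """At the stimulated drive the undepressed system has no fixed point,
    but at the trajectory's depressed x the quasi-static system regains a
    stable one matching the simulation."""
    proto = StimulusProtocol.step(2.0, 4.0, dg_e=1.45)
    traj = simulate_ensemble(weights, rate_params, gain, std, proto, duration=6.0)
    sel = (traj.t >= 3.0) & (traj.t < 3.9)
    x_op = float(traj.aux[sel].mean())
    r_op = float(traj.r_e[sel].mean())
    assert find_fixed_points_std(weights, rate_params, gain, 3.0, 2.0, 1.0).n_points == 0
    rep = find_fixed_points_std(weights, rate_params, gain, 3.0, 2.0, x_op)
    stable = rep.stable_points
    assert stable and min(abs(p.r_e - r_op) for p in stable) < 0.05 * r_op


def test_isn_index_equals_leading_eigenvalue(rng):
    gain = GainParams()
    for _ in range(300):
        w = EnsembleWeights(*rng.uniform(0.1, 3, 4))
        rp = RateParams(tau_e=rng.uniform(0.005, 0.05), tau_i=0.01, g_i=2.0)
        mech = Mechanism.std(u_d=rng.uniform(0.1, 2), tau_x=rng.uniform(0.05, 1))
        r_e, x = rng.uniform(0.01, 50), rng.uniform(0.01, 1)
        a = (x * w.jee * gain.alpha_e * np.sqrt(r_e) - 1) / rp.tau_e
        d = w.jee * gain.alpha_e * r_e ** 1.5 / rp.tau_e
        m1 = np.array([[a, d], [-mech.u_d * x, -1 / mech.tau_x - mech.u_d * r_e]])
        lead = np.linalg.eigvals(m1).real.max()
        assert isn_index_std(w, rp, gain, mech, r_e, x) == pytest.approx(lead, abs=1e-8)


def test_paradox_threshold_value(gain):
    w = EnsembleWeights(1.2, 1.0, 1.0, 0.6)
    assert paradox_threshold_std(w, gain, 1.0) == pytest.approx(1 / 2.4)


def test_regime_map_paradox_subset_of_isn(weights, rate_params, gain, std):
    jee = np.linspace(0.05, 3.0, 40)
    x = np.linspace(0.025, 1.0, 40)
    isn, par = std_regime_map(weights, rate_params, gain, std, jee, x, r_e=1.0)
    assert par.sum() > 0 and isn.sum() > par.sum()
    assert np.all(isn[par])  # paradoxical region contained in ISN region


def test_analysis_reports_slopes_and_positive_inhibitory_slope(weights, rate_params, gain, std):
    point, slopes = isn_paradox_analysis_std(weights, rate_params, gain, std, 1.0, 0.8)
    assert slopes.k_i > 0
    assert point.paradoxical == (point.x > point.x_paradox_threshold and point.slope_condition)
    with pytest.raises(ParameterError):
        isn_paradox_analysis_std(weights, rate_params, gain, std, 0.0, 0.8)


def test_trajectory_index_changes_sign_with_stimulation(weights, rate_params, gain, std):
    proto = StimulusProtocol.step(2.0, 4.0, dg_e=1.45)
    traj = simulate_ensemble(weights, rate_params, gain, std, proto, duration=6.0)
    idx = isn_trajectory_index(traj, weights, rate_params, gain, std)
    assert idx[(traj.t >= 1.5) & (traj.t < 2.0)].max() < 0
    assert idx[(traj.t >= 3.0) & (traj.t < 3.9)].min() > 0
    # wrong mechanism rejected
    with pytest.raises(ParameterError):
        isn_trajectory_index(traj, weights, rate_params, gain, P.default_stf())


def test_index_negative_on_silent_trajectory(weights, rate_params, gain, std):
    idx = isn_index_std(weights, rate_params, gain, std, 0.0, 1.0)
    assert idx == pytest.approx(max(-1 / rate_params.tau_e, -1 / std.tau_x))
    assert idx < 0


def test_elevated_baseline_network_is_isn_before_stimulation(weights, gain, std):
    """With a raised baseline drive the ensemble already sits in the ISN
    regime before stimulation."""
    rp = RateParams(tau_e=0.02, tau_i=0.01, g_e=2.6, g_i=2.0)
    proto = StimulusProtocol.step(2.0, 4.0, dg_e=0.4)
    traj = simulate_ensemble(weights, rp, gain, std, proto, duration=6.0)
    idx = isn_trajectory_index(traj, weights, rp, gain, std)
    assert idx[(traj.t >= 1.5) & (traj.t < 2.0)].min() > 0


def test_inject_to_i_probe_signs(weights, rate_params, gain, std):
    """Paradoxical effect: extra excitatory drive onto I lowers rI at the
    stimulated (ISN) fixed point and raises it at the non-ISN baseline."""
    ref = simulate_ensemble(
        weights, rate_params, gain, std, StimulusProtocol.step(2.0, 4.0, dg_e=1.45), duration=6.0
    )

    def probed(t0, t1):
        proto = StimulusProtocol.step(2.0, 4.0, dg_e=1.45)
        proto.probes.append(InjectToI(t0, t1, 0.2))
        traj = simulate_ensemble(weights, rate_params, gain, std, proto, duration=6.0)
        sel = (traj.t >= t0 + 0.5) & (traj.t < t1)
        return float(traj.r_i[sel].mean() - ref.r_i[sel].mean())

    assert probed(1.0, 1.8) > 0  # baseline: non-paradoxical
    assert probed(2.8, 3.6) < 0  # stimulated: paradoxical


def test_freeze_probe_small_perturbation(weights, rate_params, gain, std):
    """With inhibition frozen, a small rate kick decays at the non-ISN
    baseline but transiently explodes at the stimulated ISN state."""

    def run(freeze, kick):
        proto = StimulusProtocol.step(2.0, 4.0, dg_e=1.45)
        proto.probes += [FreezeInhibition(*freeze), PerturbRate(freeze[0] + 0.05, kick)]
        return simulate_ensemble(weights, rate_params, gain, std, proto, duration=6.0)

    at_base = run((1.0, 1.8), 0.01)
    sel = (at_base.t >= 1.7) & (at_base.t < 1.8)
    assert not at_base.diverged
    assert at_base.r_e[sel].mean() == pytest.approx(0.0434, abs=2e-3)

    at_stim = run((3.0, 3.4), 0.01)
    sel = (at_stim.t >= 3.05) & (at_stim.t < 3.4)
    assert at_stim.diverged or at_stim.r_e[sel].max() > 100.0


def test_std_amplification_exceeds_linear_network(weights, rate_params, gain, std):
    """The STD-stabilized supralinear ensemble amplifies the stimulus at
    least ten times more than a linear ensemble with identical weights."""
    from ntanet.metrics import amplification_index, extract_features

    proto = StimulusProtocol.step(2.0, 4.0, dg_e=1.45)
    supra = simulate_ensemble(weights, rate_params, gain, std, proto, duration=6.0)
    lin = simulate_ensemble(
        weights, rate_params, GainParams(1.0, 1.0), std, proto, duration=6.0
    )
    assert not supra.diverged and not lin.diverged
    f_s = extract_features(supra.t, supra.r_e, (2.0, 4.0))
    f_l = extract_features(lin.t, lin.r_e, (2.0, 4.0))
    amp_s = amplification_index(f_s.onset_peak - f_s.baseline, 1.45)
    amp_l = amplification_index(f_l.onset_peak - f_l.baseline, 1.45)
    assert amp_s >= 10 * amp_l
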