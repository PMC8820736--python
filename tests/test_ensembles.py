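"""Tests of the multi-ensemble block theory and two-ensemble networks."""

import numpy as np
import pytest

from ntanet import presets as P
from ntanet.ensembles import (
    BlockNetworkSpec,
    MorphBetaConfig,
    TwoEnsembleWeights,
    analytic_block_eigenvalues,
    build_block_jacobian,
    delta_re2_linear_response,
    microcircuit_blocks,
    morph_beta_params,
    simulate_two_ensembles,
    simulate_two_ensembles_from_table,
    unistability_map,
)
from ntanet.params import Mechanism, ParameterError


def _multiset_err(analytic, numeric):
    pool = list(numeric)
    worst = 0.0
    for lam in analytic:
        i = int(np.argmin([abs(lam - mu) for mu in pool]))
        worst = max(worst, abs(lam - pool.pop(i)))
    return worst


def _random_spec(rng, m=None, n=None):
    return BlockNetworkSpec(
        n=int(rng.integers(2, 9)) if n is None else n,
        a=rng.uniform(0, 5),
        b=rng.uniform(0, 5),
        c=rng.uniform(0, 5),
        d=rng.uniform(0, 5),
        e=rng.uniform(0.1, 2),
        f=rng.uniform(0.1, 2),
        k=rng.uniform(0, 1),
        m=rng.uniform(0, 1) if m is None else m,
    )


def test_global_form_recovered_at_m_equal_one(rng):
    spec = _random_spec(rng, m=1.0, n=4)
    j = build_block_jacobian(spec)
    n, a, b, c, d, e, f, k = (
        spec.n,
        spec.a,
        spec.b,
        spec.c,
        spec.d,
        spec.e,
        spec.f,
        spec.k,
    )
    eye, ones = np.eye(n), np.ones((n, n))
    explicit = np.block(
        [
            [(a - e) * eye + k * a * (ones - eye), -b * ones],
            [c * ones, -d * ones - f * eye],
        ]
    )
    assert np.allclose(j, explicit)


def test_zero_cotuning_decouples_ensembles():
    spec = BlockNetworkSpec(n=3, a=1, b=0.5, c=0.4, d=0.3, e=0.5, f=1.0, k=0.0, m=0.0)
    j = build_block_jacobian(spec)
    for blk in (j[:3, :3], j[:3, 3:], j[3:, :3], j[3:, 3:]):
        assert np.allclose(blk - np.diag(np.diag(blk)), 0)


def test_analytic_eigenvalues_match_eigensolver(rng):
    for _ in range(400):
        spec = _random_spec(rng)
        numeric = np.linalg.eigvals(build_block_jacobian(spec))
        analytic = analytic_block_eigenvalues(spec).as_spectrum(spec.n)
        assert _multiset_err(analytic, numeric) < 1e-10 * max(
            1.0, np.abs(numeric).max()
        )


def test_differential_mode_eigenvalue_with_multiplicity():
    spec = BlockNetworkSpec(n=2, a=1.0, b=0.2, c=0.2, d=0.3, e=0.5, f=1.0, k=0.1, m=1.0)
    eig = analytic_block_eigenvalues(spec)
    assert eig.lambda1 == pytest.approx(0.4)  # a - e - k*a
    numeric = np.linalg.eigvals(build_block_jacobian(spec))
    assert np.sum(np.abs(numeric - 0.4) < 1e-12) == spec.n - 1


def test_common_modes_identical_between_variants(rng):
    for _ in range(100):
        base = dict(
            n=int(rng.integers(2, 6)),
            a=rng.uniform(0.1, 5),
            b=rng.uniform(0.1, 5),
            c=rng.uniform(0.1, 5),
            d=rng.uniform(0.1, 5),
            e=rng.uniform(0.1, 2),
            f=rng.uniform(0.1, 2),
            k=rng.uniform(0, 1),
        )
        e_g = analytic_block_eigenvalues(BlockNetworkSpec(m=1.0, **base))
        e_c = analytic_block_eigenvalues(BlockNetworkSpec(m=rng.uniform(0, 0.99), **base))
        assert e_c.lambda3 == pytest.approx(e_g.lambda3, abs=1e-10)
        assert e_c.lambda4 == pytest.approx(e_g.lambda4, abs=1e-10)


def test_cotuning_lowers_differential_eigenvalue_on_map_specs(rng):
    """On the phase-diagram family (bc = 0.9ad, physiological e, f) the
    co-tuned differential mode always lies below the global one."""
    for _ in range(200):
        a, d = rng.uniform(0, 200, 2)
        bc = 0.9 * a * d
        base = dict(n=2, a=a, b=np.sqrt(bc), c=np.sqrt(bc), d=d, e=50.0, f=100.0, k=0.1)
        lam1 = analytic_block_eigenvalues(BlockNetworkSpec(m=1.0, **base)).lambda1
        lam1p = analytic_block_eigenvalues(
            BlockNetworkSpec(m=rng.uniform(0, 0.99), **base)
        ).lambda1
        assert lam1p.real < lam1.real + 1e-9


def test_unistability_map_inclusion_and_limits():
    grid = unistability_map(np.linspace(0, 200, 33), np.linspace(0, 200, 33))
    assert np.all(~grid["global"] | grid["cotuned"])  # global set inside co-tuned set
    assert grid["cotuned"].sum() > grid["global"].sum()
    assert grid["global"][:, 0].all() and grid["cotuned"][:, 0].all()  # a=0 column


def test_global_boundary_is_vertical_at_a_equals_e_over_one_minus_k():
    a_star = 50.0 / 0.9  # e/(1-k)
    for d in (10.0, 80.0, 150.0):
        bc = 0.9 * (a_star - 1) * d
        below = BlockNetworkSpec(
            n=2, a=a_star - 1, b=np.sqrt(bc), c=np.sqrt(bc), d=d, e=50.0, f=100.0, k=0.1, m=1.0
        )
        bc2 = 0.9 * (a_star + 1) * d
        above = BlockNetworkSpec(
            n=2, a=a_star + 1, b=np.sqrt(bc2), c=np.sqrt(bc2), d=d, e=50.0, f=100.0, k=0.1, m=1.0
        )
        assert analytic_block_eigenvalues(below).lambda1.real < 0
        assert analytic_block_eigenvalues(above).lambda1.real > 0


def test_unistability_verdict_matches_simulated_mode_dynamics():
    """Brute-force check of the eigenvalue verdicts: in the matching
    rectified-linear two-ensemble network, a perturbation of the symmetric
    interior fixed point along the ensemble-difference mode decays when the
    analytic spectrum says uni-stable and grows when it does not."""
    from ntanet.params import GainParams

    tau_e, tau_i = 0.02, 0.01
    gain = GainParams(alpha_e=1.0, alpha_i=1.0)
    for a, d in [(20.0, 50.0), (80.0, 50.0), (40.0, 150.0), (90.0, 10.0)]:
        bc = 0.9 * a * d
        spec = BlockNetworkSpec(
            n=2, a=a, b=np.sqrt(bc), c=np.sqrt(bc), d=d, e=50.0, f=100.0, k=0.1, m=1.0
        )
        uni = analytic_block_eigenvalues(spec).leading_real < 0
        w = TwoEnsembleWeights(
            jee=a * tau_e,
            jie=np.sqrt(bc) * tau_i,
            jei=np.sqrt(bc) * tau_e,
            jii=d * tau_i,
            jee_p=0.1 * a * tau_e,
            jie_p=np.sqrt(bc) * tau_i,
            jei_p=np.sqrt(bc) * tau_e,
            jii_p=d * tau_i,
        )
        # prescribe a symmetric interior fixed point and solve for the drive
        j = w.matrix()
        fp = np.array([5.0, 5.0, 5.0, 5.0])
        g = (np.eye(4) - j) @ fp
        delta = 1e-3 * fp.mean()
        init = (fp[:2] + np.array([delta, -delta]), fp[2:] + np.array([delta, -delta]), None)
        from ntanet.rate import simulate_network
        from ntanet.ensembles import two_ensemble_blocks

        w_ee, w_ei, w_ie, w_ii = two_ensemble_blocks(w)
        traj = simulate_network(
            w_ee, w_ei, w_ie, w_ii,
            g_e=g[:2], g_i=g[2:], gain=gain, tau_e=tau_e, tau_i=tau_i,
            mechanism=Mechanism.none(), duration=0.2, dt=2e-5, init=init,
            divergence_bound=np.inf,
        )
        diff0 = abs(traj.r_e[0, 0] - traj.r_e[0, 1])
        diff1 = abs(traj.r_e[-1, 0] - traj.r_e[-1, 1])
        if uni:
            assert diff1 < 0.5 * diff0
        else:
            assert diff1 > 2.0 * diff0


def test_multistable_network_keeps_asymmetric_state(gain):
    table = P.two_ensemble_populations(multistable=True)
    net = simulate_two_ensembles_from_table(table, gain, P.default_std(), duration=8.0, seed=3)
    post = net.r_e[(net.t >= 7.0) & (net.t < 8.0)].mean(axis=0)
    assert not net.diverged
    assert max(post) > 5 * max(min(post), 1e-6)  # one high, one low


def test_unistable_network_returns_to_symmetric_baseline(gain):
    table = P.two_ensemble_populations(multistable=False)
    net = simulate_two_ensembles_from_table(table, gain, P.default_std(), duration=8.0, seed=3)
    base = net.r_e[(net.t >= 1.5) & (net.t < 2.0)].mean(axis=0)
    post = net.r_e[(net.t >= 7.0) & (net.t < 8.0)].mean(axis=0)
    assert post[0] == pytest.approx(post[1], rel=1e-3)
    assert post[0] == pytest.approx(base[0], rel=1e-2)
    # during stimulation the stimulated ensemble is selectively active
    stim = net.r_e[(net.t >= 3.0) & (net.t < 3.9)].mean(axis=0)
    assert stim[0] > 10 * max(stim[1], 1e-6)


def test_linear_response_decoupled_and_weak_coupling_limit():
    w0 = TwoEnsembleWeights(1.2, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0)
    assert delta_re2_linear_response(w0, (1, 1, 0.5, 0.5), 1.0)["delta_re2"] == 0.0
    for eps in (1e-2, 1e-4):
        w = TwoEnsembleWeights(1.2, 1.0, 1.0, 1.0, 0.3 * eps, 0.4 * eps, 0.1 * eps, 0.1 * eps)
        r = delta_re2_linear_response(w, (0.6, 0.6, 0.5, 0.5), 1.0)
        assert r["delta_re2_weak"] / r["delta_re2"] == pytest.approx(1.0, abs=10 * eps)


@pytest.mark.parametrize("pathway", ["jie_p", "jei_p"])
def test_cross_inhibitory_pathways_suppress(pathway):
    kwargs = dict(jee=1.2, jie=1.0, jei=1.0, jii=1.0, jee_p=0.05, jie_p=0.0, jei_p=0.0, jii_p=0.0)
    lo = delta_re2_linear_response(TwoEnsembleWeights(**kwargs), (0.6, 0.6, 0.5, 0.5), 1.0)
    kwargs[pathway] = 1.0
    hi = delta_re2_linear_response(TwoEnsembleWeights(**kwargs), (0.6, 0.6, 0.5, 0.5), 1.0)
    assert hi["delta_re2"] < lo["delta_re2"]
    assert hi["delta_re2"] < 0


def test_morph_beta_parameterization():
    assert morph_beta_params(MorphBetaConfig(p=0.0))["g_e1_stim"] == pytest.approx(4.0)
    assert morph_beta_params(MorphBetaConfig(p=0.0))["g_e2_stim"] == pytest.approx(1.35)
    sym = morph_beta_params(MorphBetaConfig(p=0.5))
    assert sym["g_e1_stim"] == sym["g_e2_stim"] == pytest.approx(2.675)
    for beta in (0.0, 0.3, 1.0):
        r = morph_beta_params(MorphBetaConfig(beta=beta, j_tot=1.2))
        assert r["jee_tot"] + r["jee_p_tot"] == pytest.approx(1.2)
    with pytest.raises(ParameterError):
        MorphBetaConfig(p=1.5)


def test_microcircuit_blocks_effective_weights():
    tab = P.two_ensemble_microcircuit()
    blocks = microcircuit_blocks(tab)
    # homogeneous-ensemble effective weights recover the quoted totals
    assert blocks["w_ee"][0, 0] == pytest.approx(1.2)
    assert blocks["w_ee"][0, 1] == pytest.approx(0.36 / 99 * 100)
    assert blocks["w_ei"][0, 0] == pytest.approx(1.0)
    assert blocks["w_ii"][0, 0] == pytest.approx(1.0)
    split = microcircuit_blocks(tab, subset_split=(0.75, 0.25))
    assert split["sizes_e"] == [75, 25, 100]
    # subset splitting preserves per-connection weights: row sums match
    assert split["w_ee"][0, 0] + split["w_ee"][0, 1] == pytest.approx(1.2)
    with pytest.raises(ParameterError):
        microcircuit_blocks(tab, subset_split=(0.75, 0.35))
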