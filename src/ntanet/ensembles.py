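"""Multi-ensemble networks: block Jacobians, closed-form spectra,
uni-stability maps, two-ensemble simulations and linear-response analysis.

The analytic theory treats N identical ensembles, each a pair of one
excitatory and one inhibitory population, linearized at a common symmetric
operating point. The gain-scaled coupling terms are

    a = JEE * alphaE * [zE]_+^(alphaE-1) / tau_E   (recurrent E self-coupling)
    b = JEI * alphaE * [zE]_+^(alphaE-1) / tau_E   (I -> E)
    c = JIE * alphaI * [zI]_+^(alphaI-1) / tau_I   (E -> I)
    d = JII * alphaI * [zI]_+^(alphaI-1) / tau_I   (I self-coupling)
    e = 1/tau_E,  f = 1/tau_I

``k`` scales inter-ensemble excitation, and ``m`` in [0, 1] sets the
degree of inhibitory co-tuning: at m=1 inhibition is global (one
effective non-specific pool), at m=0 each ensemble has its own perfectly
co-tuned inhibition and the network decouples. The spectrum of the 2N x 2N
Jacobian consists of four distinct eigenvalues; the two carrying
multiplicity N-1 govern ensemble-differential modes and hence
uni-stability (a single symmetric attractor) versus multi-stability.
Co-tuning (m < 1) strictly lowers Re(lambda_1), widening the uni-stable
parameter regime.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np

from .params import GainParams, Mechanism, ParameterError, StimulusProtocol
from .presets import MicrocircuitTable, TwoEnsembleTable
from .rate import NetworkTrajectory, simulate_network

__all__ = [
    "BlockNetworkSpec",
    "build_block_jacobian",
    "BlockEigenvalues",
    "analytic_block_eigenvalues",
    "unistability_map",
    "TwoEnsembleWeights",
    "two_ensemble_blocks",
    "microcircuit_blocks",
    "simulate_two_ensembles",
    "delta_re2_linear_response",
    "MorphBetaConfig",
    "morph_beta_params",
]


@dataclass(frozen=True)
class BlockNetworkSpec:
    """Symmetric N-ensemble network in gain-scaled coordinates."""

    n: int
    a: float
    b: float
    c: float
    d: float
    e: float
    f: float
    k: float
    m: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ParameterError("need at least two ensembles")
        if not 0 <= self.m <= 1:
            raise ParameterError("co-tuning degree m must lie in [0, 1]")
        if min(self.a, self.b, self.c, self.d, self.e, self.f) < 0:
            raise ParameterError("gain-scaled couplings must be non-negative")


def build_block_jacobian(spec: BlockNetworkSpec) -> np.ndarray:
    """Assemble the 2N x 2N Jacobian; m=1 yields the global-inhibition form.

    Layout: first N rows/cols are excitatory populations, last N
    inhibitory. The co-tuned form interpolates; at m=0 the network is
    block-diagonal (N decoupled ensembles).
    """
    n, a, b, c, d = spec.n, spec.a, spec.b, spec.c, spec.d
    e, f, k, m = spec.e, spec.f, spec.k, spec.m
    eye = np.eye(n)
    ones = np.ones((n, n))
    j_ee = (a - e) * eye + k * a * (ones - eye)
    j_ei = (-n * b + (n - 1) * m * b) * eye + (-m * b) * (ones - eye)
    j_ie = (n * c - (n - 1) * m * c) * eye + (m * c) * (ones - eye)
    j_ii = (-n * d + (n - 1) * m * d - f) * eye + (-m * d) * (ones - eye)
    return np.block([[j_ee, j_ei], [j_ie, j_ii]])


@dataclass
class BlockEigenvalues:
    """The four distinct eigenvalues of the block Jacobian.

    ``lambda1`` and ``lambda2`` each have multiplicity N-1 (ensemble-
    differential modes); ``lambda3``/``lambda4`` have multiplicity 1
    (common modes, identical between the global and co-tuned variants).
    """

    lambda1: complex
    lambda2: complex
    lambda3: complex
    lambda4: complex
    variant: str

    @property
    def leading_real(self) -> float:
        return max(
            self.lambda1.real, self.lambda2.real, self.lambda3.real, self.lambda4.real
        )

    def as_spectrum(self, n: int) -> np.ndarray:
        """Full multiset of 2N eigenvalues with multiplicities."""
        return np.array(
            [self.lambda1] * (n - 1)
            + [self.lambda2] * (n - 1)
            + [self.lambda3, self.lambda4]
        )


def analytic_block_eigenvalues(spec: BlockNetworkSpec) -> BlockEigenvalues:
    """Closed-form spectrum of the block Jacobian.

    Global inhibition (m=1): ``lambda1 = a - e - k*a`` and ``lambda2 = -f``.
    Co-tuned inhibition (m<1): lambda1/2 are the roots of the 2x2
    differential-mode problem and satisfy Re(lambda1') < lambda1, the
    mechanism by which co-tuning enlarges the uni-stable regime.
    """
    n, a, b, c, d = spec.n, spec.a, spec.b, spec.c, spec.d
    e, f, k, m = spec.e, spec.f, spec.k, spec.m
    s = a - e - f - n * d + (n - 1) * k * a
    disc34 = s**2 - 4 * (
        (-a * f + e * f + k * a * f)
        - n * (a - e) * d
        - n * k * a * f
        - n * (n - 1) * k * a * d
        + n**2 * b * c
    )
    root34 = np.emath.sqrt(disc34)
    lam3 = 0.5 * (s + root34)
    lam4 = 0.5 * (s - root34)
    if m == 1.0:
        lam1, lam2 = complex(a - e - k * a), complex(-f)
        variant = "global"
    else:
        p = a - e - k * a - n * d + n * m * d - f
        disc12 = (a - e - k * a + n * d - n * m * d + f) ** 2 - 4 * n**2 * b * c * (
            1 - m
        ) ** 2
        root12 = np.emath.sqrt(disc12)
        lam1 = 0.5 * (p + root12)
        lam2 = 0.5 * (p - root12)
        variant = "cotuned"
    return BlockEigenvalues(
        lambda1=complex(lam1),
        lambda2=complex(lam2),
        lambda3=complex(lam3),
        lambda4=complex(lam4),
        variant=variant,
    )


def unistability_map(
    a_grid: np.ndarray,
    d_grid: np.ndarray,
    k: float = 0.1,
    m: float = 0.5,
    bc_rule: Optional[Callable[[float, float], float]] = None,
    n: int = 2,
    e: float = 50.0,
    f: float = 100.0,
) -> dict:
    """Uni-stability phase diagram over the (a, d) plane.

    A grid point is uni-stable when the leading real part of the analytic
    spectrum is negative: the symmetric state is the only attractor and no
    ensemble-differential mode can grow. ``bc_rule(a, d)`` supplies the
    product b*c (default ``0.9*a*d``). Returns boolean maps for the
    global-inhibition network and the co-tuned network with the given m,
    indexed as ``[i_d, i_a]``.
    """
    bc_rule = bc_rule or (lambda a, d: 0.9 * a * d)
    uni_global = np.zeros((len(d_grid), len(a_grid)), dtype=bool)
    uni_cotuned = np.zeros_like(uni_global)
    for i, d in enumerate(d_grid):
        for j, a in enumerate(a_grid):
            bc = bc_rule(float(a), float(d))
            bb = cc = np.sqrt(max(bc, 0.0))
            base = dict(n=n, a=float(a), b=bb, c=cc, d=float(d), e=e, f=f, k=k)
            eig_g = analytic_block_eigenvalues(BlockNetworkSpec(m=1.0, **base))
            eig_c = analytic_block_eigenvalues(BlockNetworkSpec(m=m, **base))
            uni_global[i, j] = eig_g.leading_real < 0
            uni_cotuned[i, j] = eig_c.leading_real < 0
    return {
        "a": np.asarray(a_grid),
        "d": np.asarray(d_grid),
        "global": uni_global,
        "cotuned": uni_cotuned,
    }


# ----------------------------------------------------------------------
# Two-ensemble simulation networks
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class TwoEnsembleWeights:
    """Symmetric reduction of the 4x4 population weight matrix.

    Unprimed entries couple populations within an ensemble, primed entries
    couple across ensembles; all are magnitudes.
    """

    jee: float
    jie: float
    jei: float
    jii: float
    jee_p: float
    jie_p: float
    jei_p: float
    jii_p: float

    def matrix(self) -> np.ndarray:
        """Signed 4x4 matrix, populations ordered (E1, E2, I1, I2)."""
        return np.array(
            [
                [self.jee, self.jee_p, -self.jei, -self.jei_p],
                [self.jee_p, self.jee, -self.jei_p, -self.jei],
                [self.jie, self.jie_p, -self.jii, -self.jii_p],
                [self.jie_p, self.jie, -self.jii_p, -self.jii],
            ]
        )


def two_ensemble_blocks(w: TwoEnsembleWeights) -> Tuple[np.ndarray, ...]:
    """Weight-magnitude blocks (w_ee, w_ei, w_ie, w_ii) for the integrator."""
    w_ee = np.array([[w.jee, w.jee_p], [w.jee_p, w.jee]])
    w_ei = np.array([[w.jei, w.jei_p], [w.jei_p, w.jei]])
    w_ie = np.array([[w.jie, w.jie_p], [w.jie_p, w.jie]])
    w_ii = np.array([[w.jii, w.jii_p], [w.jii_p, w.jii]])
    return w_ee, w_ei, w_ie, w_ii


def microcircuit_blocks(
    table: MicrocircuitTable, subset_split: Optional[Tuple[float, float]] = None
) -> dict:
    """Population blocks of the neuron-normalized two-ensemble circuit.

    Each ensemble has ``n_e/2`` excitatory and ``n_i/2`` inhibitory
    all-to-all connected neurons (no self-connections); identical neurons
    are grouped into populations, so the effective weight from a group of
    size ``s`` equals the per-connection weight times ``s`` (``s - 1``
    onto members of the same group). ``subset_split`` optionally divides
    ensemble 1's excitatory neurons into two subpopulations (e.g. the
    stimulated 75% and unstimulated 25%) while preserving exact
    per-connection weights.
    """
    ne_half = table.n_e // 2
    ni_half = table.n_i // 2
    if subset_split is None:
        sizes_e = [ne_half, ne_half]  # E1, E2
        ensemble_of_e = [0, 1]
    else:
        f1, f2 = subset_split
        if not (0 < f1 < 1 and 0 < f2 < 1 and abs(f1 + f2 - 1) < 1e-9):
            raise ParameterError("subset fractions must be in (0,1) and sum to 1")
        n1 = int(round(f1 * ne_half))
        sizes_e = [n1, ne_half - n1, ne_half]  # E1a, E1b, E2
        ensemble_of_e = [0, 0, 1]
    sizes_i = [ni_half, ni_half]
    ensemble_of_i = [0, 1]

    def eff(per_conn: float, pre_size: int, same_group: bool) -> float:
        return per_conn * (pre_size - 1 if same_group else pre_size)

    n_e, n_i = len(sizes_e), len(sizes_i)
    w_ee = np.zeros((n_e, n_e))
    for i in range(n_e):
        for j in range(n_e):
            per = table.jee if ensemble_of_e[i] == ensemble_of_e[j] else table.jee_p
            w_ee[i, j] = eff(per, sizes_e[j], i == j)
    w_ei = np.zeros((n_e, n_i))
    for i in range(n_e):
        for j in range(n_i):
            per = table.jei if ensemble_of_e[i] == ensemble_of_i[j] else table.jei_p
            w_ei[i, j] = per * sizes_i[j]
    w_ie = np.zeros((n_i, n_e))
    for i in range(n_i):
        for j in range(n_e):
            per = table.jie if ensemble_of_i[i] == ensemble_of_e[j] else table.jie_p
            w_ie[i, j] = per * sizes_e[j]
    w_ii = np.zeros((n_i, n_i))
    for i in range(n_i):
        for j in range(n_i):
            per = table.jii if ensemble_of_i[i] == ensemble_of_i[j] else table.jii_p
            w_ii[i, j] = eff(per, sizes_i[j], i == j)
    return {
        "w_ee": w_ee,
        "w_ei": w_ei,
        "w_ie": w_ie,
        "w_ii": w_ii,
        "sizes_e": sizes_e,
        "sizes_i": sizes_i,
        "ensemble_of_e": ensemble_of_e,
    }


def simulate_two_ensembles(
    weights: TwoEnsembleWeights,
    gain: GainParams,
    tau_e: float,
    tau_i: float,
    g_e,
    g_i,
    mechanism: Mechanism,
    protocol: Optional[StimulusProtocol] = None,
    duration: float = 10.0,
    dt: float = 1e-4,
    init_noise: float = 0.0,
    seed: Optional[int] = None,
    rate_cap: Optional[float] = None,
) -> NetworkTrajectory:
    """Simulate the symmetric two-ensemble population network.

    ``init_noise`` adds a seeded uniform perturbation of the given
    magnitude to the initial rates, which breaks the exact E1/E2 symmetry
    and lets multi-stable configurations fall into an asymmetric attractor.
    """
    w_ee, w_ei, w_ie, w_ii = two_ensemble_blocks(weights)
    init = None
    if init_noise > 0:
        rng = np.random.default_rng(seed)
        init = (rng.uniform(0, init_noise, 2), rng.uniform(0, init_noise, 2), None)
    return simulate_network(
        w_ee,
        w_ei,
        w_ie,
        w_ii,
        g_e=g_e,
        g_i=g_i,
        gain=gain,
        tau_e=tau_e,
        tau_i=tau_i,
        mechanism=mechanism,
        protocol=protocol,
        duration=duration,
        dt=dt,
        init=init,
        rate_cap=rate_cap,
    )


def simulate_two_ensembles_from_table(
    table: TwoEnsembleTable,
    gain: GainParams,
    mechanism: Mechanism,
    stim: Tuple[float, float] = (2.0, 4.0),
    duration: float = 10.0,
    dt: float = 1e-4,
    init_noise: float = 1e-3,
    seed: Optional[int] = 0,
) -> NetworkTrajectory:
    """Run the canonical two-ensemble protocol from a parameter table.

    Ensemble 1 is stimulated during ``stim``; both ensembles otherwise sit
    at the symmetric baseline drive.
    """
    w = TwoEnsembleWeights(
        jee=table.jee,
        jie=table.jie,
        jei=table.jei,
        jii=table.jii,
        jee_p=table.jee_p,
        jie_p=table.jie_p,
        jei_p=table.jei_p,
        jii_p=table.jii_p,
    )
    protocol = StimulusProtocol.step(
        stim[0],
        stim[1],
        dg_e=np.array([table.g_e1_stim - table.g_e1_base, 0.0]),
    )
    return simulate_two_ensembles(
        w,
        gain,
        tau_e=0.020,
        tau_i=0.010,
        g_e=np.array([table.g_e1_base, table.g_e2]),
        g_i=table.g_i,
        mechanism=mechanism,
        protocol=protocol,
        duration=duration,
        dt=dt,
        init_noise=init_noise,
        seed=seed,
    )


def delta_re2_linear_response(
    weights: TwoEnsembleWeights,
    gain_derivatives: Tuple[float, float, float, float],
    delta_g_e1: float,
) -> dict:
    """Linear response of ensemble 2's excitatory rate to drive on E1.

    ``gain_derivatives`` are the slopes (f'_E1, f'_E2, f'_I1, f'_I2) of
    the input-output functions at the operating point. Returns both the
    exact linearized response and the weak-cross-coupling approximation
    (cross terms of second order and higher dropped); their ratio tends to
    one as the primed weights vanish. Suppression of the unstimulated
    ensemble (negative response) is carried by the JIE' (E1->I2->E2) and
    JEI' (I1->E2) pathways.
    """
    fe1, fe2, fi1, fi2 = gain_derivatives
    j = weights.matrix()
    f_mat = np.diag([fe1, fe2, fi1, fi2])
    det_sys = float(np.linalg.det(np.eye(4) - f_mat @ j))
    if abs(det_sys) < 1e-12:
        raise ParameterError("operating point is singular (unstable network)")
    jee_p, jie_p, jei_p, jii_p = (
        weights.jee_p,
        weights.jie_p,
        weights.jei_p,
        weights.jii_p,
    )
    jee, jie, jei, jii = weights.jee, weights.jie, weights.jei, weights.jii
    num_full = (
        (-fe2 * jee_p) * (fi1 * jii_p) * (fi2 * jii_p)
        + fe2 * jei_p * (-fi1 * jie) * (1 + fi2 * jii)
        + fe2 * jei * (1 + fi1 * jii) * (-fi2 * jie_p)
        - (-fe2 * jee_p) * (1 + fi1 * jii) * (1 + fi2 * jii)
        - fe2 * jei_p * (fi1 * jii_p) * (-fi2 * jie_p)
        - fe2 * jei * (-fi1 * jie) * (fi2 * jii_p)
    )
    num_weak = (
        fe2 * jei_p * (-fi1 * jie) * (1 + fi2 * jii)
        + fe2 * jei * (1 + fi1 * jii) * (-fi2 * jie_p)
        - (-fe2 * jee_p) * (1 + fi1 * jii) * (1 + fi2 * jii)
        - fe2 * jei * (-fi1 * jie) * (fi2 * jii_p)
    )
    return {
        "delta_re2": num_full / det_sys * fe1 * delta_g_e1,
        "delta_re2_weak": num_weak / det_sys * fe1 * delta_g_e1,
        "det": det_sys,
    }


@dataclass(frozen=True)
class MorphBetaConfig:
    """Morphing/tuning parameterization of the two-ensemble network.

    ``p`` interpolates the extra drive between the two ensembles (p=0: all
    to E1, p=1: all to E2, p=0.5 symmetric); ``beta`` trades within- vs
    inter-ensemble excitation at a fixed total budget ``j_tot``.
    """

    p: float = 0.0
    beta: float = 1.0
    j_tot: float = 1.2
    g_base: float = 1.35
    g_max: float = 4.0

    def __post_init__(self) -> None:
        if not (0 <= self.p <= 1 and 0 <= self.beta <= 1):
            raise ParameterError("p and beta must lie in [0, 1]")


def morph_beta_params(config: MorphBetaConfig) -> dict:
    """Resolve the morphing drives and the beta-split excitatory weights.

    ``gE1_stim = g_base + (g_max - g_base)(1 - p)`` and symmetrically for
    E2; ``JEE = beta*j_tot`` and ``JEE' = (1-beta)*j_tot`` so their sum is
    constant.
    """
    span = config.g_max - config.g_base
    return {
        "g_e1_stim": config.g_base + span * (1.0 - config.p),
        "g_e2_stim": config.g_base + span * config.p,
        "g_base": config.g_base,
        "jee_tot": config.beta * config.j_tot,
        "jee_p_tot": (1.0 - config.beta) * config.j_tot,
    }
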