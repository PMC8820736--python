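"""Short-term-plasticity analysis: steady states, 3D stability with E-to-E
depression, the depressed-weight characteristic function, and the
ISN/paradoxical regime conditions.

E-to-E short-term depression multiplies JEE by a resource variable
``x in (0, 1]``; E-to-I facilitation multiplies JIE by an efficacy
``u in [1, u_max]``. Because x (and u) relax slowly compared to the rates,
the 2D characteristic function evaluated with the depressed weight
``x*JEE`` is an excellent quasi-static approximation of the full 3D
system: depression can flip the sign of the effective determinant
``det(J_STD) = -x*JEE*JII + JIE*JEI`` and thereby bend the characteristic
function downwards at large z, creating the stable stimulated fixed point
that terminates the onset transient.

Inhibition stabilization (ISN) is measured by the leading eigenvalue of
the E-E subnetwork with frozen inhibition (here the 2x2 (rE, x) block);
the paradoxical effect (inhibitory rate dropping under excitatory current
injection into I) additionally requires a positive excitatory-nullcline
slope, so in depressing networks paradoxical responses imply inhibition
stabilization but not conversely.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .params import (
    EnsembleWeights,
    GainParams,
    Mechanism,
    ParameterError,
    RateParams,
)
from .rate import RateTrajectory
from .stability import (
    CharacteristicCurve,
    FixedPointReport,
    JacobianMatrix,
    characteristic_function,
    find_fixed_points,
    gain_slope,
)

__all__ = [
    "stp_steady_state",
    "jacobian_std_3d",
    "std_characteristic_poly",
    "characteristic_function_std",
    "find_fixed_points_std",
    "det_j_std",
    "isn_index_std",
    "NullclineSlopes",
    "StdRegimePoint",
    "paradox_threshold_std",
    "isn_paradox_analysis_std",
    "std_regime_map",
    "isn_trajectory_index",
    "inhibitory_steady_rate",
]


def stp_steady_state(mech: Mechanism, r_e: float) -> float:
    """Steady-state value of the plasticity variable at a clamped rate.

    STD: ``x* = 1 / (1 + Ud * rE * tau_x)``;
    STF: ``u* = (1 + Uf * u_max * rE * tau_u) / (1 + Uf * rE * tau_u)``.
    """
    if r_e < 0:
        raise ParameterError("rate must be non-negative")
    if mech.variant == "std":
        return 1.0 / (1.0 + mech.u_d * r_e * mech.tau_x)
    if mech.variant == "stf":
        return (1.0 + mech.u_f * mech.u_max * r_e * mech.tau_u) / (
            1.0 + mech.u_f * r_e * mech.tau_u
        )
    raise ParameterError("steady state defined for std/stf mechanisms only")


def jacobian_std_3d(
    weights: EnsembleWeights,
    params: RateParams,
    gain: GainParams,
    mech: Mechanism,
    r_e: float,
    r_i: float,
    x: float,
) -> JacobianMatrix:
    """3x3 Jacobian of the (rE, rI, x) system with E-to-E depression."""
    if not 0 < x <= 1:
        raise ParameterError("STD variable x must lie in (0, 1]")
    if mech.variant != "std":
        raise ParameterError("requires an STD mechanism")
    phi_e = gain_slope(r_e, gain.alpha_e)
    phi_i = gain_slope(r_i, gain.alpha_i)
    te, ti = params.tau_e, params.tau_i
    ae = gain.alpha_e
    # d/dx of the E drive: alphaE * z^(alphaE-1) * JEE * rE with
    # z^(alphaE-1) = rE^((alphaE-1)/alphaE), i.e. JEE*alphaE*rE^((2a-1)/a).
    dz_dx = weights.jee * ae * r_e ** ((2 * ae - 1.0) / ae) if r_e > 0 else 0.0
    m = np.array(
        [
            [
                (x * weights.jee * phi_e - 1.0) / te,
                -weights.jei * phi_e / te,
                dz_dx / te,
            ],
            [weights.jie * phi_i / ti, -(1.0 + weights.jii * phi_i) / ti, 0.0],
            [-mech.u_d * x, 0.0, -1.0 / mech.tau_x - mech.u_d * r_e],
        ]
    )
    return JacobianMatrix(
        entries=m, eigenvalues=np.linalg.eigvals(m), context=(r_e, r_i, x)
    )


def std_characteristic_poly(
    weights: EnsembleWeights,
    params: RateParams,
    gain: GainParams,
    mech: Mechanism,
    r_e: float,
    r_i: float,
    x: float,
) -> np.ndarray:
    """Coefficients [1, -tr, cofactor_sum, -det] of the STD cubic."""
    m = jacobian_std_3d(weights, params, gain, mech, r_e, r_i, x).entries
    tr = float(np.trace(m))
    cof = sum(
        float(np.linalg.det(np.delete(np.delete(m, k, 0), k, 1))) for k in range(3)
    )
    det = float(np.linalg.det(m))
    return np.array([1.0, -tr, cof, -det])


def det_j_std(weights: EnsembleWeights, x: float) -> float:
    """Effective weight determinant with depressed JEE: -x*JEE*JII + JIE*JEI."""
    return -x * weights.jee * weights.jii + weights.jie * weights.jei


def characteristic_function_std(
    weights: EnsembleWeights,
    params: RateParams,
    gain: GainParams,
    g_e: float,
    g_i: float,
    x: float,
    z_grid: np.ndarray,
) -> CharacteristicCurve:
    """Characteristic function with JEE depressed by a frozen x.

    Treats the slow depression variable as constant (separation of
    timescales); at x=1 this is exactly the plain characteristic function.
    """
    if not 0 < x <= 1:
        raise ParameterError("STD variable x must lie in (0, 1]")
    if weights.jei == 0:
        raise ParameterError("the characteristic function requires JEI > 0")
    from .stability import _char_fun

    z = np.asarray(z_grid, dtype=float)
    f = _char_fun(
        z,
        weights,
        gain,
        g_e,
        g_i,
        jee_eff=x * weights.jee,
        det_j=det_j_std(weights, x),
    )
    return CharacteristicCurve(z=z, f=f)


def find_fixed_points_std(
    weights: EnsembleWeights,
    params: RateParams,
    gain: GainParams,
    g_e: float,
    g_i: float,
    x: float,
) -> FixedPointReport:
    """Fixed points of the quasi-static (frozen-x) depressed system."""
    return find_fixed_points(
        weights,
        params,
        gain,
        g_e=g_e,
        g_i=g_i,
        jee_eff=x * weights.jee,
        det_j=det_j_std(weights, x),
    )


def isn_index_std(
    weights: EnsembleWeights,
    params: RateParams,
    gain: GainParams,
    mech: Mechanism,
    r_e: float,
    x: float,
) -> float:
    """ISN index with E-to-E STD: leading eigenvalue of the frozen-inhibition
    (rE, x) block, in closed form."""
    phi_e = gain_slope(r_e, gain.alpha_e)
    ae = gain.alpha_e
    te = params.tau_e
    a = (x * weights.jee * phi_e - 1.0) / te
    bterm = 1.0 / mech.tau_x + mech.u_d * r_e
    c = (
        (weights.jee * ae * r_e ** ((2 * ae - 1.0) / ae)) / te * mech.u_d * x
        if r_e > 0
        else 0.0
    )
    disc = 0.25 * (a + bterm) ** 2 - c
    root = np.emath.sqrt(disc)
    return float(np.real((a - bterm) / 2.0 + root))


def inhibitory_steady_rate(
    weights: EnsembleWeights,
    gain: GainParams,
    g_i: float,
    r_e: float,
) -> float:
    """Solve rI = [JIE rE - JII rI + gI]_+^alphaI for a clamped rE."""

    def h(r_i):
        return (
            max(weights.jie * r_e - weights.jii * r_i + g_i, 0.0) ** gain.alpha_i - r_i
        )

    hi = max(1.0, (max(weights.jie * r_e + g_i, 0.0)) ** gain.alpha_i)
    if h(0.0) <= 0:
        return 0.0
    return float(brentq(h, 0.0, hi, xtol=1e-12))


@dataclass
class NullclineSlopes:
    """Slopes of the two nullclines in the (rE, rI) plane."""

    k_e: float
    k_i: float


@dataclass
class StdRegimePoint:
    """ISN/paradoxical verdict of a depressed ensemble at (JEE, x, rE).

    ``isn`` evaluates the closed-form inhibition-stabilization condition
    ``x > min(x1, x2)`` with ``x1 = 1/(JEE*alphaE*rE^((alphaE-1)/alphaE))``
    (the frozen-x excitatory subnetwork threshold) and ``x2`` its
    trace-based counterpart; ``isn_index`` is the leading eigenvalue of the
    frozen-inhibition (rE, x) block, the quantity tracked along
    trajectories. ``paradoxical`` requires ``x > x1`` plus the
    nullcline-slope ordering, hence the paradoxical region is always
    contained in the ISN region.
    """

    jee: float
    x: float
    r_e: float
    isn: bool
    paradoxical: bool
    isn_index: float
    x_paradox_threshold: float
    slope_condition: bool


def paradox_threshold_std(
    weights: EnsembleWeights, gain: GainParams, r_e: float
) -> float:
    """x above which the excitatory-nullcline slope is positive:
    ``x > 1 / (JEE * alphaE * rE**((alphaE-1)/alphaE))``."""
    phi_e = gain_slope(r_e, gain.alpha_e)
    if weights.jee * phi_e == 0:
        return np.inf
    return 1.0 / (weights.jee * phi_e)


def _slope_condition_std(
    weights: EnsembleWeights,
    params: RateParams,
    gain: GainParams,
    mech: Mechanism,
    r_e: float,
    r_i: float,
) -> bool:
    """Inhibitory-nullcline slope exceeds the excitatory one (with x = x*(rE)).

    Written out exactly as the stability-of-determinant condition of the
    depressed 3D system; holds automatically at stable fixed points.
    """
    phi_e = gain_slope(r_e, gain.alpha_e)
    phi_i = gain_slope(r_i, gain.alpha_i)
    beta = 1.0 / mech.tau_x + mech.u_d * r_e
    denom = 1.0 + mech.tau_x * mech.u_d * r_e
    lhs = weights.jei * phi_e * weights.jie * phi_i * beta
    rhs = (1.0 + weights.jii * phi_i) * (
        -weights.jee * mech.u_d * r_e / denom * phi_e
        + weights.jee / denom * phi_e * beta
        - beta
    )
    return lhs > rhs


def isn_paradox_analysis_std(
    weights: EnsembleWeights,
    params: RateParams,
    gain: GainParams,
    mech: Mechanism,
    r_e: float,
    x: float,
) -> tuple[StdRegimePoint, NullclineSlopes]:
    """ISN and paradoxical-effect analysis of a depressed ensemble.

    ``isn`` evaluates the closed-form stabilization condition (see
    :class:`StdRegimePoint`); ``paradoxical`` requires the depression
    variable to exceed ``1/(JEE*alphaE*rE^((alphaE-1)/alphaE))`` (positive
    frozen-x excitatory-nullcline slope) together with the slope-ordering
    condition, which is evaluated explicitly rather than assumed.
    Paradoxical implies ISN, not conversely.
    """
    if r_e <= 0:
        raise ParameterError("analysis requires rE > 0")
    if not 0 < x <= 1:
        raise ParameterError("STD variable x must lie in (0, 1]")
    r_i = inhibitory_steady_rate(weights, gain, params.g_i, r_e)
    idx = isn_index_std(weights, params, gain, mech, r_e, x)
    thr = paradox_threshold_std(weights, gain, r_e)
    x2 = thr * (
        (mech.tau_x + params.tau_e + params.tau_e * mech.tau_x * mech.u_d * r_e)
        / mech.tau_x
    )
    isn = x > min(thr, x2)
    slope_ok = _slope_condition_std(weights, params, gain, mech, r_e, r_i)
    paradox = (x > thr) and slope_ok

    # nullcline slopes in the (rE, rI) plane, with x at its steady state
    denom = 1.0 + mech.tau_x * mech.u_d * r_e
    k_e = (
        -weights.jee / denom**2 * mech.tau_x * mech.u_d * r_e
        + weights.jee / denom
        - (1.0 / gain.alpha_e) * r_e ** (1.0 / gain.alpha_e - 1.0)
    ) / weights.jei
    if r_i > 0:
        k_i = (weights.jie) / (
            weights.jii + (1.0 / gain.alpha_i) * r_i ** ((1.0 - gain.alpha_i) / gain.alpha_i)
        )
    else:
        k_i = weights.jie / weights.jii if weights.jii > 0 else np.inf
    point = StdRegimePoint(
        jee=weights.jee,
        x=x,
        r_e=r_e,
        isn=isn,
        paradoxical=paradox,
        isn_index=idx,
        x_paradox_threshold=thr,
        slope_condition=slope_ok,
    )
    return point, NullclineSlopes(k_e=k_e, k_i=k_i)


def std_regime_map(
    weights_template: EnsembleWeights,
    params: RateParams,
    gain: GainParams,
    mech: Mechanism,
    jee_grid: np.ndarray,
    x_grid: np.ndarray,
    r_e: float = 1.0,
):
    """(JEE, x) grid of ISN / paradoxical labels at a reference rate.

    Returns ``(isn, paradoxical)`` boolean arrays of shape
    ``(len(x_grid), len(jee_grid))``. The reference rate defaults to 1 Hz.
    """
    isn = np.zeros((len(x_grid), len(jee_grid)), dtype=bool)
    par = np.zeros_like(isn)
    for j, jee in enumerate(jee_grid):
        w = EnsembleWeights(
            jee=float(jee),
            jei=weights_template.jei,
            jie=weights_template.jie,
            jii=weights_template.jii,
        )
        for i, x in enumerate(x_grid):
            pt, _ = isn_paradox_analysis_std(w, params, gain, mech, r_e, float(x))
            isn[i, j] = pt.isn
            par[i, j] = pt.paradoxical
    return isn, par


def isn_trajectory_index(
    trajectory: RateTrajectory,
    weights: EnsembleWeights,
    params: RateParams,
    gain: GainParams,
    mech: Mechanism,
) -> np.ndarray:
    """ISN index evaluated along an STD trajectory (rE(t), x(t))."""
    if mech.variant != "std" or trajectory.mechanism.variant != "std":
        raise ParameterError("requires an STD trajectory")
    out = np.empty(len(trajectory.t))
    for k, (r_e, x) in enumerate(zip(trajectory.r_e, trajectory.aux)):
        out[k] = isn_index_std(weights, params, gain, mech, float(r_e), float(x))
    return out
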