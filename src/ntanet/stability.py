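"""Analytic stability machinery for the 2D supralinear E/I ensemble.

Provides the Jacobian of the two-population rate system, the classical
determinant/trace stability conditions, the ISN index (leading eigenvalue
of the isolated E-E subnetwork), and the one-dimensional characteristic
function F(z) whose zero crossings are the fixed points of the full
system. The curvature of F at large z is controlled by the sign of
det(J) = -JEE*JII + JIE*JEI: with det(J) < 0 the function bends upwards,
so increasing the excitatory drive gE eventually removes all zero
crossings and the ensemble enters runaway dynamics. The drive at which
the last fixed point disappears is the critical input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .params import EnsembleWeights, GainParams, ParameterError, RateParams

__all__ = [
    "gain_slope",
    "JacobianMatrix",
    "jacobian_2d",
    "stability_conditions_2d",
    "isn_index_2d",
    "CharacteristicCurve",
    "characteristic_function",
    "FixedPoint",
    "FixedPointReport",
    "find_fixed_points",
    "critical_input",
]


def gain_slope(rate: float, alpha: float) -> float:
    """Derivative factor ``alpha * r**((alpha-1)/alpha)`` of the power law.

    This is d([z]_+^alpha)/dz expressed through the rate ``r = [z]_+^alpha``
    at a steady state. At ``r = 0`` the one-sided derivative is 0 for
    supralinear gains (alpha > 1) and ``alpha`` for alpha <= 1 (convention:
    rectification corners use the right-hand derivative of the smooth
    branch).
    """
    r = float(rate)
    if r < 0:
        raise ParameterError("rates must be non-negative")
    if r == 0.0:
        return 0.0 if alpha > 1 else float(alpha)
    return float(alpha * r ** ((alpha - 1.0) / alpha))


@dataclass
class JacobianMatrix:
    """A Jacobian with its eigenvalues and the state it was evaluated at."""

    entries: np.ndarray
    eigenvalues: np.ndarray
    context: Tuple[float, ...]

    @property
    def stable(self) -> bool:
        return bool(np.all(self.eigenvalues.real < 0))


def jacobian_2d(
    weights: EnsembleWeights,
    params: RateParams,
    gain: GainParams,
    r_e: float,
    r_i: float,
) -> JacobianMatrix:
    """Jacobian of the two-population rate system at ``(r_e, r_i)``."""
    if r_e < 0 or r_i < 0:
        raise ParameterError("rates must be non-negative")
    phi_e = gain_slope(r_e, gain.alpha_e)
    phi_i = gain_slope(r_i, gain.alpha_i)
    m = np.array(
        [
            [
                (weights.jee * phi_e - 1.0) / params.tau_e,
                -weights.jei * phi_e / params.tau_e,
            ],
            [
                weights.jie * phi_i / params.tau_i,
                -(1.0 + weights.jii * phi_i) / params.tau_i,
            ],
        ]
    )
    return JacobianMatrix(entries=m, eigenvalues=np.linalg.eigvals(m), context=(r_e, r_i))


def stability_conditions_2d(
    weights: EnsembleWeights,
    params: RateParams,
    gain: GainParams,
    r_e: float,
    r_i: float,
) -> dict:
    """Determinant/trace stability conditions of the 2D Jacobian.

    Returns the two classical conditions (eigenvalue product positive and
    eigenvalue sum negative) evaluated at the given rates, plus their
    conjunction. For supralinear gains the verdict is rate- (hence input-)
    dependent; for linear gains it is not.
    """
    jac = jacobian_2d(weights, params, gain, r_e, r_i)
    det_m = float(np.linalg.det(jac.entries))
    tr_m = float(np.trace(jac.entries))
    return {
        "detM_positive": det_m > 0,
        "trM_negative": tr_m < 0,
        "stable": det_m > 0 and tr_m < 0,
    }


def isn_index_2d(
    weights: EnsembleWeights, params: RateParams, gain: GainParams, r_e: float
) -> float:
    """Leading eigenvalue of the isolated E-E subnetwork.

    ``tau_E^-1 (JEE * alphaE * rE**((alphaE-1)/alphaE) - 1)``; positive
    values mean the excitatory subnetwork alone is unstable, i.e. the
    ensemble is inhibition-stabilized (ISN).
    """
    if r_e < 0:
        raise ParameterError("rate must be non-negative")
    return (weights.jee * gain_slope(r_e, gain.alpha_e) - 1.0) / params.tau_e


@dataclass
class CharacteristicCurve:
    """Values of the characteristic function F on a grid of input currents."""

    z: np.ndarray
    f: np.ndarray
    params_hash: str = ""


def _char_fun(
    z,
    weights: EnsembleWeights,
    gain: GainParams,
    g_e: float,
    g_i: float,
    jee_eff: Optional[float] = None,
    det_j: Optional[float] = None,
):
    """Evaluate F(z); jee_eff/det_j allow the depressed-weight variant."""
    if weights.jei == 0:
        raise ParameterError("the characteristic function requires JEI > 0")
    jee = weights.jee if jee_eff is None else jee_eff
    det = weights.det if det_j is None else det_j
    z = np.asarray(z, dtype=float)
    r_e = np.maximum(z, 0.0) ** gain.alpha_e
    inner = (
        det / weights.jei * r_e
        + weights.jii / weights.jei * z
        - weights.jii / weights.jei * g_e
        + g_i
    )
    r_i = np.maximum(inner, 0.0) ** gain.alpha_i
    return jee * r_e - weights.jei * r_i - z + g_e


def characteristic_function(
    weights: EnsembleWeights,
    params: RateParams,
    gain: GainParams,
    g_e: float,
    g_i: float,
    z_grid: np.ndarray,
) -> CharacteristicCurve:
    """Characteristic function of the 2D ensemble on ``z_grid``.

    ``z`` is the total current into the excitatory population,
    ``z = JEE rE - JEI rI + gE``; zeros of F(z) are fixed points.
    """
    z = np.asarray(z_grid, dtype=float)
    if z.ndim != 1 or np.any(np.diff(z) <= 0):
        raise ParameterError("z_grid must be strictly increasing")
    f = _char_fun(z, weights, gain, g_e, g_i)
    if not np.all(np.isfinite(f)):
        raise ParameterError("characteristic function not finite on grid")
    return CharacteristicCurve(z=z, f=f)


@dataclass
class FixedPoint:
    r_e: float
    r_i: float
    z: float
    stability: str
    eigenvalues: np.ndarray
    dF_dz: float


@dataclass
class FixedPointReport:
    points: List[FixedPoint] = field(default_factory=list)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def stable_points(self) -> List[FixedPoint]:
        return [p for p in self.points if p.stability == "stable"]


def _classify(eigs: np.ndarray) -> str:
    re = eigs.real
    if np.all(re < 0):
        return "stable"
    if np.all(re > 0):
        return "unstable-spiral" if np.any(np.abs(eigs.imag) > 0) else "unstable-node"
    if np.any(re > 0) and np.any(re < 0):
        return "saddle"
    return "marginal"


def _scan_grid(
    weights: EnsembleWeights, g_e: float, g_i: float, z_max: float, n: int = 4000
) -> np.ndarray:
    # dense low end (where the low-activity fixed points live) plus a
    # geometric tail out to z_max; includes the rectified (z < 0) branch.
    if weights.jii > 0:
        z_lo = min(0.0, g_e, g_e - weights.jei * g_i / weights.jii) - 5.0
    else:
        z_lo = min(0.0, g_e) - 5.0
    lin = np.linspace(z_lo, min(2.0, z_max), n // 2)
    if z_max > 2.0:
        geo = np.geomspace(2.0, z_max, n - n // 2)
        return np.unique(np.concatenate([lin, geo]))
    return np.unique(lin)


def find_fixed_points(
    weights: EnsembleWeights,
    params: RateParams,
    gain: GainParams,
    g_e: Optional[float] = None,
    g_i: Optional[float] = None,
    z_max: Optional[float] = None,
    jee_eff: Optional[float] = None,
    det_j: Optional[float] = None,
) -> FixedPointReport:
    """Locate and classify all fixed points of the 2D ensemble.

    Zeros of the characteristic function are bracketed on a dense scan
    grid and refined by bisection; each root z* maps back to the rates via
    ``rE = [z*]_+^alphaE`` and ``rI = (JEE rE + gE - z*)/JEI`` (the
    substitution that defines F), and is classified by the eigenvalues of
    the full 2D Jacobian. A positive slope dF/dz at the root marks a
    saddle. ``z_max`` defaults to adaptive doubling until the tail
    behavior of F is settled.

    An empty report with F > 0 everywhere is the runaway regime (no fixed
    point exists for this drive).
    """
    g_e = params.g_e if g_e is None else g_e
    g_i = params.g_i if g_i is None else g_i

    def f(z):
        return _char_fun(z, weights, gain, g_e, g_i, jee_eff=jee_eff, det_j=det_j)

    det = weights.det if det_j is None else det_j
    if z_max is None:
        z_max = 10.0
        for _ in range(40):
            zg = _scan_grid(weights, g_e, g_i, z_max)
            fg = f(zg)
            tail_up = fg[-1] > 0 and fg[-1] > fg[-2]
            tail_down = fg[-1] < 0 and fg[-1] < fg[-2]
            if (det < 0 and tail_up) or (det >= 0 and (tail_down or tail_up)):
                break
            z_max *= 2.0
    zg = _scan_grid(weights, g_e, g_i, z_max)
    fg = f(zg)

    roots: List[float] = []
    for i in np.flatnonzero(np.sign(fg[:-1]) * np.sign(fg[1:]) < 0):
        roots.append(brentq(f, zg[i], zg[i + 1], xtol=1e-12, rtol=8.9e-16))
    for i in np.flatnonzero(fg == 0.0):
        roots.append(zg[i])
    roots = sorted(roots)
    # merge near-duplicates (grid-boundary artifacts / tangencies)
    merged: List[float] = []
    for r in roots:
        if not merged or abs(r - merged[-1]) > 1e-9 * max(1.0, abs(r)):
            merged.append(r)

    report = FixedPointReport()
    eps = 1e-7
    for z_star in merged:
        r_e = max(z_star, 0.0) ** gain.alpha_e
        r_i = (
            ((weights.jee if jee_eff is None else jee_eff) * r_e + g_e - z_star)
            / weights.jei
        )
        if r_i < -1e-10:
            continue
        r_i = max(r_i, 0.0)
        # residual of the inhibitory steady state must vanish at a true root
        resid = abs(
            r_i
            - max(weights.jie * r_e - weights.jii * r_i + g_i, 0.0) ** gain.alpha_i
        )
        if resid > 1e-8 * max(1.0, r_i):
            raise ArithmeticError(
                f"fixed-point back-mapping failed at z={z_star:.6g}: "
                f"inhibitory residual {resid:.3g}"
            )
        if jee_eff is None:
            jac = jacobian_2d(weights, params, gain, r_e, r_i)
        else:
            eff = EnsembleWeights(jee_eff, weights.jei, weights.jie, weights.jii)
            jac = jacobian_2d(eff, params, gain, r_e, r_i)
        slope = float((f(z_star + eps) - f(z_star - eps)) / (2 * eps))
        report.points.append(
            FixedPoint(
                r_e=r_e,
                r_i=r_i,
                z=z_star,
                stability=_classify(jac.eigenvalues),
                eigenvalues=jac.eigenvalues,
                dF_dz=slope,
            )
        )
    return report


def critical_input(
    weights: EnsembleWeights,
    params: RateParams,
    gain: GainParams,
    g_i: Optional[float] = None,
    bracket: Tuple[float, float] = (0.0, 20.0),
    tol: float = 1e-6,
) -> Optional[float]:
    """Critical excitatory drive at which all fixed points disappear.

    Only ensembles with det(J) < 0 have such a finite positive-feedback
    threshold; for det(J) >= 0 the function returns ``None``. Because F
    shifts upwards monotonically with gE, the transition from >= 1 to 0
    zero crossings is unique and is located by bisection to ``tol``.
    """
    if weights.det >= 0:
        return None
    g_i = params.g_i if g_i is None else g_i

    def n_points(g_e: float) -> int:
        return find_fixed_points(weights, params, gain, g_e=g_e, g_i=g_i).n_points

    lo, hi = bracket
    if n_points(lo) == 0:
        raise ParameterError("bracket low end already has no fixed points")
    for _ in range(40):
        if n_points(hi) == 0:
            break
        hi *= 2.0
    else:
        raise ParameterError("could not bracket the critical input")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if n_points(mid) == 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
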