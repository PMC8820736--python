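"""Spike-frequency adaptation analysis of the supralinear ensemble.

With SFA the ensemble is a 3D system (rE, rI, a). Its characteristic
polynomial is the cubic

    lambda^3 - tr(M) lambda^2 + (A11 + A22 + A33) lambda - det(M) = 0

where the A_kk are the diagonal cofactors of the 3x3 Jacobian. Two facts
shape the phenomenology: for weak adaptation strength b the determinant
condition fails at high excitatory rates, so adaptation cannot terminate
runaway excitation at a stable fixed point; for strong b the stimulated
fixed point loses stability through a supercritical Hopf bifurcation
(tr * cofactor_sum = det at the crossing) and the ensemble oscillates on
a stable limit cycle instead of settling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import fsolve
from scipy.signal import find_peaks

from .params import (
    EnsembleWeights,
    GainParams,
    Mechanism,
    ParameterError,
    RateParams,
    StimulusProtocol,
)
from .rate import simulate_ensemble
from .stability import gain_slope

__all__ = [
    "sfa_jacobian",
    "SfaPolynomial",
    "sfa_characteristic_poly",
    "SfaClassification",
    "classify_sfa_dynamics",
    "sfa_fixed_point",
]


def sfa_jacobian(
    weights: EnsembleWeights,
    params: RateParams,
    gain: GainParams,
    b: float,
    tau_a: float,
    r_e: float,
    r_i: float,
) -> np.ndarray:
    """3x3 Jacobian of the (rE, rI, a) system at a fixed point."""
    phi_e = gain_slope(r_e, gain.alpha_e)
    phi_i = gain_slope(r_i, gain.alpha_i)
    te, ti = params.tau_e, params.tau_i
    return np.array(
        [
            [(weights.jee * phi_e - 1.0) / te, -weights.jei * phi_e / te, -1.0 / te],
            [weights.jie * phi_i / ti, -(1.0 + weights.jii * phi_i) / ti, 0.0],
            [b / tau_a, 0.0, -1.0 / tau_a],
        ]
    )


@dataclass
class SfaPolynomial:
    """Cubic characteristic polynomial of the SFA Jacobian.

    ``lambda^3 - tr*lambda^2 + cofactor_sum*lambda - det = 0``.
    """

    tr: float
    cofactor_sum: float
    det: float
    context: tuple

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([1.0, -self.tr, self.cofactor_sum, -self.det])

    def roots(self) -> np.ndarray:
        return np.roots(self.coefficients)

    @property
    def hopf_margin(self) -> float:
        """tr * cofactor_sum - det; zero at the Hopf crossing.

        Negative at a stable fixed point (Routh-Hurwitz), positive once
        the complex pair has crossed into the right half-plane.
        """
        return self.tr * self.cofactor_sum - self.det

    def discriminant(self) -> float:
        """Cubic discriminant; negative means one real root + complex pair."""
        p, q, r = -self.tr, self.cofactor_sum, -self.det
        # discriminant of x^3 + p x^2 + q x + r
        return (
            18.0 * p * q * r - 4.0 * p**3 * r + p**2 * q**2 - 4.0 * q**3 - 27.0 * r**2
        )


def sfa_characteristic_poly(
    weights: EnsembleWeights,
    params: RateParams,
    gain: GainParams,
    b: float,
    tau_a: float,
    r_e: float,
    r_i: float,
) -> SfaPolynomial:
    """Coefficients of the SFA cubic, written out term by term."""
    if b < 0 or tau_a <= 0:
        raise ParameterError("require b >= 0 and tau_a > 0")
    phi_e = gain_slope(r_e, gain.alpha_e)
    phi_i = gain_slope(r_i, gain.alpha_i)
    te, ti, ta = params.tau_e, params.tau_i, tau_a
    ge = (weights.jee * phi_e - 1.0) / te  # E self-coupling
    gi = (1.0 + weights.jii * phi_i) / ti  # I self-coupling (magnitude)
    tr = ge - gi - 1.0 / ta
    a11 = gi / ta
    a22 = -ge / ta + b / (te * ta)
    a33 = -ge * gi + (weights.jei * phi_e / te) * (weights.jie * phi_i / ti)
    det = ge * gi * (-1.0 / ta) * (-1.0) - (
        weights.jei * phi_e / te
    ) * (weights.jie * phi_i / ti) / ta - (b / (te * ta)) * gi
    # det written explicitly: ge*gi/ta - jei*phi_e*jie*phi_i/(te*ti*ta) - b*gi/(te*ta)
    return SfaPolynomial(
        tr=tr,
        cofactor_sum=a11 + a22 + a33,
        det=det,
        context=(r_e, r_i, b, tau_a),
    )


def sfa_fixed_point(
    weights: EnsembleWeights,
    params: RateParams,
    gain: GainParams,
    mech: Mechanism,
    g_e: Optional[float] = None,
    guess: tuple = (1.0, 1.0),
) -> Optional[tuple]:
    """Solve the 3D steady state (rE, rI, a) with a = b*rE eliminated.

    Returns ``(r_e, r_i, a)`` or ``None`` if the solver fails to converge
    to a non-negative solution.
    """
    g_e = params.g_e if g_e is None else g_e
    b = mech.b

    def eqs(s):
        r_e, r_i = s
        z_e = weights.jee * r_e - weights.jei * r_i + g_e
        z_i = weights.jie * r_e - weights.jii * r_i + params.g_i
        return [
            -r_e + max(z_e, 0.0) ** gain.alpha_e - b * r_e,
            -r_i + max(z_i, 0.0) ** gain.alpha_i,
        ]

    sol, info, ier, _ = fsolve(eqs, guess, full_output=True)
    if ier != 1 or min(sol) < -1e-9:
        return None
    r_e, r_i = float(max(sol[0], 0.0)), float(max(sol[1], 0.0))
    return r_e, r_i, b * r_e


def sfa_hopf_margin_curve(
    weights: EnsembleWeights,
    params: RateParams,
    gain: GainParams,
    mech: Mechanism,
    g_e_grid: np.ndarray,
) -> np.ndarray:
    """Hopf margin tr*cofactor_sum - det along a drive grid.

    Evaluated at the (continued) stimulated fixed point for each gE; NaN
    where no fixed point is found. A sign change from negative to positive
    marks the Hopf crossing of the complex eigenvalue pair.
    """
    margins = np.full(len(g_e_grid), np.nan)
    guess = (0.05, 1.0)
    for i, g_e in enumerate(np.asarray(g_e_grid, dtype=float)):
        rp = RateParams(
            tau_e=params.tau_e,
            tau_i=params.tau_i,
            g_e=g_e,
            g_i=params.g_i,
            rate_cap=params.rate_cap,
        )
        fp = sfa_fixed_point(weights, rp, gain, mech, guess=guess)
        if fp is None:
            continue
        guess = (max(fp[0], 1e-3), max(fp[1], 1e-3))
        poly = sfa_characteristic_poly(
            weights, params, gain, mech.b, mech.tau_a, fp[0], fp[1]
        )
        margins[i] = poly.hopf_margin
    return margins


@dataclass
class SfaClassification:
    """Outcome of a stimulated SFA simulation."""

    label: str  # 'runaway' | 'limit_cycle' | 'stable'
    oscillation_frequency: Optional[float]
    amplitude_ratio: float
    hopf_margin: Optional[float]
    trajectory: object


def classify_sfa_dynamics(
    weights: EnsembleWeights,
    params: RateParams,
    gain: GainParams,
    mech: Mechanism,
    protocol: StimulusProtocol,
    duration: Optional[float] = None,
    dt: float = 1e-4,
    settle: float = 1.0,
    amplitude_threshold: float = 0.05,
) -> SfaClassification:
    """Classify the during-stimulus dynamics as runaway, limit cycle or stable.

    The trajectory is simulated with the shared integrator; after a
    settling window inside the stimulation episode, sustained oscillation
    is detected by peak counting (at least three full periods and a
    peak-to-trough excursion above ``amplitude_threshold`` of the mean).
    When a limit cycle is found, the Hopf margin tr*cofactor_sum - det of
    the cubic at the (unstable) stimulated fixed point is reported; it is
    positive past the bifurcation.
    """
    if mech.variant == "none":
        mech = Mechanism.sfa(b=0.0, tau_a=1.0)
    if mech.variant != "sfa":
        raise ParameterError("classification requires an SFA (or none) mechanism")
    if not protocol.episodes:
        raise ParameterError("protocol must include a stimulation episode")
    ep = protocol.episodes[0]
    if ep.t_end - ep.t_start <= settle:
        raise ParameterError("stimulus window shorter than the settling window")
    duration = duration or (ep.t_end + 1.0)
    traj = simulate_ensemble(
        weights, params, gain, mech, protocol, duration=duration, dt=dt
    )
    if traj.diverged and (
        traj.divergence_time is None or traj.divergence_time <= ep.t_end
    ):
        return SfaClassification("runaway", None, np.inf, None, traj)

    sel = (traj.t >= ep.t_start + settle) & (traj.t < ep.t_end)
    seg = traj.r_e[sel]
    t_seg = traj.t[sel]
    mean = float(seg.mean())
    amp = float(seg.max() - seg.min())
    ratio = amp / mean if mean > 0 else 0.0
    label = "stable"
    freq = None
    hopf = None
    if ratio > amplitude_threshold:
        # analyze only the last half of the window: transients must be gone
        half = seg[len(seg) // 2 :]
        t_half = t_seg[len(seg) // 2 :]
        peaks, _ = find_peaks(half, prominence=amplitude_threshold * mean)
        if len(peaks) >= 3:
            label = "limit_cycle"
            freq = float(1.0 / np.mean(np.diff(t_half[peaks])))
    if label == "limit_cycle":
        fp = sfa_fixed_point(
            weights,
            params,
            gain,
            mech,
            g_e=params.g_e + float(np.atleast_1d(ep.dg_e)[0]),
            guess=(mean, float(traj.r_i[sel].mean())),
        )
        if fp is not None:
            poly = sfa_characteristic_poly(
                weights, params, gain, mech.b, mech.tau_a, fp[0], fp[1]
            )
            hopf = poly.hopf_margin
    return SfaClassification(label, freq, ratio, hopf, traj)
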