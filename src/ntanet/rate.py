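"""Fixed-step Euler integration of supralinear E/I rate networks.

The generic integrator handles an arbitrary number of excitatory and
inhibitory populations with one of four ensemble mechanisms (none, SFA,
E-to-E STD, E-to-I STF). The single-ensemble convenience wrapper
:func:`simulate_ensemble` is the workhorse of the bifurcation protocols.

Dynamics (single ensemble, mechanism-dependent terms in brackets)::

    tau_E drE/dt = -rE + [ (x) JEE rE - JEI rI + gE ]_+^alphaE  (- a)
    tau_I drI/dt = -rI + [ (u) JIE rE - JII rI + gI ]_+^alphaI

with SFA      tau_a da/dt = -a + b rE
with STD      dx/dt = (1 - x)/tau_x - Ud x rE
with STF      du/dt = (1 - u)/tau_u + Uf (u_max - u) rE

The supralinear gain has no intrinsic saturation: for ensembles with
det(J) < 0 a sufficiently strong drive genuinely produces finite-time
runaway. Integration therefore stops cleanly once the excitatory rate
exceeds ``divergence_bound`` and the trajectory is flagged as diverged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .params import (
    EnsembleWeights,
    Episode,
    FreezeInhibition,
    GainParams,
    InactivateInhibition,
    InjectToI,
    Mechanism,
    ParameterError,
    PerturbRate,
    RateParams,
    StimulusProtocol,
)

__all__ = [
    "powerlaw_gain",
    "RateTrajectory",
    "NetworkTrajectory",
    "simulate_ensemble",
    "simulate_network",
    "DEFAULT_DT",
    "DIVERGENCE_BOUND",
]

#: Default Euler step (seconds), i.e. 0.1 ms.
DEFAULT_DT = 1e-4

#: Excitatory rate (Hz) above which the trajectory is declared diverged.
DIVERGENCE_BOUND = 1e6


def powerlaw_gain(z, alpha: float, cap: Optional[float] = None):
    """Rectified power-law input-output function ``[z]_+ ** alpha``.

    Parameters
    ----------
    z : array_like
        Total input current (dimensionless drive).
    alpha : float
        Exponent; must be positive.
    cap : float, optional
        If given, the output is clipped at ``cap`` (a hard firing-rate
        bound applied after the power law).
    """
    if alpha <= 0:
        raise ParameterError("gain exponent alpha must be positive")
    out = np.maximum(z, 0.0) ** alpha
    if cap is not None:
        out = np.minimum(out, cap)
    return out


@dataclass
class NetworkTrajectory:
    """Time-resolved rates of a multi-population network.

    ``r_e`` has shape ``(T, nE)``, ``r_i`` shape ``(T, nI)``; ``aux`` holds
    the per-excitatory-population mechanism variable (a, x or u) or is
    ``None`` for the plain model. When the run diverges the arrays are
    truncated at the divergence step.
    """

    t: np.ndarray
    r_e: np.ndarray
    r_i: np.ndarray
    aux: Optional[np.ndarray]
    diverged: bool
    divergence_time: Optional[float]
    mechanism: Mechanism
    dt: float


@dataclass
class RateTrajectory:
    """Single-ensemble trajectory with 1-D series (see NetworkTrajectory)."""

    t: np.ndarray
    r_e: np.ndarray
    r_i: np.ndarray
    aux: Optional[np.ndarray]
    diverged: bool
    divergence_time: Optional[float]
    mechanism: Mechanism
    dt: float

    def window(self, t0: float, t1: float) -> "RateTrajectory":
        """Restrict the trajectory to ``t0 <= t < t1``."""
        m = (self.t >= t0) & (self.t < t1)
        return RateTrajectory(
            self.t[m],
            self.r_e[m],
            self.r_i[m],
            None if self.aux is None else self.aux[m],
            self.diverged,
            self.divergence_time,
            self.mechanism,
            self.dt,
        )


def _as_vec(value, n: int) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(n, float(arr))
    if arr.shape != (n,):
        raise ParameterError(f"expected scalar or length-{n} vector, got {arr.shape}")
    return arr.copy()


def simulate_network(
    w_ee: np.ndarray,
    w_ei: np.ndarray,
    w_ie: np.ndarray,
    w_ii: np.ndarray,
    g_e,
    g_i,
    gain: GainParams,
    tau_e: float,
    tau_i: float,
    mechanism: Mechanism,
    protocol: Optional[StimulusProtocol] = None,
    duration: float = 6.0,
    dt: float = DEFAULT_DT,
    init: Optional[Tuple] = None,
    rate_cap: Optional[float] = None,
    divergence_bound: float = DIVERGENCE_BOUND,
) -> NetworkTrajectory:
    """Euler-integrate a block E/I rate network.

    Parameters
    ----------
    w_ee, w_ei, w_ie, w_ii : ndarray
        Non-negative weight-magnitude blocks; ``w_xy[i, j]`` is the
        magnitude from population ``j`` (of type Y) onto population ``i``
        (of type X). Inhibitory blocks enter with a minus sign.
    g_e, g_i : scalar or array
        Baseline external drives per population.
    mechanism : Mechanism
        Shared mechanism; STD depresses presynaptic E columns of ``w_ee``,
        STF facilitates presynaptic E columns of ``w_ie``, SFA subtracts an
        adaptation current from each excitatory population.
    protocol : StimulusProtocol, optional
        Additive drive episodes and probes.
    init : tuple, optional
        ``(r_e0, r_i0, aux0)``; defaults to rates 0 and the mechanism rest
        value.
    """
    if dt <= 0 or duration < dt:
        raise ParameterError("require dt > 0 and duration >= dt")
    w_ee = np.atleast_2d(np.asarray(w_ee, dtype=float))
    w_ei = np.atleast_2d(np.asarray(w_ei, dtype=float))
    w_ie = np.atleast_2d(np.asarray(w_ie, dtype=float))
    w_ii = np.atleast_2d(np.asarray(w_ii, dtype=float))
    n_e, n_i = w_ee.shape[0], w_ii.shape[0]
    if min(w.min() for w in (w_ee, w_ei, w_ie, w_ii)) < 0:
        raise ParameterError("weight magnitudes must be non-negative")
    protocol = protocol or StimulusProtocol()

    n_steps = int(round(duration / dt))
    t = np.arange(n_steps + 1) * dt

    # Resolve external drive per step (episodes are additive).
    g_e_t = np.tile(_as_vec(g_e, n_e), (n_steps + 1, 1))
    g_i_t = np.tile(_as_vec(g_i, n_i), (n_steps + 1, 1))
    for ep in protocol.episodes:
        k0, k1 = int(round(ep.t_start / dt)), int(round(ep.t_end / dt))
        g_e_t[k0:k1] += _as_vec(ep.dg_e, n_e)
        g_i_t[k0:k1] += _as_vec(ep.dg_i, n_i)

    inactivate = np.zeros(n_steps + 1, dtype=bool)
    freeze = np.zeros(n_steps + 1, dtype=bool)
    perturbs: dict[int, float] = {}
    for probe in protocol.probes:
        if isinstance(probe, InactivateInhibition):
            inactivate[int(round(probe.t0 / dt)) : int(round(probe.t1 / dt))] = True
        elif isinstance(probe, FreezeInhibition):
            freeze[int(round(probe.t0 / dt)) : int(round(probe.t1 / dt))] = True
        elif isinstance(probe, InjectToI):
            k0, k1 = int(round(probe.t0 / dt)), int(round(probe.t1 / dt))
            g_i_t[k0:k1] += probe.magnitude
        elif isinstance(probe, PerturbRate):
            perturbs[int(round(probe.t / dt))] = probe.magnitude
        else:  # pragma: no cover - guarded by typing
            raise ParameterError(f"unknown probe {probe!r}")

    # State.
    if init is None:
        r_e = np.zeros(n_e)
        r_i = np.zeros(n_i)
        aux = np.full(n_e, mechanism.rest_aux)
    else:
        r_e = _as_vec(init[0], n_e)
        r_i = _as_vec(init[1], n_i)
        aux = _as_vec(
            init[2] if len(init) > 2 and init[2] is not None else mechanism.rest_aux,
            n_e,
        )
    variant = mechanism.variant

    out_e = np.empty((n_steps + 1, n_e))
    out_i = np.empty((n_steps + 1, n_i))
    out_aux = None if variant == "none" else np.empty((n_steps + 1, n_e))
    out_e[0], out_i[0] = r_e, r_i
    if out_aux is not None:
        out_aux[0] = aux

    diverged = False
    divergence_time: Optional[float] = None
    frozen_value: Optional[np.ndarray] = None
    alpha_e, alpha_i = gain.alpha_e, gain.alpha_i
    last = n_steps

    with np.errstate(over="ignore", invalid="ignore"):
        for k in range(n_steps):
            if k in perturbs:
                r_e = np.maximum(r_e + perturbs[k], 0.0)
            if inactivate[k]:
                r_i = np.zeros(n_i)
            if freeze[k]:
                if frozen_value is None:
                    frozen_value = r_i.copy()
                r_i = frozen_value
            else:
                frozen_value = None

            if variant == "std":
                z_e = (w_ee * aux) @ r_e - w_ei @ r_i + g_e_t[k]
            else:
                z_e = w_ee @ r_e - w_ei @ r_i + g_e_t[k]
            if variant == "stf":
                z_i = (w_ie * aux) @ r_e - w_ii @ r_i + g_i_t[k]
            else:
                z_i = w_ie @ r_e - w_ii @ r_i + g_i_t[k]

            gain_e = powerlaw_gain(z_e, alpha_e, rate_cap)
            gain_i = powerlaw_gain(z_i, alpha_i, rate_cap)
            if variant == "sfa":
                dr_e = (-r_e + gain_e - aux) / tau_e
            else:
                dr_e = (-r_e + gain_e) / tau_e
            dr_i = (-r_i + gain_i) / tau_i

            if variant == "sfa":
                aux = aux + dt * ((-aux + mechanism.b * r_e) / mechanism.tau_a)
            elif variant == "std":
                aux = aux + dt * ((1.0 - aux) / mechanism.tau_x - mechanism.u_d * aux * r_e)
                aux = np.clip(aux, 1e-12, 1.0)
            elif variant == "stf":
                aux = aux + dt * (
                    (1.0 - aux) / mechanism.tau_u
                    + mechanism.u_f * (mechanism.u_max - aux) * r_e
                )
                aux = np.clip(aux, 1.0, mechanism.u_max)

            r_e = np.maximum(r_e + dt * dr_e, 0.0)
            if not (inactivate[k] or freeze[k]):
                r_i = np.maximum(r_i + dt * dr_i, 0.0)

            bad = not (np.all(np.isfinite(r_e)) and np.all(np.isfinite(r_i)))
            if bad or r_e.max() > divergence_bound or r_i.max() > divergence_bound:
                diverged = True
                divergence_time = t[k + 1]
                last = k
                break
            out_e[k + 1], out_i[k + 1] = r_e, r_i
            if out_aux is not None:
                out_aux[k + 1] = aux


    end = last + 1
    return NetworkTrajectory(
        t=t[:end],
        r_e=out_e[:end],
        r_i=out_i[:end],
        aux=None if out_aux is None else out_aux[:end],
        diverged=diverged,
        divergence_time=divergence_time,
        mechanism=mechanism,
        dt=dt,
    )


def simulate_ensemble(
    weights: EnsembleWeights,
    params: RateParams,
    gain: GainParams,
    mechanism: Mechanism = Mechanism.none(),
    protocol: Optional[StimulusProtocol] = None,
    duration: float = 6.0,
    dt: float = DEFAULT_DT,
    init: Optional[Tuple[float, float, Optional[float]]] = None,
    divergence_bound: float = DIVERGENCE_BOUND,
) -> RateTrajectory:
    """Simulate a single E/I ensemble (see module docstring for equations).

    The default initial condition is the quiescent state ``(0, 0)`` with
    the mechanism at rest; protocols conventionally include >= 2 s of
    baseline before the first stimulation episode so the ensemble relaxes
    to its spontaneous fixed point first.
    """
    net = simulate_network(
        w_ee=[[weights.jee]],
        w_ei=[[weights.jei]],
        w_ie=[[weights.jie]],
        w_ii=[[weights.jii]],
        g_e=params.g_e,
        g_i=params.g_i,
        gain=gain,
        tau_e=params.tau_e,
        tau_i=params.tau_i,
        mechanism=mechanism,
        protocol=protocol,
        duration=duration,
        dt=dt,
        init=init,
        rate_cap=params.rate_cap,
        divergence_bound=divergence_bound,
    )
    return RateTrajectory(
        t=net.t,
        r_e=net.r_e[:, 0],
        r_i=net.r_i[:, 0],
        aux=None if net.aux is None else net.aux[:, 0],
        diverged=net.diverged,
        divergence_time=net.divergence_time,
        mechanism=mechanism,
        dt=dt,
    )
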