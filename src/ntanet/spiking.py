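"""Conductance-based leaky integrate-and-fire network with short-term
plasticity and overlapping excitatory ensembles.

Membrane dynamics (potentials in mV, conductances dimensionless)::

    tau_m dU/dt = (Urest - U) + g_exc (Uexc - U) + (g_inh + a) (Uinh - U)

with ``g_exc = xi * g_ampa + (1 - xi) * g_nmda`` (fast AMPA charging a slow
NMDA trace) and a GABA conductance for inhibitory input. A presynaptic
spike increments the postsynaptic AMPA (or GABA) conductance by the
synaptic weight; conductances decay exponentially. Spikes fire at the
threshold, reset to rest and respect an absolute refractory period.

E-to-E synapses can be depressing (resource x per presynaptic neuron,
``dx/dt = (1-x)/tau_x`` between spikes, ``x -> x - Ud*x`` on a spike) and
E-to-I synapses facilitating (``u`` per presynaptic neuron). SFA adds an
inhibitory-reversal adaptation conductance incremented by ``b`` on each of
the neuron's own spikes.

Every neuron receives independent external excitatory drive equivalent to
300 Poisson sources; stimulating an ensemble raises the per-source rate of
its member neurons (0.1 Hz -> 0.5 Hz in the canonical protocol), which
ignites the ensemble through its strong recurrent excitation and produces
the onset transient that depression subsequently quenches.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .params import Mechanism, ParameterError

__all__ = [
    "SpikingNetworkParams",
    "EnsembleLayout",
    "make_overlapping_ensembles",
    "SpikeData",
    "generate_poisson_input",
    "StimulationPeriod",
    "canonical_schedule",
    "simulate_spiking_network",
    "ensemble_activity",
    "activity_differences",
    "pca_variance",
]


@dataclass(frozen=True)
class SpikingNetworkParams:
    """Parameters of the spiking network (times in seconds, potentials mV).

    Defaults follow the published table for the ensemble protocol:
    400 excitatory / 100 inhibitory neurons at 20% random connectivity.
    The spiking threshold and the external synaptic weight are not part of
    the published table; they are exposed here with calibrated defaults
    (-50 mV; external weight giving a low spontaneous baseline).
    """

    n_e: int = 400
    n_i: int = 100
    p_conn: float = 0.2
    u_rest: float = -70.0
    u_exc: float = 0.0
    u_inh: float = -80.0
    u_thr: float = -50.0
    tau_m_exc: float = 0.020
    tau_m_inh: float = 0.010
    tau_ref: float = 0.003
    tau_ampa: float = 0.005
    tau_gaba: float = 0.010
    tau_nmda: float = 0.100
    xi: float = 0.5
    jee: float = 0.19
    jie: float = 0.10
    jei: float = 0.10
    jii: float = 0.06
    jee_p: float = 0.019
    jie_p: float = 0.05
    jei_p: float = 0.04
    jii_p: float = 0.006
    n_ext_sources: int = 300
    ext_rate_baseline: float = 0.1
    ext_rate_stim: float = 0.5
    w_ext: float = 0.8
    mechanism: Mechanism = field(default_factory=Mechanism.std)
    sfa_b: float = 0.0
    sfa_tau_a: float = 0.1

    def __post_init__(self) -> None:
        if not (self.u_inh < self.u_rest < self.u_thr < self.u_exc):
            raise ParameterError("require Uinh < Urest < Uthr < Uexc")
        if not 0 < self.p_conn <= 1:
            raise ParameterError("connection probability must be in (0, 1]")
        if not 0 <= self.xi <= 1:
            raise ParameterError("receptor weighting xi must be in [0, 1]")


@dataclass
class EnsembleLayout:
    """Possibly overlapping ensembles of excitatory neuron ids."""

    members: List[np.ndarray]
    n_e: int

    def __post_init__(self) -> None:
        for m in self.members:
            if len(m) == 0:
                raise ParameterError("ensembles must be non-empty")
            if np.any(m < 0) or np.any(m >= self.n_e):
                raise ParameterError("ensemble membership must index E neurons")

    @property
    def n_ensembles(self) -> int:
        return len(self.members)

    def shares_ensemble(self) -> np.ndarray:
        """Boolean (n_e, n_e) matrix: pre/post pair share >= 1 ensemble."""
        ind = np.zeros((self.n_ensembles, self.n_e), dtype=bool)
        for k, m in enumerate(self.members):
            ind[k, m] = True
        return (ind.T.astype(int) @ ind.astype(int)) > 0


def make_overlapping_ensembles(
    n_e: int,
    n_ensembles: int = 5,
    size: int = 200,
    seed: Optional[int] = None,
) -> EnsembleLayout:
    """Draw ``n_ensembles`` random (overlapping) subsets of the E population."""
    rng = np.random.default_rng(seed)
    members = [
        np.sort(rng.choice(n_e, size=size, replace=False)) for _ in range(n_ensembles)
    ]
    return EnsembleLayout(members=members, n_e=n_e)


@dataclass
class SpikeData:
    """Spike events plus simulation metadata."""

    neuron_ids: np.ndarray
    times: np.ndarray
    n_e: int
    n_i: int
    duration: float
    seed: Optional[int] = None

    @property
    def n_spikes(self) -> int:
        return len(self.times)

    def counts(self) -> np.ndarray:
        return np.bincount(self.neuron_ids, minlength=self.n_e + self.n_i)

    def excitatory(self) -> "SpikeData":
        m = self.neuron_ids < self.n_e
        return SpikeData(
            self.neuron_ids[m], self.times[m], self.n_e, 0, self.duration, self.seed
        )


def generate_poisson_input(
    n_sources: int, rate: float, duration: float, seed: Optional[int] = None
) -> SpikeData:
    """Independent homogeneous Poisson spike trains (events sorted by time)."""
    if rate < 0:
        raise ParameterError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    ids, times = [], []
    for i in range(n_sources):
        n = rng.poisson(rate * duration)
        times.append(np.sort(rng.uniform(0, duration, n)))
        ids.append(np.full(n, i, dtype=int))
    ids = np.concatenate(ids) if ids else np.array([], dtype=int)
    times = np.concatenate(times) if times else np.array([])
    order = np.argsort(times, kind="stable")
    return SpikeData(ids[order], times[order], n_sources, 0, duration, seed)


@dataclass(frozen=True)
class StimulationPeriod:
    """A stimulation window targeting one ensemble (or an explicit subset)."""

    t_start: float
    t_end: float
    ensemble: int
    subset: Optional[np.ndarray] = None  # explicit E neuron ids, overrides ensemble


def canonical_schedule(layout: EnsembleLayout, seed: Optional[int] = None):
    """The canonical 26 s protocol: each ensemble stimulated for 2 s in turn
    (2-4, 6-8, ..., 18-20 s), then 75% of the last ensemble at 22-24 s."""
    periods = [
        StimulationPeriod(2.0 + 4.0 * k, 4.0 + 4.0 * k, k)
        for k in range(layout.n_ensembles)
    ]
    rng = np.random.default_rng(seed)
    last = layout.members[-1]
    subset1 = np.sort(rng.choice(last, size=int(round(0.75 * len(last))), replace=False))
    t0 = 2.0 + 4.0 * layout.n_ensembles
    periods.append(
        StimulationPeriod(t0, t0 + 2.0, layout.n_ensembles - 1, subset=subset1)
    )
    return periods


def simulate_spiking_network(
    params: SpikingNetworkParams,
    layout: EnsembleLayout,
    schedule: Sequence[StimulationPeriod],
    duration: float,
    dt: float = 1e-4,
    seed: Optional[int] = None,
) -> SpikeData:
    """Euler-integrate the spiking network and return its spikes.

    Connectivity is drawn once per seed (Bernoulli ``p_conn``, no self
    connections); a synapse uses the within-ensemble weight when pre and
    post share at least one ensemble, the inter-ensemble weight otherwise.
    Inhibitory neurons belong to no ensemble and connect with the
    within-ensemble weights. The external drive is the aggregated Poisson
    count of ``n_ext_sources`` independent sources per neuron.
    """
    for p in schedule:
        if p.subset is None and not (0 <= p.ensemble < layout.n_ensembles):
            raise ParameterError(f"schedule references unknown ensemble {p.ensemble}")
    rng = np.random.default_rng(seed)
    n_e, n_i, n = params.n_e, params.n_i, params.n_e + params.n_i

    # -- weights ------------------------------------------------------
    shared = layout.shares_ensemble()
    w = np.zeros((n, n))
    w[:n_e, :n_e] = np.where(shared, params.jee, params.jee_p)
    w[n_e:, :n_e] = params.jie  # E -> I: no ensemble identity for I cells
    w[:n_e, n_e:] = params.jei
    w[n_e:, n_e:] = params.jii
    conn = rng.random((n, n)) < params.p_conn
    np.fill_diagonal(conn, False)
    w *= conn

    w_ee = w[:n_e, :n_e]  # post E x pre E (depressing)
    w_ie = w[n_e:, :n_e]  # post I x pre E (facilitating)
    w_exc_gaba = w[:, n_e:]  # post all x pre I

    mech = params.mechanism
    std_on = mech.variant == "std"
    stf_on = mech.variant == "stf"
    sfa_on = params.sfa_b > 0

    # -- external rate per neuron per step ----------------------------
    base = params.n_ext_sources * params.ext_rate_baseline
    stim_total = params.n_ext_sources * params.ext_rate_stim

    n_steps = int(round(duration / dt))
    stim_rate = np.full(n, base)
    stim_masks = []
    for p in schedule:
        ids = p.subset if p.subset is not None else layout.members[p.ensemble]
        mask = np.zeros(n, dtype=bool)
        mask[ids] = True
        stim_masks.append(
            (int(round(p.t_start / dt)), int(round(p.t_end / dt)), mask)
        )

    # -- state --------------------------------------------------------
    u = np.full(n, params.u_rest)
    g_ampa = np.zeros(n)
    g_nmda = np.zeros(n)
    g_gaba = np.zeros(n)
    a_sfa = np.zeros(n_e)
    x = np.ones(n_e)
    u_fac = np.ones(n_e)
    refrac = np.zeros(n, dtype=int)
    ref_steps = max(1, int(round(params.tau_ref / dt)))
    tau_m = np.where(np.arange(n) < n_e, params.tau_m_exc, params.tau_m_inh)

    d_ampa = dt / params.tau_ampa
    d_nmda = dt / params.tau_nmda
    d_gaba = dt / params.tau_gaba
    d_x = dt / mech.tau_x if std_on else 0.0
    d_u = dt / mech.tau_u if stf_on else 0.0
    d_a = dt / params.sfa_tau_a

    out_ids: List[np.ndarray] = []
    out_times: List[float] = []
    rate = stim_rate.copy()
    active = np.zeros(len(stim_masks), dtype=bool)

    for k in range(n_steps):
        # resolve stimulation state lazily
        changed = False
        for idx, (k0, k1, mask) in enumerate(stim_masks):
            now = k0 <= k < k1
            if now != active[idx]:
                active[idx] = now
                changed = True
        if changed:
            rate = np.full(n, base)
            for idx, (k0, k1, mask) in enumerate(stim_masks):
                if active[idx]:
                    rate[mask] = stim_total

        # external Poisson drive
        ext = rng.poisson(rate * dt)
        if ext.any():
            g_ampa += params.w_ext * ext

        # conductance decay / NMDA charging
        g_nmda += d_nmda * (g_ampa - g_nmda)
        g_ampa -= d_ampa * g_ampa
        g_gaba -= d_gaba * g_gaba
        if sfa_on:
            a_sfa -= d_a * a_sfa
        if std_on:
            x += d_x * (1.0 - x)
        if stf_on:
            u_fac += d_u * (1.0 - u_fac)

        g_exc = params.xi * g_ampa + (1.0 - params.xi) * g_nmda
        g_inh = g_gaba.copy()
        if sfa_on:
            g_inh[:n_e] += a_sfa
        du = (
            (params.u_rest - u)
            + g_exc * (params.u_exc - u)
            + g_inh * (params.u_inh - u)
        ) * (dt / tau_m)
        in_ref = refrac > 0
        u = np.where(in_ref, params.u_rest, u + du)
        u = np.clip(u, params.u_inh, params.u_exc)
        refrac[in_ref] -= 1

        spiking = u >= params.u_thr
        if spiking.any():
            ids = np.flatnonzero(spiking)
            out_ids.append(ids)
            out_times.append((k + 1) * dt)
            u[ids] = params.u_rest
            refrac[ids] = ref_steps

            e_ids = ids[ids < n_e]
            i_ids = ids[ids >= n_e]
            if len(e_ids):
                factor = x[e_ids] if std_on else np.ones(len(e_ids))
                g_ampa[:n_e] += w_ee[:, e_ids] @ factor
                fac = u_fac[e_ids] if stf_on else np.ones(len(e_ids))
                g_ampa[n_e:] += w_ie[:, e_ids] @ fac
                if std_on:
                    x[e_ids] -= mech.u_d * x[e_ids]
                    np.clip(x, 1e-12, 1.0, out=x)
                if stf_on:
                    u_fac[e_ids] += mech.u_f * (mech.u_max - u_fac[e_ids])
                    np.clip(u_fac, 1.0, mech.u_max, out=u_fac)
                if sfa_on:
                    a_sfa[e_ids] += params.sfa_b
            if len(i_ids):
                g_gaba += w_exc_gaba[:, i_ids - n_e].sum(axis=1)

    if out_ids:
        ids = np.concatenate(out_ids)
        times = np.repeat(np.array(out_times), [len(s) for s in out_ids])
    else:
        ids, times = np.array([], dtype=int), np.array([])
    return SpikeData(ids, times, n_e, n_i, duration, seed)


def ensemble_activity(
    spikes: SpikeData, layout: EnsembleLayout, bin_size: float = 0.01
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-ensemble population rate (Hz) in fixed bins.

    Returns ``(bin_centers, rates)`` with ``rates`` of shape
    ``(n_bins, n_ensembles)``: spike count of the ensemble per bin divided
    by ``bin_size * ensemble_size``.
    """
    if bin_size <= 0:
        raise ParameterError("bin size must be positive")
    edges = np.arange(0.0, spikes.duration + bin_size / 2, bin_size)
    centers = 0.5 * (edges[:-1] + edges[1:])
    rates = np.zeros((len(centers), layout.n_ensembles))
    for k, members in enumerate(layout.members):
        if len(members) == 0:
            raise ParameterError("empty ensemble")
        sel = np.isin(spikes.neuron_ids, members)
        counts, _ = np.histogram(spikes.times[sel], bins=edges)
        rates[:, k] = counts / (bin_size * len(members))
    return centers, rates


def activity_differences(
    centers: np.ndarray,
    rates: np.ndarray,
    schedule: Sequence[StimulationPeriod],
) -> List[dict]:
    """Per-period stimulated-minus-unstimulated activity differences.

    For each stimulation period: the onset difference subtracts the mean
    of the unstimulated ensembles' maxima from the stimulated ensemble's
    maximum; the fixed-point difference applies the same subtraction to the
    middle-1 s averages.
    """
    n_ens = rates.shape[1]
    if n_ens < 2:
        raise ParameterError("need at least two ensembles for a reference")
    out = []
    for p in schedule:
        sel = (centers >= p.t_start) & (centers < p.t_end)
        span = p.t_end - p.t_start
        mid = (centers >= p.t_start + 0.5 * (span - 1.0)) & (
            centers < p.t_start + 0.5 * (span + 1.0)
        )
        others = [k for k in range(n_ens) if k != p.ensemble]
        peak_stim = rates[sel, p.ensemble].max()
        peak_others = np.mean([rates[sel, k].max() for k in others])
        fp_stim = rates[mid, p.ensemble].mean()
        fp_others = np.mean([rates[mid, k].mean() for k in others])
        out.append(
            {
                "ensemble": p.ensemble,
                "t_start": p.t_start,
                "onset_diff": float(peak_stim - peak_others),
                "fixedpoint_diff": float(fp_stim - fp_others),
            }
        )
    return out


def pca_variance(
    spikes: SpikeData,
    window: Tuple[float, float],
    bin_size: float = 0.01,
    n_components: int = 2,
) -> dict:
    """PCA of binned, mean-centered excitatory spiking in a time window.

    Bins each excitatory neuron's spikes, mean-centers per neuron, and
    returns the explained-variance fractions (all components sum to one)
    plus the trajectory projected on the first ``n_components`` PCs.
    """
    from sklearn.decomposition import PCA

    t0, t1 = window
    edges = np.arange(t0, t1 + bin_size / 2, bin_size)
    if len(edges) < 3:
        raise ParameterError("window must contain at least two bins")
    exc = spikes.excitatory()
    mat = np.zeros((len(edges) - 1, spikes.n_e))
    for i in range(spikes.n_e):
        mat[:, i], _ = np.histogram(exc.times[exc.neuron_ids == i], bins=edges)
    mat -= mat.mean(axis=0, keepdims=True)
    pca = PCA()
    proj = pca.fit_transform(mat)
    return {
        "explained_fraction": pca.explained_variance_ratio_,
        "projection": proj[:, :n_components],
        "first_two": float(pca.explained_variance_ratio_[:2].sum()),
    }
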