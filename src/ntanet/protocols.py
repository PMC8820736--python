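"""Named, reproducible experiment protocols.

Each protocol runs one canonical experiment with its published parameter
set, returns the computed quantities as a plain dict, and (optionally)
writes tabular outputs plus a resolved-config snapshot to an output
directory. All randomness is controlled by the ``seed`` argument.
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable, Dict, Optional

import numpy as np
import pandas as pd

from . import presets as P
from .ensembles import (
    TwoEnsembleWeights,
    microcircuit_blocks,
    simulate_two_ensembles_from_table,
    unistability_map,
)
from .io import write_json
from .metrics import association_index, decision_distance, extract_features
from .params import (
    Episode,
    InactivateInhibition,
    InjectToI,
    Mechanism,
    ParameterError,
    StimulusProtocol,
)
from .rate import simulate_ensemble, simulate_network
from .sfa import classify_sfa_dynamics
from .spiking import (
    EnsembleLayout,
    SpikingNetworkParams,
    activity_differences,
    canonical_schedule,
    ensemble_activity,
    make_overlapping_ensembles,
    pca_variance,
    simulate_spiking_network,
)
from .stability import critical_input, find_fixed_points
from .stp import isn_trajectory_index, std_regime_map

__all__ = ["PROTOCOLS", "run_protocol", "STRONG_SFA_B"]

#: Adaptation strength used for the "strong SFA" (oscillatory) protocol;
#: chosen once by a coarse multiplier sweep on the published b=1.0 (see
#: docs/methods.md).
STRONG_SFA_B = 300.0


def _canonical_protocol(dg_e: float = P.SINGLE_ENSEMBLE_G_STIM - 1.55):
    return StimulusProtocol.step(P.STIM_START, P.STIM_END, dg_e=dg_e)


def protocol_runaway(seed: int = 0, dt: float = 1e-4) -> dict:
    """Plain supralinear ensemble destabilized by a suprathreshold input."""
    w, rp, g = (
        P.single_ensemble_weights(),
        P.single_ensemble_rate_params(),
        P.default_gain(),
    )
    traj = simulate_ensemble(w, rp, g, protocol=_canonical_protocol(), duration=6.0, dt=dt)
    return {
        "trajectory": traj,
        "diverged": traj.diverged,
        "divergence_time": traj.divergence_time,
    }


def protocol_std_stabilization(
    seed: int = 0, dt: float = 1e-4, inactivate_inhibition: bool = False
) -> dict:
    """E-to-E depression quenches the onset transient into a stable state."""
    w, rp, g = (
        P.single_ensemble_weights(),
        P.single_ensemble_rate_params(),
        P.default_gain(),
    )
    proto = _canonical_protocol()
    bound = np.inf if inactivate_inhibition else 1e6
    if inactivate_inhibition:
        proto.probes.append(InactivateInhibition(2.5, 3.5))
    traj = simulate_ensemble(
        w, rp, g, P.default_std(), proto, duration=6.0, dt=dt, divergence_bound=bound
    )
    feats = extract_features(traj.t, traj.r_e, (P.STIM_START, P.STIM_END))
    return {"trajectory": traj, "features": feats, "diverged": traj.diverged}


def protocol_stf_stabilization(
    seed: int = 0, dt: float = 1e-4, inactivate_inhibition: bool = False
) -> dict:
    """E-to-I facilitation stabilizes the ensemble (but needs inhibition)."""
    w, rp, g = (
        P.single_ensemble_weights(),
        P.single_ensemble_rate_params(),
        P.default_gain(),
    )
    proto = _canonical_protocol()
    bound = np.inf if inactivate_inhibition else 1e6
    if inactivate_inhibition:
        proto.probes.append(InactivateInhibition(2.5, 3.5))
    traj = simulate_ensemble(
        w, rp, g, P.default_stf(), proto, duration=6.0, dt=dt, divergence_bound=bound
    )
    feats = (
        extract_features(traj.t, traj.r_e, (P.STIM_START, P.STIM_END))
        if not traj.diverged
        else None
    )
    return {"trajectory": traj, "features": feats, "diverged": traj.diverged}


def protocol_sfa_classify(
    seed: int = 0, b_grid=(1.0, STRONG_SFA_B), dt: float = 1e-4
) -> dict:
    """Classify stimulated SFA dynamics over a grid of adaptation strengths."""
    w, rp, g = (
        P.single_ensemble_weights(),
        P.single_ensemble_rate_params(),
        P.default_gain(),
    )
    rows = []
    for b in b_grid:
        c = classify_sfa_dynamics(w, rp, g, P.default_sfa(float(b)), _canonical_protocol(), dt=dt)
        rows.append(
            {
                "b": float(b),
                "class": c.label,
                "oscillation_frequency": c.oscillation_frequency,
                "hopf_margin": c.hopf_margin,
            }
        )
    return {"table": pd.DataFrame(rows)}


def protocol_fixed_points(seed: int = 0, g_e: Optional[float] = None) -> dict:
    """Fixed-point report and critical input of the canonical ensemble."""
    w, rp, g = (
        P.single_ensemble_weights(),
        P.single_ensemble_rate_params(),
        P.default_gain(),
    )
    g_e = rp.g_e if g_e is None else g_e
    report = find_fixed_points(w, rp, g, g_e=g_e)
    return {
        "report": report,
        "critical_input": critical_input(w, rp, g),
        "table": pd.DataFrame(
            [
                {
                    "rE": p.r_e,
                    "rI": p.r_i,
                    "z": p.z,
                    "stability": p.stability,
                    "dF_dz": p.dF_dz,
                }
                for p in report.points
            ]
        ),
    }


def protocol_regime_scan(
    seed: int = 0,
    jee_grid=np.linspace(0.2, 2.0, 13),
    g_e_grid=np.linspace(0.5, 12.0, 13),
) -> dict:
    """(JEE, gE) map of fixed-point count and evoked rate.

    Uses the regime-scan weight set; the unstable (zero-fixed-point) region
    grows with both JEE and gE.
    """
    rp, g = P.single_ensemble_rate_params(), P.default_gain()
    rows = []
    for jee in jee_grid:
        w = P.regime_scan_weights(float(jee))
        for g_e in g_e_grid:
            rep = find_fixed_points(w, rp, g, g_e=float(g_e))
            stable = rep.stable_points
            rows.append(
                {
                    "JEE": float(jee),
                    "gE": float(g_e),
                    "n_fixed_points": rep.n_points,
                    "max_rate": max((p.r_e for p in stable), default=np.nan),
                    "unstable": rep.n_points == 0,
                }
            )
    return {"table": pd.DataFrame(rows)}


def protocol_isn_timecourse(seed: int = 0, dt: float = 1e-4) -> dict:
    """ISN-index time course and paradoxical-effect probes (STD ensemble)."""
    w, rp, g = (
        P.single_ensemble_weights(),
        P.single_ensemble_rate_params(),
        P.default_gain(),
    )
    std = P.default_std()
    traj = simulate_ensemble(w, rp, g, std, _canonical_protocol(), duration=6.0, dt=dt)
    index = isn_trajectory_index(traj, w, rp, g, std)

    def probe(t0, t1, magnitude=0.2):
        proto = _canonical_protocol()
        proto.probes.append(InjectToI(t0, t1, magnitude))
        probed = simulate_ensemble(w, rp, g, std, proto, duration=6.0, dt=dt)
        sel = (traj.t >= t0 + 0.5) & (traj.t < t1)
        return float(probed.r_i[sel].mean() - traj.r_i[sel].mean())

    return {
        "trajectory": traj,
        "isn_index": index,
        "baseline_index": float(index[(traj.t >= 1.5) & (traj.t < 2.0)].mean()),
        "stim_index": float(index[(traj.t >= 3.0) & (traj.t < 3.9)].mean()),
        "baseline_probe_drI": probe(1.0, 1.8),
        "stim_probe_drI": probe(2.8, 3.6),
    }


def protocol_regime_map_std(
    seed: int = 0,
    jee_grid=np.linspace(0.05, 3.0, 60),
    x_grid=np.linspace(0.02, 1.0, 50),
    r_e: float = 1.0,
) -> dict:
    """(JEE, x) map of ISN / paradoxical regions at a reference rate."""
    w, rp, g = (
        P.single_ensemble_weights(),
        P.single_ensemble_rate_params(),
        P.default_gain(),
    )
    isn, par = std_regime_map(w, rp, g, P.default_std(), jee_grid, x_grid, r_e=r_e)
    jj, xx = np.meshgrid(jee_grid, x_grid)
    table = pd.DataFrame(
        {
            "JEE": jj.ravel(),
            "x": xx.ravel(),
            "isn": isn.ravel(),
            "paradoxical": par.ravel(),
        }
    )
    return {"isn": isn, "paradoxical": par, "table": table}


def protocol_two_ensemble_attractors(seed: int = 0, dt: float = 1e-4) -> dict:
    """Multi-stable vs uni-stable two-ensemble networks (STD-stabilized)."""
    g = P.default_gain()
    out = {}
    for label, multistable in (("multistable", True), ("unistable", False)):
        table = P.two_ensemble_populations(multistable)
        net = simulate_two_ensembles_from_table(
            table, g, P.default_std(), duration=8.0, dt=dt, seed=seed
        )
        sel_post = (net.t >= 7.0) & (net.t < 8.0)
        sel_base = (net.t >= 1.5) & (net.t < 2.0)
        out[label] = {
            "trajectory": net,
            "baseline": net.r_e[sel_base].mean(axis=0),
            "post": net.r_e[sel_post].mean(axis=0),
        }
    return out


def protocol_unistability_map(
    seed: int = 0,
    a_grid=np.linspace(0.0, 200.0, 41),
    d_grid=np.linspace(0.0, 200.0, 41),
    k: float = 0.1,
    m: float = 0.5,
) -> dict:
    """Uni-stability maps for global vs co-tuned inhibition (b*c = 0.9*a*d)."""
    grid = unistability_map(a_grid, d_grid, k=k, m=m)
    aa, dd = np.meshgrid(grid["a"], grid["d"])
    table = pd.DataFrame(
        {
            "a": aa.ravel(),
            "d": dd.ravel(),
            "uni_global": grid["global"].ravel(),
            "uni_cotuned": grid["cotuned"].ravel(),
        }
    )
    return {**grid, "table": table}


def _pattern_completion_run(dg: float, dt: float = 1e-4):
    g = P.default_gain()
    tab = P.two_ensemble_microcircuit()
    blocks = microcircuit_blocks(tab, subset_split=(0.75, 0.25))
    proto = StimulusProtocol(
        episodes=[
            Episode(2.0, 4.0, dg_e=np.array([dg, 0.0, 0.0])),
            Episode(6.0, 8.0, dg_e=np.array([dg, dg, 0.0])),
        ]
    )
    return simulate_network(
        blocks["w_ee"],
        blocks["w_ei"],
        blocks["w_ie"],
        blocks["w_ii"],
        g_e=tab.g_e_base,
        g_i=tab.g_i,
        gain=g,
        tau_e=0.020,
        tau_i=0.010,
        mechanism=P.default_std(),
        protocol=proto,
        duration=10.0,
        dt=dt,
    )


def protocol_pattern_completion(
    seed: int = 0, g_e1_grid=(2.5, 3.0, 3.5, 4.0), dt: float = 1e-4
) -> dict:
    """Association index and decision distance vs. stimulation strength.

    Phase one stimulates 75% of ensemble 1 (Subset 1) and measures pattern
    completion in the unstimulated Subset 2; phase two stimulates all of
    ensemble 1 and measures the distance of (rE1, rE2) from the symmetric
    decision boundary.
    """
    tab = P.two_ensemble_microcircuit()
    rows = []
    for g_stim in g_e1_grid:
        net = _pattern_completion_run(float(g_stim) - tab.g_e_base, dt=dt)
        f11 = extract_features(net.t, net.r_e[:, 0], (2.0, 4.0))
        f12 = extract_features(net.t, net.r_e[:, 1], (2.0, 4.0))
        r_e1 = 0.75 * net.r_e[:, 0] + 0.25 * net.r_e[:, 1]
        f_e1 = extract_features(net.t, r_e1, (6.0, 8.0))
        f_e2 = extract_features(net.t, net.r_e[:, 2], (6.0, 8.0))
        rows.append(
            {
                "gE1": float(g_stim),
                "assoc_onset": association_index(f11.onset_peak, f12.onset_peak),
                "assoc_fixed_point": association_index(
                    f11.fixed_point, max(f12.fixed_point, 0.0)
                ),
                "distance_onset": decision_distance(f_e1.onset_peak, f_e2.onset_peak),
                "distance_fixed_point": decision_distance(
                    f_e1.fixed_point, f_e2.fixed_point
                ),
                "subset2_onset_peak": f12.onset_peak,
                "subset2_fixed_point": f12.fixed_point,
            }
        )
    return {"table": pd.DataFrame(rows)}


def protocol_morphing(
    seed: int = 0,
    p_grid=(0.0, 0.25, 0.5, 0.75, 1.0),
    jee_tot_grid=(0.0, 0.6, 1.2),
    dt: float = 1e-4,
) -> dict:
    """Morphing experiment: peak and fixed-point activity vs. input mix.

    The extra drive is split between the two ensembles by ``p``; the onset
    peak grows strongly with the recurrent E-to-E budget while the
    fixed-point activity depends on it only weakly.
    """
    g = P.default_gain()
    base_tab = P.two_ensemble_microcircuit()
    rows = []
    for jee_tot in jee_tot_grid:
        tab = P.two_ensemble_microcircuit(jee_tot=float(jee_tot))
        blocks = microcircuit_blocks(tab)
        for p in p_grid:
            span = tab.g_e_stim - tab.g_e_base
            dg1, dg2 = span * (1.0 - float(p)), span * float(p)
            proto = StimulusProtocol(
                episodes=[Episode(2.0, 4.0, dg_e=np.array([dg1, dg2]))]
            )
            net = simulate_network(
                blocks["w_ee"],
                blocks["w_ei"],
                blocks["w_ie"],
                blocks["w_ii"],
                g_e=tab.g_e_base,
                g_i=tab.g_i,
                gain=g,
                tau_e=0.020,
                tau_i=0.010,
                mechanism=P.default_std(),
                protocol=proto,
                duration=6.0,
                dt=dt,
            )
            f1 = extract_features(net.t, net.r_e[:, 0], (2.0, 4.0))
            f2 = extract_features(net.t, net.r_e[:, 1], (2.0, 4.0))
            rows.append(
                {
                    "p": float(p),
                    "jee_tot": float(jee_tot),
                    "peak_e1": f1.onset_peak,
                    "peak_e2": f2.onset_peak,
                    "fp_e1": f1.fixed_point,
                    "fp_e2": f2.fixed_point,
                    "distance_onset": decision_distance(f1.onset_peak, f2.onset_peak),
                    "distance_fixed_point": decision_distance(
                        f1.fixed_point, f2.fixed_point
                    ),
                }
            )
    return {"table": pd.DataFrame(rows)}


def protocol_spiking_ensembles(
    seed: int = 7,
    duration: float = 26.0,
    n_e: int = 800,
    n_i: int = 200,
    dt: float = 1e-4,
    pca_window: tuple = (0.0, 10.0),
) -> dict:
    """The canonical spiking-ensemble protocol.

    Five overlapping 200-neuron ensembles are stimulated for 2 s each,
    then 75% of the last ensemble; returns spikes, binned ensemble
    activity, per-period onset/fixed-point differences and the PCA of the
    early spiking activity.
    """
    params = SpikingNetworkParams(n_e=n_e, n_i=n_i)
    layout = make_overlapping_ensembles(n_e, seed=seed)
    schedule = canonical_schedule(layout, seed=seed)
    schedule = [p for p in schedule if p.t_start < duration]
    spikes = simulate_spiking_network(
        params, layout, schedule, duration=duration, dt=dt, seed=seed
    )
    centers, rates = ensemble_activity(spikes, layout)
    full = [p for p in schedule if p.subset is None and p.t_end <= duration]
    diffs = activity_differences(centers, rates, full)
    pca = pca_variance(spikes, pca_window)
    out = {
        "spikes": spikes,
        "layout": layout,
        "schedule": schedule,
        "centers": centers,
        "rates": rates,
        "differences": diffs,
        "pca_first_two": pca["first_two"],
        "pca_projection": pca["projection"],
    }
    subset_periods = [p for p in schedule if p.subset is not None]
    if subset_periods and subset_periods[0].t_end <= duration:
        p = subset_periods[0]
        ens = layout.members[p.ensemble]
        sub2 = np.setdiff1d(ens, p.subset)
        lay2 = EnsembleLayout(members=[p.subset, sub2], n_e=n_e)
        c2, r2 = ensemble_activity(spikes, lay2)
        sel = (c2 >= p.t_start) & (c2 < p.t_end)
        basewin = (c2 >= p.t_start - 1.0) & (c2 < p.t_start)
        mid = (c2 >= p.t_start + 0.5) & (c2 < p.t_start + 1.5)
        out["subset2_onset_peak"] = float(r2[sel, 1].max())
        out["subset2_baseline"] = float(r2[basewin, 1].mean())
        out["subset2_fixed_point"] = float(r2[mid, 1].mean())
    return out


PROTOCOLS: Dict[str, Callable[..., dict]] = {
    "runaway": protocol_runaway,
    "fixed-points": protocol_fixed_points,
    "regime-scan": protocol_regime_scan,
    "sfa-classify": protocol_sfa_classify,
    "std-stabilization": protocol_std_stabilization,
    "stf-stabilization": protocol_stf_stabilization,
    "isn-timecourse": protocol_isn_timecourse,
    "regime-map-std": protocol_regime_map_std,
    "two-ensemble-attractors": protocol_two_ensemble_attractors,
    "unistability-map": protocol_unistability_map,
    "pattern-completion": protocol_pattern_completion,
    "morphing": protocol_morphing,
    "spiking-ensembles": protocol_spiking_ensembles,
}


def run_protocol(
    name: str, seed: int = 0, outdir: Optional[str] = None, **overrides
) -> dict:
    """Run a named protocol; optionally write its tabular outputs.

    Writes ``<name>.csv`` for protocols with a main table, per-trajectory
    CSVs, spikes as a two-column CSV, and a resolved-config snapshot.
    """
    if name not in PROTOCOLS:
        raise ParameterError(
            f"unknown protocol {name!r}; available: {sorted(PROTOCOLS)}"
        )
    result = PROTOCOLS[name](seed=seed, **overrides)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        snapshot = {"protocol": name, "seed": seed}
        snapshot.update(
            {k: v for k, v in overrides.items() if np.isscalar(v) or v is None}
        )
        write_json(snapshot, out / f"{name}-config.json")
        if "table" in result:
            result["table"].to_csv(out / f"{name}.csv", index=False)
        if "spikes" in result:
            sp = result["spikes"]
            pd.DataFrame({"neuron_id": sp.neuron_ids, "time_s": sp.times}).to_csv(
                out / f"{name}-spikes.csv", index=False
            )
        if "trajectory" in result:
            from .io import save_trajectory

            save_trajectory(
                result["trajectory"], out / f"{name}-trajectory.csv", snapshot
            )
    return result
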