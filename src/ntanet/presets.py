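"""Published parameter sets for the canonical protocols.

The single-ensemble set drives the runaway/stabilization examples, the
plasticity defaults apply everywhere a mechanism is enabled unless
overridden, and the two-ensemble/spiking sets parameterize the
multi-ensemble and spiking protocols.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import EnsembleWeights, GainParams, Mechanism, RateParams

__all__ = [
    "single_ensemble_weights",
    "single_ensemble_rate_params",
    "regime_scan_weights",
    "default_gain",
    "default_sfa",
    "default_std",
    "default_stf",
    "STIM_START",
    "STIM_END",
    "SINGLE_ENSEMBLE_G_STIM",
    "TwoEnsembleTable",
    "two_ensemble_populations",
    "MicrocircuitTable",
    "two_ensemble_microcircuit",
]

#: Canonical stimulation window (seconds): 2 s of baseline relaxation,
#: then a 2 s stimulation episode.
STIM_START = 2.0
STIM_END = 4.0

#: Excitatory drive during stimulation of the single ensemble.
SINGLE_ENSEMBLE_G_STIM = 3.0


def single_ensemble_weights() -> EnsembleWeights:
    """Single-ensemble weights (det(J) = -0.08 < 0, positive feedback)."""
    return EnsembleWeights(jee=1.8, jei=1.0, jie=1.0, jii=0.6)


def regime_scan_weights(jee: float) -> EnsembleWeights:
    """Weights used for the (JEE, gE) regime scan; JEE is swept."""
    return EnsembleWeights(jee=jee, jei=1.0, jie=0.45, jii=1.5)


def single_ensemble_rate_params(rate_cap: float | None = None) -> RateParams:
    """tauE=20 ms, tauI=10 ms, baseline gE=1.55, gI=2.0."""
    return RateParams(tau_e=0.020, tau_i=0.010, g_e=1.55, g_i=2.0, rate_cap=rate_cap)


def default_gain() -> GainParams:
    return GainParams(alpha_e=2.0, alpha_i=2.0)


def default_sfa(b: float = 1.0) -> Mechanism:
    """SFA with tau_a=200 ms; b=1.0 is the weak (non-stabilizing) default."""
    return Mechanism.sfa(b=b, tau_a=0.2)


def default_std() -> Mechanism:
    """E-to-E STD with tau_x=200 ms, Ud=1.0."""
    return Mechanism.std(u_d=1.0, tau_x=0.2)


def default_stf() -> Mechanism:
    """E-to-I STF with tau_u=200 ms, Uf=1.0, Umax=6.0."""
    return Mechanism.stf(u_f=1.0, u_max=6.0, tau_u=0.2)


@dataclass(frozen=True)
class TwoEnsembleTable:
    """Population-level weights/drives for the two-ensemble attractor demo."""

    jee: float
    jie: float = 0.6
    jei: float = 1.0
    jii: float = 0.6
    jee_p: float = 0.0
    jie_p: float = 0.6
    jei_p: float = 1.0
    jii_p: float = 0.6
    g_e1_base: float = 2.2
    g_e1_stim: float = 3.0
    g_e2: float = 2.2
    g_i: float = 2.0


def two_ensemble_populations(multistable: bool = True) -> TwoEnsembleTable:
    """Two-ensemble population networks with global-like inhibition.

    The multistable and uni-stable examples differ only in the recurrent
    E-to-E strength (1.4 vs 1.3, with inter-ensemble strength 10% of it).
    """
    if multistable:
        return TwoEnsembleTable(jee=1.4, jee_p=0.14)
    return TwoEnsembleTable(jee=1.3, jee_p=0.13)


@dataclass(frozen=True)
class MicrocircuitTable:
    """Per-connection weights of the neuron-normalized two-ensemble circuit.

    Each of the two ensembles has ``n_e/2`` excitatory and ``n_i/2``
    inhibitory all-to-all connected neurons; per-connection weights are the
    quoted numerators divided by the relevant (fan-in) neuron counts.
    """

    n_e: int = 200
    n_i: int = 50
    jee_tot: float = 1.2
    jie_tot: float = 1.0
    jei_tot: float = 1.0
    jii_tot: float = 1.0
    jee_p_tot: float = 0.36
    jie_p_tot: float = 0.4
    jei_p_tot: float = 0.1
    jii_p_tot: float = 0.1
    g_e_base: float = 1.35
    g_e_stim: float = 4.0
    g_i: float = 2.0

    @property
    def jee(self) -> float:
        return self.jee_tot / (self.n_e / 2 - 1)

    @property
    def jie(self) -> float:
        return self.jie_tot / (self.n_e / 2)

    @property
    def jei(self) -> float:
        return self.jei_tot / (self.n_i / 2)

    @property
    def jii(self) -> float:
        return self.jii_tot / (self.n_i / 2 - 1)

    @property
    def jee_p(self) -> float:
        return self.jee_p_tot / (self.n_e / 2 - 1)

    @property
    def jie_p(self) -> float:
        return self.jie_p_tot / (self.n_e / 2)

    @property
    def jei_p(self) -> float:
        return self.jei_p_tot / (self.n_i / 2)

    @property
    def jii_p(self) -> float:
        return self.jii_p_tot / (self.n_i / 2)


def two_ensemble_microcircuit(**overrides) -> MicrocircuitTable:
    return MicrocircuitTable(**overrides)
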