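"""Parameter containers for supralinear E/I ensemble models.

Conventions
-----------
* Time is measured in seconds internally (published tables in ms are
  converted on load, see :mod:`ntanet.io`).
* Rates are in Hz, synaptic weights and external drives are dimensionless.
* Weight magnitudes are all non-negative; inhibitory signs are applied
  inside the rate equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np

__all__ = [
    "GainParams",
    "EnsembleWeights",
    "RateParams",
    "Mechanism",
    "Episode",
    "InactivateInhibition",
    "FreezeInhibition",
    "PerturbRate",
    "InjectToI",
    "StimulusProtocol",
    "ParameterError",
]


class ParameterError(ValueError):
    """Raised for invalid model parameters."""


@dataclass(frozen=True)
class GainParams:
    """Exponents of the rectified power-law input-output functions.

    ``rate = [input]_+ ** alpha`` for each population; supralinear for
    ``alpha > 1``. Both default to 2, the canonical quadratic gain.
    """

    alpha_e: float = 2.0
    alpha_i: float = 2.0

    def __post_init__(self) -> None:
        if self.alpha_e <= 0 or self.alpha_i <= 0:
            raise ParameterError("gain exponents must be positive")


@dataclass(frozen=True)
class EnsembleWeights:
    """Synaptic weight magnitudes of a single E/I ensemble.

    All entries are >= 0; the signs (inhibition negative) live in the
    equations. ``det`` is the determinant of the signed compound weight
    matrix [[JEE, -JEI], [JIE, -JII]]; ensembles with ``det < 0`` can
    generate positive-feedback (runaway) dynamics.
    """

    jee: float
    jei: float
    jie: float
    jii: float

    def __post_init__(self) -> None:
        if min(self.jee, self.jei, self.jie, self.jii) < 0:
            raise ParameterError("weight magnitudes must be non-negative")

    @property
    def det(self) -> float:
        return -self.jee * self.jii + self.jie * self.jei


@dataclass(frozen=True)
class RateParams:
    """Time constants, external drives and optional firing-rate cap."""

    tau_e: float = 0.020
    tau_i: float = 0.010
    g_e: float = 0.0
    g_i: float = 0.0
    rate_cap: Optional[float] = None

    def __post_init__(self) -> None:
        if self.tau_e <= 0 or self.tau_i <= 0:
            raise ParameterError("time constants must be positive")
        if self.rate_cap is not None and self.rate_cap <= 0:
            raise ParameterError("rate_cap must be positive when set")


@dataclass(frozen=True)
class Mechanism:
    """Activity-dependent stabilization mechanism of an ensemble.

    Variants
    --------
    ``none``
        Plain supralinear dynamics.
    ``sfa``
        Spike-frequency adaptation: a negative feedback current ``a`` with
        ``tau_a da/dt = -a + b*rE`` subtracted from the excitatory drive.
    ``std``
        E-to-E short-term depression: a synaptic resource ``x in (0, 1]``
        with ``dx/dt = (1-x)/tau_x - Ud*x*rE`` multiplying JEE.
    ``stf``
        E-to-I short-term facilitation: an efficacy ``u in [1, u_max]``
        with ``du/dt = (1-u)/tau_u + Uf*(u_max-u)*rE`` multiplying JIE.
    """

    variant: str = "none"
    # SFA
    b: Optional[float] = None
    tau_a: Optional[float] = None
    # STD
    u_d: Optional[float] = None
    tau_x: Optional[float] = None
    # STF
    u_f: Optional[float] = None
    u_max: Optional[float] = None
    tau_u: Optional[float] = None

    def __post_init__(self) -> None:
        required = {
            "none": (),
            "sfa": ("b", "tau_a"),
            "std": ("u_d", "tau_x"),
            "stf": ("u_f", "u_max", "tau_u"),
        }
        if self.variant not in required:
            raise ParameterError(f"unknown mechanism variant {self.variant!r}")
        for name in required[self.variant]:
            if getattr(self, name) is None:
                raise ParameterError(
                    f"mechanism {self.variant!r} requires field {name!r}"
                )
        for name in ("b", "tau_a", "u_d", "tau_x", "u_f", "u_max", "tau_u"):
            if name not in required[self.variant] and getattr(self, name) is not None:
                raise ParameterError(
                    f"field {name!r} is not part of mechanism {self.variant!r}"
                )
        if self.variant == "sfa" and (self.b < 0 or self.tau_a <= 0):
            raise ParameterError("SFA requires b >= 0 and tau_a > 0")
        if self.variant == "std" and (self.u_d <= 0 or self.tau_x <= 0):
            raise ParameterError("STD requires u_d > 0 and tau_x > 0")
        if self.variant == "stf" and (
            self.u_f <= 0 or self.tau_u <= 0 or self.u_max < 1
        ):
            raise ParameterError("STF requires u_f > 0, tau_u > 0 and u_max >= 1")

    # -- constructors -------------------------------------------------
    @classmethod
    def none(cls) -> "Mechanism":
        return cls("none")

    @classmethod
    def sfa(cls, b: float = 1.0, tau_a: float = 0.2) -> "Mechanism":
        return cls("sfa", b=b, tau_a=tau_a)

    @classmethod
    def std(cls, u_d: float = 1.0, tau_x: float = 0.2) -> "Mechanism":
        return cls("std", u_d=u_d, tau_x=tau_x)

    @classmethod
    def stf(
        cls, u_f: float = 1.0, u_max: float = 6.0, tau_u: float = 0.2
    ) -> "Mechanism":
        return cls("stf", u_f=u_f, u_max=u_max, tau_u=tau_u)

    @property
    def rest_aux(self) -> float:
        """Resting value of the mechanism variable (a=0, x=1, u=1)."""
        return 0.0 if self.variant in ("none", "sfa") else 1.0


ArrayLike = Union[float, Sequence[float], np.ndarray]


@dataclass(frozen=True)
class Episode:
    """Additive external-drive episode during ``[t_start, t_end)``.

    ``dg_e``/``dg_i`` may be scalars (applied to every population) or
    per-population arrays for multi-ensemble networks.
    """

    t_start: float
    t_end: float
    dg_e: ArrayLike = 0.0
    dg_i: ArrayLike = 0.0

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ParameterError("episode requires t_start < t_end")


@dataclass(frozen=True)
class InactivateInhibition:
    """Force all inhibitory rates to zero during ``[t0, t1)``."""

    t0: float
    t1: float


@dataclass(frozen=True)
class FreezeInhibition:
    """Hold inhibitory rates at their pre-probe values during ``[t0, t1)``."""

    t0: float
    t1: float


@dataclass(frozen=True)
class PerturbRate:
    """Instantaneous additive kick to excitatory rates at time ``t``."""

    t: float
    magnitude: float


@dataclass(frozen=True)
class InjectToI:
    """Additive excitatory current into inhibitory populations in ``[t0, t1)``."""

    t0: float
    t1: float
    magnitude: float


Probe = Union[InactivateInhibition, FreezeInhibition, PerturbRate, InjectToI]


@dataclass
class StimulusProtocol:
    """Stimulation episodes plus optional perturbation probes."""

    episodes: List[Episode] = field(default_factory=list)
    probes: List[Probe] = field(default_factory=list)

    @classmethod
    def step(
        cls, t_start: float, t_end: float, dg_e: ArrayLike, dg_i: ArrayLike = 0.0
    ) -> "StimulusProtocol":
        """Single stimulation episode, the canonical protocol."""
        return cls(episodes=[Episode(t_start, t_end, dg_e, dg_i)])
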