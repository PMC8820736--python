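"""Scalar indices and trajectory-feature extraction.

The association index quantifies pattern completion from the stimulated
(rE11) and unstimulated (rE12) subsets of an ensemble; the separation
index contrasts two ensembles; the decision distance measures how far a
two-ensemble activity point lies from the symmetric (diagonal) decision
boundary; the amplification index is the evoked-peak/input ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .params import ParameterError
from .rate import RateTrajectory

__all__ = [
    "association_index",
    "separation_index",
    "decision_distance",
    "amplification_index",
    "TrajectoryFeatures",
    "extract_features",
]


def association_index(r_e11: float, r_e12: float) -> float:
    """Pattern-completion index ``1 + (rE12 - rE11)/(rE12 + rE11)``.

    For the usual regime ``rE12 <= rE11`` it ranges from 0 (no completion,
    unstimulated subset silent) to 1 (full completion, equal rates).
    """
    if r_e11 < 0 or r_e12 < 0:
        raise ParameterError("rates must be non-negative")
    if r_e11 + r_e12 == 0:
        raise ParameterError("association index undefined for two silent subsets")
    return 1.0 + (r_e12 - r_e11) / (r_e12 + r_e11)


def separation_index(r_e1: float, r_e2: float) -> float:
    """Relative pattern separation ``(rE2 - rE1)/(rE1 + rE2)`` in [-1, 1]."""
    if r_e1 < 0 or r_e2 < 0:
        raise ParameterError("rates must be non-negative")
    if r_e1 + r_e2 == 0:
        raise ParameterError("separation index undefined for two silent ensembles")
    return (r_e2 - r_e1) / (r_e1 + r_e2)


def decision_distance(x: float, y: float) -> float:
    """Distance of the activity point (rE1, rE2) from the diagonal boundary.

    ``L = sqrt(x^2+y^2) * sin(|45 deg - arcsin(x/sqrt(x^2+y^2))|)`` with the
    angles in degrees; algebraically identical to the perpendicular
    distance ``|x - y|/sqrt(2)``. Defined as 0 at the origin.
    """
    if x < 0 or y < 0:
        raise ParameterError("rates must be non-negative")
    r = math.hypot(x, y)
    if r == 0:
        return 0.0
    angle = abs(45.0 - math.degrees(math.asin(x / r)))
    return r * math.sin(math.radians(angle))


def amplification_index(peak_rate: float, input_strength: float) -> float:
    """Evoked peak rate divided by the driving input strength."""
    if input_strength <= 0:
        raise ParameterError("input strength must be positive")
    return peak_rate / input_strength


@dataclass
class TrajectoryFeatures:
    """Summary features of a stimulated trajectory.

    ``fixed_point`` is the mean rate over the middle 1 s of the (2 s)
    stimulation window; ``baseline`` the mean over the second preceding
    stimulus onset. ``onset_peak >= fixed_point`` is typical but not
    enforced.
    """

    onset_peak: float
    onset_time: float
    fixed_point: float
    baseline: float


def extract_features(
    t: np.ndarray,
    rate: np.ndarray,
    stim_window: Tuple[float, float],
) -> TrajectoryFeatures:
    """Extract onset-peak / fixed-point / baseline features of one rate series.

    The fixed point is averaged over the middle 1 s of the stimulation
    window (falling back to the central 50% with a warning for windows
    shorter than 1 s); the onset peak is the maximum over the window with
    ties broken to the earliest time.
    """
    t = np.asarray(t)
    rate = np.asarray(rate)
    t0, t1 = stim_window
    if t0 < t[0] or t1 > t[-1] + 1e-12:
        raise ParameterError("stimulation window outside trajectory span")
    span = t1 - t0
    sel = (t >= t0) & (t < t1)
    if not np.any(sel):
        raise ParameterError("empty stimulation window")
    seg, t_seg = rate[sel], t[sel]
    i_peak = int(np.argmax(seg))
    if span >= 1.0:
        mid0 = t0 + 0.5 * (span - 1.0)
        mid1 = t0 + 0.5 * (span + 1.0)
    else:
        warnings.warn(
            "stimulation window shorter than 1 s; using central 50% for the "
            "fixed-point average"
        )
        mid0, mid1 = t0 + 0.25 * span, t1 - 0.25 * span
    mid = (t >= mid0) & (t < mid1)
    base = (t >= t0 - 1.0) & (t < t0)
    return TrajectoryFeatures(
        onset_peak=float(seg[i_peak]),
        onset_time=float(t_seg[i_peak]),
        fixed_point=float(rate[mid].mean()),
        baseline=float(rate[base].mean()) if np.any(base) else float("nan"),
    )


def features_from_trajectory(
    trajectory: RateTrajectory, stim_window: Tuple[float, float]
) -> TrajectoryFeatures:
    """Convenience wrapper extracting features of a single-ensemble run."""
    return extract_features(trajectory.t, trajectory.r_e, stim_window)
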