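"""Config loading and tabular output.

Config files are YAML mappings using the conventional symbol names
(JEE, JEI, JIE, JII, alphaE, alphaI, tauE, tauI, gE, gI, rate_cap plus a
``mechanism`` block); time constants in configs are in milliseconds, as in
the published tables, and are converted to seconds on load.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .params import EnsembleWeights, GainParams, Mechanism, ParameterError, RateParams
from .rate import RateTrajectory

__all__ = ["load_config", "save_trajectory", "write_json"]


def _ms(value: float) -> float:
    return float(value) / 1000.0


def load_config(path: Union[str, Path]) -> dict:
    """Load a YAML parameter file into model objects.

    Returns a dict with keys ``weights``, ``params``, ``gain`` and
    ``mechanism`` (mechanism defaults to none).
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ParameterError("config must be a mapping")
    try:
        weights = EnsembleWeights(
            jee=float(raw["JEE"]),
            jei=float(raw["JEI"]),
            jie=float(raw["JIE"]),
            jii=float(raw["JII"]),
        )
    except KeyError as err:
        raise ParameterError(f"config missing weight field {err}") from err
    gain = GainParams(
        alpha_e=float(raw.get("alphaE", 2.0)), alpha_i=float(raw.get("alphaI", 2.0))
    )
    params = RateParams(
        tau_e=_ms(raw.get("tauE", 20.0)),
        tau_i=_ms(raw.get("tauI", 10.0)),
        g_e=float(raw.get("gE", 0.0)),
        g_i=float(raw.get("gI", 0.0)),
        rate_cap=(None if raw.get("rate_cap") is None else float(raw["rate_cap"])),
    )
    mech_raw = raw.get("mechanism", {"variant": "none"})
    variant = mech_raw.get("variant", "none")
    if variant == "sfa":
        mech = Mechanism.sfa(b=float(mech_raw["b"]), tau_a=_ms(mech_raw["taua"]))
    elif variant == "std":
        mech = Mechanism.std(u_d=float(mech_raw["Ud"]), tau_x=_ms(mech_raw["taux"]))
    elif variant == "stf":
        mech = Mechanism.stf(
            u_f=float(mech_raw["Uf"]),
            u_max=float(mech_raw["Umax"]),
            tau_u=_ms(mech_raw["tauu"]),
        )
    elif variant == "none":
        mech = Mechanism.none()
    else:
        raise ParameterError(f"unknown mechanism variant {variant!r}")
    return {"weights": weights, "params": params, "gain": gain, "mechanism": mech}


def save_trajectory(
    trajectory: RateTrajectory,
    path: Union[str, Path],
    provenance: Optional[dict] = None,
) -> Path:
    """Write a trajectory as CSV (t, rE, rI, aux) with a JSON sidecar."""
    path = Path(path)
    frame = pd.DataFrame(
        {
            "t": trajectory.t,
            "rE": trajectory.r_e,
            "rI": trajectory.r_i,
            "aux": (
                trajectory.aux
                if trajectory.aux is not None
                else np.full(len(trajectory.t), np.nan)
            ),
        }
    )
    frame.to_csv(path, index=False)
    sidecar = {
        "diverged": trajectory.diverged,
        "divergence_time": trajectory.divergence_time,
        "dt": trajectory.dt,
        "mechanism": asdict(trajectory.mechanism),
        "provenance": provenance or {},
    }
    write_json(sidecar, path.with_suffix(".json"))
    return path


def write_json(obj: dict, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, default=_jsonable))
    return path


def _jsonable(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    raise TypeError(f"not JSON serializable: {type(value)}")
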