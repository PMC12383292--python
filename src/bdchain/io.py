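"""Declarative config files, trajectory files and structured reports.

Configs are YAML with two sections: ``model`` (the 17 symbol-named
coefficient entries plus the delays) and an optional ``simulation``
section.  Unknown keys are hard errors: seventeen similarly named
coefficients invite silent typos.  Trajectories are plain delimited text
with the fixed header ``t,x1,x2,x3`` plus a YAML metadata sidecar
carrying the package version, seed, scheme, step and parameter hash.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coefficients import Coefficient, make_coefficient
from .integrate import SimulationConfig, Trajectory
from .model import COEFF_NAMES, ModelParameters, validate_params

__all__ = [
    "ConfigError",
    "params_to_dict",
    "params_from_dict",
    "write_config",
    "read_config",
    "write_trajectory",
    "read_trajectory",
    "write_metadata",
    "write_report",
]

_COEFF_KEYS = {"kind", "midline", "amplitude", "angular_rate"}
_SIM_KEYS = {
    "dt", "horizon", "seed", "scheme", "positivity_policy",
    "clamp_floor", "delay_interpolation",
}


class ConfigError(ValueError):
    """Malformed or incomplete configuration file."""


def _coeff_to_dict(c: Coefficient) -> dict:
    if c.kind == "generic":
        raise ConfigError("generic coefficients cannot be serialized to config files")
    out = {"kind": c.kind, "midline": c.midline, "amplitude": c.amplitude}
    if c.angular_rate != float(np.pi):
        out["angular_rate"] = c.angular_rate
    return out


def params_to_dict(params: ModelParameters) -> dict:
    return {
        "coefficients": {
            name: _coeff_to_dict(getattr(params, name)) for name in COEFF_NAMES
        },
        "tau1": params.tau1,
        "tau2": params.tau2,
    }


def params_from_dict(model: dict, context: str = "config") -> ModelParameters:
    if not isinstance(model, dict):
        raise ConfigError(f"{context}: model section must be a mapping")
    unknown = set(model) - {"coefficients", "tau1", "tau2"}
    if unknown:
        raise ConfigError(f"{context}: unknown model keys {sorted(unknown)}")
    entries = model.get("coefficients")
    if not isinstance(entries, dict):
        raise ConfigError(f"{context}: missing 'coefficients' mapping")
    unknown = set(entries) - set(COEFF_NAMES)
    if unknown:
        raise ConfigError(f"{context}: unknown coefficients {sorted(unknown)}")
    missing = set(COEFF_NAMES) - set(entries)
    if missing:
        raise ConfigError(f"{context}: missing coefficients {sorted(missing)}")
    coeffs = {}
    for name in COEFF_NAMES:
        spec = entries[name]
        if not isinstance(spec, dict):
            raise ConfigError(f"{context}: coefficient {name} must be a mapping")
        bad = set(spec) - _COEFF_KEYS
        if bad:
            raise ConfigError(f"{context}: coefficient {name} has unknown keys {sorted(bad)}")
        if "kind" not in spec:
            raise ConfigError(f"{context}: coefficient {name} needs a 'kind'")
        coeffs[name] = make_coefficient(
            spec["kind"],
            midline=float(spec.get("midline", 0.0)),
            amplitude=float(spec.get("amplitude", 0.0)),
            angular_rate=float(spec.get("angular_rate", np.pi)),
            name=name,
            allow_zero=name.startswith("sigma"),
        )
    return ModelParameters(
        **coeffs,
        tau1=float(model.get("tau1", 0.0)),
        tau2=float(model.get("tau2", 0.0)),
    )


def _sim_from_dict(section: dict, context: str) -> SimulationConfig:
    if not isinstance(section, dict):
        raise ConfigError(f"{context}: simulation section must be a mapping")
    unknown = set(section) - _SIM_KEYS
    if unknown:
        raise ConfigError(f"{context}: unknown simulation keys {sorted(unknown)}")
    cfg = SimulationConfig(**section)
    cfg.validate()
    return cfg


def write_config(
    path: Union[str, Path],
    params: ModelParameters,
    sim: Optional[SimulationConfig] = None,
) -> None:
    doc: dict = {"model": params_to_dict(params)}
    if sim is not None:
        doc["simulation"] = {
            "dt": sim.dt, "horizon": sim.horizon, "seed": sim.seed,
            "scheme": sim.scheme, "positivity_policy": sim.positivity_policy,
            "clamp_floor": sim.clamp_floor,
            "delay_interpolation": sim.delay_interpolation,
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_config(
    path: Union[str, Path],
) -> tuple[ModelParameters, Optional[SimulationConfig]]:
    """Parse and fully validate a config file; typos are errors."""
    p = Path(path)
    try:
        doc = yaml.safe_load(p.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{p}: not valid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"{p}: top level must be a mapping")
    unknown = set(doc) - {"model", "simulation"}
    if unknown:
        raise ConfigError(f"{p}: unknown top-level keys {sorted(unknown)}")
    if "model" not in doc:
        raise ConfigError(f"{p}: missing 'model' section")
    params = params_from_dict(doc["model"], context=str(p))
    problems = validate_params(params)
    if problems:
        raise ConfigError(f"{p}: invalid parameters: {'; '.join(problems)}")
    sim = None
    if "simulation" in doc:
        sim = _sim_from_dict(doc["simulation"], context=str(p))
    return params, sim


def write_trajectory(traj: Trajectory, path: Union[str, Path]) -> None:
    traj.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_trajectory(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = ["t", "x1", "x2", "x3"]
    if list(df.columns) != expected:
        raise ConfigError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    return df


def write_metadata(traj: Trajectory, path: Union[str, Path]) -> None:
    meta = {
        "package_version": __version__,
        "seed": traj.seed,
        "scheme": traj.scheme,
        "dt": traj.dt,
        "horizon": traj.horizon,
        "params_hash": traj.params_hash,
        "clamp_count": traj.clamp_count,
    }
    Path(path).write_text(yaml.safe_dump(meta, sort_keys=True))


def write_report(payload: dict, path: Union[str, Path]) -> None:
    """Machine-readable criteria report (JSON)."""
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
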