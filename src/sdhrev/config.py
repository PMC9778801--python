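"""Structured run configuration: YAML parameter/variant files and validation.

A run configuration resolves to exactly one parameter set and one
experiment.  Unknown keys are rejected by name so that typos in
hand-written configs fail loudly rather than silently running the basal
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .kinetics import ClampedEnvironment
from .params import (
    ConfigurationError,
    ParameterSet,
    build_base_parameters,
    cycle_residuals,
    make_variant,
)

__all__ = ["RunConfig", "load_config", "parameter_set_to_dict", "write_parameter_file"]

_ENV_KEYS = {"fum", "suc", "Hplus", "O2", "E_out"}
_GRID_KEYS = {"start", "stop", "step", "values"}
_EXPERIMENT_KINDS = {"simulate", "sweep", "titrate"}
_TOP_KEYS = {
    "label",
    "overrides",
    "environment",
    "experiment",
    "grid",
    "fum_grid",
    "eout_set",
    "pool_totals",
    "seed",
    "output",
}


@dataclass
class RunConfig:
    """A fully validated run request."""

    label: str = "basal"
    overrides: dict[str, float] = field(default_factory=dict)
    environment: ClampedEnvironment = field(default_factory=ClampedEnvironment)
    experiment: str = "simulate"
    grid: np.ndarray | None = None
    fum_grid: np.ndarray | None = None
    eout_set: tuple[float, ...] | None = None
    pool_totals: dict[str, float] | None = None
    seed: int = 0
    output: str | None = None

    def parameter_set(self) -> ParameterSet:
        base = build_base_parameters()
        if self.pool_totals:
            from dataclasses import replace

            pools = dict(base.pool_totals)
            pools.update(self.pool_totals)
            base = replace(base, pool_totals=pools)
        return make_variant(base, self.overrides, label=self.label)


def _check_keys(mapping: dict, allowed: set[str], context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        name = sorted(unknown)[0]
        raise ConfigurationError(f"unknown key {context}.{name}" if context else f"unknown key {name!r}")


def _parse_grid(spec, context: str) -> np.ndarray:
    if isinstance(spec, (list, tuple)):
        return np.asarray(spec, float)
    if isinstance(spec, dict):
        _check_keys(spec, _GRID_KEYS, context)
        if "values" in spec:
            return np.asarray(spec["values"], float)
        start, stop, step = spec["start"], spec["stop"], spec["step"]
        return np.arange(start, stop + np.sign(step) * 1e-9, step)
    raise ConfigurationError(f"{context} must be a list or start/stop/step mapping")


def load_config(source: str | Path | dict) -> RunConfig:
    """Parse and validate a YAML run configuration (path, text, or mapping)."""
    if isinstance(source, dict):
        raw = source
    else:
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigurationError("configuration must be a mapping")
    _check_keys(raw, _TOP_KEYS, "")

    env_raw = raw.get("environment", {}) or {}
    _check_keys(env_raw, _ENV_KEYS, "environment")
    env = ClampedEnvironment(**{k: float(v) for k, v in env_raw.items()})

    overrides = {str(k): float(v) for k, v in (raw.get("overrides") or {}).items()}
    pool_totals = raw.get("pool_totals")
    if pool_totals is not None:
        pool_totals = {str(k): float(v) for k, v in pool_totals.items()}
        for name, total in pool_totals.items():
            if total <= 0:
                raise ConfigurationError(f"pool_totals.{name} must be positive")

    experiment = str(raw.get("experiment", "simulate"))
    if experiment not in _EXPERIMENT_KINDS:
        raise ConfigurationError(
            f"experiment must be one of {sorted(_EXPERIMENT_KINDS)}, got {experiment!r}"
        )

    cfg = RunConfig(
        label=str(raw.get("label", "basal")),
        overrides=overrides,
        environment=env,
        experiment=experiment,
        grid=_parse_grid(raw["grid"], "grid") if "grid" in raw else None,
        fum_grid=_parse_grid(raw["fum_grid"], "fum_grid") if "fum_grid" in raw else None,
        eout_set=tuple(float(v) for v in raw["eout_set"]) if "eout_set" in raw else None,
        pool_totals=pool_totals,
        seed=int(raw.get("seed", 0)),
        output=raw.get("output"),
    )
    cfg.parameter_set()  # validates overrides and detailed balance eagerly
    return cfg


def parameter_set_to_dict(ps: ParameterSet) -> dict:
    """Flat serializable view of a parameter set, units in the key names."""
    out = {
        "label": ps.label,
        "thermal_voltage_mV": ps.constants.thermal_voltage_mV,
        "alpha": ps.constants.alpha,
        "flux_conversion_pmol_per_min_mg_per_uM_s": ps.constants.flux_conversion,
        "sod_Vmax21_uM_per_s": ps.sod_Vmax21,
        "sod_Km21_uM": ps.sod_Km21,
        "k22_per_s": ps.k22,
    }
    for name, total in ps.pool_totals.items():
        out[f"pool_{name}_uM"] = total
    for i in range(1, 21):
        out[f"k{i}"] = ps.k[i]
        out[f"keq{i}"] = ps.keq[i]
    for i, v in ps.k_rev.items():
        out[f"kminus{i}"] = v
    out["cycle_residuals"] = list(cycle_residuals(ps))
    return out


def write_parameter_file(ps: ParameterSet, path: str | Path) -> None:
    """Dump a parameter set as YAML (flat keys, full double precision)."""
    with open(path, "w") as fh:
        yaml.safe_dump(parameter_set_to_dict(ps), fh, sort_keys=False)
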