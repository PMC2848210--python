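"""YAML run configuration: one section per pipeline stage, strict keys.

Unknown keys anywhere in the file are rejected with a message naming the
offending section, so typos never silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .assay import CELL_LINE_PROFILES, CompartmentParams, GateSpec, Bounds
from .oscillator import OscillatorParams, StimulusProfile
from .population import HeterogeneitySpec, PopulationConfig
from .synthetic import FieldSpec, IntensityParams

__all__ = ["RunConfig", "ConfigError", "load_config", "config_hash"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class AssayConfig:
    compartments: CompartmentParams = field(default_factory=CompartmentParams)
    gates: GateSpec = field(default_factory=GateSpec)
    min_area_px: int = 20
    cell_line: str | None = None

    def __post_init__(self) -> None:
        if self.cell_line is not None and self.cell_line not in CELL_LINE_PROFILES:
            raise ConfigError(
                f"unknown cell line {self.cell_line!r}; known: {sorted(CELL_LINE_PROFILES)}"
            )


@dataclass(frozen=True)
class TraceAnalysisConfig:
    smooth_window: int = 3
    min_prominence: float = 0.2
    min_separation_min: float = 20.0


@dataclass(frozen=True)
class SimulationConfig:
    stimulus: StimulusProfile = field(default_factory=StimulusProfile)
    t_end_min: float = 600.0
    dt_min: float = 1.0


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    out_dir: str = "transloc_out"
    synthetic: FieldSpec = field(default_factory=FieldSpec)
    fields_per_well: int = 4
    wells: tuple[str, ...] = ("A1",)
    assay: AssayConfig = field(default_factory=AssayConfig)
    oscillator: OscillatorParams = field(default_factory=OscillatorParams)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    traces: TraceAnalysisConfig = field(default_factory=TraceAnalysisConfig)

    def compartment_params(self) -> CompartmentParams:
        """Assay compartment geometry, honoring a cell-line profile if set."""
        if self.assay.cell_line is not None:
            return CompartmentParams(**CELL_LINE_PROFILES[self.assay.cell_line])
        return self.assay.compartments


_NESTED = {
    "synthetic": FieldSpec,
    "assay": AssayConfig,
    "oscillator": OscillatorParams,
    "simulation": SimulationConfig,
    "population": PopulationConfig,
    "traces": TraceAnalysisConfig,
    "intensity": IntensityParams,
    "compartments": CompartmentParams,
    "gates": GateSpec,
    "heterogeneity": HeterogeneitySpec,
    "stimulus": StimulusProfile,
}

_TUPLE_KEYS = {"nucleus_radius_px", "tau_bounds", "k_deg_bounds", "wells"}
_BOUNDS_KEYS = {"r01_perimeter", "r01_circularity", "r02_intensity", "r02_sd"}


def _build(cls: type, data: Mapping[str, Any], section: str) -> Any:
    if not isinstance(data, Mapping):
        raise ConfigError(f"section {section!r} must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section {section!r}")
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        sub = _NESTED.get(key)
        if sub is not None and isinstance(value, Mapping):
            kwargs[key] = _build(sub, value, f"{section}.{key}")
        elif key in _BOUNDS_KEYS:
            if not isinstance(value, (list, tuple)) or len(value) != 2:
                raise ConfigError(f"{section}.{key} must be a [lo, hi] pair")
            lo = -float("inf") if value[0] is None else float(value[0])
            hi = float("inf") if value[1] is None else float(value[1])
            kwargs[key] = Bounds(lo, hi)
        elif key in _TUPLE_KEYS and isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section {section!r}: {exc}") from exc


def load_config(path: str | Path | None = None, overrides: Mapping[str, Any] | None = None) -> RunConfig:
    """Load a RunConfig from YAML (missing file sections use defaults)."""
    data: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError("top-level config must be a mapping")
        data.update(raw)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    return _build(RunConfig, data, "<root>")


def config_hash(config: RunConfig) -> str:
    """Stable hash of a config for the run manifest."""

    def encode(obj: Any) -> Any:
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        if isinstance(obj, float) and obj in (float("inf"), -float("inf")):
            return str(obj)
        return obj

    blob = json.dumps(encode(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
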