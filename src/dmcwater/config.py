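"""Run configuration: one TOML file describing a complete, reproducible run.

Unknown keys are rejected — a config is the canonical record of what was
simulated, so silent typos are format errors.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .dielectric import DielectricParams
from .dynamics import SimConfig

__all__ = ["RunConfig", "load_run_config", "CONFIG_SCHEMA"]


@dataclass(frozen=True)
class RunConfig:
    """Simulation block + paths + dielectric overrides + observable requests."""

    sim: SimConfig = field(default_factory=SimConfig)
    dielectric: DielectricParams = field(default_factory=DielectricParams)
    table_path: str | None = None      # None → packaged default table
    output_dir: str = "."
    log_level: str = "info"


_SIM_FIELDS = {f.name for f in dataclasses.fields(SimConfig)}
_DIEL_FIELDS = {f.name for f in dataclasses.fields(DielectricParams)}
_TOP_FIELDS = {"sim", "dielectric", "table_path", "output_dir", "log_level"}

CONFIG_SCHEMA = {
    "sim": sorted(_SIM_FIELDS),
    "dielectric": sorted(_DIEL_FIELDS),
    "top-level": sorted(_TOP_FIELDS),
}


def load_run_config(path) -> RunConfig:
    """Parse and schema-validate a TOML run configuration."""
    raw = tomllib.loads(Path(path).read_text())
    unknown = set(raw) - _TOP_FIELDS
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    sim_raw = dict(raw.get("sim", {}))
    unknown = set(sim_raw) - _SIM_FIELDS
    if unknown:
        raise ValueError(f"unknown [sim] config keys: {sorted(unknown)}")
    if "snapshot_times" in sim_raw:
        sim_raw["snapshot_times"] = tuple(sim_raw["snapshot_times"])
    diel_raw = dict(raw.get("dielectric", {}))
    unknown = set(diel_raw) - _DIEL_FIELDS
    if unknown:
        raise ValueError(f"unknown [dielectric] config keys: {sorted(unknown)}")
    if "components" in diel_raw:
        diel_raw["components"] = tuple(
            tuple(c) for c in diel_raw["components"]
        )
    return RunConfig(
        sim=SimConfig(**sim_raw),
        dielectric=DielectricParams(**diel_raw),
        table_path=raw.get("table_path"),
        output_dir=raw.get("output_dir", "."),
        log_level=raw.get("log_level", "info"),
    )
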