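"""Run configuration: the method's constants in one place.

Precedence: built-in defaults < config file < command-line flags.  The config
file is a flat ``key = value`` text file; keys match the dataclass fields.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline, with the method's defaults."""

    atom_mode: str = "CA"
    network_cutoff: float = 8.5       # Å, residue-contact edge threshold
    contact_distance: float = 15.0    # Å, docking-interface definition d
    rel_asa_threshold: float = 0.001  # relative ASA > 0.1% marks surface
    near_native_rmsd: float = 10.0    # Å, strict upper bound
    true_interface_cutoff: float = 10.0  # Å, any-atom rule on the complex
    weight_grid_lo: float = 0.0
    weight_grid_hi: float = 2.0
    weight_grid_step: float = 0.05
    default_weight: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "network_cutoff",
            "contact_distance",
            "rel_asa_threshold",
            "near_native_rmsd",
            "true_interface_cutoff",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def weight_grid(self) -> tuple[float, float, float]:
        return (self.weight_grid_lo, self.weight_grid_hi, self.weight_grid_step)

    def describe(self) -> str:
        return " ".join(
            f"{f.name}={getattr(self, f.name)}" for f in dataclasses.fields(self)
        )


_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(RunConfig)}


def _coerce(name: str, raw: str) -> Any:
    ftype = _FIELD_TYPES[name]
    if ftype in ("int", int):
        return int(raw)
    if ftype in ("float", float):
        return float(raw)
    return raw


def load_config(
    path: Optional[str | Path] = None, overrides: Optional[dict[str, Any]] = None
) -> RunConfig:
    """Defaults, overlaid by a flat key=value file, overlaid by overrides."""
    values: dict[str, Any] = {}
    if path is not None:
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, raw = (part.strip() for part in line.split("=", 1))
            if key not in _FIELD_TYPES:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            values[key] = _coerce(key, raw)
    if overrides:
        for key, val in overrides.items():
            if val is not None:
                logger.info("CLI override: %s=%s", key, val)
                values[key] = val
    return RunConfig(**values)
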