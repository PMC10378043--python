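"""Run configuration: every clinical threshold the pipeline uses, in one place."""

from __future__ import annotations

import json
import tomllib
from dataclasses import asdict, dataclass, fields
from pathlib import Path

from .agreement import EPSILON_MM
from .classify import ASYMMETRY_MM, SEVERITY_EDGES_MM, VM_THRESHOLD_MM


@dataclass
class RunConfig:
    mode: str = "minrect"                 # minrect | plexus_margin | auto
    epsilon_mm: float = EPSILON_MM        # agreement error threshold
    vm_threshold_mm: float = VM_THRESHOLD_MM
    severity_edges_mm: tuple[float, float, float] = SEVERITY_EDGES_MM
    asymmetry_mm: float = ASYMMETRY_MM
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.mode not in ("minrect", "plexus_margin", "auto"):
            raise ValueError(f"unknown measurement mode {self.mode!r}")
        for name in ("epsilon_mm", "vm_threshold_mm", "asymmetry_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.severity_edges_mm = tuple(float(e) for e in self.severity_edges_mm)
        if len(self.severity_edges_mm) != 3 or not (
                self.severity_edges_mm[0] < self.severity_edges_mm[1]
                < self.severity_edges_mm[2]):
            raise ValueError(
                f"severity_edges_mm not increasing: {self.severity_edges_mm}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["severity_edges_mm"] = list(self.severity_edges_mm)
        return d


def load_config(path=None) -> RunConfig:
    """Load a TOML or JSON config file; absent keys take defaults, unknown keys fail."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    else:
        with open(path) as fh:
            raw = json.load(fh)
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**raw)


__all__ = ["RunConfig", "load_config"]
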