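"""Run configuration: validation, TOML loading, and output provenance.

Every CLI run resolves its configuration (file values overridden by
flags), validates it, and writes the fully resolved config as JSON next
to its outputs so any run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .biophysical import BioParams, load_calibration
from .minimal import MinimalParams

__all__ = ["RunConfig", "ConfigError", "grid_from_spec"]


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending field."""


#: default sweep grids per model: (start, stop, step) for (AMPA, NMDA)
DEFAULT_GRIDS = {
    "minimal": {"ga": (0.0, 0.06, 0.002), "gn": (0.0, 1.2, 0.02)},
    "biophysical": {"ga": (0.0, 0.4, 0.02), "gn": (0.0, 12.0, 0.25)},
}


def grid_from_spec(spec: tuple[float, float, float]) -> np.ndarray:
    """Inclusive arange from a (start, stop, step) triple."""
    start, stop, step = spec
    if step <= 0 or stop < start:
        raise ConfigError(f"grid spec must have step > 0 and stop >= start, got {spec}")
    n = int(round((stop - start) / step))
    return start + step * np.arange(n + 1)


@dataclass
class RunConfig:
    """Resolved configuration of one CLI run."""

    model: str = "minimal"
    g_ampa: float = 0.0
    g_nmda: float = 0.0
    duration: Optional[float] = None  #: native units (s / ms); None -> default
    transient: Optional[float] = None
    rtol: float = 1e-8
    atol: float = 1e-10
    sample_dt: Optional[float] = None
    ga_grid: Optional[tuple[float, float, float]] = None
    gn_grid: Optional[tuple[float, float, float]] = None
    ratio: Optional[float] = None
    out_dir: str = "daneuron_out"
    make_figures: bool = True
    calibration: Optional[str] = None  #: path to a biophysical TOML override
    param_overrides: dict = field(default_factory=dict)
    #: kept for interface stability; the models are deterministic
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("minimal", "biophysical"):
            raise ConfigError(f"model: must be 'minimal' or 'biophysical', got {self.model!r}")
        for name in ("g_ampa", "g_nmda"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: must be non-negative")
        if self.duration is not None and self.duration <= 0:
            raise ConfigError("duration: must be positive")
        if self.rtol <= 0 or self.atol <= 0:
            raise ConfigError("rtol/atol: must be positive")
        if self.ga_grid is None:
            self.ga_grid = DEFAULT_GRIDS[self.model]["ga"]
        if self.gn_grid is None:
            self.gn_grid = DEFAULT_GRIDS[self.model]["gn"]

    @classmethod
    def from_sources(cls, config_path: Optional[str], **flags) -> "RunConfig":
        """Build from an optional TOML file merged with CLI flags.

        Flag values override file values; ``None`` flags are ignored.
        """
        values: dict = {}
        if config_path:
            try:
                with open(config_path, "rb") as fh:
                    raw = tomllib.load(fh)
            except tomllib.TOMLDecodeError as exc:
                raise ConfigError(f"config file: invalid TOML ({exc})") from exc
            table = raw.get("run", raw)
            known = {f_.name for f_ in fields(cls)}
            unknown = set(table) - known
            if unknown:
                raise ConfigError(f"config file: unknown keys {sorted(unknown)}")
            for key, val in table.items():
                if key in ("ga_grid", "gn_grid") and val is not None:
                    val = tuple(val)
                values[key] = val
        for key, val in flags.items():
            if val is not None:
                values[key] = val
        return cls(**values)

    def params(self):
        """Materialize the model parameter set for this run."""
        if self.model == "minimal":
            base = MinimalParams()
            over = dict(self.param_overrides)
            over.update(g_a=self.g_ampa, g_n=self.g_nmda)
        else:
            base = (
                load_calibration(self.calibration)
                if self.calibration
                else BioParams()
            )
            over = dict(self.param_overrides)
            over.update(gbar_ampa=self.g_ampa, gbar_nmda=self.g_nmda)
        try:
            return base.replace(**over)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"param_overrides: {exc}") from exc

    def solver_settings(self):
        from .dynamics import SolverSettings

        return SolverSettings(
            rtol=self.rtol, atol=self.atol, sample_dt=self.sample_dt
        )

    def resolved(self) -> dict:
        out = dataclasses.asdict(self)
        out["tool_version"] = __version__
        return out

    def write_resolved(self, out_dir: Path) -> Path:
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "run_config.json"
        path.write_text(json.dumps(self.resolved(), indent=2, default=list) + "\n")
        return path
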