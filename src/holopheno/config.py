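"""Run configuration: a single YAML file drives the whole pipeline.

Every threshold and convention used by the analysis stages (bin width,
IQR fence multiplier, per-bin test, alpha levels, daily window, permutation
count) is surfaced here so a full paper-style run is one config.  Unknown
keys are rejected with the offending key named.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .design import (
    EnvParams,
    ExperimentDesign,
    OtuParams,
    PhysiologyParams,
    SimulationParams,
    YieldParams,
)

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]

_PARAM_BLOCKS = {
    "env": EnvParams,
    "physiology": PhysiologyParams,
    "otu": OtuParams,
    "yields": YieldParams,
}


class ConfigError(ValueError):
    """A run configuration violates the schema."""


@dataclass
class RunConfig:
    """Validated pipeline configuration with documented defaults."""

    out_dir: str = "holopheno_out"
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "env", "physio", "agro", "micro")
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    params: SimulationParams = field(default_factory=SimulationParams)
    # analysis conventions
    bin_width_min: int = 30
    iqr_k: float = 1.5
    alpha: float = 0.05
    test: str = "student"  # student | welch | mannwhitney
    bh: bool = False
    window: tuple[str, str] = ("10:00", "16:00")
    sapflow_window_das: tuple[int, int] = (77, 83)
    granier: bool = False
    kw_mode: str = "auto"  # auto | exact | chi2
    n_perm: int = 999
    write_raw: bool = False
    # pre-existing inputs when the simulate stage is disabled
    env_log: str | None = None
    plant_log: str | None = None
    otu_counts: str | None = None
    otu_meta: str | None = None
    yield_table: str | None = None

    def __post_init__(self) -> None:
        known = {"simulate", "env", "physio", "agro", "micro"}
        bad = set(self.stages) - known
        if bad:
            raise ConfigError(f"unknown stages: {sorted(bad)}")
        if self.test not in {"student", "welch", "mannwhitney"}:
            raise ConfigError(f"unknown test {self.test!r}")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if "simulate" not in self.stages:
            needed = {
                "env": ["env_log"],
                "physio": ["plant_log"],
                "agro": ["yield_table"],
                "micro": ["otu_counts", "otu_meta"],
            }
            for stage, paths in needed.items():
                if stage in self.stages:
                    for p in paths:
                        if getattr(self, p) is None:
                            raise ConfigError(
                                f"stage {stage!r} without the simulate stage "
                                f"requires input path {p!r}"
                            )


def _build(cls, payload: dict, context: str):
    if not isinstance(payload, dict):
        raise ConfigError(f"{context} must be a mapping")
    names = {f.name for f in fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise ConfigError(f"unknown key {sorted(unknown)[0]!r} in {context}")
    coerced = {}
    for key, val in payload.items():
        if isinstance(val, list):
            val = tuple(val)
        elif isinstance(val, dict):
            # cell-keyed maps round-trip through "hybrid/inoculation/regime"
            val = {
                (tuple(k.split("/")) if isinstance(k, str) and "/" in k else k): v
                for k, v in val.items()
            }
        coerced[key] = val
    return cls(**coerced)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    top_names = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - top_names
    if unknown:
        raise ConfigError(f"unknown key {sorted(unknown)[0]!r} in config")
    payload = dict(raw)
    if "design" in payload:
        payload["design"] = _build(ExperimentDesign, payload["design"], "design")
    if "params" in payload:
        blocks = payload["params"]
        if not isinstance(blocks, dict):
            raise ConfigError("params must be a mapping")
        unknown = set(blocks) - set(_PARAM_BLOCKS)
        if unknown:
            raise ConfigError(f"unknown key {sorted(unknown)[0]!r} in params")
        built = {
            name: _build(_PARAM_BLOCKS[name], block, f"params.{name}")
            for name, block in blocks.items()
        }
        payload["params"] = SimulationParams(**built)
    for key in ("stages", "window", "sapflow_window_das"):
        if key in payload and isinstance(payload[key], list):
            payload[key] = tuple(payload[key])
    return RunConfig(**payload)


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {
            ("/".join(k) if isinstance(k, tuple) else k): _as_plain(v)
            for k, v in obj.items()
        }
    return obj


def save_config(config: RunConfig, path) -> None:
    """Serialise a RunConfig to YAML (tuple-keyed maps use 'a/b/c' keys)."""
    payload = {
        f.name: _as_plain(getattr(config, f.name)) for f in fields(RunConfig)
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
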