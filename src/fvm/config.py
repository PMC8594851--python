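"""Run configuration: validation, YAML round-trip, presets.

A :class:`RunConfig` bundles the force-law parameters, the
initial-condition spec, the stop criteria and the declared output
paths.  Configs serialize to a YAML file whose sections mirror the
dataclasses; :func:`parse_config` rejects unknown keys and reports
schema violations with their key paths.  Flag-style overrides passed to
:func:`parse_config` win over file values.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any, Optional

import yaml

from .engine import StopCriteria
from .initialization import (
    DistSpec,
    InitSpec,
    Injection,
    RingGeometry,
    SquareGeometry,
    TriangleGeometry,
    standard_spec,
)
from .model_core import ForceMode, ModelParams

__all__ = ["OutputSpec", "RunConfig", "parse_config", "standard_conditions"]

_GEOMETRY_TYPES = {
    "square": SquareGeometry,
    "triangle": TriangleGeometry,
    "ring": RingGeometry,
}


@dataclass(frozen=True)
class OutputSpec:
    """Declared output paths; data goes only to these, logs to stderr."""

    summary: Optional[str] = None
    step_log: Optional[str] = None
    trajectory: Optional[str] = None
    snapshot_fractions: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "snapshot_fractions", tuple(self.snapshot_fractions)
        )
        for f in self.snapshot_fractions:
            if not 0 < f <= 1:
                raise ValueError("snapshot fractions must be in (0, 1]")


@dataclass(frozen=True)
class RunConfig:
    model: ModelParams = field(default_factory=ModelParams)
    init: InitSpec = field(default_factory=InitSpec)
    stop: StopCriteria = field(default_factory=StopCriteria)
    outputs: OutputSpec = field(default_factory=OutputSpec)
    adaptive: bool = True
    record_trajectory: bool = False
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model"]["force_mode"] = self.model.force_mode.value
        if self.init.geometry is not None:
            kind = {v: k for k, v in _GEOMETRY_TYPES.items()}[
                type(self.init.geometry)
            ]
            d["init"]["geometry"] = {"kind": kind, **asdict(self.init.geometry)}
        d["init"]["spatial"] = [asdict(s) for s in self.init.spatial]
        d["init"]["mass"] = asdict(self.init.mass)
        d["init"]["injections"] = [asdict(i) for i in self.init.injections]
        d["outputs"]["snapshot_fractions"] = list(
            self.outputs.snapshot_fractions
        )
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _build(cls, section: dict, path: str):
    """Construct a dataclass from a dict, rejecting unknown keys."""
    allowed = set(cls.__dataclass_fields__)
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) at {path}: {sorted(unknown)}")
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config at {path}: {exc}") from exc


def _parse_init(section: dict) -> InitSpec:
    section = dict(section)
    if "spatial" in section:
        section["spatial"] = tuple(
            _build(DistSpec, dict(s), "init.spatial") for s in section["spatial"]
        )
    if "mass" in section:
        section["mass"] = _build(DistSpec, dict(section["mass"]), "init.mass")
    if "injections" in section:
        section["injections"] = tuple(
            _build(Injection, dict(i) | {"position": tuple(dict(i)["position"])},
                   "init.injections")
            for i in section["injections"]
        )
    geom = section.get("geometry")
    if geom is not None:
        geom = dict(geom)
        kind = geom.pop("kind", None)
        if kind not in _GEOMETRY_TYPES:
            raise ValueError(f"invalid config at init.geometry.kind: {kind!r}")
        section["geometry"] = _build(
            _GEOMETRY_TYPES[kind], geom, f"init.geometry({kind})"
        )
    return _build(InitSpec, section, "init")


def _parse_model(section: dict) -> ModelParams:
    section = dict(section)
    if "metric_weights" in section and section["metric_weights"] is not None:
        section["metric_weights"] = tuple(section["metric_weights"])
    if "force_mode" in section:
        try:
            section["force_mode"] = ForceMode(section["force_mode"])
        except ValueError as exc:
            raise ValueError(f"invalid config at model.force_mode: {exc}")
    return _build(ModelParams, section, "model")


def parse_config(
    path: str | Path | None = None,
    overrides: dict[str, Any] | None = None,
    preset: str | None = None,
) -> RunConfig:
    """Load and validate a RunConfig.

    ``preset='standard'`` starts from the Standard Conditions; a config
    file layers on top of the preset, and ``overrides`` (dotted keys
    such as ``'model.aib'``) win over both.
    """
    data: dict[str, Any] = {}
    if preset is not None:
        if preset != "standard":
            raise ValueError(f"unknown preset {preset!r}")
        data = standard_conditions().to_dict()
        for k in ("outputs", "adaptive", "record_trajectory", "log_level"):
            data.pop(k, None)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must contain a mapping")
        for key, val in loaded.items():
            if isinstance(val, dict) and isinstance(data.get(key), dict):
                data[key] = data[key] | val
            else:
                data[key] = val
    for dotted, value in (overrides or {}).items():
        parts = dotted.split(".")
        node = data
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = value

    known = {"model", "init", "stop", "outputs", "adaptive",
             "record_trajectory", "log_level"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")

    return RunConfig(
        model=_parse_model(data.get("model", {})),
        init=_parse_init(data.get("init", {})),
        stop=_build(StopCriteria, data.get("stop", {}), "stop"),
        outputs=_build(OutputSpec, {
            **data.get("outputs", {}),
            **({"snapshot_fractions": tuple(data["outputs"]["snapshot_fractions"])}
               if "snapshot_fractions" in data.get("outputs", {}) else {}),
        }, "outputs"),
        adaptive=bool(data.get("adaptive", True)),
        record_trajectory=bool(data.get("record_trajectory", False)),
        log_level=str(data.get("log_level", "INFO")),
    )


def standard_conditions(
    aib: float = 280.0,
    seed: int = 0,
    n_agents: int = 100,
    tickstop: int = 0,
    agent_stop: int = 0,
    dt_stop: float = 0.0,
    **model_overrides,
) -> RunConfig:
    """Standard Conditions config: the baseline study conditions."""
    return RunConfig(
        model=ModelParams(aib=aib, **model_overrides),
        init=standard_spec(seed=seed, n_agents=n_agents),
        stop=StopCriteria(
            tickstop=tickstop, agent_stop=agent_stop, dt_stop=dt_stop
        ),
    )
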