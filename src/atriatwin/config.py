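"""YAML run configuration with strict (unknown-keys-are-errors) parsing."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .labeling import FiberRule, StructureRules
from .synthgeo import GeometryConfig, OrificeSpec, TorsoConfig
from .uac import UACNormConfig

SCHEMA_VERSION = 1


def _build(cls, data: dict, section: str):
    valid = {f.name for f in fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in config section {section!r}")
    return cls(**data)


@dataclass
class SimulationConfig:
    duration_ms: float = 150.0
    dt_ms: float = 1.0
    low_pass_hz: float = 150.0
    high_pass_hz: float = 0.5
    scale: float = 0.2
    eikonal_tol_ms: float = 1e-3
    cable_velocity: float = 1.5     # m/s, tuned for physiologic inter-atrial delay
    retrograde_cables: bool = True


@dataclass
class CalibrationConfig:
    n_samples: int = 64
    seed: int = 1
    scheme: str = "sobol"
    lowpass_hz: float = 60.0
    n_san: int = 2
    n_bb: int = 2
    with_pc: bool = True


@dataclass
class RunConfig:
    """Top-level configuration for the CLI pipeline stages."""

    version: int = SCHEMA_VERSION
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    torso: TorsoConfig = field(default_factory=TorsoConfig)
    structures: StructureRules = field(default_factory=StructureRules)
    fibers: FiberRule = field(default_factory=FiberRule)
    uac: UACNormConfig = field(default_factory=UACNormConfig)
    velocities: dict = field(default_factory=dict)   # region -> [v_l, v_t]
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        version = data.pop("version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {version}")
        sections = {
            "geometry": GeometryConfig, "torso": TorsoConfig,
            "structures": StructureRules, "fibers": FiberRule,
            "uac": UACNormConfig, "simulation": SimulationConfig,
            "calibration": CalibrationConfig,
        }
        kwargs = {"version": version}
        for name, klass in sections.items():
            sub = data.pop(name, {})
            if name == "geometry":
                for key in ("ra_orifices", "la_orifices", "appendages"):
                    if key in sub:
                        sub[key] = {k: OrificeSpec(**v) if isinstance(v, dict) else v
                                    for k, v in sub[key].items()}
                if "fo_patch" in sub and isinstance(sub["fo_patch"], dict):
                    sub["fo_patch"] = OrificeSpec(**sub["fo_patch"])
                for key in ("la_semi_axes", "ra_semi_axes", "atria"):
                    if key in sub:
                        sub[key] = tuple(sub[key])
            if name == "torso":
                for key in ("semi_axes", "center"):
                    if key in sub:
                        sub[key] = tuple(sub[key])
            kwargs[name] = _build(klass, sub, name)
        kwargs["velocities"] = {k: tuple(v) for k, v in data.pop("velocities", {}).items()}
        if data:
            raise ValueError(f"unknown top-level config key(s) {sorted(data)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path=None) -> str:
        def clean(o):
            if isinstance(o, dict):
                return {k: clean(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [clean(v) for v in o]
            return o

        text = yaml.safe_dump(clean(asdict(self)), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text
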