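"""Run configuration: a single YAML document covering simulator, controller
and analysis settings, with the published default parameters built in."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .errors import ParameterError
from .phase import BoutParams, HeelStrikeConfig, HptParams
from .reflex import SrcParams
from .synth import GaitParams

CONTROLLERS = ("src", "hpt")


def _asdict(obj) -> dict:
    if dataclasses.is_dataclass(obj):
        return {f.name: _asdict(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    return obj


def _build(cls, data: dict | None, nested: dict | None = None):
    data = dict(data or {})
    for key, sub_cls in (nested or {}).items():
        if key in data and isinstance(data[key], dict):
            data[key] = sub_cls(**data[key])
    try:
        return cls(**data)
    except TypeError as exc:
        raise ParameterError(f"invalid {cls.__name__} block: {exc}") from exc


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    controller: str = "src"
    duration: float = 30.0  # s of simulated walking
    seed: int = 0
    gait: GaitParams = field(default_factory=GaitParams)
    src: SrcParams = field(default_factory=SrcParams)
    hpt: HptParams = field(default_factory=HptParams)
    analyze_mech: bool = True
    analyze_ilm: bool = True
    outdir: str = "exoassist_out"

    def __post_init__(self) -> None:
        if self.controller not in CONTROLLERS:
            raise ParameterError(
                f"unknown controller '{self.controller}'; expected one of "
                f"{CONTROLLERS}")

    def to_dict(self) -> dict:
        d = _asdict(self)
        d["gait"]["noise_sd"] = dict(self.gait.noise_sd or {})
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)  # where results go does not change what they are
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        gait = _build(GaitParams, data.pop("gait", None))
        src = _build(SrcParams, data.pop("src", None))
        hpt = _build(HptParams, data.pop("hpt", None), nested={
            "extension_bout": BoutParams,
            "flexion_bout": BoutParams,
            "hs_config": HeelStrikeConfig,
        })
        try:
            return cls(gait=gait, src=src, hpt=hpt, **data)
        except TypeError as exc:
            raise ParameterError(f"invalid config: {exc}") from exc

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ParameterError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
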