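"""Pipeline configuration: defaults, YAML loading and validation.

Unknown keys are rejected so a typo in a config file fails loudly instead
of silently falling back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from cineclust.phantom import LesionSpec, PhantomConfig
from cineclust.regularizers import LOSS_TERMS, CurriculumSchedule

CONFIG_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class FlowSettings:
    n_levels: int = 3
    iterations: int = 50
    smoothness: float = 15.0

    def validate(self) -> None:
        if self.n_levels < 1:
            raise ValueError("flow.n_levels must be >= 1")
        if self.iterations < 1:
            raise ValueError("flow.iterations must be >= 1")
        if self.smoothness <= 0:
            raise ValueError("flow.smoothness must be > 0")


@dataclass(frozen=True)
class Stc2Settings:
    sigma: float = 1.5
    eps: float = 2.5
    min_samples: int = 5
    k: int = 6
    lambda_s: float = 0.5
    lambda_t: float = 0.5
    energy_quantile: float = 0.8
    neighbor_radius: int = 3
    max_nodes: int = 20000

    def validate(self) -> None:
        if self.sigma <= 0:
            raise ValueError("stc2.sigma must be > 0")
        if self.eps <= 0:
            raise ValueError("stc2.eps must be > 0")
        if self.min_samples < 1:
            raise ValueError("stc2.min_samples must be >= 1")
        if self.k < 2:
            raise ValueError("stc2.k must be >= 2")
        if self.lambda_s < 0 or self.lambda_t < 0:
            raise ValueError("stc2.lambda_s/lambda_t must be >= 0")
        if self.lambda_s == 0 and self.lambda_t == 0:
            raise ValueError("stc2.lambda_s and lambda_t must not both be 0")
        if not 0 < self.energy_quantile <= 1:
            raise ValueError("stc2.energy_quantile must be in (0, 1]")
        if self.neighbor_radius < 1:
            raise ValueError("stc2.neighbor_radius must be >= 1")


@dataclass(frozen=True)
class DegradeSettings:
    enabled: bool = True
    factor: int = 2
    noise_sd: float = 0.02

    def validate(self) -> None:
        if self.factor < 1:
            raise ValueError("degrade.factor must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("degrade.noise_sd must be >= 0")


def _default_phantom() -> PhantomConfig:
    # 128 x 128 keeps the full pipeline interactive; the phantom itself
    # defaults to the 224 x 224 acquisition grid when built directly.
    return PhantomConfig(
        height=128, width=128, n_frames=20,
        ring_radii=(26.0, 40.0), contraction_amplitude=0.1,
        lesion_specs=(LesionSpec(center=(40.0, 64.0), radius=9.0,
                                 intensity_delta=0.2, motion_damping=0.8),),
        noise_sd=0.01, seed=0)


def _default_weights() -> dict[str, float]:
    w = {name: 1.0 for name in LOSS_TERMS}
    w["topo"] = 0.2
    return w


@dataclass
class PipelineConfig:
    phantom: PhantomConfig = field(default_factory=_default_phantom)
    flow: FlowSettings = field(default_factory=FlowSettings)
    stc2: Stc2Settings = field(default_factory=Stc2Settings)
    degrade: DegradeSettings = field(default_factory=DegradeSettings)
    loss: dict[str, float] = field(default_factory=_default_weights)
    schedule: CurriculumSchedule = field(default_factory=CurriculumSchedule)
    seed: int = 0
    output_dir: str = "cineclust_out"

    def validate(self) -> None:
        self.phantom.validate()
        self.flow.validate()
        self.stc2.validate()
        self.degrade.validate()
        unknown = set(self.loss) - set(LOSS_TERMS)
        if unknown:
            raise ValueError(f"loss: unknown weight names {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phantom"]["lesion_specs"] = [
            dataclasses.asdict(l) for l in self.phantom.lesion_specs]
        d["schema_version"] = CONFIG_SCHEMA_VERSION
        return d


def _build(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"{context}: unknown keys {sorted(unknown)}")
    return cls(**data)


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data)
    data.pop("schema_version", None)
    known = {"phantom", "flow", "stc2", "degrade", "loss", "schedule",
             "seed", "output_dir"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"config: unknown keys {sorted(unknown)}")
    kwargs: dict = {}
    if "phantom" in data:
        pd = dict(data["phantom"])
        lesions = pd.pop("lesion_specs", [])
        specs = tuple(
            _build(LesionSpec, {**l, "center": tuple(l["center"])}, "lesion_specs")
            for l in lesions)
        if "ring_center" in pd and pd["ring_center"] is not None:
            pd["ring_center"] = tuple(pd["ring_center"])
        if "ring_radii" in pd:
            pd["ring_radii"] = tuple(pd["ring_radii"])
        kwargs["phantom"] = _build(PhantomConfig, {**pd, "lesion_specs": specs},
                                   "phantom")
    if "flow" in data:
        kwargs["flow"] = _build(FlowSettings, data["flow"], "flow")
    if "stc2" in data:
        kwargs["stc2"] = _build(Stc2Settings, data["stc2"], "stc2")
    if "degrade" in data:
        kwargs["degrade"] = _build(DegradeSettings, data["degrade"], "degrade")
    if "schedule" in data:
        kwargs["schedule"] = _build(CurriculumSchedule, data["schedule"], "schedule")
    if "loss" in data:
        kwargs["loss"] = {**_default_weights(), **data["loss"]}
    for key in ("seed", "output_dir"):
        if key in data:
            kwargs[key] = data[key]
    cfg = PipelineConfig(**kwargs)
    cfg.validate()
    return cfg


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
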