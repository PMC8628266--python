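"""Run configuration: one declarative object driving end-to-end runs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

from ritpipe.errors import ConfigError
from ritpipe.synthetic import (
    BloodKinetics,
    OrganKinetics,
    SyntheticConfig,
    TherapySimConfig,
)

DEFAULT_ACTIVITIES_BQ: tuple[float, ...] = (0.925e6, 1.85e6, 3.7e6)


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs; exactly one source per data kind."""

    biodist_input: str | None = None
    caliper_input: str | None = None
    weights_input: str | None = None
    synthetic: SyntheticConfig | None = None
    therapy_sim: TherapySimConfig | None = None
    imaging_nuclide: str = "In-111"
    therapy_nuclide: str = "Y-90"
    nuclide_overrides: Mapping[str, Mapping[str, float]] | None = None
    activities_bq: tuple[float, ...] = DEFAULT_ACTIVITIES_BQ
    tail_mode: str = "physical"
    t0_mode: str = "auto"
    method: str = "analytic"
    per_animal: bool = False
    normalize_bw: bool = True
    reference_bw_g: float = 20.0
    report_rounding_gy: float = 0.1
    endpoint_diameter_mm: float = 12.0
    observation_end_d: float = 56.0
    diameter_mode: str = "max"
    normalized_volume_day: float = 28.0
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.biodist_input is not None and self.synthetic is not None:
            raise ConfigError(
                "configure either biodist_input or a synthetic config, not both"
            )
        if self.caliper_input is not None and self.therapy_sim is not None:
            raise ConfigError(
                "configure either caliper_input or a therapy_sim config, not both"
            )
        if not self.activities_bq or any(a <= 0 for a in self.activities_bq):
            raise ConfigError("activities_bq must be non-empty and positive")

    def resolved_synthetic(self) -> SyntheticConfig:
        cfg = self.synthetic if self.synthetic is not None else SyntheticConfig()
        return dataclasses.replace(cfg, seed=self.seed)

    def resolved_therapy_sim(self) -> TherapySimConfig:
        cfg = self.therapy_sim if self.therapy_sim is not None else TherapySimConfig()
        return dataclasses.replace(
            cfg,
            seed=self.seed,
            endpoint_diameter_mm=self.endpoint_diameter_mm,
            observation_end_d=self.observation_end_d,
        )


def _parse_synthetic(data: Mapping[str, Any]) -> SyntheticConfig:
    kwargs: dict[str, Any] = dict(data)
    if "organs" in kwargs and kwargs["organs"] is not None:
        kwargs["organs"] = {
            name: OrganKinetics(**params) for name, params in kwargs["organs"].items()
        }
    if "blood" in kwargs and kwargs["blood"] is not None:
        kwargs["blood"] = BloodKinetics(**kwargs["blood"])
    for key in ("times_h", "groups", "sqap_organs"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    return SyntheticConfig(**kwargs)


def run_config_from_dict(data: Mapping[str, Any]) -> RunConfig:
    kwargs: dict[str, Any] = dict(data)
    if kwargs.get("synthetic") is not None:
        kwargs["synthetic"] = _parse_synthetic(kwargs["synthetic"])
    if kwargs.get("therapy_sim") is not None:
        kwargs["therapy_sim"] = TherapySimConfig(**kwargs["therapy_sim"])
    if kwargs.get("activities_bq") is not None:
        kwargs["activities_bq"] = tuple(float(a) for a in kwargs["activities_bq"])
    unknown = set(kwargs) - {f.name for f in dataclasses.fields(RunConfig)}
    if unknown:
        raise ConfigError(f"unknown run-config key(s): {sorted(unknown)}")
    return RunConfig(**kwargs)


def load_run_config(path: str | Path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as handle:
        data = yaml.safe_load(handle) or {}
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: run config must be a mapping")
    return run_config_from_dict(data)


def config_digest(config: RunConfig) -> str:
    """Stable SHA-256 over the canonical JSON form of the config."""
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()
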