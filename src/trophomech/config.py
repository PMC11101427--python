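"""Pipeline configuration: one YAML document validated into typed sections.

Defaults reproduce the standard analysis conditions: 3900 Pa / nu 0.457
substrate imaged at 0.3086 um/px, a 128/64/48 px PIV cascade with a 0.6
correlation threshold, 80 px ROI dilation with 12-48 h aggregation, and
the two-day stimulation regimen of one 5% compression step per day.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .fttc import ElasticSubstrate, FTTCConfig
from .piv import PIVConfig

__all__ = ["RegimenConfig", "ROIConfig", "ScenarioConfig", "PipelineConfig",
           "cumulative_regimen_strain"]


@dataclass(frozen=True)
class RegimenConfig:
    """Strain-stimulation regimen: ``step_strain_pct`` applied
    ``steps_per_day`` times per day for ``days`` days."""

    step_strain_pct: float = 5.0
    steps_per_day: int = 1
    days: int = 2

    def __post_init__(self) -> None:
        if self.step_strain_pct < 0:
            raise ValueError("step_strain_pct must be >= 0")
        if self.steps_per_day < 1 or self.days < 1:
            raise ValueError("steps_per_day and days must be >= 1")


@dataclass(frozen=True)
class ROIConfig:
    dilation_px: int = 80
    window_start_h: float = 12.0
    window_end_h: float = 48.0

    def __post_init__(self) -> None:
        if self.dilation_px < 0:
            raise ValueError("dilation_px must be >= 0")
        if self.window_end_h <= self.window_start_h:
            raise ValueError("aggregation window must have positive length")


@dataclass(frozen=True)
class ScenarioConfig:
    """Default synthetic acquisition for the `simulate` stage: a contracting
    patch in a small field, sampled every 3 h out to 24 h (kept short so a
    pipeline run stays interactive; times are configurable)."""

    patch_center_um: tuple[float, float] = (59.0, 59.0)
    patch_radius_um: float = 18.0
    peak_traction_pa: float = 80.0
    onset_time_h: float = 6.0
    field_extent_px: tuple[int, int] = (384, 384)
    time_step_h: float = 3.0
    duration_h: float = 24.0
    bead_density_per_um2: float = 0.05
    noise_sd: float = 0.02
    n_replicates: int = 2


@dataclass(frozen=True)
class PipelineConfig:
    substrate: ElasticSubstrate = field(default_factory=ElasticSubstrate)
    piv: PIVConfig = field(default_factory=PIVConfig)
    fttc: FTTCConfig = field(default_factory=FTTCConfig)
    roi: ROIConfig = field(default_factory=ROIConfig)
    regimen: RegimenConfig = field(default_factory=RegimenConfig)
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.piv.pixel_size != self.substrate.pixel_size:
            raise ValueError("piv.pixel_size and substrate.pixel_size disagree")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(section_cls, key, tuple_keys=()):
            data = dict(raw.get(key, {}))
            for tk in tuple_keys:
                if tk in data:
                    data[tk] = tuple(data[tk])
            return section_cls(**data)

        return cls(
            substrate=build(ElasticSubstrate, "substrate"),
            piv=build(PIVConfig, "piv", tuple_keys=("window_sizes",)),
            fttc=build(FTTCConfig, "fttc"),
            roi=build(ROIConfig, "roi"),
            regimen=build(RegimenConfig, "regimen"),
            scenario=build(
                ScenarioConfig, "scenario",
                tuple_keys=("patch_center_um", "field_extent_px"),
            ),
            seed=int(raw.get("seed", 0)),
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Stable hash of the full configuration, for run provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def cumulative_regimen_strain(cfg: PipelineConfig | RegimenConfig) -> float:
    """Total strain (percent) accumulated by the regimen, adding engineering
    strains across cycles: e.g. one 5% step per day for 2 days -> 10%."""
    reg = cfg.regimen if isinstance(cfg, PipelineConfig) else cfg
    return reg.step_strain_pct * reg.steps_per_day * reg.days
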