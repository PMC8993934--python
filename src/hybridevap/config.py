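"""Pipeline configuration: YAML in, validated pydantic models out.

Unknown keys are rejected so typos fail loudly. Every run writes a
provenance record (config hash, seed, package version) next to its outputs.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["PipelineConfig", "load_config", "provenance_record"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GenerateSection(_Strict):
    n_days: int = 1095
    n_sites: int = 2
    noise_sd_mm: float = 0.05
    grid: bool = False
    ny: int = 2
    nx: int = 2


class SoilSection(_Strict):
    depths_tall_mm: list[float] = [100.0, 400.0, 800.0]
    depths_short_mm: list[float] = [100.0, 400.0]
    w_wp: float = 0.10
    w_c: float = 0.30
    w_r: float = 0.05
    porosity: float = 0.45


class PrepareSection(_Strict):
    rain_threshold_mm: float = 0.5
    ept_scaling: str = "none"  # none | post_rain | full
    ept_epsilon_mm: float = 0.1
    anomaly_window_days: int = 31
    partition_k_tall: float = 0.6
    partition_k_short: float = 0.8


class TrainSection(_Strict):
    hidden: list[int] = [64, 64, 64]
    dropout: float = Field(0.1, ge=0.0, lt=1.0)
    learning_rate: float = Field(0.000142, gt=0.0)
    batch_size: int = Field(100, gt=0)
    max_epochs: int = Field(1000, gt=0)
    train_fraction: float = Field(0.85, gt=0.0, lt=1.0)
    patience: int = Field(20, gt=0)


class RunSection(_Strict):
    mode: str = "hybrid"
    veg_class: str = "tall"
    frac_tall: float = 0.7
    frac_short: float = 0.2
    frac_bare: float = 0.1
    frac_water: float = 0.0
    interception_on: bool = True
    interception_coef: float = 0.2
    alpha_pt: float = 1.26


class PipelineConfig(_Strict):
    seed: int = 0
    workdir: str = "pipeline_out"
    generate: GenerateSection = Field(default_factory=GenerateSection)
    soil: SoilSection = Field(default_factory=SoilSection)
    prepare: PrepareSection = Field(default_factory=PrepareSection)
    train: TrainSection = Field(default_factory=TrainSection)
    run: RunSection = Field(default_factory=RunSection)


def load_config(path: str | Path) -> PipelineConfig:
    """Load and schema-validate a YAML pipeline config."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.model_validate(raw)


def provenance_record(cfg: PipelineConfig, out_dir: Path) -> dict:
    """Write provenance.json (config hash, seed, versions) and return it."""
    from . import __version__

    blob = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    rec = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": cfg.seed,
        "hybridevap_version": __version__,
        "python": platform.python_version(),
    }
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "provenance.json").write_text(json.dumps(rec, indent=2))
    return rec
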