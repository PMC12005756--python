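"""Pipeline configuration: a single validated YAML-backed object.

Unknown keys are rejected so typos fail loudly; a config round-trips
through YAML unchanged.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Tuple, Union

import yaml
from pydantic import BaseModel, ConfigDict

from .pipeline import AnalysisConfig
from .simulate import RunSpec, SimulationConfig

__all__ = ["RunSettings", "AnalysisSettings", "StatsSettings", "PipelineConfig"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class RunSettings(_Strict):
    """Acquisition/rendering settings of simulated runs."""

    rt_window: Tuple[float, float] = (600.0, 1320.0)
    mz_window: Tuple[float, float] = (1000.0, 1600.0)
    resolution: float = 15000.0
    charges: Tuple[int, ...] = (18, 19, 20, 21, 22)
    charge_weights: Tuple[float, ...] = (1.0, 2.0, 3.0, 2.0, 1.0)
    rt_sigma: float = 6.0
    scan_interval: float = 3.0
    mz_step: float = 0.02
    noise_sd: float = 20.0
    total_ion_area: float = 1.0e8

    def to_run_spec(self, seed: int = 0) -> RunSpec:
        return RunSpec(seed=seed, **self.model_dump())


class AnalysisSettings(_Strict):
    """Tolerances and knobs of the measurement chain."""

    resolution: float = 15000.0
    charge_pool: Tuple[int, ...] = (18, 19, 20, 21, 22)
    eic_w: float = 2.0
    rt_half_width: float = 18.0
    allotype_tol: float = 2.0
    pair_tol: float = 1.5
    threshold_k: float = 8.0
    min_charges: int = 3
    smooth_width_mz: float = 1.0
    tophat_width_mz: float = 1.0
    align: bool = True

    def to_analysis_config(self) -> AnalysisConfig:
        return AnalysisConfig(**self.model_dump())


class StatsSettings(_Strict):
    comparisons: List[Tuple[str, str]] = [
        ("total_plasma", "total_SF"),
        ("total_plasma", "ACPA_plasma"),
        ("total_SF", "ACPA_SF"),
        ("ACPA_plasma", "ACPA_SF"),
    ]
    impute_value: float = 0.01
    pca_mode: str = "per_patient_centered"
    min_pairs: int = 4


class PipelineConfig(_Strict):
    """Top-level pipeline configuration (simulate / analyze / stats)."""

    seed: int = 0
    n_patients: int = 2
    reference_path: Optional[str] = None
    run: RunSettings = RunSettings()
    analysis: AnalysisSettings = AnalysisSettings()
    stats: StatsSettings = StatsSettings()

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))
        return path

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(run=self.run.to_run_spec(self.seed))
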