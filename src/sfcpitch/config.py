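"""Pipeline configuration: one validated block holding every study constant.

Defaults reproduce the published analysis settings (0.004 s frames, a
−100 cent / 400 ms auditory perturbation, the uniform prior bounds, σq = 1e-8
process noise, U(−3.5, 3.5) training noise, 10^5 training simulations with
10^4 posterior samples over 10 repetitions, 100-run output averaging and
100×1000 bootstrap effect sizes).  Desk-scale test budgets override the
inference block only; everything is data, not code.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .inference import PriorSpec
from .params import PARAM_NAMES, ParameterSet
from .simulate import PerturbationSpec

__all__ = ["PipelineConfig", "load_config", "config_hash"]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PlantConfig(_StrictModel):
    k: float = Field(160000.0, gt=0)
    b: float = Field(1600.0, gt=0)
    m: float = Field(1.0, gt=0)
    dt: float = Field(0.004, gt=0)
    trial_s: float = Field(1.2, gt=0)
    sigma_q: float = Field(1e-8, gt=0)
    integrator_upstream: bool = True  # command integrator precedes the spring-mass plant


class PerturbationConfig(_StrictModel):
    magnitude: float = -100.0
    onset: float = Field(0.0, ge=0)
    duration: float = Field(0.400, gt=0)

    def to_spec(self) -> PerturbationSpec:
        return PerturbationSpec(magnitude=self.magnitude, onset=self.onset, duration=self.duration)


class PriorBounds(_StrictModel):
    delta_a_ms: tuple[float, float] = (50.0, 200.0)
    delta_s_ms: tuple[float, float] = (3.0, 80.0)
    sigma_log10: tuple[float, float] = (-6.5, -3.0)
    r: tuple[float, float] = (0.1, 6.0)
    g_c: tuple[float, float] = (0.1, 8.0)

    @model_validator(mode="after")
    def _ordered(self) -> "PriorBounds":
        for name in PARAM_NAMES:
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"prior bound for {name!r}: lower {lo} > upper {hi}")
        return self

    def to_spec(self) -> PriorSpec:
        return PriorSpec(bounds={name: tuple(getattr(self, name)) for name in PARAM_NAMES})


class InferenceConfig(_StrictModel):
    n_sims: int = Field(100_000, gt=0)
    n_posterior_samples: int = Field(10_000, gt=0)
    n_reps: int = Field(10, gt=0)
    backend: Literal["abc", "density"] = "density"
    accept_quantile: float = Field(0.01, gt=0, le=1)
    abc_adjust: bool = False  # local-linear regression correction of accepted draws
    abc_adjust_features: int = Field(10, gt=0)
    abc_adjust_ridge: float = Field(0.01, ge=0)
    training_noise_halfwidth: float = Field(3.5, ge=0)
    density_components: int = Field(8, gt=0)
    density_features: int = Field(15, gt=0)


class ExperimentConfig(_StrictModel):
    n_runs_mean: int = Field(100, ge=2)  # simulations averaged per reported output
    n_boot: int = Field(100, gt=0)
    boot_size: int = Field(1000, gt=0)
    sensitivity_offsets: list[float] = Field(default_factory=lambda: [-2.0, -1.0, 0.0, 1.0, 2.0])


class SyntheticConfig(_StrictModel):
    native_frames: int = Field(413, gt=0)
    se_profile_cents: float = Field(1.5, ge=0, le=3)
    n_pseudo_subjects_ca: int = Field(16, ge=2)
    n_pseudo_subjects_control: int = Field(11, ge=2)
    jitter_window_ms: float = Field(50.0, ge=0)


class PipelineConfig(_StrictModel):
    plant: PlantConfig = Field(default_factory=PlantConfig)
    perturbation: PerturbationConfig = Field(default_factory=PerturbationConfig)
    prior: PriorBounds = Field(default_factory=PriorBounds)
    inference: InferenceConfig = Field(default_factory=InferenceConfig)
    experiments: ExperimentConfig = Field(default_factory=ExperimentConfig)
    synthetic: SyntheticConfig = Field(default_factory=SyntheticConfig)
    seed: int = 0
    out_dir: str = "results"

    def desk_scale(self) -> "PipelineConfig":
        """A reduced-budget copy used for fast ABC-backed runs."""
        cfg = self.model_copy(deep=True)
        cfg.inference.n_sims = 20_000
        cfg.inference.n_reps = 3
        cfg.inference.backend = "abc"
        return cfg

    def headline_scale(self) -> "PipelineConfig":
        """Budget for the group-comparison and ablation studies.

        Larger training sets with a tight acceptance quantile and the
        local-linear ABC correction, so pooled medians are accurate point
        estimates (see docs/methods.md on budgets).
        """
        cfg = self.model_copy(deep=True)
        cfg.inference.n_sims = 60_000
        cfg.inference.n_reps = 3
        cfg.inference.backend = "abc"
        cfg.inference.accept_quantile = 0.002
        cfg.inference.abc_adjust = True
        return cfg


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config; an empty/missing-section file yields all defaults.

    Unknown keys and invalid bounds raise with the offending field named.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError(f"config file {path} must contain a mapping")
            data = loaded
    data.update(overrides)
    return PipelineConfig(**data)


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash of the fully-resolved configuration."""
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def published_parameter_sets() -> dict[str, ParameterSet]:
    """The published inferred parameter sets for the two groups."""
    from .synthetic import INFERRED_CA, INFERRED_CONTROL

    return {"ca": INFERRED_CA, "control": INFERRED_CONTROL}
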