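"""Run configuration: a single validated, serialisable description of an
experiment from which the run is reproducible given its master seed.

The file format is YAML; unknown keys are rejected with field-level errors.
Defaults follow the reference study conditions: α = 1%, ε = 12, 500-step
cutoff, 10 replicates, 18 h / 51 h doubling times, 144 h / 99% / 40,000-cell
stop criteria, 0.01 competing weight in the dynamic model.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .geometry import RadiusDistribution
from .patterns import ClassifierParams
from .rules import RuleKind, RuleParams
from .dynamics import GrowthParams

__all__ = ["RunConfig", "load_config", "save_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class RadiusConfig(_Strict):
    family: str = "lognormal"
    mean_diameter: float = Field(6.6, gt=0)
    sd_diameter: float = Field(0.33, ge=0)

    def to_params(self) -> RadiusDistribution:
        return RadiusDistribution(self.family, self.mean_diameter, self.sd_diameter)


class AggregationConfig(_Strict):
    n_cells: int = Field(250, ge=1)
    box_side: float | None = None
    step_size: float = Field(1.0, gt=0)
    max_iterations: int = Field(10_000, ge=1)
    convergence_displacement: float = Field(0.01, gt=0)
    contact_slack: float = Field(0.05, ge=0)


class RuleConfig(_Strict):
    kind: str = "competing"
    alpha: float = Field(0.01, ge=0, le=1)
    epsilon: int = Field(12, ge=1)
    weight: float = Field(1.0, ge=0, le=1)
    competing_exponent: float = Field(2.0, gt=0)

    def to_params(self) -> RuleParams:
        return RuleParams(
            kind=RuleKind(self.kind),
            alpha=self.alpha,
            epsilon=self.epsilon,
            weight=self.weight,
            competing_exponent=self.competing_exponent,
        )


class GrowthConfig(_Strict):
    doubling_time_pos: float = Field(18.0, gt=0)
    doubling_time_neg: float = Field(51.0, gt=0)
    spring_stiffness: float = Field(5.0, gt=0)
    spring_rest_length_factor: float = Field(1.0, gt=0)
    mechanics_dt: float = Field(0.1, gt=0)
    rule_dt: float = Field(1.0, gt=0)
    duration: float = Field(144.0, gt=0)
    changed_fraction_stop: float = Field(0.99, gt=0, le=1)
    max_cells: int = Field(40_000, ge=1)
    competing_weight: float = Field(0.01, ge=0, le=1)

    def to_params(self) -> GrowthParams:
        return GrowthParams(**self.model_dump())


class ClassifierConfig(_Strict):
    hi: float = Field(0.90, gt=0, le=1)
    lo: float = Field(0.10, ge=0, lt=1)
    radial_delta: float = Field(0.15, ge=0)
    method: str = "permutation"
    connected_min_frac: float = Field(0.6, ge=0, le=1)

    def to_params(self) -> ClassifierParams:
        return ClassifierParams(
            hi=self.hi,
            lo=self.lo,
            radial_delta=self.radial_delta,
            method=self.method,
            connected_min_frac=self.connected_min_frac,
        )


class RunConfig(_Strict):
    """Everything needed to reproduce one experiment."""

    seed: int = 0
    replicates: int = Field(10, ge=1)
    max_steps: int = Field(500, ge=1)
    dynamic: bool = False
    out_dir: str = "ebsim-run"
    radius: RadiusConfig = RadiusConfig()
    aggregation: AggregationConfig = AggregationConfig()
    rule: RuleConfig = RuleConfig()
    growth: GrowthConfig = GrowthConfig()
    classifier: ClassifierConfig = ClassifierConfig()


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Missing sections take the defaults above; unknown keys raise a
    validation error naming the offending field.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        raise ValueError(f"empty configuration file: {path}")
    if not isinstance(data, dict):
        raise ValueError("configuration root must be a mapping")
    return RunConfig.model_validate(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
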