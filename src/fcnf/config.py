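"""Validated pipeline configuration.

One JSON document configures the whole pipeline: the run design, the
feedback (thermometer) settings, the synthetic-cohort generator, and
the group-statistics options. Unknown keys are rejected and every
field is validated on load, so a malformed configuration fails before
any computation starts.

A single global seed fans out to per-stage seeds through a documented
rule: ``stage_seed = SeedSequence([seed, STAGE_INDEX[stage]])`` reduced
to a 31-bit integer, so any stage can be re-run in isolation and
reproduce its part of a pipeline run.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .fc import FeedbackConfig
from .simulate import CohortParams

__all__ = ["DesignConfig", "FeedbackSettings", "SimulateSettings",
           "StatsSettings", "PipelineConfig", "stage_seed", "STAGE_INDEX"]

STAGE_INDEX = {"simulate": 1, "feedback": 2, "metrics": 3, "groupstats": 4, "moderation": 5}


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage 31-bit seed from the global seed."""
    return int(
        np.random.SeedSequence([seed, STAGE_INDEX[stage]]).generate_state(1)[0]
        % (2**31)
    )


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DesignConfig(_Strict):
    """Run structure: fixation, then alternating mini-block pairs."""

    fixation_len: int = Field(20, ge=0)
    n_pairs: int = Field(7, ge=0)
    fcnf_len: int = Field(20, ge=1)
    nonf_len: int = Field(20, ge=1)
    n_runs: int = Field(4, ge=1)
    start_condition: Literal["fcnf", "nonf"] = "fcnf"

    @model_validator(mode="after")
    def _nonempty(self) -> "DesignConfig":
        if self.n_pairs == 0 and self.fixation_len == 0:
            raise ValueError("empty schedule")
        return self


class FeedbackSettings(_Strict):
    implementation: Literal["negative", "weighted_negative", "positive"] = (
        "weighted_negative"
    )
    upper_bound: float | None = None
    n_segments: int = Field(10, ge=1)
    frozen_segment: int = Field(6, ge=1)
    window_length: int = Field(20, ge=3)

    @model_validator(mode="after")
    def _bounds(self) -> "FeedbackSettings":
        if self.upper_bound == 0.0:
            raise ValueError("upper_bound must be nonzero")
        if self.frozen_segment > self.n_segments:
            raise ValueError("frozen_segment must lie in 1..n_segments")
        return self

    def to_feedback_config(self) -> FeedbackConfig:
        return FeedbackConfig(
            implementation=self.implementation,
            upper_bound=self.upper_bound,
            n_segments=self.n_segments,
            frozen_segment=self.frozen_segment,
            window_length=self.window_length,
        )


class SimulateSettings(_Strict):
    """Cohort generator settings; see ``fcnf.simulate.CohortParams``."""

    n_subjects: int = Field(20, ge=2)
    rho_base_mean: float = 0.15
    link_stait_rho: float = 0.08
    link_tcaq_rho: float = -0.08
    rho_noise_sd: float = Field(0.08, ge=0)
    delta_mean: float = -0.15
    link_stais_delta: float = 0.04
    link_xw_delta: float = -0.035
    link_xwz_delta: float = 0.04
    delta_noise_sd: float = Field(0.04, ge=0)
    drift_mean: float = -0.01
    drift_sd: float = Field(0.015, gt=0)
    gamma: float = Field(0.5, ge=0)
    ar_coef: float = Field(0.3, ge=0, lt=1)
    noise_sd: float = Field(1.0, gt=0)
    counterbalance: bool = True

    def to_cohort_params(self, seed: int) -> CohortParams:
        fields = self.model_dump(exclude={"counterbalance"})
        return CohortParams(seed=seed, **fields)


class StatsSettings(_Strict):
    bootstrap_b: int = Field(1000, ge=100)
    outlier_threshold: float | None = Field(None, gt=0)
    fisher_variant: Literal["z", "t"] = "z"
    slope_scope: Literal["all", "fcnf_only", "nonf_only"] = "all"
    correction: Literal["none", "bh"] = "none"


class PipelineConfig(_Strict):
    design: DesignConfig = DesignConfig()
    feedback: FeedbackSettings = FeedbackSettings()
    simulate: SimulateSettings = SimulateSettings()
    stats: StatsSettings = StatsSettings()
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))

    @classmethod
    def experiment3(cls, **overrides) -> "PipelineConfig":
        """The extended design: 40-volume feedback blocks, five pairs, three runs."""
        base = cls(**overrides)
        return base.model_copy(
            update={
                "design": DesignConfig(
                    fixation_len=20, n_pairs=5, fcnf_len=40, nonf_len=20, n_runs=3
                )
            }
        )
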