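"""Run configuration: a validated, serialisable bundle of task, agent and
experiment settings whose defaults reproduce the study setup
(T=5 trials, K=200 segments, 5-segment blocks, gamma=8, D=20, b0=(1,1),
upper utilities +/-2)."""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .agents import AgentSpec
from .task import TaskConfig

__all__ = ["RunConfig", "load_config"]


class TaskSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    trials_per_segment: int = Field(5, ge=1)
    n_segments: int = Field(200, ge=1)
    success_threshold: int = Field(4, ge=1)
    block_length: int = Field(5, ge=1)
    schedule: list[int] | None = None

    def to_task_config(self) -> TaskConfig:
        return TaskConfig(
            trials_per_segment=self.trials_per_segment,
            n_segments=self.n_segments,
            success_threshold=self.success_threshold,
            block_length=self.block_length,
            schedule=tuple(self.schedule) if self.schedule else None,
        )


class AgentSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    type: str = "adp"
    gamma: float = Field(8.0, gt=0)
    duration_prior: str = "imprecise"
    D: int = Field(20, ge=1)
    a0: float = Field(1.0 / 3.0, gt=0)
    a0_anchor: float = Field(1.0, ge=0)
    b0: float = Field(1.0, gt=0)
    utility_failure: float = -2.0
    utility_success: float = 2.0
    action_rule: str = "argmax"

    def to_agent_spec(self, seed: int = 0) -> AgentSpec:
        return AgentSpec(
            type=self.type, gamma=self.gamma,
            duration_prior=self.duration_prior, D=self.D,
            a0=self.a0, a0_anchor=self.a0_anchor, b0=self.b0,
            utility_upper=(self.utility_failure, self.utility_success),
            action_rule=self.action_rule, seed=seed,
        )


class ExperimentSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_agents: int = Field(1, ge=1)
    master_seed: int = 0
    analysis_last_n: int = Field(100, ge=1)


class RunConfig(BaseModel):
    """Top-level validated configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    task: TaskSection = TaskSection()
    agent: AgentSection = AgentSection()
    experiment: ExperimentSection = ExperimentSection()

    def echo(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.model_dump(), indent=2) + "\n")


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a JSON or YAML config; None or empty file -> defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    if not text.strip():
        return RunConfig()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    return RunConfig.model_validate(data)
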