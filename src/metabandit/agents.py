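"""Agent types and the closed-loop agent-environment simulation.

Four agent types:

* ``rc``  — random choice reference: uniform over the four options, no
  inference, no learning.
* ``iv``  — instrumental agent: full hierarchy with a single meta-control
  state whose epistemic weight is 0 (pure expected-utility policy prior).
* ``efe`` — expected-free-energy agent: single meta-control state with
  epistemic weight 1 (utility plus information gain).
* ``adp`` — adaptive agent: two meta-control states with weights (1, 0); the
  upper level infers which state to occupy, so the effective weight alpha_bar
  moves continuously in [0, 1] as a function of context beliefs and learned
  segment-outcome statistics.

The per-segment schedule: (1) the upper level advances its predictive beliefs
and evaluates the expected free energy of the two control signals, forming a
segment-start policy prior and downward messages (the segment-start alpha_bar
is logged before any outcome of the segment is seen); (2) the trial level runs
five plan/act/observe steps; (3) the segment outcome and the trial level's
final context and meta-state beliefs feed the upper posterior; (4) Dirichlet
counts are updated at both levels (total added mass 5 below, 1 above).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .durations import IMPRECISE, PRECISE, make_duration_prior
from .lower import LowerLevel
from .task import TaskConfig, TaskEnvironment, is_ev_plus
from .upper import UpperLevel

__all__ = ["AgentSpec", "ExperimentLog", "make_agent", "run_experiment",
           "run_group"]

_ALPHA_MAPS = {"rc": (), "iv": (0.0,), "efe": (1.0,), "adp": (1.0, 0.0)}
_PRIORS = {"imprecise": IMPRECISE, "precise": PRECISE}


@dataclass(frozen=True)
class AgentSpec:
    """Full configuration of one agent instance."""

    type: str = "adp"
    gamma: float = 8.0
    duration_prior: str = "imprecise"  # or "precise"
    D: int = 20
    a0: float = 1.0 / 3.0              # baseline lower-level Dirichlet count per cell
    a0_anchor: float = 1.0             # weight of the true table in the prior mean
    b0: float = 1.0                    # upper-level Dirichlet prior (1,1)
    utility_upper: tuple[float, float] = (-2.0, 2.0)  # (failure, success)
    action_rule: str = "argmax"
    seed: int = 0
    #: override of the meta-state -> epistemic-weight mapping; e.g. (1.0, 1.0)
    #: clamps an adaptive agent to the pure expected-free-energy mode
    alpha_map_override: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.type not in _ALPHA_MAPS:
            raise ValueError(f"unknown agent type {self.type!r}")
        if self.duration_prior not in _PRIORS:
            raise ValueError(f"unknown duration prior {self.duration_prior!r}")
        if self.type == "rc" and self.alpha_map_override is not None:
            raise ValueError("the random-choice agent has no meta-control states")

    @property
    def alpha_map(self) -> tuple[float, ...]:
        if self.alpha_map_override is not None:
            return self.alpha_map_override
        return _ALPHA_MAPS[self.type]


@dataclass
class ExperimentLog:
    """Trial- and segment-resolved record of one simulated experiment."""

    spec: AgentSpec
    config: TaskConfig
    trials: pd.DataFrame = field(repr=False)
    segments: pd.DataFrame = field(repr=False)

    @property
    def success(self) -> np.ndarray:
        return self.segments["success"].to_numpy()


class RandomAgent:
    """Uniform action sampler; traverses the loop but never infers."""

    def __init__(self, spec: AgentSpec, config: TaskConfig,
                 rng: np.random.Generator):
        self.spec = spec
        self.config = config
        self.rng = rng

    def run_segment(self, env: TaskEnvironment) -> dict:
        T = self.config.trials_per_segment
        trial_rows = []
        for t in range(1, T + 1):
            option = int(self.rng.integers(self.config.n_options)) + 1
            obs = env.step(option)
            trial_rows.append((env.segment, t, env.context, option, obs.h,
                               obs.w[0], obs.w[1], np.nan))
        result = env.end_segment()
        seg_row = dict(segment=result.segment, context=result.context,
                       success=int(result.success), alpha_prior=np.nan,
                       alpha_mean=np.nan, alpha_post=np.nan,
                       context_mode=0, q_true_context=np.nan)
        return {"trials": trial_rows, "segment": seg_row}


class HierarchicalAgent:
    """Two-level active-inference agent (IV, EFE or ADP variant)."""

    def __init__(self, spec: AgentSpec, config: TaskConfig,
                 rng: np.random.Generator,
                 table_anchor: np.ndarray | None = None):
        self.spec = spec
        self.config = config
        self.rng = rng
        theta, beta = _PRIORS[spec.duration_prior]
        prior = make_duration_prior(theta, beta, spec.D)
        alpha_map = spec.alpha_map
        n_meta = len(alpha_map)
        # Vague prior about the true state-outcome contingencies: a flat
        # baseline count plus a weak anchor on the true tables.  A fully
        # exchangeable prior (anchor 0) leaves the six contexts permanently
        # indistinguishable — the learning updates preserve the symmetry — so
        # some anchoring is required for context identification to be
        # well-posed against the true labels.
        a = np.full((config.n_contexts, config.n_options, 3), spec.a0)
        if table_anchor is not None and spec.a0_anchor > 0:
            a = a + spec.a0_anchor * table_anchor
        self.lower = LowerLevel(a, T=config.trials_per_segment,
                                threshold=config.success_threshold,
                                gamma=spec.gamma, alpha_map=alpha_map,
                                action_rule=spec.action_rule)
        self.upper = UpperLevel(prior, n_contexts=config.n_contexts,
                                n_meta=n_meta, gamma=spec.gamma,
                                utility=spec.utility_upper,
                                alpha_map=np.asarray(alpha_map), b0=spec.b0)

    def run_segment(self, env: TaskEnvironment) -> dict:
        T = self.config.trials_per_segment
        _, _, messages = self.upper.start_segment()
        self.lower.start_segment(messages.p_c_down, messages.p_i_down)
        trial_rows = []
        alphas = []
        for t in range(1, T + 1):
            state = self.lower.plan()
            option0 = self.lower.choose(state, self.rng)
            obs = env.step(option0 + 1)
            self.lower.observe(option0, obs.h, obs.w)
            alphas.append(state.alpha_bar)
            trial_rows.append((env.segment, t, env.context, option0 + 1, obs.h,
                               obs.w[0], obs.w[1], state.alpha_bar))
        result = env.end_segment()
        o_k = int(result.success)
        q_c_final = self.lower.q_c.copy()
        q_i_final = self.lower.q_i.copy()
        self.lower.finish_segment()
        upper_state = self.upper.end_segment(o_k, q_c_final, q_i_final)
        alpha_post = float(
            upper_state.q_s.sum(axis=(0, 1))
            @ self.upper.alpha_map[: self.upper.n_meta]
        )
        seg_row = dict(
            segment=result.segment,
            context=result.context,
            success=o_k,
            alpha_prior=messages.alpha_bar,
            alpha_mean=float(np.mean(alphas)),
            alpha_post=alpha_post,
            context_mode=int(np.argmax(q_c_final)) + 1,
            q_true_context=float(q_c_final[result.context - 1]),
        )
        return {"trials": trial_rows, "segment": seg_row}


def make_agent(spec: AgentSpec, config: TaskConfig | None = None,
               rng: np.random.Generator | None = None,
               table_anchor: np.ndarray | None = None):
    """Instantiate the agent class matching ``spec.type``."""
    config = config or TaskConfig()
    rng = rng or np.random.default_rng(spec.seed)
    if spec.type == "rc":
        return RandomAgent(spec, config, rng)
    return HierarchicalAgent(spec, config, rng, table_anchor=table_anchor)


_TRIAL_COLUMNS = ["segment", "trial", "context", "option", "outcome_class",
                  "w_blue", "w_red", "alpha_bar"]


def run_experiment(spec: AgentSpec, config: TaskConfig | None = None,
                   rng: np.random.Generator | None = None) -> ExperimentLog:
    """Run one agent for the full experiment and return its log.

    The same (spec, config) with the same seed reproduces the log exactly:
    a single Generator seeded from ``spec.seed`` drives both the environment
    and the agent's action sampling, in a fixed interleaving.
    """
    config = config or TaskConfig()
    rng = rng or np.random.default_rng(spec.seed)
    env = TaskEnvironment(config, rng=rng)
    agent = make_agent(spec, config, rng, table_anchor=env.table.probs)
    trial_rows: list[tuple] = []
    seg_rows: list[dict] = []
    for _ in range(config.n_segments):
        out = agent.run_segment(env)
        trial_rows.extend(out["trials"])
        seg_rows.append(out["segment"])
    trials = pd.DataFrame(trial_rows, columns=_TRIAL_COLUMNS)
    segments = pd.DataFrame(seg_rows)
    segments["ev_plus"] = [is_ev_plus(c) for c in segments["context"]]
    return ExperimentLog(spec=spec, config=config, trials=trials,
                         segments=segments)


def run_group(spec: AgentSpec, n_agents: int, config: TaskConfig | None = None,
              master_seed: int = 0, progress: bool = False) -> list[ExperimentLog]:
    """n independent replicas with distinct substreams of one master seed."""
    config = config or TaskConfig()
    seeds = np.random.SeedSequence(master_seed).spawn(n_agents)
    logs = []
    iterator = range(n_agents)
    for idx in iterator:
        rng = np.random.default_rng(seeds[idx])
        log = run_experiment(replace(spec, seed=idx), config, rng=rng)
        logs.append(log)
        if progress:
            print(f"  {spec.type} replica {idx + 1}/{n_agents}", flush=True)
    return logs
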