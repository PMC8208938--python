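"""The generative process: a six-context, four-option point-collection task.

Runs of five trials form a *segment*; a segment is a success when at least
four points of a single colour (blue or red) were collected.  The hidden
context — one of six option-outcome tables — switches every block of five
segments.  Contexts come in three pairs; the two variants of a pair (EV- and
EV+) differ only in option 4, which yields a point of the pair's dominant
colour with certainty in EV+ and nothing with certainty in EV-.  Options 1-3
are stochastic with profile (0.8, 0.1, 0.1) over the three outcome classes
{no-point, blue, red}.

Outcome coding throughout: point-type vector f in {(0,0),(1,0),(0,1)} for
{none, blue, red}, scalar class h in {1,2,3} respectively.  Public indices
(contexts 1..6, options 1..4, classes 1..3) are 1-based as in the logs;
arrays are 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "OptionOutcomeTable",
    "TaskConfig",
    "TrialObservation",
    "SegmentResult",
    "default_context_tables",
    "context_schedule",
    "sample_point",
    "accumulate_points",
    "encode_point_type",
    "evaluate_segment",
    "context_label",
    "is_ev_plus",
    "TaskEnvironment",
]

N_CONTEXTS = 6
N_OPTIONS = 4
N_OUTCOMES = 3  # no-point, blue, red

#: point-type vectors indexed by outcome class (0-based)
POINT_TYPES = np.array([[0, 0], [1, 0], [0, 1]], dtype=int)


@dataclass(frozen=True)
class OptionOutcomeTable:
    """True outcome probabilities, shape (6 contexts, 4 options, 3 classes).

    Context order: pair 1 EV-, pair 1 EV+, pair 2 EV-, pair 2 EV+,
    pair 3 EV-, pair 3 EV+.
    """

    probs: np.ndarray = field(repr=False)

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (N_CONTEXTS, N_OPTIONS, N_OUTCOMES):
            raise ValueError(f"table must be 6x4x3, got {p.shape}")
        if not np.allclose(p.sum(axis=-1), 1.0, atol=1e-12):
            raise ValueError("every (context, option) row must sum to 1")
        object.__setattr__(self, "probs", p)


def context_label(context: int) -> str:
    """1-based context index -> label like '3:EV+'."""
    pair = (context - 1) // 2 + 1
    variant = "EV-" if (context - 1) % 2 == 0 else "EV+"
    return f"{pair}:{variant}"


def is_ev_plus(context: int) -> bool:
    """True when the 1-based context index is an EV+ variant."""
    return (context - 1) % 2 == 1


#: per pair: (dominant colour class 1-based, option slot of the colour option)
_PAIR_LAYOUT = {1: (2, 1), 2: (2, 2), 3: (3, 1)}


def default_context_tables() -> OptionOutcomeTable:
    """Canonical six-context table.

    Within each context exactly one of options 1-3 yields the pair's dominant
    colour with 0.8 while the other two yield no-point with 0.8 (remaining
    classes 0.1 each); option 4 is deterministic — the dominant colour in EV+
    and no-point in EV-.  Pairs 1 and 2 share the dominant colour (blue) but
    place the colour option in different slots, pair 3 is red with the colour
    option in slot 1; every context therefore has a distinct table, the
    (0.1, 0.8, 0.1) blue profile appears in exactly the four pair-1/pair-2
    contexts, and in pair 3 options 2 and 3 give red with probability 0.1.
    """
    probs = np.zeros((N_CONTEXTS, N_OPTIONS, N_OUTCOMES))
    for pair in (1, 2, 3):
        dom, colour_slot = _PAIR_LAYOUT[pair]
        for variant in (0, 1):  # 0 = EV-, 1 = EV+
            c = 2 * (pair - 1) + variant
            for opt in range(3):
                row = np.full(N_OUTCOMES, 0.1)
                row[dom - 1 if opt == colour_slot - 1 else 0] = 0.8
                probs[c, opt] = row
            probs[c, 3] = np.eye(N_OUTCOMES)[dom - 1 if variant else 0]
    return OptionOutcomeTable(probs=probs)


@dataclass(frozen=True)
class TaskConfig:
    trials_per_segment: int = 5
    n_segments: int = 200
    success_threshold: int = 4
    block_length: int = 5
    n_contexts: int = N_CONTEXTS
    n_options: int = N_OPTIONS
    schedule: tuple[int, ...] | None = None  # explicit per-segment 1-based contexts

    def __post_init__(self):
        if self.trials_per_segment < 1:
            raise ValueError("trials_per_segment must be >= 1")
        if self.success_threshold > self.trials_per_segment:
            raise ValueError("success_threshold cannot exceed trials_per_segment")
        if self.schedule is not None and len(self.schedule) != self.n_segments:
            raise ValueError("explicit schedule length must equal n_segments")


@dataclass(frozen=True)
class TrialObservation:
    """One trial: chosen option l (1-based), point type f, cumulative w, class h."""

    l: int
    f: tuple[int, int]
    w: tuple[int, int]
    h: int


@dataclass(frozen=True)
class SegmentResult:
    segment: int  # 1-based
    context: int  # true context, 1-based
    success: bool


def context_schedule(config: TaskConfig) -> np.ndarray:
    """Deterministic per-segment context sequence (1-based indices).

    Cycles the pairs 1 -> 2 -> 3 while alternating variants EV-, EV+, one
    context per block of ``block_length`` segments:
    1:EV-, 2:EV+, 3:EV-, 1:EV+, 2:EV-, 3:EV+, then repeats.
    """
    if config.schedule is not None:
        return np.asarray(config.schedule, dtype=int)
    if config.n_segments % config.block_length != 0:
        raise ValueError(
            f"block_length {config.block_length} must divide "
            f"n_segments {config.n_segments}"
        )
    n_blocks = config.n_segments // config.block_length
    blocks = []
    for b in range(n_blocks):
        pair = b % 3 + 1
        variant = b % 2  # alternates EV-, EV+ every block
        blocks.append(2 * (pair - 1) + variant + 1)
    return np.repeat(blocks, config.block_length)


def sample_point(table: OptionOutcomeTable, context: int, option: int,
                 rng: np.random.Generator) -> tuple[int, int]:
    """Draw a point-type vector f for a 1-based (context, option)."""
    row = table.probs[context - 1, option - 1]
    j = rng.choice(N_OUTCOMES, p=row)
    return tuple(POINT_TYPES[j])


def accumulate_points(w_prev: Sequence[int], f: Sequence[int]) -> tuple[int, int]:
    """w_t = f_t + w_{t-1}, componentwise."""
    return (w_prev[0] + f[0], w_prev[1] + f[1])


def encode_point_type(f: Sequence[int]) -> int:
    """Map the point-type vector to a scalar class: (0,0)->1, (1,0)->2, (0,1)->3."""
    f = tuple(f)
    mapping = {(0, 0): 1, (1, 0): 2, (0, 1): 3}
    if f not in mapping:
        raise ValueError(f"illegal point-type vector {f!r}")
    return mapping[f]


def evaluate_segment(w_final: Sequence[int], threshold: int = 4, *,
                     segment: int = 0, context: int = 0) -> SegmentResult:
    """Success iff at least ``threshold`` points of a single colour."""
    success = w_final[0] >= threshold or w_final[1] >= threshold
    return SegmentResult(segment=segment, context=context, success=bool(success))


class TaskEnvironment:
    """Stateful generative process an agent interacts with trial by trial."""

    def __init__(self, config: TaskConfig | None = None,
                 table: OptionOutcomeTable | None = None,
                 rng: np.random.Generator | int | None = None):
        self.config = config or TaskConfig()
        self.table = table or default_context_tables()
        self.rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        self.schedule = context_schedule(self.config)
        self.reset()

    def reset(self) -> None:
        self.segment = 1
        self.trial = 1
        self.w = (0, 0)
        self._trials: list[TrialObservation] = []

    @property
    def context(self) -> int:
        """True context of the current segment (1-based)."""
        return int(self.schedule[self.segment - 1])

    def step(self, option: int) -> TrialObservation:
        """Execute one trial with the chosen 1-based option."""
        T = self.config.trials_per_segment
        if self.trial > T:
            raise RuntimeError("segment finished; call end_segment() first")
        f = sample_point(self.table, self.context, option, self.rng)
        self.w = accumulate_points(self.w, f)
        obs = TrialObservation(l=option, f=f, w=self.w, h=encode_point_type(f))
        self._trials.append(obs)
        self.trial += 1
        return obs

    def end_segment(self) -> SegmentResult:
        """Score the finished segment and advance to the next one."""
        if self.trial != self.config.trials_per_segment + 1:
            raise RuntimeError("segment not finished")
        result = evaluate_segment(self.w, self.config.success_threshold,
                                  segment=self.segment, context=self.context)
        self.segment += 1
        self.trial = 1
        self.w = (0, 0)
        self._trials.clear()
        return result
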