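"""Group- and instance-level statistics over experiment logs.

The quantities mirror the analyses the simulation study is built around:
group mean success rates per segment, per-instance success probabilities over
a segment window, relative-segment alignment to context changes, survival
functions of instance performance, context-inference accuracy histograms and
pooled option-type choice probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agents import ExperimentLog
from .task import is_ev_plus

__all__ = [
    "group_mean_success_rate",
    "instance_success_probability",
    "align_relative_segments",
    "survival_function",
    "context_inference_accuracy",
    "option_type_choice_probs",
    "alpha_in_variant",
    "summarize_groups",
]


def group_mean_success_rate(logs: list[ExperimentLog], k: int) -> float:
    """Mean success at 1-based segment k across instances."""
    vals = []
    for log in logs:
        seg = log.segments
        if k < 1 or k > len(seg):
            raise ValueError(f"segment {k} missing from log")
        vals.append(seg["success"].iloc[k - 1])
    return float(np.mean(vals))


def instance_success_probability(log: ExperimentLog,
                                 omega: np.ndarray) -> float:
    """Mean success of one instance over the 1-based segment set Omega."""
    omega = np.asarray(omega, dtype=int)
    if omega.size == 0:
        raise ValueError("Omega must be non-empty")
    succ = log.segments["success"].to_numpy()
    if omega.min() < 1 or omega.max() > len(succ):
        raise ValueError("Omega outside the experiment range")
    return float(succ[omega - 1].mean())


def align_relative_segments(schedule: np.ndarray, last_n: int = 100,
                            block_length: int = 5) -> dict[int, np.ndarray]:
    """Segment sets Omega_r per relative segment number r in {0..block-1}.

    r = 0 is the first segment after each context change inside the analysed
    window (the last ``last_n`` segments); on the default 200-segment schedule
    Omega_0 = (101, 106, ...), Omega_1 = (102, 107, ...) and so on.  The sets
    are pairwise disjoint and cover the window.
    """
    K = len(schedule)
    start = K - last_n + 1  # first analysed segment, 1-based
    omegas: dict[int, list[int]] = {r: [] for r in range(block_length)}
    for k in range(start, K + 1):
        r = (k - 1) % block_length  # schedule changes at block boundaries
        omegas[r].append(k)
    return {r: np.asarray(v, dtype=int) for r, v in omegas.items()}


def survival_function(values: np.ndarray,
                      grid: np.ndarray | None = None) -> pd.DataFrame:
    """Complementary cumulative distribution S(x) = P(value >= x).

    Evaluated on a fixed grid (default 101 points on [0, 1]); the threshold
    is closed, so S(0.8) counts instances at or above 0.8.
    """
    values = np.asarray(values, dtype=float)
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    surv = np.array([(values >= x).mean() for x in grid])
    return pd.DataFrame({"threshold": grid, "survival": surv})


def context_inference_accuracy(logs: list[ExperimentLog],
                               window: slice = slice(100, None)) -> pd.DataFrame:
    """Fraction of segments whose posterior mode hits the true context.

    Grouped by context variant (EV-, EV+); one row per instance and variant.
    Ties resolve to the lowest context index upstream (argmax convention).
    """
    rows = []
    for n, log in enumerate(logs):
        seg = log.segments.iloc[window]
        hit = (seg["context_mode"] == seg["context"]).to_numpy()
        for ev, name in ((False, "EV-"), (True, "EV+")):
            mask = seg["ev_plus"].to_numpy() == ev
            rows.append(dict(instance=n, variant=name,
                             accuracy=float(hit[mask].mean())))
    return pd.DataFrame(rows)


#: option-type labels used for pooled choice probabilities
OPTION_TYPES = ("80%-1", "100%-1", "80%-0", "100%-0")


def _option_type(table: np.ndarray, context: int, option: int) -> str:
    """Classify a 1-based (context, option) by its point profile."""
    row = table[context - 1, option - 1]
    p_point = row[1] + row[2]
    if p_point >= 1.0 - 1e-9:
        return "100%-1"
    if p_point <= 1e-9:
        return "100%-0"
    return "80%-1" if p_point > 0.5 else "80%-0"


def option_type_choice_probs(logs: list[ExperimentLog], table: np.ndarray,
                             window_start: int = 101) -> pd.DataFrame:
    """Pooled choice probabilities over option types, split by variant.

    Pools all trials from segment ``window_start`` on, across instances.
    """
    counts: dict[tuple[str, str], int] = {}
    totals: dict[str, int] = {"EV-": 0, "EV+": 0}
    for log in logs:
        tr = log.trials[log.trials["segment"] >= window_start]
        for ctx, opt in zip(tr["context"].to_numpy(), tr["option"].to_numpy()):
            variant = "EV+" if is_ev_plus(int(ctx)) else "EV-"
            typ = _option_type(table, int(ctx), int(opt))
            counts[(variant, typ)] = counts.get((variant, typ), 0) + 1
            totals[variant] += 1
    rows = [dict(variant=v, option_type=t,
                 probability=counts.get((v, t), 0) / max(totals[v], 1))
            for v in ("EV-", "EV+") for t in OPTION_TYPES]
    return pd.DataFrame(rows)


def alpha_in_variant(log: ExperimentLog, ev_plus: bool,
                     window: slice = slice(100, None),
                     column: str = "alpha_mean") -> float:
    """Instance-mean epistemic weight over segments of one variant."""
    seg = log.segments.iloc[window]
    return float(seg.loc[seg["ev_plus"] == ev_plus, column].mean())


def summarize_groups(groups: dict[str, list[ExperimentLog]],
                     window: slice = slice(100, None)) -> pd.DataFrame:
    """One tidy row per (agent group, instance) with headline quantities."""
    rows = []
    for name, logs in groups.items():
        for n, log in enumerate(logs):
            seg = log.segments.iloc[window]
            rows.append(dict(
                group=name,
                instance=n,
                success=float(seg["success"].mean()),
                success_ev_plus=float(seg.loc[seg["ev_plus"], "success"].mean()),
                success_ev_minus=float(seg.loc[~seg["ev_plus"], "success"].mean()),
                accuracy=float((seg["context_mode"] == seg["context"]).mean()),
                alpha_ev_minus=alpha_in_variant(log, False, window),
                alpha_ev_plus=alpha_in_variant(log, True, window),
            ))
    return pd.DataFrame(rows)
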