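"""Bounded discrete-gamma duration priors and explicit-duration (semi-Markov)
context transition machinery.

Context dwell times are modelled with an explicit-duration hidden Markov model
(hidden semi-Markov model, HSMM): alongside the context ``c`` the model tracks
a duration counter ``d``.  While ``d > 1`` the context is frozen and the
counter counts down deterministically; when ``d = 1`` the context switches
uniformly to one of the remaining contexts and a fresh duration is drawn from
the prior ``p0(d)``.

Two named priors matter in practice:

* the *imprecise* prior (theta=1, beta=0.2) is geometric on its support, which
  makes the induced context chain (approximately) a plain HMM with a constant
  switch probability per segment;
* the *precise* prior (theta=20, beta=4) concentrates around d=5 and lets an
  agent anticipate the moment of change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DurationPrior",
    "ChangeProfile",
    "make_duration_prior",
    "hsmm_step",
    "effective_change_probability",
    "IMPRECISE",
    "PRECISE",
]


@dataclass(frozen=True)
class DurationPrior:
    """Bounded discrete-gamma prior over context dwell times d in {1..D}."""

    theta: float
    beta: float
    D: int
    p0: np.ndarray = field(repr=False)

    @property
    def mean(self) -> float:
        return float(np.sum(np.arange(1, self.D + 1) * self.p0))

    @property
    def variance(self) -> float:
        d = np.arange(1, self.D + 1)
        return float(np.sum(d**2 * self.p0) - self.mean**2)


@dataclass(frozen=True)
class ChangeProfile:
    """Effective change probability rho(tau) for tau = 1..tau_max."""

    rho: np.ndarray


def make_duration_prior(theta: float, beta: float, D: int = 20) -> DurationPrior:
    """Normalised p0(d) proportional to d**(theta-1) * exp(-beta*d) on 1..D."""
    if theta <= 0 or beta <= 0:
        raise ValueError(f"theta and beta must be positive, got {theta=}, {beta=}")
    if D < 1:
        raise ValueError(f"support bound D must be >= 1, got {D=}")
    d = np.arange(1, D + 1, dtype=float)
    # log-space to stay finite for large theta (e.g. theta=20 -> d**19)
    logp = (theta - 1.0) * np.log(d) - beta * d
    logp -= logp.max()
    p0 = np.exp(logp)
    p0 /= p0.sum()
    return DurationPrior(theta=theta, beta=beta, D=D, p0=p0)


#: canonical imprecise (HMM-like) and precise (anticipatory) priors
IMPRECISE = (1.0, 0.2)
PRECISE = (20.0, 4.0)


def hsmm_step(joint: np.ndarray, p0: np.ndarray) -> np.ndarray:
    """Advance a normalised joint belief over (context, duration) one segment.

    ``joint`` has shape (n_contexts, D).  Mass with d > 1 moves to
    (same context, d-1); mass with d = 1 is redistributed uniformly over the
    other n_contexts-1 contexts with a fresh duration drawn from ``p0``.
    """
    joint = np.asarray(joint, dtype=float)
    n_c, D = joint.shape
    total = joint.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"input joint must be normalised, got total mass {total}")
    out = np.zeros_like(joint)
    # deterministic countdown
    out[:, : D - 1] = joint[:, 1:]
    # renewal: mass at d=1 switches context and redraws a duration
    ending = joint[:, 0]  # shape (n_c,)
    switch = (ending.sum() - ending) / (n_c - 1)  # uniform over the *other* contexts
    out += switch[:, None] * p0[None, :]
    return out


def effective_change_probability(prior: DurationPrior, tau_max: int = 15,
                                 n_contexts: int = 6) -> ChangeProfile:
    """Probability that the context changes at segment tau after a fresh change.

    Starting from a fresh-change state (duration distributed as p0), iterate
    the HSMM countdown; rho(tau) is the probability that the duration counter
    sits at 1 at step tau-1, i.e. that a switch occurs between segments
    tau-1 and tau.  For the geometric (imprecise) prior this is the constant
    hazard of an HMM; for the precise prior it peaks around multiples of the
    mean dwell time.
    """
    joint = np.zeros((n_contexts, prior.D))
    joint[0] = prior.p0
    rho = np.empty(tau_max)
    for tau in range(1, tau_max + 1):
        rho[tau - 1] = joint[:, 0].sum()
        joint = hsmm_step(joint, prior.p0)
    return ChangeProfile(rho=rho)


def survival_by_enumeration(prior: DurationPrior, tau: int,
                            n_contexts: int = 6) -> float:
    """Brute-force P(context at step tau equals the fresh-change context).

    Enumerates every duration/renewal path explicitly; exponential in the
    number of renewals, intended only as a cross-check oracle for small tau.
    """
    p0 = prior.p0

    def recurse(step: int, same: bool, d: int) -> float:
        # context occupancy probability contributed from (same?, remaining d)
        if step == tau:
            return 1.0 if same else 0.0
        if d > 1:
            return recurse(step + 1, same, d - 1)
        # renewal: switch to one of the other contexts, redraw duration
        total = 0.0
        for nd in range(1, prior.D + 1):
            pd = p0[nd - 1]
            if pd == 0.0:
                continue
            if same:
                # leaves the reference context with certainty
                total += pd * recurse(step + 1, False, nd)
            else:
                # returns with prob 1/(n-1), stays away otherwise
                total += pd * (
                    recurse(step + 1, True, nd) / (n_contexts - 1)
                    + recurse(step + 1, False, nd) * (n_contexts - 2) / (n_contexts - 1)
                )
        return total

    return float(sum(p0[d - 1] * recurse(0, True, d) for d in range(1, prior.D + 1)))
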