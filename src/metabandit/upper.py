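"""Segment-level model over (context, duration, meta-control state).

The upper level treats one whole segment as a single time step.  Its hidden
state is s'' = (c'', d'', i''): context (6), duration counter (D=20, advanced
by the explicit-duration HSMM machinery) and meta-control state (2 for the
adaptive agent).  The only upper-level observation is the binary segment
outcome (failure/success), whose likelihood per (i, c) is learned as Dirichlet
counts b.  The two upper policies deterministically set the next segment's
meta-control state; their prior is a softmax of the (negative) expected free
energy, which combines expected success utility U = (+2, -2), the expected
information gain about s'' and the expected Dirichlet novelty of b.

Downward messages to the trial level pass through identity links: the prior
over the auxiliary context is the upper context marginal, the prior over the
auxiliary meta-state is the i'' marginal, and alpha_bar is the expected
epistemic weight under that marginal.  Upward messages (the lower level's
final q_c and q_i) enter the upper state posterior multiplicatively, in the
belief-propagation style that the identity links reduce to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .durations import DurationPrior, hsmm_step
from .lower import dirichlet_expectations

__all__ = [
    "UpperBeliefState",
    "LinkMessages",
    "upper_predictive",
    "upper_efe",
    "upper_policy_posterior",
    "upper_state_posterior",
    "update_upper_dirichlet",
    "link_down",
    "UpperLevel",
]

_FLOOR = 1e-16


@dataclass
class UpperBeliefState:
    """Per-policy conditional beliefs and the policy posterior."""

    q_s_given_pi: np.ndarray  # (n_pi, n_contexts, D, n_meta)
    q_pi2: np.ndarray         # (n_pi,)

    @property
    def q_s(self) -> np.ndarray:
        """Policy-marginalised belief over s''."""
        return np.einsum("p,pcdi->cdi", self.q_pi2, self.q_s_given_pi)


@dataclass(frozen=True)
class LinkMessages:
    """Downward priors for the trial level plus the expected epistemic weight."""

    p_c_down: np.ndarray
    p_i_down: np.ndarray
    alpha_bar: float


def upper_predictive(q_s_prev: np.ndarray, prior: DurationPrior,
                     pi2: int, n_meta: int) -> np.ndarray:
    """One-segment-ahead predictive for candidate policy pi2 (0-based).

    The (c, d) component advances by the HSMM countdown; the meta-control
    component is set deterministically by the control signal.
    """
    cd = q_s_prev.sum(axis=-1)  # marginal over (c, d)
    cd = hsmm_step(cd, prior.p0)
    out = np.zeros(q_s_prev.shape[:2] + (n_meta,))
    out[:, :, pi2] = cd
    return out


def upper_efe(predictive: np.ndarray, b: np.ndarray,
              utility: tuple[float, float] = (-2.0, 2.0)) -> float:
    """Expected free energy of one upper policy under its predictive belief.

    ``b`` has shape (n_meta, n_contexts, 2) over outcomes (failure, success).
    G = -(expected utility + state information gain + Dirichlet novelty),
    everything evaluated one segment ahead with Dirichlet mean likelihoods.
    """
    mean, _ = dirichlet_expectations(b)  # (i, c, o)
    # joint over (c, i) — duration does not touch the outcome likelihood
    q_ci = predictive.sum(axis=1)  # (c, i)
    lik = np.transpose(mean, (1, 0, 2))  # (c, i, o)
    p_o = np.einsum("ci,cio->o", q_ci, lik)
    p_o = np.maximum(p_o, _FLOOR)
    exp_util = float(p_o @ np.asarray(utility))
    # state info gain: I((c,i); o) under the predictive
    ratio = np.log(np.maximum(lik, _FLOOR)) - np.log(p_o)[None, None, :]
    state_ig = float(np.einsum("ci,cio,cio->", q_ci, lik, ratio))
    # Dirichlet novelty of b: exact one-observation KL per (i, c) row
    from scipy.special import digamma

    b0 = b.sum(axis=-1, keepdims=True)
    kl_unit = np.log(b0 / b) + digamma(b + 1.0) - digamma(b0 + 1.0)  # (i, c, o)
    novelty = float(np.einsum("ci,cio,ico->", q_ci, lik, kl_unit))
    return -(exp_util + state_ig + novelty)


def upper_state_posterior(predictive: np.ndarray, o_k: int, b: np.ndarray,
                          q_c_msg: np.ndarray, q_i_msg: np.ndarray) -> np.ndarray:
    """Q(s''|pi'') from predictive prior, outcome likelihood and lower messages.

    Identity links make the lower-level message a multiplicative factor
    q_c_msg(c) * q_i_msg(i) on the upper joint.
    """
    mean, _ = dirichlet_expectations(b)  # (i, c, o)
    lik = mean[:, :, o_k].T  # (c, i)
    post = predictive * lik[:, None, :] * q_c_msg[:, None, None] * q_i_msg[None, None, :]
    total = post.sum()
    if total <= 0:
        # numerical floor: fall back to the predictive re-weighted by likelihood
        post = np.maximum(predictive * lik[:, None, :], _FLOOR)
        total = post.sum()
    return post / total


def upper_policy_posterior(G: np.ndarray, log_evidence: np.ndarray,
                           gamma: float = 8.0) -> np.ndarray:
    """Q(pi'') ∝ softmax(-gamma G) * exp(log evidence per policy)."""
    logits = -gamma * np.asarray(G) + np.asarray(log_evidence)
    logits = logits - logits.max()
    q = np.exp(logits)
    return q / q.sum()


def update_upper_dirichlet(b: np.ndarray, o_k: int, q_i: np.ndarray,
                           q_c: np.ndarray) -> np.ndarray:
    """b[i, c, o_k] += q_i(i) * q_c(c); adds total mass exactly 1."""
    b = b.copy()
    b[:, :, o_k] += np.outer(q_i, q_c)
    return b


def link_down(q_s: np.ndarray, alpha_map: np.ndarray) -> LinkMessages:
    """Identity-link downward messages from a belief over (c'', d'', i'')."""
    p_c = q_s.sum(axis=(1, 2))
    p_i = q_s.sum(axis=(0, 1))
    p_c = p_c / p_c.sum()
    p_i = p_i / p_i.sum()
    alpha_bar = float(p_i @ alpha_map[: len(p_i)])
    return LinkMessages(p_c_down=p_c, p_i_down=p_i, alpha_bar=alpha_bar)


class UpperLevel:
    """Segment-by-segment upper inference loop."""

    def __init__(self, duration_prior: DurationPrior, n_contexts: int = 6,
                 n_meta: int = 2, gamma: float = 8.0,
                 utility: tuple[float, float] = (-2.0, 2.0),
                 alpha_map: tuple[float, ...] = (1.0, 0.0),
                 b0: float = 1.0):
        self.prior = duration_prior
        self.n_contexts = n_contexts
        self.n_meta = n_meta
        self.n_pi = n_meta  # one upper policy per reachable meta-state
        self.gamma = gamma
        self.utility = utility
        self.alpha_map = np.asarray(alpha_map, dtype=float)
        self.b = np.full((n_meta, n_contexts, 2), b0)
        # initial belief: uniform context, duration from the prior, uniform meta
        q0 = np.ones((n_contexts, duration_prior.D, n_meta))
        q0 *= duration_prior.p0[None, :, None]
        self.q_s = q0 / q0.sum()

    def start_segment(self) -> tuple[np.ndarray, np.ndarray, LinkMessages]:
        """Predictive step, policy prior and downward messages (no evidence yet)."""
        self.predictive = np.stack([
            upper_predictive(self.q_s, self.prior, p, self.n_meta)
            for p in range(self.n_pi)
        ])
        G = np.array([upper_efe(self.predictive[p], self.b, self.utility)
                      for p in range(self.n_pi)])
        logits = -self.gamma * G
        logits -= logits.max()
        prior_pi = np.exp(logits)
        prior_pi /= prior_pi.sum()
        self.G = G
        self.prior_pi = prior_pi
        q_s_start = np.einsum("p,pcdi->cdi", prior_pi, self.predictive)
        messages = link_down(q_s_start, self.alpha_map)
        return G, prior_pi, messages

    def end_segment(self, o_k: int, q_c_msg: np.ndarray,
                    q_i_msg: np.ndarray) -> UpperBeliefState:
        """Absorb the segment outcome and the lower level's final beliefs."""
        mean, _ = dirichlet_expectations(self.b)
        lik = mean[:, :, o_k].T  # (c, i)
        q_given = np.empty_like(self.predictive)
        log_evidence = np.empty(self.n_pi)
        for p in range(self.n_pi):
            joint = (self.predictive[p] * lik[:, None, :]
                     * q_c_msg[:, None, None] * q_i_msg[None, None, :])
            total = joint.sum()
            log_evidence[p] = np.log(max(total, _FLOOR))
            if total <= 0:
                joint = np.maximum(self.predictive[p] * lik[:, None, :], _FLOOR)
                total = joint.sum()
            q_given[p] = joint / total
        q_pi2 = upper_policy_posterior(self.G, log_evidence, self.gamma)
        state = UpperBeliefState(q_s_given_pi=q_given, q_pi2=q_pi2)
        self.q_s = state.q_s
        q_i_post = self.q_s.sum(axis=(0, 1))
        q_c_post = self.q_s.sum(axis=(1, 2))
        self.b = update_upper_dirichlet(self.b, o_k, q_i_post, q_c_post)
        return state
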