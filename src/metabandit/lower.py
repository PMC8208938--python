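"""Within-segment (trial-level) generative model and variational updates.

A lower-level policy is a full sequence of T=5 option choices.  Because the
chosen-option dynamics are deterministic, beliefs about the location sequence
are degenerate and the whole within-segment problem reduces to:

* a posterior over the auxiliary context ``q_c`` (which option-outcome table
  is active), driven by expected log-likelihoods of the observed outcomes
  under the Dirichlet beliefs about the tables;
* a posterior over the auxiliary meta-control state ``q_i``, driven by how
  well each meta-state's policy prior matches the policy posterior;
* a posterior over policies ``q_pi`` proportional to
  exp(gamma * [alpha_bar * info_gain + expected_utility]) on the policies
  consistent with the actions already executed (the past free energy F is
  identical for all consistent policies and infinite for the rest, so it
  drops out of the softmax).

The expected free energy of a policy combines the expected probability of
segment success (utility) with an additive information gain: per future trial,
the mutual information between the context and the predicted outcome plus the
expected Dirichlet novelty (exact one-observation KL).  Both are computed from
Dirichlet mean probabilities.  Every EFE term depends on a policy only through
the *multiset* of its remaining options (outcomes are iid given context and
option), which the implementation exploits: quantities are evaluated once per
multiset (<= 56 of them) and broadcast to the full policy set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import digamma


def logsumexp(x: np.ndarray) -> float:
    """Max-subtracted log-sum-exp over a 1-d array (cheap local variant)."""
    x = np.asarray(x, dtype=float)
    m = np.max(x)
    if not np.isfinite(m):
        return m
    return float(m + np.log(np.sum(np.exp(x - m))))

__all__ = [
    "PolicySetLower",
    "LowerBeliefState",
    "EFETermsLower",
    "enumerate_policies",
    "dirichlet_expectations",
    "lower_efe_terms",
    "lower_policy_prior",
    "past_free_energy",
    "lower_policy_posterior",
    "update_lower_state_beliefs",
    "update_lower_dirichlet",
    "LowerLevel",
]

_FLOOR = 1e-300


@dataclass(frozen=True)
class PolicySetLower:
    """Exhaustive, lexicographically ordered option sequences (0-based)."""

    policies: np.ndarray  # (n_policies, T) int
    n_options: int
    T: int

    def consistency_mask(self, executed: list[int] | np.ndarray) -> np.ndarray:
        """True for policies whose first len(executed) entries match."""
        executed = np.asarray(executed, dtype=int)
        t = len(executed)
        if t == 0:
            return np.ones(len(self.policies), dtype=bool)
        return np.all(self.policies[:, :t] == executed[None, :], axis=1)


def enumerate_policies(n_options: int, T: int) -> PolicySetLower:
    """All n_options**T option sequences, lexicographic, stable across runs."""
    if n_options < 1 or T < 1:
        raise ValueError("n_options and T must be >= 1")
    n = n_options**T
    if n > 10**7:
        raise ValueError(f"policy space of size {n} exceeds the enumeration guard")
    grids = np.meshgrid(*[np.arange(n_options)] * T, indexing="ij")
    policies = np.stack([g.ravel() for g in grids], axis=1)
    return PolicySetLower(policies=policies, n_options=n_options, T=T)


def dirichlet_expectations(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean probabilities and expected log probabilities of Dirichlet rows.

    The last axis indexes outcome classes; any leading axes are row batches.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise ValueError("Dirichlet counts must be strictly positive")
    a0 = a.sum(axis=-1, keepdims=True)
    return a / a0, digamma(a) - digamma(a0)


# ---------------------------------------------------------------------------
# multiset machinery


@lru_cache(maxsize=None)
def _multisets(n_options: int, m: int) -> tuple[np.ndarray, np.ndarray]:
    """All option-count vectors summing to m, and their multinomial weights.

    Returns (counts, log_mult) with counts of shape (K, n_options); log_mult
    is the log number of distinct sequences realising each count vector.
    """
    from math import lgamma

    def compositions(k, total):
        if k == 1:
            yield (total,)
            return
        for first in range(total + 1):
            for rest in compositions(k - 1, total - first):
                yield (first,) + rest

    counts = np.array(list(compositions(n_options, m)), dtype=int)
    log_mult = np.array([
        lgamma(m + 1) - sum(lgamma(c + 1) for c in row) for row in counts
    ])
    return counts, log_mult


def _shift_cap(dist: np.ndarray, axis: int) -> np.ndarray:
    """Move mass one step up the point-count axis, accumulating at the cap."""
    out = np.zeros_like(dist)
    src = [slice(None)] * dist.ndim
    dst = [slice(None)] * dist.ndim
    src[axis], dst[axis] = slice(0, -1), slice(1, None)
    out[tuple(dst)] = dist[tuple(src)]
    src[axis] = slice(-1, None)
    dst[axis] = slice(-1, None)
    out[tuple(dst)] += dist[tuple(src)]
    return out


def _apply_option(dist: np.ndarray, p: np.ndarray) -> np.ndarray:
    """One trial of option play: p has shape (..., 3) over {none, blue, red}."""
    return (
        p[..., 0, None, None] * dist
        + p[..., 1, None, None] * _shift_cap(dist, -2)
        + p[..., 2, None, None] * _shift_cap(dist, -1)
    )


def multiset_success_probs(mean: np.ndarray, w: tuple[int, int], m: int,
                           threshold: int) -> tuple[np.ndarray, np.ndarray]:
    """P(segment success | context, remaining-option multiset).

    ``mean`` is the (n_contexts, n_options, 3) outcome-probability table,
    ``w`` the current (blue, red) point counts and ``m`` the number of trials
    left.  Returns (counts (K, n_options), success (K, n_contexts)) where the
    point counts are tracked on a grid capped at ``threshold``.
    """
    n_c, n_opt, _ = mean.shape
    counts, _ = _multisets(n_opt, m)
    K = len(counts)
    grid = threshold + 1
    dist = np.zeros((K, n_c, grid, grid))
    dist[:, :, min(w[0], threshold), min(w[1], threshold)] = 1.0
    for l in range(n_opt):
        col = counts[:, l]
        for step in range(1, int(col.max()) + 1):
            rows = col >= step
            dist[rows] = _apply_option(dist[rows], mean[None, :, l, :])
    success = dist[:, :, threshold, :].sum(axis=-1) + dist[:, :, :threshold, threshold].sum(axis=-1)
    return counts, success


def _unit_novelty(a: np.ndarray) -> np.ndarray:
    """Exact KL(Dir(a + e_j) || Dir(a)) per cell: ln(a0/a_j)+psi(a_j+1)-psi(a0+1)."""
    a0 = a.sum(axis=-1, keepdims=True)
    return np.log(a0 / a) + digamma(a + 1.0) - digamma(a0 + 1.0)


def _option_info_from(mean: np.ndarray, kl_unit: np.ndarray,
                      q_c: np.ndarray) -> np.ndarray:
    log_mean = np.log(np.maximum(mean, _FLOOR))
    pbar = np.einsum("c,clj->lj", q_c, mean)
    ratio = log_mean - np.log(np.maximum(pbar, _FLOOR))[None]
    state_ig = np.einsum("c,clj,clj->l", q_c, mean, ratio)
    novelty = np.einsum("c,clj,clj->l", q_c, mean, kl_unit)
    return state_ig + novelty


def option_info_terms(a: np.ndarray, q_c: np.ndarray) -> np.ndarray:
    """Per-option expected information gain for a single trial.

    Sum of the context information gain (mutual information between the
    context and the predicted outcome, under Dirichlet mean probabilities)
    and the expected Dirichlet novelty, the exact KL of a unit count update
    ln(a0/a_j) + psi(a_j + 1) - psi(a0 + 1), averaged over predicted outcomes.
    Returns shape (n_options,).
    """
    mean, _ = dirichlet_expectations(a)
    return _option_info_from(mean, _unit_novelty(a), q_c)


# ---------------------------------------------------------------------------
# spec-level per-policy operations (exact; used directly by the agent loop
# through their per-multiset internals)


@dataclass
class EFETermsLower:
    """Per-policy EFE ingredients at the current trial.

    ``info_gain`` and ``exp_utility`` have shape (n_policies, T); columns
    before the current trial are zero (those actions are in the past).
    Utility lives entirely in the final column (segment success is scored at
    tau = T).  ``consistent`` marks policies compatible with executed actions.
    """

    info_gain: np.ndarray
    exp_utility: np.ndarray
    consistent: np.ndarray
    gamma: float = 8.0
    alpha_map: tuple[float, ...] = (1.0, 0.0)

    def total(self, alpha: float) -> np.ndarray:
        """-G(pi'|alpha)/gamma = alpha * info gain + expected utility, per policy."""
        return alpha * self.info_gain.sum(axis=1) + self.exp_utility.sum(axis=1)


def lower_efe_terms(policy_set: PolicySetLower, a: np.ndarray, q_c: np.ndarray,
                    executed: list[int], w: tuple[int, int] = (0, 0),
                    threshold: int = 4, gamma: float = 8.0,
                    alpha_map: tuple[float, ...] = (1.0, 0.0)) -> EFETermsLower:
    """Expected free-energy terms for every policy at trial t = len(executed)+1."""
    T = policy_set.T
    t0 = len(executed)  # number of completed trials
    m = T - t0
    mean, _ = dirichlet_expectations(a)
    consistent = policy_set.consistency_mask(executed)
    pols = policy_set.policies

    info = option_info_terms(a, q_c)
    info_gain = np.zeros((len(pols), T))
    info_gain[:, t0:] = info[pols[:, t0:]]

    exp_utility = np.zeros((len(pols), T))
    counts, succ = multiset_success_probs(mean, w, m, threshold)
    succ_marg = succ @ q_c  # (K,)
    # map each policy's remaining-action counts onto its multiset row
    key = {tuple(row): i for i, row in enumerate(counts)}
    rem_counts = np.stack(
        [np.sum(pols[:, t0:] == l, axis=1) for l in range(policy_set.n_options)],
        axis=1,
    )
    idx = np.array([key[tuple(row)] for row in rem_counts])
    exp_utility[:, T - 1] = succ_marg[idx]
    info_gain[~consistent] = 0.0
    exp_utility[~consistent] = 0.0
    return EFETermsLower(info_gain=info_gain, exp_utility=exp_utility,
                         consistent=consistent, gamma=gamma, alpha_map=tuple(alpha_map))


def lower_policy_prior(terms: EFETermsLower, meta_state: int) -> np.ndarray:
    """p(pi'|i') = softmax(-G(pi'|i')) over consistent policies."""
    alpha = terms.alpha_map[meta_state]
    logits = terms.gamma * terms.total(alpha)
    logits = np.where(terms.consistent, logits, -np.inf)
    out = np.exp(logits - logsumexp(logits))
    return out / out.sum()


def past_free_energy(policy_set: PolicySetLower, executed: list[int],
                     outcomes: list[int], q_c: np.ndarray, a: np.ndarray,
                     p_c_down: np.ndarray) -> np.ndarray:
    """F(pi') per policy: KL[q_c || p_down] minus accumulated expected
    log-likelihood of this segment's outcomes, +inf for inconsistent policies.

    ``outcomes`` holds 1-based outcome classes h_t for the executed trials.
    """
    _, elog = dirichlet_expectations(a)
    kl = float(np.sum(q_c * (np.log(np.maximum(q_c, _FLOOR))
                             - np.log(np.maximum(p_c_down, _FLOOR)))))
    ll = 0.0
    for l, h in zip(executed, outcomes):
        ll += float(q_c @ elog[:, l, h - 1])
    F = np.full(len(policy_set.policies), np.inf)
    F[policy_set.consistency_mask(executed)] = kl - ll
    return F


def lower_policy_posterior(terms: EFETermsLower, F: np.ndarray,
                           q_i: np.ndarray) -> np.ndarray:
    """Q(pi') ∝ exp(gamma [alpha_bar * IG + EU] - F), in log space."""
    alpha_bar = float(np.dot(q_i, terms.alpha_map[: len(q_i)]))
    logits = terms.gamma * terms.total(alpha_bar) - F
    logits = np.where(np.isfinite(logits), logits, -np.inf)
    out = np.exp(logits - logsumexp(logits))
    return out / out.sum()


def update_lower_state_beliefs(executed: list[int], outcomes: list[int],
                               q_pi: np.ndarray, terms: EFETermsLower,
                               a: np.ndarray, p_c_down: np.ndarray,
                               p_i_down: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-field updates of the auxiliary context and meta-state beliefs.

    q_c ∝ p_down(c) exp(sum_t E[ln p(o_t | l_t, c, A')]) and
    q_i ∝ p_down(i) exp(sum_pi Q(pi') ln p(pi'|i')).
    """
    _, elog = dirichlet_expectations(a)
    log_qc = np.log(np.maximum(p_c_down, _FLOOR)).copy()
    for l, h in zip(executed, outcomes):
        log_qc += elog[:, l, h - 1]
    q_c = np.exp(log_qc - logsumexp(log_qc))
    q_c /= q_c.sum()

    log_qi = np.log(np.maximum(p_i_down, _FLOOR)).copy()
    for i in range(len(p_i_down)):
        log_prior = np.full(len(q_pi), -np.inf)
        prior = lower_policy_prior(terms, i)
        np.log(np.maximum(prior, _FLOOR), out=log_prior, where=prior > 0)
        log_qi[i] += float(np.sum(q_pi * np.where(q_pi > 0, log_prior, 0.0)))
    q_i = np.exp(log_qi - logsumexp(log_qi))
    q_i /= q_i.sum()
    return q_c, q_i


def update_lower_dirichlet(a: np.ndarray, h: int, q_l: np.ndarray,
                           q_c: np.ndarray) -> np.ndarray:
    """a[c, l, h] += q_c(c) * q_l(l); adds total mass exactly 1."""
    a = a.copy()
    a[:, :, h - 1] += np.outer(q_c, q_l)
    return a


# ---------------------------------------------------------------------------
# fast per-segment engine (multiset representation throughout)


@dataclass
class LowerBeliefState:
    """Trial-resolved belief snapshot within a segment."""

    q_c: np.ndarray
    q_i: np.ndarray
    alpha_bar: float
    action_marginal: np.ndarray
    policy_entropy: float


class LowerLevel:
    """Runs the five-trial inference/action loop of one segment.

    Equivalent to the per-policy operations above (verified in tests) but
    works on remaining-action multisets, so a trial costs O(56) policy
    evaluations instead of O(1024).
    """

    def __init__(self, a: np.ndarray, T: int = 5, threshold: int = 4,
                 gamma: float = 8.0, alpha_map: tuple[float, ...] = (1.0, 0.0),
                 action_rule: str = "sample"):
        self.a = np.asarray(a, dtype=float)
        self.n_contexts, self.n_options, _ = self.a.shape
        self.T = T
        self.threshold = threshold
        self.gamma = gamma
        self.alpha_map = np.asarray(alpha_map, dtype=float)
        if action_rule not in ("sample", "argmax"):
            raise ValueError(f"unknown action rule {action_rule!r}")
        self.action_rule = action_rule

    def start_segment(self, p_c_down: np.ndarray, p_i_down: np.ndarray) -> None:
        # counts only change at segment end, so cache their expectations here
        self._mean, self._elog = dirichlet_expectations(self.a)
        self._kl_unit = _unit_novelty(self.a)
        self.p_c_down = np.asarray(p_c_down, dtype=float)
        self.p_i_down = np.asarray(p_i_down, dtype=float)
        self.q_c = self.p_c_down.copy()
        self.q_i = self.p_i_down.copy()
        self.executed: list[int] = []   # 0-based options
        self.outcomes: list[int] = []   # 1-based classes
        self.w = (0, 0)
        self._elog_sum = np.zeros(self.n_contexts)
        self.trace: list[LowerBeliefState] = []

    # -- internals ---------------------------------------------------------

    def _policy_weights(self):
        """Per-multiset EFE ingredients for the remaining trials."""
        m = self.T - len(self.executed)
        counts, log_mult = _multisets(self.n_options, m)
        _, succ = multiset_success_probs(self._mean, self.w, m, self.threshold)
        succ_marg = succ @ self.q_c
        info = _option_info_from(self._mean, self._kl_unit, self.q_c)
        ig = counts @ info
        return counts, log_mult, ig, succ_marg

    def _posterior_over_multisets(self, counts, log_mult, ig, succ_marg):
        alpha_bar = float(self.q_i @ self.alpha_map[: len(self.q_i)])
        logw = self.gamma * (alpha_bar * ig + succ_marg)  # per-sequence log weight
        log_seq_mass = logw + log_mult                    # per-multiset total
        q_mu = np.exp(log_seq_mass - logsumexp(log_seq_mass))
        q_mu /= q_mu.sum()
        return alpha_bar, logw, q_mu

    def plan(self) -> LowerBeliefState:
        """Recompute beliefs and the next-action marginal at the current trial.

        The policy posterior and the meta-state belief are coupled coordinate
        updates of the same variational objective, so they are iterated to
        their mean-field fixed point (the pair reinforces itself: an
        information-heavy posterior favours the epistemic meta-state, which
        raises alpha_bar and sharpens the posterior further).
        """
        counts, log_mult, ig, succ_marg = self._policy_weights()
        # per-meta-state log policy priors (fixed within the iteration)
        logp_i = [self.gamma * (self.alpha_map[i] * ig + succ_marg)
                  for i in range(len(self.p_i_down))]
        logZ_i = [logsumexp(lp + log_mult) for lp in logp_i]
        log_p_down = np.log(np.maximum(self.p_i_down, _FLOOR))
        for _ in range(64):
            _, _, q_mu = self._posterior_over_multisets(
                counts, log_mult, ig, succ_marg)
            log_qi = log_p_down.copy()
            for i in range(len(self.p_i_down)):
                log_qi[i] += float(np.sum(q_mu * (logp_i[i] - logZ_i[i])))
            q_i_new = np.exp(log_qi - logsumexp(log_qi))
            q_i_new /= q_i_new.sum()
            delta = float(np.max(np.abs(q_i_new - self.q_i)))
            self.q_i = q_i_new
            if delta < 1e-8:
                break
        # policy posterior and action marginal at the fixed point
        alpha_bar, logw, q_mu = self._posterior_over_multisets(
            counts, log_mult, ig, succ_marg)
        m = counts.sum(axis=1)[0] if len(counts) else 0
        # marginal over the next action: share of sequences in each multiset
        # that start with a given option is counts_l / m
        action_marginal = q_mu @ (counts / max(m, 1))
        action_marginal = np.maximum(action_marginal, 0)
        action_marginal /= action_marginal.sum()
        # entropy of the sequence posterior (uniform within a multiset)
        logq_seq = logw - logsumexp(logw + log_mult)
        entropy = -float(np.sum(q_mu * logq_seq))
        state = LowerBeliefState(q_c=self.q_c.copy(), q_i=self.q_i.copy(),
                                 alpha_bar=alpha_bar,
                                 action_marginal=action_marginal,
                                 policy_entropy=entropy)
        self.trace.append(state)
        return state

    def choose(self, state: LowerBeliefState, rng: np.random.Generator) -> int:
        """Pick the next option (0-based) from the planned action marginal."""
        if self.action_rule == "argmax":
            return int(np.argmax(state.action_marginal))
        return int(rng.choice(self.n_options, p=state.action_marginal))

    def observe(self, option: int, h: int, w: tuple[int, int]) -> None:
        """Register the executed option (0-based), outcome class h and new w."""
        self.executed.append(option)
        self.outcomes.append(h)
        self.w = w
        self._elog_sum += self._elog[:, option, h - 1]
        log_qc = np.log(np.maximum(self.p_c_down, _FLOOR)) + self._elog_sum
        self.q_c = np.exp(log_qc - logsumexp(log_qc))
        self.q_c /= self.q_c.sum()

    def finish_segment(self) -> None:
        """Segment-end Dirichlet learning with the final context beliefs."""
        for l, h in zip(self.executed, self.outcomes):
            q_l = np.zeros(self.n_options)
            q_l[l] = 1.0
            self.a = update_lower_dirichlet(self.a, h, q_l, self.q_c)
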