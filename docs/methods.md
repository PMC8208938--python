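# Methods

## The task

The environment is a restless multi-armed bandit with segment-wise goals.
Time is organised in *segments* of T = 5 trials; on every trial the agent
chooses one of four options and receives a blue point, a red point, or
nothing.  A segment is a success when at least 4 points of a single colour
were collected.  Which option yields what is governed by a hidden *context*,
one of six tables that switches every block of 5 segments (200 segments in a
run, so 1,000 trials).

The six contexts form three pairs.  Within a pair the two variants, EV− and
EV+, share options 1–3 and differ only in option 4: it yields a point of the
pair's dominant colour with certainty in EV+ and nothing with certainty in
EV−.  Each context carries exactly one stochastic colour option
(probability 0.8 of the dominant colour), two options that mostly give
nothing (0.8 no-point), and the deterministic option 4.  Pairs 1 and 2 share
the dominant colour (blue) but place the colour option in different slots;
pair 3 is red.  This makes every context identifiable in principle while
option 4 remains the unique variant-discriminating probe: with the pair known
but the variant not, option 4 has expected return 0.5 against the colour
option's 0.8, so an agent that values information will probe it and an agent
that values only return will not.  The default block schedule cycles the
pairs 1 → 2 → 3 while alternating the variants EV−, EV+, so consecutive
blocks always differ and every context recurs several times in 200 segments.
The whole table and schedule are configurable.

## The agent

The agent is a two-level generative model inverted by variational inference.

**Trial level.**  Policies are complete 5-trial option sequences
(4^5 = 1024).  Locations are set deterministically by actions, so beliefs
within a segment reduce to a categorical posterior over the auxiliary context
`q_c`, a posterior over the auxiliary meta-control state `q_i`, and a policy
posterior

    Q(pi) ∝ exp( gamma [ alpha_bar * InfoGain(pi) + E[U](pi) ] )

restricted to policies consistent with the actions already taken (the past
free energy is identical on that set and infinite off it).  `E[U](pi)` is the
predicted probability of reaching the 4-point threshold by the end of the
segment, computed by dynamic programming over the capped point-count grid
under Dirichlet-mean outcome probabilities.  `InfoGain` adds, per future
trial, (i) the mutual information between the context and the predicted
outcome and (ii) the expected Dirichlet novelty of the outcome-table beliefs,
using the exact one-observation KL
`ln(a0/a_j) + psi(a_j+1) − psi(a0+1)`.  Information is accumulated additively
across future trials from the current beliefs, without conditioning on
hypothetical intermediate outcomes; this is the standard treatment in
discrete active inference and follows the per-step sum in the model's policy
prior.  The precision is gamma = 8.

Because outcomes are i.i.d. given context and option, every EFE ingredient
depends on a policy only through the multiset of its remaining options.  The
implementation therefore evaluates at most C(m+3,3) ≤ 56 multisets per trial
and broadcasts to policies; tests verify exact agreement with the
per-policy path.

`q_c` multiplies the downward context message by the exponentiated expected
log-likelihood (digamma form) of this segment's outcomes.  `q_i` multiplies
the downward meta-state message by `exp(Σ_pi Q(pi) ln p(pi|i))`, i.e. it
moves toward the meta-state whose policy prior better matches the posterior.
The policy and meta-state updates are coupled coordinate updates of one
variational objective and are iterated to their fixed point within each
trial; the pair is self-reinforcing, which is what lets the effective
epistemic weight saturate.

The effective weight is `alpha_bar = Σ_i q_i(i) alpha(i)` with
alpha = (1, 0) over the two meta-control states.  The IV agent fixes
alpha = 0, the EFE agent alpha = 1, the adaptive (ADP) agent carries both
states and infers between them; the random-choice (RC) agent bypasses
inference entirely.

**Segment level.**  The hidden state is (context, duration counter,
meta-control state).  Context dwell times follow a bounded discrete-gamma
prior `p0(d) ∝ d^(theta−1) e^(−beta d)` on d = 1..20; the transition is a
deterministic countdown that, on expiry, moves uniformly to one of the other
five contexts and redraws a duration (an explicit-duration semi-Markov
chain).  Two canonical priors are used: *imprecise* (theta=1, beta=0.2),
geometric on its support and therefore equivalent to a plain HMM with
per-segment switch probability 1 − e^(−0.2) ≈ 0.18, and *precise*
(theta=20, beta=4), sharply concentrated at 5 segments.  Both have dwell-time
mean ≈ 5.  The induced change-probability profile rho(tau) — the probability
that a switch occurs tau segments after the last one — is flat for the
imprecise prior and peaked at multiples of 5 for the precise one.

The only segment-level observation is the binary outcome, with Dirichlet
likelihood counts b per (meta-state, context), initialised at (1, 1).  The
two upper policies deterministically set the next segment's meta-control
state; their prior is `sigma(−gamma G)` where G combines expected utility
(U = +2 success, −2 failure), the expected information gain about the hidden
state and the expected Dirichlet novelty of b, all one segment ahead.  At
segment start the policy prior (no evidence yet) defines the downward
messages: the context marginal, the meta-state marginal, and the segment-
start alpha_bar that the anticipation analyses use.  After the outcome, the
per-policy state posterior multiplies the predictive prior, the Dirichlet-
mean outcome likelihood and the lower level's final `q_c`, `q_i` (identity
links make the lower message a multiplicative factor; the exponentiated
mean-field form of that message is degenerate for exact identity links, so
the belief-propagation-style product is used).  The policy posterior weighs
the prior by each policy's marginal evidence.  Dirichlet counts are updated
once per segment: total mass 5 at the trial level (one per trial, spread by
the segment-final `q_c`) and 1 at the segment level.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| gamma | 8 | policy precision at both levels |
| U upper | (−2, +2) | outcome preferences (failure, success) |
| U lower | 0/1 | threshold indicator at the final trial |
| theta, beta, D | (1, 0.2) or (20, 4), 20 | duration prior |
| a0, a0_anchor | 1/3, 1.0 | trial-level Dirichlet prior: `a = a0 + a0_anchor * A_true` |
| b0 | 1.0 | segment-level Dirichlet prior per cell |
| action rule | argmax | deterministic maximum of the next-action marginal |

Two defaults deserve justification.

*Prior anchoring.*  A fully symmetric trial-level prior makes the six
context labels exchangeable, and every update preserves that symmetry: a
uniform `q_c` spreads identical counts to every context, so contexts can
never differentiate and behaviour stays at chance indefinitely.  The prior
is therefore a weak anchor on the true tables (one pseudo-observation of the
true row plus a flat 1/3 per cell, concentration 2 per row), read as the
agent having vague but correctly labelled prior knowledge of the
contingencies.  This also makes context-identification accuracy against the
true labels meaningful.  Setting `a0_anchor = 0` recovers the symmetric
prior for experimentation.

*Deterministic action selection.*  Sampling actions from the policy
posterior adds irreducible choice noise: the softmax over 1024 sequences
(many sharing outcome-equivalent multisets with large multiplicities) leaves
~45% of the action mass off the best option even in a fully known context,
which caps exploit-mode success near 0.55 and makes high instance-level
success probabilities unattainable.  With argmax, between-instance
variability comes entirely from the stochastic outcomes, and instance
success distributions reach the observed ranges.  `action_rule="sample"`
remains available.

## Emergent behaviour

With these mechanics and no per-context tuning: the EFE agent probes
option 4, excels in EV+ (success ≈ 0.98) and pays for it in EV− (≈ 0.47);
the IV agent is the mirror image; the ADP agent learns, through the
correlation between its meta-state beliefs and segment outcomes, to
downregulate its epistemic weight in EV− blocks (most instances end below
the 0.5 level) while matching the EFE agent in EV+.  With the precise
duration prior the ADP agent lowers its segment-start epistemic weight at
the first post-change segment *before seeing any outcome of that block* —
anticipatory meta-control — whereas the imprecise-prior agent reacts only
after evidence arrives.

## Numerical choices

* All policy weights are handled in log space with max subtraction;
  probabilities are floored at 1e-300 before logs; argmax ties break to the
  lowest index.
* The point-count DP caps counts at the success threshold (cells mean "at
  least threshold"), which is exact for the success indicator.
* Expected log-likelihoods use the digamma form; EFE outcome predictions use
  Dirichlet means (following the model's printed functionals).
* Replicas draw independent generator substreams spawned from one master
  seed; a run is bit-reproducible from (config, seed).

## Problem sizes

Default experiments are 200 segments (1,000 trials); statistics use the last
100 segments, treating the first half as the learning phase.  Group analyses
in the test suite use 30 replicas per agent type; the acceptance script runs
the full 100 replicas per type.  These sizes keep a complete reproduction in
the tens of minutes on a single core while matching the study's scale.

## Known limitations

* The additive information gain overcounts repeated probes of the same
  option (five pulls of option 4 are scored at five times the one-pull gain
  although one observation resolves the variant); this inflates the
  epistemic drive of repeated informative choices.
* Meta-control learning relies on the weak correlation between meta-state
  beliefs and outcomes through the shared Dirichlet counts b; with symmetric
  priors it differentiates slowly, and a minority of adaptive instances
  never learn to downregulate — visible as the spread in instance-level
  success.
* Context identity is anchored by the prior; with `a0_anchor = 0` the model
  is label-exchangeable and accuracy against true labels is undefined in
  principle.
* The synthetic task generator *is* the study environment; none of the
  passing tests speak to richer real-world structure (drifting outcome
  probabilities, unequal block lengths, more than two meta-control modes).
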