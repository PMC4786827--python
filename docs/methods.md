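# Methods

## Model

A fixed population of `g` groups with `n` members each evolves over `T`
discrete generations. Each generation applies five steps in order:
provision, group competition, reproduction, mutation, migration. Group size
and population size are invariant throughout.

### Strategies and within-group equilibrium

Strategies are piecewise linear response functions `c = f(x̄)` from the
others' average contribution to one's own, determined by three anchor
values in `{0, 0.5, 1}` at `x̄ = 0, 0.5, 1` and linear interpolation on the
two half-intervals. The 27 possible anchor triples are labelled by the
base-3 value of the digit string (digit = 2·anchor, most significant digit
first). Labels 0, 13, 26 are the constant (unconditional) strategies.

Contributions actually played are the long-run outcome of repeated
interaction within the group. We model this as synchronous belief/response
dynamics: every member starts from the same initial belief about the
others' average (default 1 — optimistic), contributes its response, and
updates its belief to the realized average of the *other* members'
contributions. The equilibrium contribution is

- the fixed point, if the profile converges (max-norm change `< tol`);
- the per-member average over one period, if the profile enters a cycle
  (detected by exact recurrence of the profile rounded to 12 decimals);
- the average over a trailing window (default 50 rounds) if neither occurs
  within `max_iter` rounds — a safety net for slowly contracting orbits;
  e.g. a lone free rider among mirroring Type-5 players induces geometric
  decay at rate `(n−2)/(n−1)`, which at `n = 20` needs ≈330 rounds to meet
  `tol = 1e−9`, beyond the default `max_iter = 200`. The residual error of
  the windowed average is ~1e−4 and immaterial to population dynamics.

Synchronous updating is chosen because it is deterministic and
order-free; any asynchronous scheme would need an update schedule that is
an extra modelling degree of freedom. Beliefs always reset to optimistic at
each provision step: each generation's interaction episode starts afresh.

Members sharing a strategy provably share one trajectory (identical initial
belief and identical others-totals), so the engine solves the dynamics per
*distinct* label and memoizes results by the group's label-count vector.
The per-member solver (`group_equilibrium`) is retained as the reference
implementation and the two routes are tested against each other.

### Payoffs

`w_ij = w0 + 1 − c_ij + (r/n)·Σ_k c_kj` with `1 < r < n`. The default
`r = 2` makes the marginal per-capita return `r/n = 0.1` at the reference
group size and has the convenient property that the difference between two
groups' average payoffs equals the difference between their average
contributions (group mean payoff is `w0 + 1 + (r−1)·C_j`), so contests
decided on contributions and contests decided on payoffs coincide. `w0`
sets selection strength: at `w0 = 0` payoff differences are large relative
to payoffs (strong selection); large `w0` washes them out.

### Group competition

Each group independently engages in a conflict with probability `k` and is
matched with a uniformly drawn other group, giving about `k·g` conflicts
per generation. The engaging group wins with probability
`clamp(0.5 + 5(C_i − C_j), 0, 1)`: equal contributions toss a coin, a mean
contribution edge of 0.1 wins with certainty. The winner repopulates the
loser's site during reproduction. A group may be drawn as opponent more
than once; if a site loses repeatedly, the last conflict determines who
repopulates it.

We also implemented and evaluated two alternative conflict-rate semantics —
a conflict pool with per-group Bernoulli(`k`) entry and within-pool pairing
(≈ `k·g/2` conflicts), and an all-or-nothing round in which with
probability `k` every group is paired. Both weaken inter-group selection
enough that runs intermittently trap in the all-defect state for thousands
of generations and the long-run cooperation level falls well below the
regime this model family is known for; the per-group engagement reading
produces stable recovery and is the package default.

### Reproduction, mutation, migration

Reproduction is within-site Wright–Fisher sampling: every site is refilled
by `n` independent draws with replacement from its source group (itself,
or the winning group for a defeated site), each member weighted by its
share of the source group's total payoff. With `w0 ≥ 0` total payoffs are
strictly positive; a zero-total-payoff source (possible only with negative
`w0`) falls back to uniform draws and is logged.

Mutation replaces each agent's strategy, independently with probability
`mu`, by a uniform draw over the configured strategy space (the draw may
repeat the current label). Migration marks each agent independently with
probability `m` and permutes the marked agents uniformly over their vacated
slots, conserving group sizes exactly and the population's strategy
multiset; a migrant may land back in its own group.

### Recorded statistics

Per-generation rows are computed at the provision step — they describe the
contributions actually played before selection reshuffles membership:
population mean contribution, `Var(c_j)` (population variance of group
means; inter-group selection proxy), `E[Var(c_ij)]` (mean over groups of
within-group population variance; intra-group proxy), and the 27 strategy
frequencies.

All variances and covariances are *population* moments (divide by N). This
is load-bearing, not stylistic: the law of total variance for the two
proxies, the Price identity `Δp·w = Cov_q(w_j, p_j) + E_q[Cov_j(w_ij, p_ij)]`,
and the public-goods closed forms (`between = (r−1)·Var_q(p_j)`,
`within = −E_q[Var_j(p_ij)]`) hold exactly only under this convention.
`price_oracle` computes the next-generation trait frequency by brute force
(fitness-proportional reproduction within groups, payoff-proportional group
shares) and is used purely as an independent check of the decomposition.

Cooperative epochs are maximal runs of generations with population mean
contribution strictly above a threshold (default 0.6; a generation exactly
at the threshold ends an epoch). Summaries report whole-run means and
"stabilized" means over the trailing 20% of generations, with
normal-approximation 95% confidence intervals across replicate runs and
optional least-squares trends for sweeps.

## Parameters

| parameter | meaning | default | range explored |
|---|---|---|---|
| `n` | group size | 20 | 5–30 |
| `g` | number of groups | 20 | `round(400/n)` when sweeping `n` |
| `k` | per-group conflict probability | 0.20 | 0.05–0.30 |
| `m` | per-agent migration probability | 0.15 | 0.05–0.25 |
| `mu` | per-agent mutation probability | 0.01 | — |
| `w0` | baseline payoff (selection strength) | 0 | 0–5 |
| `r` | total return to cooperation | 2 | `1 < r < n` |
| `T` | generations | 5000 | — |

When group size is swept, the number of groups is adjusted to hold the
population near 400 agents. Replicate `i` of sweep cell `c` uses seed
`base_seed + 1000·c + i`; all seeds are echoed into experiment summaries.

## Problem sizes

The reference experiment scale is 50 replicates of 5000 generations
(20 groups × 20 agents), which the engine completes in about four minutes
on one CPU thanks to the count-vector equilibrium cache. The test suite
exercises this full scale once through a shared fixture; directional sweep
checks and the examples use reduced scales (2–3 replicates, 1000–1500
generations) that preserve the qualitative orderings.

## What the simulation does and does not show

The model abstracts from everything but the selection structure: agents
have no memory across generations, no individual recognition (only the
others' average is observable), groups are equally sized and fully mixed
internally, and transmission is payoff-proportional without distinguishing
genetic from cultural channels. Robust findings at the defaults: cooperation
collapses first (exploitable strategies are purged), then recovers under
inter-group selection; the strategy that fixates (~80% of the population,
Type 2 `002`) is exactly the one that cannot be exploited below
half-contribution yet sustains full group contribution; restricting the
space to unconditional strategies keeps cooperation at zero; cooperation
rises with `k` and `w0` and falls with `n` and `m`.

Two caveats for interpreting the stabilized numbers. First, the
within-group proxy `E[Var(c_ij)]` stabilizes near 0.006 here: late-run
groups are internally homogeneous (pure Type-2 groups at full contribution
or collapsed groups at zero), so within-group contribution variance is
small, while `Var(c_j)` stabilizes near 0.13. Second, the long-run
cooperation level is the balance of two slow processes — poisoning of
cooperative groups by immigrant/mutant members that break the
full-contribution equilibrium, and restoration of collapsed sites by
conflict — so it is sensitive to the conflict-rate semantics discussed
above.

## Known limitations

- The equilibrium concept assumes infinitely repeated interaction within a
  generation; finite or discounted play is out of scope.
- Non-convergent, non-cyclic orbits are summarized by a trailing-window
  average; this is a pragmatic choice, not a theory of equilibrium
  selection.
- No spatial or network structure between groups: conflict opponents are
  uniform. Confidence intervals use the normal approximation across
  replicates; no further inference is attempted.
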