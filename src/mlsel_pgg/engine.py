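"""Generation loop: provision, group conflict, reproduction, mutation, migration.

The population holds ``g`` groups of ``n`` agents each; both sizes stay
constant throughout a run. Each generation:

1. *Public goods provision.* Every group plays the repeated public goods
   game: contributions are the within-group equilibrium of the members'
   response functions (optimistic initial beliefs), and payoffs follow
   w_ij = w0 + 1 - c_ij + (r/n) * sum_k c_kj with 1 < r < n.
2. *Group competition.* Each group independently engages in conflict with
   probability k and is paired with a uniformly random other group. Group i
   beats its opponent j with probability clamp(0.5 + 5 (C_i - C_j), 0, 1),
   so a mean-contribution edge above 0.1 wins for sure. The winner
   repopulates the loser's site at reproduction.
3. *Reproduction.* Every site is refilled by n draws with replacement from
   its source group (itself, or the winning group for a lost site), each
   member weighted by its share of the source group's total payoff.
4. *Mutation.* With probability mu an agent adopts a uniformly random
   strategy from the configured strategy space (possibly its current one).
5. *Migration.* With probability m an agent is marked a migrant; migrants
   are permuted uniformly over the vacated slots, which keeps every group at
   exactly n members.

Per-generation statistics (mean contribution, the two variance proxies,
strategy frequencies) are recorded at the provision step, i.e. they describe
the contributions actually played that generation, before selection
reshuffles membership.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .equilibrium import solve_counts
from .stats import RunRecord, variance_proxies_arrays
from .strategy import N_STRATEGIES, strategy_space_labels

__all__ = [
    "SimConfig",
    "PopulationState",
    "GroupOutcome",
    "payoffs",
    "provision",
    "conflict_win_prob",
    "group_conflicts",
    "reproduce",
    "mutate",
    "migrate",
    "step_generation",
    "run",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimConfig:
    """All model parameters for one simulation run.

    Baseline values follow the reference parameterization: 20 groups of 20,
    conflict probability k = 0.20, migration m = 0.15, mutation mu = 0.01,
    baseline payoff w0 = 0 (strong intra-group selection), total return to
    cooperation r = 2 (MPCR = r/n = 0.1), T = 5000 generations.
    """

    n: int = 20
    g: int = 20
    k: float = 0.20
    m: float = 0.15
    mu: float = 0.01
    w0: float = 0.0
    r: float = 2.0
    T: int = 5000
    strategy_space: str = "full"
    init: str = "random"  # "random" or "homogeneous"
    init_label: int = 0
    seed: int = 0
    eq_max_iter: int = 200
    eq_tol: float = 1e-9
    eq_window: int = 50
    epoch_threshold: float = 0.6

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size n must be >= 2")
        if self.g < 2:
            raise ValueError("number of groups g must be >= 2")
        if not 1.0 < self.r < self.n:
            raise ValueError(f"need 1 < r < n, got r={self.r}, n={self.n}")
        for name in ("k", "m", "mu"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.epoch_threshold < 1.0:
            raise ValueError("epoch_threshold must be in (0, 1)")
        if self.init not in ("random", "homogeneous"):
            raise ValueError(f"unknown init {self.init!r}")
        if self.T < 0:
            raise ValueError("T must be >= 0")
        strategy_space_labels(self.strategy_space)  # validates

    @property
    def mpcr(self) -> float:
        """Marginal per-capita return r/n."""
        return self.r / self.n


@dataclass
class PopulationState:
    """Ordered groups of strategy labels plus generation counter and RNG."""

    labels: np.ndarray  # (g, n) int array of strategy labels
    generation: int
    rng: np.random.Generator

    @property
    def g(self) -> int:
        return self.labels.shape[0]

    @property
    def n(self) -> int:
        return self.labels.shape[1]


@dataclass
class GroupOutcome:
    """Provision outcome of one group: contributions, payoffs, group mean."""

    contributions: np.ndarray
    payoffs: np.ndarray
    mean_contribution: float


def payoffs(contributions: np.ndarray, w0: float, r: float, n: int) -> np.ndarray:
    """Public goods payoffs w_ij = w0 + 1 - c_ij + (r/n) * sum of contributions.

    The pot (including the player's own contribution) is multiplied by r and
    split evenly over all n members; 1 < r < n makes full defection the
    dominant strategy while full contribution is the social optimum.
    """
    c = np.asarray(contributions, dtype=float)
    if not 1.0 < r < n:
        raise ValueError(f"need 1 < r < n, got r={r}, n={n}")
    if c.min() < 0.0 or c.max() > 1.0:
        raise ValueError("contributions must lie in [0, 1]")
    return w0 + 1.0 - c + (r / n) * c.sum()


class _EquilibriumCache:
    """Memoizes per-label equilibrium contributions keyed by label counts.

    The equilibrium depends on the group only through its multiset of
    strategies, and members sharing a label share their equilibrium
    contribution, so one 27-vector per distinct count vector suffices.
    """

    def __init__(self, config: SimConfig, max_entries: int = 300_000) -> None:
        self._cfg = config
        self._max = max_entries
        self._data: dict[bytes, np.ndarray] = {}

    def lookup(self, counts: np.ndarray) -> np.ndarray:
        key = counts.tobytes()
        hit = self._data.get(key)
        if hit is None:
            cfg = self._cfg
            present, contribs, _, _ = solve_counts(
                counts.tolist(),
                initial_belief=1.0,
                max_iter=cfg.eq_max_iter,
                tol=cfg.eq_tol,
                window=cfg.eq_window,
            )
            hit = np.full(len(counts), np.nan)
            hit[present] = contribs
            if len(self._data) >= self._max:
                self._data.clear()
            self._data[key] = hit
        return hit


def provision(
    state: PopulationState, config: SimConfig, cache: _EquilibriumCache | None = None
) -> list[GroupOutcome]:
    """Play the public goods game in every group; return per-group outcomes."""
    if cache is None:
        cache = _EquilibriumCache(config)
    outcomes = []
    for j in range(state.g):
        group = state.labels[j]
        counts = np.bincount(group, minlength=N_STRATEGIES).astype(np.int32)
        by_label = cache.lookup(counts)
        c = by_label[group]
        w = payoffs(c, config.w0, config.r, config.n)
        outcomes.append(GroupOutcome(c, w, float(c.mean())))
    return outcomes


def conflict_win_prob(ci: float, cj: float) -> float:
    """Probability that the group with mean contribution ``ci`` beats ``cj``.

    clamp(0.5 + 5 (ci - cj), 0, 1): equal means toss a fair coin, and a mean
    contribution advantage of 0.1 or more wins with certainty.
    """
    return float(np.clip(0.5 + 5.0 * (ci - cj), 0.0, 1.0))


def group_conflicts(
    state: PopulationState,
    outcomes: Sequence[GroupOutcome],
    config: SimConfig,
    rng: np.random.Generator,
) -> dict[int, int]:
    """Resolve this generation's conflicts.

    Each group independently engages in conflict with probability k and is
    randomly paired with one of the other groups; each conflict is settled
    by one Bernoulli draw with :func:`conflict_win_prob`. The expected
    number of conflicts per generation is therefore k * g. A group may be
    drawn as an opponent more than once; when a site loses several
    conflicts the last resolution determines who repopulates it. Returns a
    map from each losing site to the index of the winning group.
    """
    g = state.g
    losers_to_winners: dict[int, int] = {}
    engaged = np.flatnonzero(rng.random(g) < config.k)
    for a in engaged:
        a = int(a)
        b = int(rng.integers(g - 1))
        if b >= a:
            b += 1
        p_a = conflict_win_prob(
            outcomes[a].mean_contribution, outcomes[b].mean_contribution
        )
        if rng.random() < p_a:
            losers_to_winners[b] = a
        else:
            losers_to_winners[a] = b
    if len(engaged):
        logger.debug(
            "generation %d: %d conflicts", state.generation, len(engaged)
        )
    return losers_to_winners


def reproduce(
    state: PopulationState,
    outcomes: Sequence[GroupOutcome],
    conflicts: dict[int, int],
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Fitness-proportional reproduction with winner repopulation.

    Each site is refilled by n independent draws with replacement from its
    source group (the site's own members, or the conflict winner's members
    for a lost site), weighted by payoff share. A source group with zero
    total payoff falls back to uniform draws (logged); this cannot happen
    for w0 >= 0.
    """
    n = state.n
    new_labels = np.empty_like(state.labels)
    for site in range(state.g):
        src = conflicts.get(site, site)
        w = outcomes[src].payoffs
        total = w.sum()
        if total <= 0.0:
            logger.warning(
                "group %d has zero total payoff; using uniform reproduction", src
            )
            cum = np.arange(1, n + 1) / n
        else:
            cum = np.cumsum(w) / total
        idx = np.searchsorted(cum, rng.random(n), side="right")
        idx = np.minimum(idx, n - 1)  # guard against roundoff at 1.0
        new_labels[site] = state.labels[src][idx]
    return new_labels


def mutate(
    labels: np.ndarray,
    mu: float,
    strategy_space: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Each agent independently adopts a uniform random strategy w.p. mu.

    The draw is over the configured strategy space and may equal the current
    label. Returns a new array; the input is not modified.
    """
    out = labels.copy()
    if mu <= 0.0:
        return out
    space = strategy_space_labels(strategy_space)
    mask = rng.random(labels.shape) < mu
    n_mut = int(mask.sum())
    if n_mut:
        out[mask] = rng.choice(space, size=n_mut)
    return out


def migrate(labels: np.ndarray, m: float, rng: np.random.Generator) -> np.ndarray:
    """Each agent is marked a migrant w.p. m; migrants swap slots globally.

    Migrants are reassigned by a uniform random permutation of the vacated
    slots across all groups, so group sizes stay exactly n and the multiset
    of strategies in the population is conserved. A migrant may, by chance,
    land back in its own group.
    """
    out = labels.copy()
    if m <= 0.0:
        return out
    flat = out.reshape(-1)
    idx = np.flatnonzero(rng.random(flat.shape[0]) < m)
    if len(idx) > 1:
        flat[idx] = flat[rng.permutation(idx)]
    return out


def step_generation(
    state: PopulationState,
    config: SimConfig,
    cache: _EquilibriumCache | None = None,
) -> tuple[PopulationState, dict]:
    """Advance one generation; return the new state and this generation's row.

    Statistics reflect the provision step: the contributions played this
    generation, before conflict and reproduction act on them.
    """
    rng = state.rng
    outcomes = provision(state, config, cache)
    contrib = np.stack([o.contributions for o in outcomes])
    var_between, mean_var_within = variance_proxies_arrays(contrib)
    freqs = np.bincount(state.labels.reshape(-1), minlength=N_STRATEGIES) / (
        state.g * state.n
    )
    row = {
        "generation": state.generation,
        "mean_contribution": float(contrib.mean()),
        "var_between": var_between,
        "mean_var_within": mean_var_within,
        "freqs": freqs,
    }
    conflicts = group_conflicts(state, outcomes, config, rng)
    labels = reproduce(state, outcomes, conflicts, config, rng)
    labels = mutate(labels, config.mu, config.strategy_space, rng)
    labels = migrate(labels, config.m, rng)
    assert labels.shape == (config.g, config.n)
    new_state = PopulationState(labels=labels, generation=state.generation + 1, rng=rng)
    return new_state, row


def initial_state(config: SimConfig) -> PopulationState:
    """Build the generation-0 population prescribed by the config."""
    rng = np.random.default_rng(config.seed)
    space = strategy_space_labels(config.strategy_space)
    if config.init == "random":
        labels = rng.choice(space, size=(config.g, config.n))
    else:
        if config.init_label not in set(int(l) for l in space):
            raise ValueError(
                f"init_label {config.init_label} not in strategy space "
                f"{config.strategy_space!r}"
            )
        labels = np.full((config.g, config.n), config.init_label, dtype=np.int64)
    return PopulationState(labels=labels, generation=0, rng=rng)


def run(config: SimConfig, cache: _EquilibriumCache | None = None) -> RunRecord:
    """Run one full simulation of T generations; return the time series.

    ``cache`` may be shared between replicate runs of one configuration:
    equilibria depend only on the group's strategy counts and the
    equilibrium controls, not on the seed.
    """
    state = initial_state(config)
    if cache is None:
        cache = _EquilibriumCache(config)
    T = config.T
    mean_c = np.empty(T)
    var_b = np.empty(T)
    var_w = np.empty(T)
    freqs = np.empty((T, N_STRATEGIES))
    for t in range(T):
        state, row = step_generation(state, config, cache)
        mean_c[t] = row["mean_contribution"]
        var_b[t] = row["var_between"]
        var_w[t] = row["mean_var_within"]
        freqs[t] = row["freqs"]
        assert state.labels.size == config.g * config.n
    return RunRecord(
        generation=np.arange(T),
        mean_contribution=mean_c,
        var_between=var_b,
        mean_var_within=var_w,
        freqs=freqs,
    )
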