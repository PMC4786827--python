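"""Observables: variance proxies, cooperative epochs, Price decomposition.

All variances and covariances here are *population* moments (divide by N,
not N-1). This is not a stylistic choice: the Price-equation algebra, the
law-of-total-variance identity for the two selection proxies, and the
closed forms for the public-goods payoff all hold exactly only under the
population convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RunRecord",
    "EpochSummary",
    "PriceDecomposition",
    "variance_proxies",
    "variance_proxies_arrays",
    "cooperative_epochs",
    "price_decomposition",
    "price_oracle",
    "viability_condition",
    "aggregate_runs",
    "summarize_run",
    "fit_trend",
]

N_STRATEGIES = 27


@dataclass
class RunRecord:
    """Per-generation time series of one simulation run.

    Columns: generation index, population mean contribution, Var(c_j) (the
    between-group proxy: population variance of group-mean contributions),
    E[Var(c_ij)] (the within-group proxy: mean over groups of the
    within-group population variance), and the 27 strategy frequencies.
    """

    generation: np.ndarray
    mean_contribution: np.ndarray
    var_between: np.ndarray
    mean_var_within: np.ndarray
    freqs: np.ndarray  # (T, 27)

    def __len__(self) -> int:
        return len(self.generation)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "generation": self.generation,
                "mean_contribution": self.mean_contribution,
                "var_between": self.var_between,
                "mean_var_within": self.mean_var_within,
            }
        )
        for l in range(N_STRATEGIES):
            df[f"freq_{l:02d}"] = self.freqs[:, l]
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RunRecord":
        freqs = np.column_stack(
            [df[f"freq_{l:02d}"].to_numpy() for l in range(N_STRATEGIES)]
        )
        return cls(
            generation=df["generation"].to_numpy(),
            mean_contribution=df["mean_contribution"].to_numpy(),
            var_between=df["var_between"].to_numpy(),
            mean_var_within=df["mean_var_within"].to_numpy(),
            freqs=freqs,
        )

    def stabilized_slice(self, fraction: float = 0.2) -> slice:
        """Index slice for the trailing ``fraction`` of generations.

        Always covers at least the final generation, so summaries of very
        short records stay well defined.
        """
        start = int(round(len(self) * (1.0 - fraction)))
        start = min(start, max(len(self) - 1, 0))
        return slice(start, len(self))


@dataclass
class EpochSummary:
    """Cooperative epochs: maximal runs of generations above the threshold."""

    epochs: list[tuple[int, int]]  # (start generation index, length)
    mean_length: float
    count: int
    defined: bool  # False when no epoch exists (mean_length reported as 0)


@dataclass
class PriceDecomposition:
    """Between/within-group partition of one generation's selection on a trait.

    ``predicted_delta_p * mean_payoff == between_term + within_term`` holds by
    construction; the between term is the q-weighted covariance of group mean
    payoff with group trait frequency, the within term the q-weighted mean of
    within-group payoff-trait covariances.
    """

    between_term: float
    within_term: float
    mean_payoff: float
    predicted_delta_p: float


def variance_proxies_arrays(contributions: np.ndarray) -> tuple[float, float]:
    """Selection-strength proxies from a (g, n) contribution matrix.

    Returns ``(var_between, mean_var_within)``: the population variance of
    group means (inter-group selection proxy Var(c_j)) and the unweighted
    mean over groups of within-group population variance (intra-group proxy
    E[Var(c_ij)]).
    """
    c = np.asarray(contributions, dtype=float)
    if c.size == 0:
        raise ValueError("no contributions given")
    group_means = c.mean(axis=1)
    return float(np.var(group_means)), float(c.var(axis=1).mean())


def variance_proxies(outcomes: Sequence) -> tuple[float, float]:
    """Same as :func:`variance_proxies_arrays`, from GroupOutcome objects."""
    if len(outcomes) == 0:
        raise ValueError("no outcomes given")
    c = np.stack([o.contributions for o in outcomes])
    return variance_proxies_arrays(c)


def cooperative_epochs(
    mean_series: Sequence[float], threshold: float = 0.6
) -> EpochSummary:
    """Maximal runs of consecutive generations strictly above ``threshold``.

    A generation at exactly the threshold ends an epoch. With no epochs the
    mean length is undefined and reported as 0 with ``defined=False``.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    above = np.asarray(mean_series, dtype=float) > threshold
    if above.size == 0 or not above.any():
        return EpochSummary([], 0.0, 0, defined=False)
    padded = np.concatenate([[False], above, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    epochs = [(int(s), int(e - s)) for s, e in zip(starts, ends)]
    lengths = np.array([l for _, l in epochs], dtype=float)
    return EpochSummary(epochs, float(lengths.mean()), len(epochs), defined=True)


def _as_group_arrays(
    groups: Sequence[tuple[Sequence[float], Sequence[float]]],
) -> list[tuple[np.ndarray, np.ndarray]]:
    out = []
    for traits, pay in groups:
        t = np.asarray(traits, dtype=float)
        w = np.asarray(pay, dtype=float)
        if t.shape != w.shape or t.ndim != 1 or t.size == 0:
            raise ValueError("each group needs matching non-empty trait/payoff vectors")
        out.append((t, w))
    return out


def price_decomposition(
    groups: Sequence[tuple[Sequence[float], Sequence[float]]],
    weights: Sequence[float] | None = None,
) -> PriceDecomposition:
    """Price-equation partition of selection on a trait into two levels.

    ``groups`` holds per-group pairs (trait values p_ij, payoffs w_ij);
    ``weights`` are the group population shares q_j (defaults to equal,
    matching equally sized groups). The predicted one-generation change in
    the trait's population frequency is

        delta_p = [ Cov_q(w_j, p_j) + E_q[Cov_j(w_ij, p_ij)] ] / w

    whose first term measures inter-group selection (it is positive when
    high-trait groups earn more) and whose second measures intra-group
    selection (negative whenever the trait is individually costly).
    """
    arrs = _as_group_arrays(groups)
    gcount = len(arrs)
    if gcount == 0:
        raise ValueError("need at least one group")
    q = (
        np.full(gcount, 1.0 / gcount)
        if weights is None
        else np.asarray(weights, dtype=float)
    )
    if len(q) != gcount or not np.isclose(q.sum(), 1.0):
        raise ValueError("weights must match group count and sum to 1")
    w_j = np.array([w.mean() for _, w in arrs])
    p_j = np.array([t.mean() for t, _ in arrs])
    w_bar = float(q @ w_j)
    if w_bar <= 0.0:
        raise ValueError("mean payoff must be positive for the Price equation")
    between = float(q @ (w_j * p_j) - (q @ w_j) * (q @ p_j))
    within = float(
        sum(qj * float(np.mean(t * w) - t.mean() * w.mean()) for qj, (t, w) in zip(q, arrs))
    )
    return PriceDecomposition(
        between_term=between,
        within_term=within,
        mean_payoff=w_bar,
        predicted_delta_p=(between + within) / w_bar,
    )


def price_oracle(
    groups: Sequence[tuple[Sequence[float], Sequence[float]]],
    weights: Sequence[float] | None = None,
) -> float:
    """Brute-force expected one-generation trait-frequency change.

    Group shares update by selective migration q'_j = q_j w_j / w, and
    within each group the expected trait frequency after fitness-
    proportional reproduction is p'_j = sum_i w_ij p_ij / sum_i w_ij.
    Returns p' - p. Serves as the independent check of
    :func:`price_decomposition`; it never shares that code path.
    """
    arrs = _as_group_arrays(groups)
    gcount = len(arrs)
    q = (
        np.full(gcount, 1.0 / gcount)
        if weights is None
        else np.asarray(weights, dtype=float)
    )
    w_j = np.array([w.mean() for _, w in arrs])
    w_bar = float(q @ w_j)
    if w_bar <= 0.0:
        raise ValueError("mean payoff must be positive")
    q_next = q * w_j / w_bar
    p_next_j = np.array([float((w @ t) / w.sum()) for t, w in arrs])
    p_now = float(q @ np.array([t.mean() for t, _ in arrs]))
    return float(q_next @ p_next_j) - p_now


def viability_condition(
    var_between_p: float, mean_var_within_p: float, r: float, n: int
) -> bool:
    """Sign of the Price numerator for a binary contribute/defect trait.

    Substituting the public goods payoff gives between term
    (r-1) Var_q(p_j) and within term -E_q[Var_j(p_ij)], so the trait gains
    ground iff (r-1) Var_q(p_j) > E_q[Var_j(p_ij)]: inter-group selection
    must outweigh the always-opposing intra-group selection.
    """
    if var_between_p < 0 or mean_var_within_p < 0:
        raise ValueError("variances must be nonnegative")
    if not 1.0 < r < n:
        raise ValueError(f"need 1 < r < n, got r={r}, n={n}")
    return (r - 1.0) * var_between_p > mean_var_within_p


@dataclass
class RunSummary:
    """Run-level scalar summaries used in sweep tables."""

    mean_contribution_overall: float
    mean_contribution_stabilized: float
    mean_epoch_length: float
    n_epochs: int
    final_freqs: np.ndarray


def summarize_run(
    record: RunRecord,
    epoch_threshold: float = 0.6,
    stabilized_fraction: float = 0.2,
) -> RunSummary:
    """Scalar summaries of one run.

    The "stabilized" mean averages the trailing ``stabilized_fraction`` of
    generations; the overall mean covers the whole run. Final strategy
    frequencies are averaged over the same trailing window.
    """
    sl = record.stabilized_slice(stabilized_fraction)
    ep = cooperative_epochs(record.mean_contribution, epoch_threshold)
    return RunSummary(
        mean_contribution_overall=float(record.mean_contribution.mean()),
        mean_contribution_stabilized=float(record.mean_contribution[sl].mean()),
        mean_epoch_length=ep.mean_length,
        n_epochs=ep.count,
        final_freqs=record.freqs[sl].mean(axis=0),
    )


@dataclass
class Aggregate:
    """Across-run aggregation: mean time series and run-level CIs."""

    mean_record: RunRecord
    n_runs: int
    mean_contribution_overall: float
    mean_contribution_stabilized: float
    mean_epoch_length: float
    ci95_overall: tuple[float, float]
    ci95_epoch_length: tuple[float, float]
    ci_defined: bool
    final_freqs: np.ndarray


def _ci95(values: np.ndarray) -> tuple[tuple[float, float], bool]:
    m = float(values.mean())
    if len(values) < 2:
        return (m, m), False
    se = float(values.std(ddof=1)) / np.sqrt(len(values))
    return (m - 1.96 * se, m + 1.96 * se), True


def aggregate_runs(
    records: Sequence[RunRecord],
    epoch_threshold: float = 0.6,
    stabilized_fraction: float = 0.2,
) -> Aggregate:
    """Average replicate runs generation by generation.

    Every column is averaged across runs at each generation; run-level
    scalars (overall mean contribution, mean epoch length) get normal-
    approximation 95% confidence intervals over runs. With a single run the
    CI is undefined and collapses to the point estimate (``ci_defined`` is
    False).
    """
    if len(records) == 0:
        raise ValueError("need at least one run")
    T = len(records[0])
    if any(len(r) != T for r in records):
        raise ValueError("all runs must have equal length")
    mean_rec = RunRecord(
        generation=records[0].generation.copy(),
        mean_contribution=np.mean([r.mean_contribution for r in records], axis=0),
        var_between=np.mean([r.var_between for r in records], axis=0),
        mean_var_within=np.mean([r.mean_var_within for r in records], axis=0),
        freqs=np.mean([r.freqs for r in records], axis=0),
    )
    summaries = [
        summarize_run(r, epoch_threshold, stabilized_fraction) for r in records
    ]
    overall = np.array([s.mean_contribution_overall for s in summaries])
    stabilized = np.array([s.mean_contribution_stabilized for s in summaries])
    epoch_len = np.array([s.mean_epoch_length for s in summaries])
    ci_overall, defined = _ci95(overall)
    ci_epoch, _ = _ci95(epoch_len)
    return Aggregate(
        mean_record=mean_rec,
        n_runs=len(records),
        mean_contribution_overall=float(overall.mean()),
        mean_contribution_stabilized=float(stabilized.mean()),
        mean_epoch_length=float(epoch_len.mean()),
        ci95_overall=ci_overall,
        ci95_epoch_length=ci_epoch,
        ci_defined=defined,
        final_freqs=np.mean([s.final_freqs for s in summaries], axis=0),
    )


def fit_trend(x: Sequence[float], y: Sequence[float]):
    """Ordinary least-squares trend of a sweep summary against its parameter.

    Thin wrapper over :func:`scipy.stats.linregress`; returns the linregress
    result (slope, intercept, rvalue, pvalue, stderr).
    """
    return sps.linregress(np.asarray(x, float), np.asarray(y, float))
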