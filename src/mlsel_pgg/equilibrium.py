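"""Within-group equilibrium contributions under repeated interaction.

Group members hold a belief about the average contribution of the *others*
and contribute according to their response function; beliefs are then updated
to the realized average of the others' contributions, synchronously for all
members. The equilibrium contribution is the long-run average of this
process: a fixed point if the dynamics converge, the per-member average over
one period if they settle on a cycle, and the average over a trailing window
if neither happens within the iteration budget. Members start from optimistic
beliefs (everyone contributes fully) unless told otherwise.

Because anchors sit on a coarse grid and interpolation is linear, orbits of
many groups live on a small rational set, so exact recurrence detection on
the (rounded) contribution vector finds fixed points and cycles quickly; the
trailing-window average is the safety net for slowly contracting or
non-periodic orbits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .strategy import ANCHOR_TABLE, StrategySpec, decode, respond_vectorized

__all__ = ["EquilibriumResult", "group_equilibrium", "equilibrium_by_counts"]

#: Decimal places used for exact-recurrence detection of orbits.
_CYCLE_ROUND = 12


@dataclass
class EquilibriumResult:
    """Equilibrium contribution profile of one group.

    ``cycle_length`` is 1 for a fixed point and the detected period for a
    cycle; when neither is found within ``max_iter`` rounds, ``converged`` is
    False and ``cycle_length`` reports the trailing-window length that was
    averaged instead.
    """

    contributions: np.ndarray
    converged: bool
    cycle_length: int


def group_equilibrium(
    strategies: Sequence[StrategySpec | int],
    initial_belief: float = 1.0,
    max_iter: int = 200,
    tol: float = 1e-9,
    window: int = 50,
) -> EquilibriumResult:
    """Equilibrium contributions for a group of conditional strategists.

    Parameters
    ----------
    strategies
        The members' strategies (specs or labels); order is preserved.
    initial_belief
        Common initial belief about the others' average contribution;
        defaults to 1 (optimistic: everyone expects full contribution).
    max_iter
        Maximum number of synchronous belief/response rounds (>= 2).
    tol
        Fixed-point tolerance on the max-norm change of the contribution
        vector between rounds.
    window
        Trailing-window length averaged when no fixed point or cycle is
        detected within ``max_iter``.
    """
    labels = [s.label if isinstance(s, StrategySpec) else int(s) for s in strategies]
    if len(labels) == 0:
        raise ValueError("group must be non-empty")
    if max_iter < 2:
        raise ValueError("max_iter must be >= 2")
    if not 0.0 <= initial_belief <= 1.0:
        raise ValueError(f"initial_belief must be in [0, 1], got {initial_belief}")
    for l in labels:
        decode(l)  # validates
    anchors = ANCHOR_TABLE[np.asarray(labels)]
    n = len(labels)

    c = respond_vectorized(anchors, np.full(n, float(initial_belief)))
    history = [c]
    seen = {_orbit_key(c): 0}
    for t in range(1, max_iter):
        if n == 1:
            belief = np.full(1, float(initial_belief))
        else:
            total = c.sum()
            belief = (total - c) / (n - 1)
        c_new = respond_vectorized(anchors, belief)
        if np.max(np.abs(c_new - c)) < tol:
            return EquilibriumResult(c_new, converged=True, cycle_length=1)
        key = _orbit_key(c_new)
        if key in seen:
            start = seen[key]
            period = t - start
            avg = np.mean(history[start:t], axis=0)
            return EquilibriumResult(avg, converged=True, cycle_length=period)
        seen[key] = t
        history.append(c_new)
        c = c_new
    w = min(window, len(history))
    avg = np.mean(history[-w:], axis=0)
    return EquilibriumResult(avg, converged=False, cycle_length=w)


def _orbit_key(c: np.ndarray) -> bytes:
    return np.round(c, _CYCLE_ROUND).tobytes()


#: Per-label anchors as plain floats, for the scalar fast path.
_ANCHORS_PY: list[tuple[float, float, float]] = [
    tuple(row) for row in ANCHOR_TABLE
]


def _respond_scalar(anchors: tuple[float, float, float], x: float) -> float:
    a0, a1, a2 = anchors
    if x <= 0.5:
        c = a0 + (a1 - a0) * (2.0 * x)
    else:
        c = a1 + (a2 - a1) * (2.0 * x - 1.0)
    if c < 0.0:
        return 0.0
    if c > 1.0:
        return 1.0
    return c


def solve_counts(
    counts,
    initial_belief: float = 1.0,
    max_iter: int = 200,
    tol: float = 1e-9,
    window: int = 50,
) -> tuple[list[int], list[float], bool, int]:
    """Scalar-arithmetic equilibrium solver over distinct labels only.

    Members sharing a strategy have identical beliefs and contributions at
    every synchronous round (they start from the same belief and face the
    same others' totals), so the group dynamics reduce to one trajectory per
    label present. Groups rarely hold more than a handful of distinct
    strategies, so the loop runs on plain Python floats; this is the
    engine's hot path and is algorithmically identical to
    :func:`group_equilibrium`.

    Returns ``(present_labels, contributions, converged, cycle_length)``.
    """
    n = int(sum(counts))
    if n == 0:
        raise ValueError("group must be non-empty")
    if max_iter < 2:
        raise ValueError("max_iter must be >= 2")
    present = [l for l in range(len(counts)) if counts[l] > 0]
    cnt = [float(counts[l]) for l in present]
    anch = [_ANCHORS_PY[l] for l in present]
    k = len(present)
    inv = 1.0 / (n - 1) if n > 1 else 0.0

    # Orbit keys quantize contributions to ~1e-12 by integer scaling; round()
    # with a digit count is an order of magnitude slower in this loop.
    scale = 10.0 ** _CYCLE_ROUND
    c = [_respond_scalar(a, float(initial_belief)) for a in anch]
    history = [c]
    seen = {tuple(int(x * scale) for x in c): 0}
    for t in range(1, max_iter):
        if n == 1:
            c_new = c
        else:
            total = 0.0
            for i in range(k):
                total += cnt[i] * c[i]
            c_new = [_respond_scalar(anch[i], (total - c[i]) * inv) for i in range(k)]
        delta = 0.0
        for i in range(k):
            d = c_new[i] - c[i]
            if d < 0.0:
                d = -d
            if d > delta:
                delta = d
        if delta < tol:
            return present, c_new, True, 1
        key = tuple(int(x * scale) for x in c_new)
        if key in seen:
            start = seen[key]
            period = t - start
            cyc = history[start:t]
            avg = [sum(v[i] for v in cyc) / period for i in range(k)]
            return present, avg, True, period
        seen[key] = t
        history.append(c_new)
        c = c_new
    w = min(window, len(history))
    tail = history[-w:]
    avg = [sum(v[i] for v in tail) / w for i in range(k)]
    return present, avg, False, w


def equilibrium_by_counts(
    counts: np.ndarray,
    initial_belief: float = 1.0,
    max_iter: int = 200,
    tol: float = 1e-9,
    window: int = 50,
) -> tuple[np.ndarray, bool, int]:
    """Equilibrium contribution per strategy label from a label-count vector.

    Returns ``(contrib_by_label, converged, cycle_length)`` where
    ``contrib_by_label`` has the length of ``counts`` with NaN at absent
    labels. Thin array wrapper over :func:`solve_counts`.
    """
    counts = np.asarray(counts)
    present, contribs, converged, cycle_length = solve_counts(
        counts.tolist(), initial_belief, max_iter, tol, window
    )
    by_label = np.full(counts.shape[0], np.nan)
    by_label[present] = contribs
    return by_label, converged, cycle_length
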