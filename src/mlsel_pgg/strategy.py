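"""Conditional strategies as piecewise linear response functions.

A strategy maps the average contribution of the *other* group members,
``xbar`` in [0, 1], to the player's own contribution. Each strategy is fixed
by three anchor contribution levels -- the contributions prescribed at
xbar = 0, 0.5 and 1 -- each drawn from {0, 0.5, 1}, and linear interpolation
between the anchors. Writing the anchors as ternary digits in {0, 1, 2}
(digit = 2 * contribution) gives a 3-digit ternary string; its decimal value,
most-significant digit first, is the strategy's label in [0, 26].

Canonical examples: label 0 ("000") is the free rider, label 5 ("012") the
perfectly conditional cooperator c = xbar, label 26 ("222") the unconditional
cooperator, and label 2 ("002") contributes nothing below xbar = 0.5 and
rises linearly to full contribution at xbar = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "StrategySpec",
    "decode",
    "encode",
    "respond",
    "ternary_string",
    "strategy_space_labels",
    "UNCONDITIONAL_LABELS",
    "N_STRATEGIES",
    "ANCHOR_TABLE",
]

N_STRATEGIES = 27

#: Labels whose response function is constant in xbar: 000, 111, 222.
UNCONDITIONAL_LABELS = (0, 13, 26)

_ALLOWED_ANCHORS = (0.0, 0.5, 1.0)


class InvalidStrategyError(ValueError):
    """Raised for labels outside [0, 26] or anchors off the {0, 0.5, 1} grid."""


@dataclass(frozen=True)
class StrategySpec:
    """One of the 27 conditional strategies.

    Attributes
    ----------
    label : int
        Decimal identifier in [0, 26]; the base-3 value of ``digits``.
    digits : tuple[int, int, int]
        Ternary digits, most significant first (the digit for xbar = 0 first).
    anchors : tuple[float, float, float]
        Contribution levels at xbar = 0, 0.5, 1; anchors[i] == digits[i] / 2.
    """

    label: int
    digits: tuple[int, int, int]
    anchors: tuple[float, float, float]

    def ternary(self) -> str:
        """3-character ternary string, e.g. '012' for label 5."""
        return "".join(str(d) for d in self.digits)

    def is_unconditional(self) -> bool:
        return self.digits[0] == self.digits[1] == self.digits[2]


def decode(label: int) -> StrategySpec:
    """Decode a decimal label in [0, 26] into its strategy.

    >>> decode(5).digits
    (0, 1, 2)
    >>> decode(26).anchors
    (1.0, 1.0, 1.0)
    """
    label = int(label)
    if not 0 <= label <= 26:
        raise InvalidStrategyError(f"strategy label must be in [0, 26], got {label}")
    d0, rem = divmod(label, 9)
    d1, d2 = divmod(rem, 3)
    digits = (d0, d1, d2)
    anchors = (d0 / 2.0, d1 / 2.0, d2 / 2.0)
    return StrategySpec(label=label, digits=digits, anchors=anchors)


def encode(anchors: Sequence[float]) -> StrategySpec:
    """Encode three anchor contribution levels (at xbar = 0, 0.5, 1).

    Each anchor must lie on the grid {0, 0.5, 1}. Inverse of :func:`decode`.

    >>> encode((0.5, 0.0, 1.0)).ternary()
    '102'
    >>> encode((0.0, 0.5, 1.0)).label
    5
    """
    if len(anchors) != 3:
        raise InvalidStrategyError(f"expected 3 anchors, got {len(anchors)}")
    digits = []
    for a in anchors:
        if a not in _ALLOWED_ANCHORS:
            raise InvalidStrategyError(
                f"anchor {a!r} not in {{0, 0.5, 1}}"
            )
        digits.append(int(round(2 * a)))
    label = 9 * digits[0] + 3 * digits[1] + digits[2]
    return decode(label)


def ternary_string(label: int) -> str:
    """Ternary string of a label; convenience for reports."""
    return decode(label).ternary()


def respond(strategy: StrategySpec | int, xbar: float) -> float:
    """Contribution prescribed at others' average contribution ``xbar``.

    Linear interpolation between the anchors on [0, 0.5] and [0.5, 1]; the
    single breakpoint sits at xbar = 0.5. The result is clamped to [0, 1]
    (vacuously, since anchors already lie in [0, 1]).
    """
    if isinstance(strategy, (int, np.integer)):
        strategy = decode(strategy)
    x = float(xbar)
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"xbar must be in [0, 1], got {xbar}")
    a0, a1, a2 = strategy.anchors
    if x <= 0.5:
        c = a0 + (a1 - a0) * (2.0 * x)
    else:
        c = a1 + (a2 - a1) * (2.0 * x - 1.0)
    return min(1.0, max(0.0, c))


def _anchor_table() -> np.ndarray:
    """(27, 3) array of anchors, row l = anchors of label l."""
    tab = np.empty((N_STRATEGIES, 3))
    for l in range(N_STRATEGIES):
        tab[l] = decode(l).anchors
    return tab


#: (27, 3) anchor lookup used by the vectorized engine paths.
ANCHOR_TABLE = _anchor_table()
ANCHOR_TABLE.setflags(write=False)


def respond_vectorized(anchors: np.ndarray, xbar: np.ndarray) -> np.ndarray:
    """Vectorized response: ``anchors`` is (..., 3), ``xbar`` broadcastable.

    Same two-segment interpolation as :func:`respond`, used on whole groups.
    """
    a0, a1, a2 = anchors[..., 0], anchors[..., 1], anchors[..., 2]
    lo = a0 + (a1 - a0) * (2.0 * xbar)
    hi = a1 + (a2 - a1) * (2.0 * xbar - 1.0)
    c = np.where(xbar <= 0.5, lo, hi)
    return np.clip(c, 0.0, 1.0)


def strategy_space_labels(space: str) -> np.ndarray:
    """Labels available under a strategy-space restriction.

    ``"full"`` gives all 27 strategies; ``"unconditional"`` restricts to the
    constant-response strategies {0, 13, 26} (the control in which
    cooperation cannot be established under strong intra-group selection).
    """
    if space == "full":
        return np.arange(N_STRATEGIES)
    if space == "unconditional":
        return np.asarray(UNCONDITIONAL_LABELS)
    raise ValueError(f"unknown strategy space {space!r}")
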