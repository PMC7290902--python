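"""Payoff structure of the investing-in-education game.

Each individual has played, once, a game "against the field": the strategy is
whether to invest in a formal academic education (E) or not (NE), and the
labor market answers with professional success (S) or nonsuccess (NS).  The
four strategy/outcome pairs map to four payoffs — ``t`` for (NE, S), ``r``
for (E, S), ``p`` for (NE, NS) and ``s`` for (E, NS) — ordered like a
prisoner's dilemma, ``t > r > p > s``.  Successful individuals additionally
split into two kinds, A and B, earning different success payoffs
(``t_A > t_B``, ``r_A > r_B``); unsuccessful payoffs do not depend on kind.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "Education",
    "Outcome",
    "Kind",
    "Strategy",
    "STRATEGIES",
    "GameParams",
    "payoff_value",
    "payoff_table",
    "check_dilemma_ordering",
]


class Education(str, enum.Enum):
    """Whether the individual invested in formal education."""

    E = "E"
    NE = "NE"


class Outcome(str, enum.Enum):
    """The field's answer: professional success or not."""

    S = "S"
    NS = "NS"


class Kind(str, enum.Enum):
    """Payoff kind of an individual; only matters under success."""

    A = "A"
    B = "B"


class Strategy(NamedTuple):
    education: Education
    outcome: Outcome


#: Canonical strategy order, aligned with the payoff order (t, r, p, s).
STRATEGIES: tuple[Strategy, ...] = (
    Strategy(Education.NE, Outcome.S),   # -> t
    Strategy(Education.E, Outcome.S),    # -> r
    Strategy(Education.NE, Outcome.NS),  # -> p
    Strategy(Education.E, Outcome.NS),   # -> s
)


@dataclass(frozen=True)
class GameParams:
    """The six payoff values plus the fraction ``c`` of kind-A individuals.

    Parameters
    ----------
    t_A, t_B
        Payoffs of successful nonstudents of kind A and B (``t_A > t_B``).
    r_A, r_B
        Payoffs of successful students of kind A and B (``r_A > r_B``).
    p
        Payoff of unsuccessful nonstudents, identical for both kinds.
    s
        Payoff of unsuccessful students ("sucker's payoff"), identical for
        both kinds.
    c
        Fraction of kind-A individuals in the population, in [0, 1].
    """

    t_A: float
    t_B: float
    r_A: float
    r_B: float
    p: float
    s: float
    c: float

    def __post_init__(self) -> None:
        for kind, t, r in (("A", self.t_A, self.r_A), ("B", self.t_B, self.r_B)):
            if not (t > r > self.p > self.s):
                raise ValueError(
                    f"payoff ordering t > r > p > s violated for kind {kind}: "
                    f"t={t}, r={r}, p={self.p}, s={self.s}"
                )
        if not (self.t_A > self.t_B and self.r_A > self.r_B):
            raise ValueError(
                "kind-A success payoffs must exceed kind-B ones "
                f"(t_A={self.t_A}, t_B={self.t_B}, r_A={self.r_A}, r_B={self.r_B})"
            )
        if not 0.0 <= self.c <= 1.0:
            raise ValueError(f"c must lie in [0, 1], got {self.c}")
        if not check_dilemma_ordering(self):
            # The 2r > t + s condition is a dilemma refinement, not needed by
            # any simulation step, so it warns instead of failing hard.
            warnings.warn(
                "payoffs violate r > (t + s)/2 for at least one kind; the game "
                "is not a strict prisoner's dilemma",
                stacklevel=2,
            )


def check_dilemma_ordering(params: GameParams) -> bool:
    """True iff the payoffs form a strict prisoner's dilemma for both kinds.

    Requires ``t > r > p > s`` per kind and additionally
    ``r > (t + s) / 2`` per kind (mutual cooperation beats alternating
    exploitation).
    """
    for t, r in ((params.t_A, params.r_A), (params.t_B, params.r_B)):
        if not (t > r > params.p > params.s):
            return False
        if not r > (t + params.s) / 2.0:
            return False
    return True


def _as_strategy(strategy: Strategy | tuple) -> Strategy:
    try:
        edu, out = strategy
        return Strategy(Education(edu), Outcome(out))
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid strategy {strategy!r}: expected (E|NE, S|NS)") from exc


def payoff_value(strategy: Strategy | tuple, kind: Kind | str, params: GameParams) -> float:
    """Payoff earned by an individual of the given kind for a played strategy.

    ``(NE, S) -> t_kind``, ``(E, S) -> r_kind``, ``(NE, NS) -> p``,
    ``(E, NS) -> s``; the kind only differentiates successful individuals.
    """
    strat = _as_strategy(strategy)
    try:
        k = Kind(kind)
    except ValueError as exc:
        raise ValueError(f"invalid kind {kind!r}: expected 'A' or 'B'") from exc
    if strat.outcome is Outcome.S:
        if strat.education is Education.NE:
            return params.t_A if k is Kind.A else params.t_B
        return params.r_A if k is Kind.A else params.r_B
    return params.p if strat.education is Education.NE else params.s


def payoff_table(params: GameParams) -> np.ndarray:
    """(4, 2) payoff lookup: rows follow :data:`STRATEGIES`, columns (A, B)."""
    return np.array(
        [
            [params.t_A, params.t_B],
            [params.r_A, params.r_B],
            [params.p, params.p],
            [params.s, params.s],
        ],
        dtype=float,
    )
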