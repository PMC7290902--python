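"""Toroidal lattice population with exact-count random attribute assignment.

The population lives on an ``n x n`` square lattice whose opposite edges are
identified (a torus), so every cell has a full Moore neighborhood of eight
distinct cells and there are no edge effects.  Each cell is one individual
with a gender, a payoff kind (A/B), a played strategy (education x outcome)
and the resulting payoff.

Attributes are distributed by shuffling exact-count label pools: the number
of individuals in each category equals the largest-remainder rounding of
``n^2`` times the configured fraction on every realization, not merely in
expectation.  Gender is shuffled independently of everything else; strategy
and kind are allocated jointly (eight categories) so that the six payoff
categories also hit their target counts exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .game import GameParams, payoff_table

__all__ = [
    "PopulationParams",
    "NeighborIndex",
    "Population",
    "build_torus_neighbors",
    "allocate_counts",
    "payoff_distribution",
    "assign_population",
]

#: Strategy-category labels in canonical (t, r, p, s) order.
_STRATEGY_LABELS = [("NE", "S"), ("E", "S"), ("NE", "NS"), ("E", "NS")]


@dataclass(frozen=True)
class PopulationParams:
    """Lattice size and the population composition fractions.

    All strategy fractions are absolute population fractions:
    ``rho_NE`` nonstudents (so students are ``1 - rho_NE``), ``rho_NE_S``
    successful nonstudents and ``rho_E_S`` successful students.  The
    unsuccessful fractions follow by difference.
    """

    n: int = 100
    male_fraction: float = 0.493
    rho_NE: float = 0.188
    rho_NE_S: float = 0.05
    rho_E_S: float = 0.75

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 3:
            raise ValueError(f"lattice side n must be an integer >= 3, got {self.n}")
        for name in ("male_fraction", "rho_NE", "rho_NE_S", "rho_E_S"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.rho_NE_S > self.rho_NE + 1e-12:
            raise ValueError(
                f"rho_NE_S={self.rho_NE_S} exceeds the nonstudent fraction rho_NE={self.rho_NE}"
            )
        if self.rho_E_S > self.rho_E + 1e-12:
            raise ValueError(
                f"rho_E_S={self.rho_E_S} exceeds the student fraction rho_E={self.rho_E:g}"
            )

    @property
    def rho_E(self) -> float:
        return 1.0 - self.rho_NE

    @property
    def rho_NE_NS(self) -> float:
        return self.rho_NE - self.rho_NE_S

    @property
    def rho_E_NS(self) -> float:
        return self.rho_E - self.rho_E_S

    @property
    def size(self) -> int:
        return self.n * self.n

    def strategy_fractions(self) -> np.ndarray:
        """Fractions of the four strategies in (t, r, p, s) order."""
        return np.array([self.rho_NE_S, self.rho_E_S, self.rho_NE_NS, self.rho_E_NS])


@dataclass(frozen=True)
class NeighborIndex:
    """Flat (n^2, 8) index of each cell's Moore neighbors on the torus."""

    n: int
    idx: np.ndarray = field(repr=False)

    def neighbors(self, row: int, col: int) -> np.ndarray:
        """Flat indices of the 8 neighbors of cell ``(row, col)``."""
        if not (0 <= row < self.n and 0 <= col < self.n):
            raise IndexError(f"cell ({row}, {col}) outside {self.n}x{self.n} lattice")
        return self.idx[row * self.n + col]


def build_torus_neighbors(n: int) -> NeighborIndex:
    """Eight-neighbor (unit-radius Moore) index with toroidal wrap-around.

    Requires ``n >= 3``; on a smaller torus the wrapped offsets collide and
    cells would list duplicate neighbors.
    """
    if n < 3:
        raise ValueError(f"torus with Moore neighborhoods requires n >= 3, got {n}")
    rows, cols = np.divmod(np.arange(n * n), n)
    offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    idx = np.empty((n * n, 8), dtype=np.int64)
    for j, (dr, dc) in enumerate(offsets):
        idx[:, j] = ((rows + dr) % n) * n + (cols + dc) % n
    idx.setflags(write=False)
    return NeighborIndex(n=n, idx=idx)


def allocate_counts(fractions, total: int) -> np.ndarray:
    """Integer category counts by largest-remainder apportionment.

    Each count is ``floor(fraction * total)`` plus at most one unit; leftover
    units go to the categories with the largest fractional remainders, ties
    broken by category order.  The counts sum to ``total`` exactly.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.ndim != 1 or fractions.size == 0:
        raise ValueError("fractions must be a non-empty 1-D sequence")
    if np.any(fractions < 0):
        raise ValueError(f"fractions must be non-negative, got {fractions}")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got sum {fractions.sum()!r}")
    if total < 0 or int(total) != total:
        raise ValueError(f"total must be a non-negative integer, got {total}")
    exact = fractions * total
    counts = np.floor(exact + 1e-9).astype(np.int64)  # guard exact products
    counts = np.minimum(counts, int(total))
    short = int(total - counts.sum())
    if short > 0:
        remainders = exact - counts
        # stable sort on descending remainder -> ties keep category order
        order = np.argsort(-remainders, kind="stable")
        counts[order[:short]] += 1
    return counts


def payoff_distribution(pp: PopulationParams, gp: GameParams) -> tuple[np.ndarray, np.ndarray]:
    """Six payoff values and their population fractions.

    Order: ``(t_A, t_B, r_A, r_B, p, s)`` with fractions
    ``(rho_NE_S*c, rho_NE_S*(1-c), rho_E_S*c, rho_E_S*(1-c), rho_NE_NS,
    rho_E_NS)``.
    """
    values = np.array([gp.t_A, gp.t_B, gp.r_A, gp.r_B, gp.p, gp.s], dtype=float)
    probs = np.array(
        [
            pp.rho_NE_S * gp.c,
            pp.rho_NE_S * (1.0 - gp.c),
            pp.rho_E_S * gp.c,
            pp.rho_E_S * (1.0 - gp.c),
            pp.rho_NE_NS,
            pp.rho_E_NS,
        ]
    )
    return values, probs


@dataclass
class Population:
    """Per-cell attributes on the torus, stored as flat length-``n^2`` arrays.

    ``gender`` is 0 for male, 1 for female; ``kind`` is 0 for A, 1 for B;
    ``strategy`` indexes :data:`depgame.game.STRATEGIES` (t, r, p, s order);
    ``payoff`` is the payoff implied by strategy and kind.
    """

    n: int
    gender: np.ndarray
    kind: np.ndarray
    strategy: np.ndarray
    payoff: np.ndarray

    @property
    def size(self) -> int:
        return self.n * self.n

    @property
    def male(self) -> np.ndarray:
        return self.gender == 0

    def payoffs_consistent(self, gp: GameParams) -> bool:
        """Check that stored payoffs equal the game's strategy/kind mapping."""
        table = payoff_table(gp)
        return bool(np.array_equal(table[self.strategy, self.kind], self.payoff))

    def to_dataframe(self) -> pd.DataFrame:
        rows, cols = np.divmod(np.arange(self.size), self.n)
        edu = np.array([lbl[0] for lbl in _STRATEGY_LABELS])
        out = np.array([lbl[1] for lbl in _STRATEGY_LABELS])
        return pd.DataFrame(
            {
                "row": rows,
                "col": cols,
                "gender": np.where(self.gender == 0, "male", "female"),
                "kind": np.where(self.kind == 0, "A", "B"),
                "education": edu[self.strategy],
                "outcome": out[self.strategy],
                "payoff": self.payoff,
            }
        )


def assign_population(
    pp: PopulationParams, gp: GameParams, rng: np.random.Generator
) -> Population:
    """Draw one population realization with exact-count random assignment.

    Two independent shuffles consume the random stream in a fixed order:
    first the gender pool, then a joint (strategy, kind) pool whose eight
    category counts come from :func:`allocate_counts` on the strategy
    fractions split ``c : 1-c`` by kind.  Gender is therefore independent of
    the payoff, and kind is independent of education/outcome (the A:B ratio
    within every strategy equals ``c : 1-c`` up to integer rounding).
    """
    total = pp.size
    gender_counts = allocate_counts([pp.male_fraction, 1.0 - pp.male_fraction], total)
    gender = np.repeat(np.arange(2, dtype=np.int8), gender_counts)
    rng.shuffle(gender)

    strat_fracs = pp.strategy_fractions()
    joint = np.concatenate([[f * gp.c, f * (1.0 - gp.c)] for f in strat_fracs])
    joint_counts = allocate_counts(joint, total)
    codes = np.repeat(np.arange(8, dtype=np.int8), joint_counts)
    rng.shuffle(codes)
    strategy = codes >> 1
    kind = codes & 1

    payoff = payoff_table(gp)[strategy, kind]
    return Population(n=pp.n, gender=gender, kind=kind, strategy=strategy, payoff=payoff)
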