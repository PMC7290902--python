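"""One-shot frustration transition and prevalence statistics.

Every individual starts healthy, computes the mean payoff of the eight Moore
neighbors and transitions to the depressed state when that neighborhood mean
exceeds the personal payoff by strictly more than a gender-specific
threshold: sigma for men, tau for women.  The rule is evaluated once for all
cells simultaneously — there is no cascade, recovery or time loop.

The module also carries an exact enumeration oracle that computes the same
prevalence analytically under an i.i.d. approximation of the payoff field,
used throughout the test-suite as an independent reference for the
simulator.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import gammaln

from .game import GameParams
from .population import (
    NeighborIndex,
    Population,
    PopulationParams,
    payoff_distribution,
)

__all__ = [
    "Thresholds",
    "PrevalenceResult",
    "neighborhood_mean",
    "neighborhood_means",
    "transition_states",
    "prevalence",
    "exact_prevalence_oracle",
]

_N_NEIGHBORS = 8


@dataclass(frozen=True)
class Thresholds:
    """Frustration thresholds: ``sigma`` for men, ``tau`` for women.

    Any finite real value is allowed; negative thresholds mean even an
    individual richer than the neighborhood average can become depressed.
    """

    sigma: float
    tau: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.sigma) and math.isfinite(self.tau)):
            raise ValueError(f"thresholds must be finite, got {self}")


@dataclass(frozen=True)
class PrevalenceResult:
    """Depressed fractions overall and by gender.

    ``ratio`` is the female/male prevalence ratio: ``inf`` when only women
    are depressed, ``nan`` (flagged undefined) when nobody is.
    """

    x: float
    x_male: float
    x_female: float
    ratio: float

    @property
    def ratio_defined(self) -> bool:
        return not math.isnan(self.ratio)

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def _female_male_ratio(x_male: float, x_female: float) -> float:
    if x_male > 0:
        return x_female / x_male
    return math.inf if x_female > 0 else math.nan


def neighborhood_means(pop: Population, nbr: NeighborIndex) -> np.ndarray:
    """Mean neighbor payoff q-bar for every cell (own payoff excluded)."""
    if nbr.n != pop.n:
        raise ValueError(f"neighbor index is for n={nbr.n}, population has n={pop.n}")
    return pop.payoff[nbr.idx].mean(axis=1)


def neighborhood_mean(pop: Population, nbr: NeighborIndex, cell: tuple[int, int]) -> float:
    """q-bar of a single cell ``(row, col)``."""
    row, col = cell
    return float(pop.payoff[nbr.neighbors(row, col)].mean())


def transition_states(pop: Population, nbr: NeighborIndex, th: Thresholds) -> np.ndarray:
    """Boolean depressed indicator per cell after the one-shot rule.

    A cell is depressed iff ``q_bar - q_i`` STRICTLY exceeds sigma (men) or
    tau (women); ties stay healthy.
    """
    excess = neighborhood_means(pop, nbr) - pop.payoff
    threshold = np.where(pop.male, th.sigma, th.tau)
    return excess > threshold


def prevalence(states: np.ndarray, pop: Population) -> PrevalenceResult:
    """Prevalence overall and per gender stratum for one realization."""
    states = np.asarray(states, dtype=bool)
    if states.shape != pop.payoff.shape:
        raise ValueError("states are not aligned with the population")
    male = pop.male
    n_male = int(male.sum())
    n_female = pop.size - n_male
    if n_male == 0 or n_female == 0:
        raise ValueError("prevalence by gender requires both strata to be non-empty")
    x_male = float(states[male].mean())
    x_female = float(states[~male].mean())
    return PrevalenceResult(
        x=float(states.mean()),
        x_male=x_male,
        x_female=x_female,
        ratio=_female_male_ratio(x_male, x_female),
    )


def _compositions(total: int, bins: int) -> np.ndarray:
    """All weak compositions of ``total`` into ``bins`` parts, shape (M, bins)."""
    if bins == 1:
        return np.array([[total]], dtype=np.int64)
    rows = []
    for k in range(total + 1):
        rest = _compositions(total - k, bins - 1)
        rows.append(np.column_stack([np.full(len(rest), k, dtype=np.int64), rest]))
    return np.vstack(rows)


def _multinomial_pmf(counts: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Multinomial pmf rows that is exact for zero-probability categories."""
    n = int(counts[0].sum())
    log_coef = gammaln(n + 1) - gammaln(counts + 1).sum(axis=1)
    log_p = np.where(probs > 0.0, np.log(np.where(probs > 0.0, probs, 1.0)), 0.0)
    log_pmf = log_coef + (counts * log_p).sum(axis=1)  # 0 * log 0 := 0
    pmf = np.exp(log_pmf)
    pmf[np.any((counts > 0) & (probs == 0.0), axis=1)] = 0.0
    return pmf


def exact_prevalence_oracle(
    pp: PopulationParams, gp: GameParams, th: Thresholds
) -> PrevalenceResult:
    """Analytic prevalence under an i.i.d. payoff-field approximation.

    The own payoff is drawn from the six-category payoff distribution pi and
    the eight neighbor payoffs from an independent Multinomial(8, pi); the
    depressed probability for threshold theta is

        sum_q pi(q) * sum_k Multinomial(k; 8, pi) * 1[ mean(k) - q > theta ]

    with the sum over all C(13, 5) = 1287 neighbor compositions enumerated
    exactly.  Men and women share pi, so the gender values only differ
    through sigma versus tau, and the overall prevalence is their
    male-fraction-weighted mean.  The simulator's exact-count assignment
    deviates from i.i.d. only at O(1/n^2).
    """
    values, probs = payoff_distribution(pp, gp)
    comps = _compositions(_N_NEIGHBORS, len(values))
    pmf = _multinomial_pmf(comps, probs)
    means = comps @ values / _N_NEIGHBORS

    def prob_depressed(theta: float) -> float:
        total = 0.0
        for q, pq in zip(values, probs):
            if pq > 0.0:
                total += pq * pmf[means - q > theta].sum()
        return float(total)

    x_male = prob_depressed(th.sigma)
    x_female = prob_depressed(th.tau)
    x = pp.male_fraction * x_male + (1.0 - pp.male_fraction) * x_female
    return PrevalenceResult(
        x=x, x_male=x_male, x_female=x_female, ratio=_female_male_ratio(x_male, x_female)
    )
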