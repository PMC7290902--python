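"""Iterative threshold calibration against a target prevalence.

Starting from ``(sigma(0), tau(0))``, each iteration simulates the one-shot
transition, compares the resulting prevalence ``x(j)`` with the target
``x_o`` and nudges the thresholds on a fixed Delta-grid:

* ``x(j) - x_o > +epsilon``  -> both thresholds move up by Delta (a higher
  threshold admits fewer depressed individuals, shrinking ``x``);
* ``x(j) - x_o < -epsilon``  -> both thresholds move down by Delta;
* otherwise the female/male prevalence ratio is checked: below the target
  interval, tau moves down by Delta (making women more susceptible raises
  the ratio); above it — or undefined because no man is depressed — tau
  moves up by Delta.

The loop stops at the first step ``T`` where ``|x(T) - x_o| <= epsilon``
AND the ratio lies inside the interval; the thresholds at that step are the
calibrated ``sigma*``, ``tau*``.  The update direction is chosen so every
step reduces the active error term; the loop is a plain coordinate descent
on the Delta-grid, with a safety iteration cap for infeasible settings
(e.g. Delta too coarse for epsilon).

By default one population realization is drawn at the start and reused for
every iteration, which makes ``x(j)`` a deterministic monotone function of
the thresholds; ``population_mode="fresh"`` redraws it each step for
sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .game import GameParams
from .dynamics import Thresholds, prevalence, transition_states
from .population import PopulationParams, assign_population, build_torus_neighbors

__all__ = ["CalibrationSpec", "CalibrationStep", "CalibrationTrace", "calibrate"]

#: Trace actions.  ``tau_up`` is only reachable through the high-ratio rule,
#: the symmetric completion of the low-ratio adjustment.
_ACTIONS = ("accept", "both_up", "both_down", "tau_down", "tau_up")


@dataclass(frozen=True)
class CalibrationSpec:
    """Settings of the threshold-adaptation loop.

    Parameters
    ----------
    x_o
        Target overall prevalence, in (0, 1).
    epsilon
        Maximum absolute prevalence error accepted, > 0.
    delta
        Threshold step size, > 0; thresholds stay on the grid
        ``{sigma0 - k * delta}`` exactly.
    sigma0, tau0
        Initial thresholds.
    ratio_low, ratio_high
        Acceptance interval for the female/male prevalence ratio.
    max_iterations
        Safety cap; exceeding it yields a non-converged trace.
    population_mode
        ``"fixed"`` (one realization reused each iteration, default) or
        ``"fresh"`` (redrawn each iteration).
    """

    x_o: float = 0.20
    epsilon: float = 0.01
    delta: float = 0.05
    sigma0: float = 1.0
    tau0: float = 1.0
    ratio_low: float = 1.5
    ratio_high: float = 3.0
    max_iterations: int = 1000
    population_mode: str = "fixed"

    def __post_init__(self) -> None:
        if not 0.0 < self.x_o < 1.0:
            raise ValueError(f"x_o must lie in (0, 1), got {self.x_o}")
        if self.epsilon <= 0 or self.delta <= 0:
            raise ValueError("epsilon and delta must be positive")
        if not self.ratio_low < self.ratio_high:
            raise ValueError("ratio_low must be below ratio_high")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.population_mode not in ("fixed", "fresh"):
            raise ValueError(f"unknown population_mode {self.population_mode!r}")


@dataclass(frozen=True)
class CalibrationStep:
    j: int
    sigma: float
    tau: float
    x: float
    x_male: float
    x_female: float
    ratio: float
    action: str


@dataclass
class CalibrationTrace:
    """Per-iteration record of the calibration and its final state."""

    spec: CalibrationSpec
    steps: list[CalibrationStep] = field(default_factory=list)
    converged: bool = False

    @property
    def T(self) -> int:
        return self.steps[-1].j

    @property
    def sigma_star(self) -> float:
        return self.steps[-1].sigma

    @property
    def tau_star(self) -> float:
        return self.steps[-1].tau

    @property
    def thresholds(self) -> Thresholds:
        return Thresholds(self.sigma_star, self.tau_star)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ for s in self.steps])

    def summary(self) -> dict:
        last = self.steps[-1]
        return {
            "converged": self.converged,
            "T": last.j,
            "sigma_star": last.sigma,
            "tau_star": last.tau,
            "x": last.x,
            "ratio": last.ratio,
            "used_high_ratio_rule": any(s.action == "tau_up" for s in self.steps),
        }


def calibrate(
    pp: PopulationParams,
    gp: GameParams,
    spec: CalibrationSpec,
    rng: np.random.Generator,
) -> CalibrationTrace:
    """Run the threshold-adaptation loop; see the module docstring.

    Thresholds are tracked as integer step counts on the Delta-grid, so grid
    values such as ``sigma0 - 4 * delta`` are reproduced without
    floating-point drift.
    """
    nbr = build_torus_neighbors(pp.n)
    pop = assign_population(pp, gp, rng)
    trace = CalibrationTrace(spec=spec)
    k_sigma = 0  # net DOWN steps of sigma (sigma = sigma0 - k_sigma * delta)
    k_tau = 0

    for j in range(spec.max_iterations + 1):
        if spec.population_mode == "fresh" and j > 0:
            pop = assign_population(pp, gp, rng)
        # derived from integer step counts; rounding clears binary dust so
        # grid values like 1.70 print exactly
        sigma = round(spec.sigma0 - k_sigma * spec.delta, 12)
        tau = round(spec.tau0 - k_tau * spec.delta, 12)
        res = prevalence(transition_states(pop, nbr, Thresholds(sigma, tau)), pop)
        err = res.x - spec.x_o
        ratio_ok = (
            not math.isnan(res.ratio) and spec.ratio_low <= res.ratio <= spec.ratio_high
        )
        if err > spec.epsilon:
            action = "both_up"  # too many depressed -> raise both thresholds
            k_sigma -= 1
            k_tau -= 1
        elif err < -spec.epsilon:
            action = "both_down"
            k_sigma += 1
            k_tau += 1
        elif ratio_ok:
            action = "accept"
        elif math.isnan(res.ratio) or res.ratio > spec.ratio_high:
            action = "tau_up"  # undefined ratio handled as above the interval
            k_tau -= 1
        else:
            action = "tau_down"
            k_tau += 1
        trace.steps.append(
            CalibrationStep(j, sigma, tau, res.x, res.x_male, res.x_female, res.ratio, action)
        )
        if action == "accept":
            trace.converged = True
            break
    return trace
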