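"""Post-calibration ensembles and composition sweeps.

After calibration the thresholds are treated as fixed psychological
characteristics of the population; what varies across experiments is the
composition of payoffs.  ``run_ensemble`` repeats the one-shot simulation on
independent population realizations; the ``sweep_*`` functions move one of
the composition fractions along a grid (holding the others fixed) and run an
ensemble at every feasible grid point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .game import GameParams
from .dynamics import PrevalenceResult, Thresholds, prevalence, transition_states
from .population import PopulationParams, assign_population, build_torus_neighbors

__all__ = [
    "first_set_game",
    "first_set_population",
    "EnsembleResult",
    "SweepPoint",
    "SweepResult",
    "run_ensemble",
    "sweep_rho_ne_s",
    "sweep_rho_e_s",
    "sweep_rho_ne",
    "sweep_grid_3d",
]

_FEASIBILITY_TOL = 1e-12


def first_set_game() -> GameParams:
    """Payoffs and kind split of the reference configuration."""
    return GameParams(t_A=15, t_B=10, r_A=9, r_B=6, p=1, s=-1, c=0.60)


def first_set_population() -> PopulationParams:
    """Lattice and composition of the reference configuration.

    100 x 100 torus, 49.3% men, 18.8% nonstudents of whom 5 percentage
    points are successful, 75 points of successful students.
    """
    return PopulationParams(
        n=100, male_fraction=0.493, rho_NE=0.188, rho_NE_S=0.05, rho_E_S=0.75
    )


@dataclass
class EnsembleResult:
    """Replicate-level prevalence results and their summary statistics.

    ``ratio_of_means`` divides the mean female prevalence by the mean male
    prevalence; ``mean_ratio`` averages the per-replicate ratios over the
    replicates where the ratio is defined.
    """

    replicates: list[PrevalenceResult]

    @property
    def eta(self) -> int:
        return len(self.replicates)

    @property
    def x_values(self) -> np.ndarray:
        return np.array([r.x for r in self.replicates])

    @property
    def x_mean(self) -> float:
        return float(self.x_values.mean())

    @property
    def x_std(self) -> float:
        if self.eta < 2:
            return 0.0
        return float(self.x_values.std(ddof=1))

    @property
    def x_se(self) -> float:
        return self.x_std / math.sqrt(self.eta)

    @property
    def x_male_mean(self) -> float:
        return float(np.mean([r.x_male for r in self.replicates]))

    @property
    def x_female_mean(self) -> float:
        return float(np.mean([r.x_female for r in self.replicates]))

    @property
    def ratio_of_means(self) -> float:
        xm = self.x_male_mean
        if xm > 0:
            return self.x_female_mean / xm
        return math.inf if self.x_female_mean > 0 else math.nan

    @property
    def mean_ratio(self) -> float:
        ratios = [r.ratio for r in self.replicates if r.ratio_defined and math.isfinite(r.ratio)]
        return float(np.mean(ratios)) if ratios else math.nan

    def summary(self) -> dict:
        return {
            "eta": self.eta,
            "x_mean": self.x_mean,
            "x_std": self.x_std,
            "x_male_mean": self.x_male_mean,
            "x_female_mean": self.x_female_mean,
            "ratio_of_means": self.ratio_of_means,
            "mean_ratio": self.mean_ratio,
        }

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([r.__dict__ for r in self.replicates])
        df.insert(0, "replicate", np.arange(self.eta))
        return df


def run_ensemble(
    pp: PopulationParams,
    gp: GameParams,
    th: Thresholds,
    eta: int,
    rng: np.random.Generator,
) -> EnsembleResult:
    """Run ``eta`` independent one-shot simulations at fixed thresholds.

    Each replicate draws a fresh population from a child stream spawned off
    ``rng``, so the whole ensemble is reproducible from one master seed.
    """
    if eta < 1:
        raise ValueError(f"eta must be >= 1, got {eta}")
    nbr = build_torus_neighbors(pp.n)
    replicates = []
    for child in rng.spawn(eta):
        pop = assign_population(pp, gp, child)
        replicates.append(prevalence(transition_states(pop, nbr, th), pop))
    return EnsembleResult(replicates=replicates)


@dataclass
class SweepPoint:
    params: dict
    feasible: bool
    ensemble: EnsembleResult | None = None


@dataclass
class SweepResult:
    """Per-grid-point ensembles; infeasible points are flagged, never dropped."""

    swept: tuple[str, ...]
    points: list[SweepPoint] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for pt in self.points:
            row = dict(pt.params)
            row["feasible"] = pt.feasible
            if pt.ensemble is not None:
                row.update(pt.ensemble.summary())
            rows.append(row)
        return pd.DataFrame(rows)

    def feasible_points(self) -> list[SweepPoint]:
        return [p for p in self.points if p.feasible]

    def argmax(self, key: str) -> dict:
        """Grid point (params dict) with the largest ensemble mean x̄ among
        feasible points; ``key`` names the swept parameter reported."""
        pts = self.feasible_points()
        if not pts:
            raise ValueError("sweep has no feasible points")
        best = max(pts, key=lambda p: p.ensemble.x_mean)
        return {key: best.params[key], "x_mean": best.ensemble.x_mean}


def _feasible(pp_kwargs: dict) -> bool:
    rho_ne = pp_kwargs["rho_NE"]
    return (
        pp_kwargs["rho_NE_S"] <= rho_ne + _FEASIBILITY_TOL
        and pp_kwargs["rho_E_S"] <= 1.0 - rho_ne + _FEASIBILITY_TOL
    )


def _sweep(
    base: PopulationParams,
    gp: GameParams,
    th: Thresholds,
    point_kwargs: list[dict],
    swept: tuple[str, ...],
    eta: int,
    rng: np.random.Generator,
) -> SweepResult:
    result = SweepResult(swept=swept)
    for kwargs in point_kwargs:
        merged = {
            "n": base.n,
            "male_fraction": base.male_fraction,
            "rho_NE": base.rho_NE,
            "rho_NE_S": base.rho_NE_S,
            "rho_E_S": base.rho_E_S,
            **kwargs,
        }
        label = {k: merged[k] for k in ("rho_NE", "rho_NE_S", "rho_E_S")}
        if not _feasible(merged):
            result.points.append(SweepPoint(params=label, feasible=False))
            continue
        pp = PopulationParams(**merged)
        ens = run_ensemble(pp, gp, th, eta, rng.spawn(1)[0])
        result.points.append(SweepPoint(params=label, feasible=True, ensemble=ens))
    return result


def sweep_rho_ne_s(
    base: PopulationParams,
    gp: GameParams,
    th: Thresholds,
    grid,
    eta: int,
    rng: np.random.Generator,
) -> SweepResult:
    """Sweep the successful-nonstudent fraction at fixed ``rho_NE``.

    The unsuccessful-nonstudent fraction absorbs the change, so increasing
    ``rho_NE_S`` converts p-payoff holders into t-payoff holders.
    """
    points = [{"rho_NE_S": float(v)} for v in grid]
    return _sweep(base, gp, th, points, ("rho_NE_S",), eta, rng)


def sweep_rho_e_s(
    base: PopulationParams,
    gp: GameParams,
    th: Thresholds,
    grid,
    eta: int,
    rng: np.random.Generator,
    rho_ne_s_variants=(0.0, 0.05),
) -> dict[float, SweepResult]:
    """Sweep the successful-student fraction for each ``rho_NE_S`` variant.

    ``rho_E`` stays fixed, so increasing ``rho_E_S`` converts s-payoff
    holders into r-payoff holders.  Returns one SweepResult per variant,
    keyed by the variant value.
    """
    out: dict[float, SweepResult] = {}
    for variant in rho_ne_s_variants:
        points = [{"rho_E_S": float(v), "rho_NE_S": float(variant)} for v in grid]
        out[float(variant)] = _sweep(base, gp, th, points, ("rho_E_S",), eta, rng)
    return out


def sweep_rho_ne(
    base: PopulationParams,
    gp: GameParams,
    th: Thresholds,
    grid,
    eta: int,
    rng: np.random.Generator,
) -> SweepResult:
    """Sweep the nonstudent fraction at fixed ``rho_NE_S`` and ``rho_E_S``.

    Points where ``rho_E_S > 1 - rho_NE`` or ``rho_NE_S > rho_NE`` are
    infeasible and flagged.
    """
    points = [{"rho_NE": float(v)} for v in grid]
    return _sweep(base, gp, th, points, ("rho_NE",), eta, rng)


def sweep_grid_3d(
    base: PopulationParams,
    gp: GameParams,
    th: Thresholds,
    rho_ne_s_grid,
    rho_ne_grid,
    rho_e_s_grid,
    eta: int,
    rng: np.random.Generator,
) -> SweepResult:
    """Full factorial sweep over the three composition fractions.

    Infeasible cells are flagged and skipped.  The per-slice maximizer of
    x̄ over ``rho_E_S`` can be read off the result via
    :meth:`SweepResult.to_dataframe`.
    """
    points = [
        {"rho_NE_S": float(a), "rho_NE": float(b), "rho_E_S": float(c)}
        for a in rho_ne_s_grid
        for b in rho_ne_grid
        for c in rho_e_s_grid
    ]
    return _sweep(base, gp, th, points, ("rho_NE_S", "rho_NE", "rho_E_S"), eta, rng)
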