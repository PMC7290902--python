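# Methods

## Model

The population is an *n* × *n* toroidal lattice (wrap-around in both
directions) whose cells are individuals connected to their eight Moore
neighbors. The torus removes edge effects: every neighborhood has exactly
eight distinct members, which requires *n* ≥ 3.

Each individual carries four attributes: gender (male/female), payoff kind
(A/B), a played strategy (education E/NE crossed with labor-market outcome
S/NS) and the payoff the strategy implies — *t* for (NE, S), *r* for (E, S),
*p* for (NE, NS), *s* for (E, NS), with kind splitting the success payoffs
into *t*<sub>A</sub>/*t*<sub>B</sub> and *r*<sub>A</sub>/*r*<sub>B</sub>.
The game is played exactly once and exogenously: individuals do not choose
strategies to maximize payoff, the composition of strategies is a model
input. The payoff ordering *t* > *r* > *p* > *s* is enforced per kind at
construction; the prisoner's-dilemma refinement *r* > (*t* + *s*)/2 is
checked per kind but only warns, since no simulation step depends on it.

The disease dynamics is a one-shot threshold rule: individual *i* becomes
depressed iff the mean payoff of the eight neighbors exceeds the personal
payoff by strictly more than σ\* (men) or τ\* (women). Ties stay healthy;
the strict comparison makes the depressed set nested in the thresholds
(lowering a threshold can only add cases), which the calibration relies on.
There is no second round, recovery, or contagion.

## Population generator

The generator is the model's study condition, not a test fixture. It
emulates a cohort of young adults parameterized by official-statistics-style
fractions: a male fraction (default 49.3%), a nonstudent fraction
ρ<sub>NE</sub> (default 18.8%), and the *absolute* population fractions of
successful nonstudents ρ<sub>NE,S</sub> (default 5%) and successful students
ρ<sub>E,S</sub> (default 75%); unsuccessful fractions follow by difference,
e.g. ρ<sub>E,NS</sub> = (1 − ρ<sub>NE</sub>) − ρ<sub>E,S</sub>. Treating
ρ<sub>·,S</sub> as absolute fractions (rather than success rates within the
student/nonstudent stratum) keeps ρ<sub>E,S</sub> + ρ<sub>E,NS</sub> equal
to the fixed student share; combinations with
ρ<sub>E,S</sub> > 1 − ρ<sub>NE</sub> are rejected (or flagged infeasible in
sweeps).

Category counts are integers obtained by largest-remainder apportionment of
*n*² × fraction (leftover units go to the largest fractional remainders,
ties broken by category order), and attributes are assigned by shuffling
exact-count label pools. Two independent shuffles consume the seeded stream
in a fixed order: gender first, then a *joint* (strategy × kind) pool of
eight categories with fractions split *c* : 1 − *c* by kind. The joint pool
is deliberate: it makes the six payoff-category counts exact on every
realization (independent kind and strategy pools would leave the joint
counts hypergeometrically random) while keeping kind independent of
education/outcome — the A:B ratio inside every strategy is *c* : 1 − *c* up
to rounding. Exact counts also shrink replicate-to-replicate variance: the
only randomness left is the spatial arrangement, so the ensemble standard
deviation (~0.2 percentage points at *n* = 100) is far below the binomial
√(x(1−x)/n²) (~0.4 points).

What the generator does *not* emulate: any correlation between gender and
payoff (assignment is independent by construction, verified by a chi-square
test), spatial clustering of socioeconomic attributes (neighborhoods are
well-mixed), and heterogeneity in network degree. Passing tests therefore
say nothing about populations where success clusters geographically or by
gender — in real cohorts those correlations exist, and they would change
both the prevalence level and the calibrated thresholds.

## Exact enumeration oracle

For an independent check of the simulator, the depressed probability is
computed analytically under an i.i.d. approximation: own payoff drawn from
the six-category distribution π, the eight neighbor payoffs from
Multinomial(8, π), and

x(θ) = Σ<sub>q</sub> π(q) Σ<sub>k</sub> M(k; 8, π) · 1[(Σ k·v)/8 − q > θ],

with all C(13, 5) = 1287 compositions enumerated exactly (log-space pmf;
zero-probability categories handled as 0·log 0 = 0). The simulator's
exact-count assignment deviates from i.i.d. at O(1/*n*²); simulation/oracle
agreement is tested at 3 Monte-Carlo standard errors plus a 10/*n*²
allowance for that discrepancy. The oracle treats men and women as sharing
π, differing only through σ versus τ.

## Calibration

The calibration loop holds one population realization fixed (default) so
that prevalence is a deterministic, monotone function of the thresholds,
and walks the thresholds on the exact Δ-grid {σ(0) − kΔ} (integer step
counts, no floating-point drift):

1. prevalence error > +ε → both thresholds **up** by Δ;
2. prevalence error < −ε → both **down** by Δ;
3. error inside the band but female/male ratio below the target interval →
   τ down by Δ (a lower τ makes women more susceptible, raising the ratio);
   ratio above the interval, or undefined because no man is depressed →
   τ up by Δ;
4. stop at the first step where both criteria hold.

Each branch moves its error toward zero, which with the monotone, bounded
prevalence function makes the loop a terminating coordinate descent
whenever the Δ-grid is fine enough to land inside the ε-band; a
`max_iterations` cap (default 1000) catches infeasible settings (e.g.
Δ = 0.5 with ε = 10⁻⁴ oscillates forever). The high-ratio branch is the
symmetric completion of the low-ratio rule and is flagged in the trace when
used. A `population_mode="fresh"` option redraws the population each
iteration for sensitivity analysis; it forfeits the determinism and the
termination argument, so the default is the fixed realization.

Two structural consequences are worth knowing. First, from a symmetric
start (σ(0) = τ(0)) the loop reaches the ratio interval from below in Δ-size
nudges, so the accepted ratio typically sits just above the lower bound
(≈1.5 with the defaults) rather than mid-interval. Second, on the default
configuration the accepted prevalence tends to sit in the upper half of the
ε-band, because each τ-step adds prevalence and the loop stops at the first
acceptable state.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| payoffs (t_A, t_B, r_A, r_B, p, s) | 15, 10, 9, 6, 1, −1 | dimensionless game payoffs |
| c | 0.60 | kind-A fraction |
| n | 100 | lattice side (10 000 individuals) |
| male fraction | 0.493 | gender split |
| ρ_NE, ρ_NE,S, ρ_E,S | 0.188, 0.05, 0.75 | composition fractions (absolute) |
| x_o, ε | 0.20, 0.01 | target prevalence and band |
| Δ | 0.05 | threshold step |
| σ(0), τ(0) | 1, 1 | initial thresholds |
| ratio interval | [1.5, 3.0] | female/male prevalence ratio |
| η | 100 | post-calibration replicates |

With these defaults the calibration converges in ~130 steps to
σ\* = 4.75, τ\* = 1.9 (seed 42; other seeds move the endpoint by a few Δ),
and the η = 100 ensemble gives x̄ ≈ 20.2% ± 0.2 points with a female/male
ratio ≈ 1.5 — the numbers in the README's worked example, recomputed by
`scripts/acceptance.py` on every run.

## Ensembles and sweeps

`run_ensemble` spawns one child random stream per replicate from the master
generator, so every result is bit-reproducible from a single seed; sweep
drivers spawn one child per grid point the same way. Sweeps hold the
thresholds fixed at the values calibrated on the default configuration —
the thresholds are read as psychological characteristics of the population,
not quantities to re-fit per composition — and vary one fraction while its
complement absorbs the change (ρ<sub>NE,NS</sub> for the ρ<sub>NE,S</sub>
sweep, ρ<sub>E,NS</sub> for the ρ<sub>E,S</sub> sweep). Infeasible grid
points are flagged and carried in the output rather than dropped. Trend
assertions in the tests compare neighboring grid points with a one-combined-
standard-error slack, using η = 30 replicates per grid point and 5-point
grids; the first-set ensemble itself uses the full η = 100.

## Known limitations

- One-shot dynamics: no disease course, remission or treatment; prevalence
  is a static functional of the payoff field and thresholds.
- The calibration's stopping rule pins the achieved ratio near the lower
  interval bound and cannot produce a mid-interval ratio from a symmetric
  start (see above); likewise σ\* − τ\* is determined by the loop, not set.
- The i.i.d. oracle ignores the exact-count constraint; at *n* ≤ 10 the
  O(1/*n*²) discrepancy is no longer negligible.
- Undefined ratio handling (no depressed men → treat as above the interval)
  raises τ, which cannot itself create depressed men; a configuration whose
  male prevalence is structurally zero will hit the iteration cap.
- Only unit-radius Moore neighborhoods on a torus; no alternative
  topologies, neighborhood radii, or migration.
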