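# Methods

This note documents the models, estimators and numerical conventions
implemented in `sasim`, the defaults chosen where the underlying
methods leave the choice open, and what the bundled test subjects do
and do not demonstrate.

## Model contract and experiment engine

A model declares a fixed parameter set with defaults and, given a
parameter mapping and an integer seed, yields a run handle producing an
*observation series*: a data frame with a strictly increasing integer
`tick` column (starting at 1, one tick = one output interval) and named
numeric outputs.  Determinism is part of the contract: identical
`(params, seed, ticks)` must reproduce the series bit for bit, which
requires the model to draw all randomness from the generator created
from its seed.  Both bundled simulators and the analytic fixtures obey
this; the test suite enforces it.

**Seeding.**  Per-replication seeds are the low 63 bits of a
counter-keyed BLAKE2b hash of `(master_seed, replication_index)`.  This
is platform-independent, stable across releases, and collisions are
resolved deterministically.  Within one experiment the same seed list
is reused for every design point (common random numbers), which removes
between-point seed noise from sensitivity contrasts; replications and
different master seeds remain independent.

**Objectives.**  A user objective maps one run's parameter set and
series to named scalars.  It is evaluated once per replication; the
sensitivity methods consume the per-design-point *mean* over
replications.  Averaging before effect estimation targets the expected
response surface and shrinks elementary-effect noise; the
per-replication values stay available in the `output` table for
dispersion analyses.  When no objective is given, the time average of
every output column is used.

**Execution order** is design-major, replication-minor, and results are
independent of any future parallelisation by contract.

## Experimental designs

Factors are uniform over inclusive `[lower, upper]` ranges; all designs
are generated on the unit cube and mapped affinely to physical units,
and both coordinate systems are kept on the design object.  Latin
hypercube sampling places exactly one point per marginal stratum
`[j/n, (j+1)/n)`, uniformly within the stratum, with an independent
random permutation per factor.  Full factorial grids are evenly spaced
including both endpoints.  Integer-valued model parameters (population
counts, regrowth times) are swept as reals and rounded half-up only
when the concrete parameter set is built, so the sensitivity math stays
on a continuous cube; the emitted `paramset` table records the rounded
values actually passed to the model.

## Morris elementary-effects screening

Trajectories follow the classic one-at-a-time orientation scheme: a
random base point on the p-level grid, a random factor order, and a
random step direction per factor among those keeping the point inside
the cube, giving `r (k+1)` model evaluations for `r` trajectories.

* **Step size.** The standard step Δ = p/(2(p−1)) requires an even
  level count; the alternative Δ = 1/(p−1) is a single grid spacing.
  The default mode (`auto`) uses the standard step for even p and the
  single-spacing step for odd p (e.g. the package default p = 5).
  The alternative step matters for oscillatory responses: for
  f = sin(2πx) at p = 8 the standard step only ever straddles the
  oscillation so that every elementary effect shares one sign
  (μ\* = |μ| exactly), whereas the single-spacing step resolves the
  sign changes and produces the nonmonotonicity signature |μ| ≪ μ\*.
* **Units.** Effects are computed in unit-cube coordinates —
  `(y(upper) − y(lower))/Δ` with "upper" the point with the larger
  coordinate — so factors with different physical units are directly
  comparable and the estimator does not depend on the walk direction.
* **σ divisor.** σ uses the population divisor r by default, matching
  the classical definition; `sigma_divisor="r-1"` switches to the
  sample form for comparability with other toolkits.

For affine responses every elementary effect equals the unit-cube
slope, making μ = μ\* = |slope| and σ = 0 to machine precision — the
suite uses this as an exactness oracle.

## Sobol' variance decomposition

The plan is the A/B/AB_i scheme: two independent N × k base samples
and, per factor, A with column i replaced from B, evaluated in the
order A, B, AB_1..AB_k (N(k+2) runs).  Estimators:

* total variance V(Y): sample variance (divisor 2N−1) of the pooled
  A and B evaluations — all non-hybrid points, documented so external
  cross-checks can match it;
* first order: V_i ≈ mean(f_B · (f_ABi − f_A)) (Saltelli 2010);
* total order: V(Y) − V_{−i} ≈ mean((f_A − f_ABi)²)/2 (Jansen).

Estimates are never clamped: slightly negative values are the expected
small-N behaviour of these estimators and a warning recommends a larger
N.  A constant output raises a degenerate-variance error rather than
returning indices.  Percentile-bootstrap confidence bounds (resampling
the N sample indices jointly across all blocks; 500 resamples by
default from the CLI flag) are available for interpreting small-N runs.

The base sampler is pseudo-random uniform by default with Latin
hypercube available by flag.  On additive oracles at N = 8192 the
random sampler leaves first-order errors up to ≈ 0.05 depending on the
seed, while the stratified sampler keeps them well below 0.03; the
estimator-accuracy tests therefore use the LHS flag where a tight band
is asserted.

Verification is against closed forms computed independently: the
Ishigami function (V(Y) = a²/8 + bπ⁴/5 + b²π⁸/18 + 1/2, V1 =
(1+bπ⁴/5)²/2, V2 = a²/8, V13 = b²π⁸(1/18−1/50)), the additive linear
function (S_i = c_i²/Σc_j²), and the product x1·x2 (S = 3/7, ST = 4/7).
The closed forms themselves are confirmed in-test by brute-force
Monte-Carlo conditional-variance estimation (10⁶ points).

## Replication stability

The coefficient of variation uses the sample standard deviation
(divisor n−1) over the absolute mean; it is undefined (error, or NaN
inside curve tables) for zero-mean outputs.  For each of `s`
LHS-sampled parameter sets the engine simulates `r_max` replications
*once* and evaluates the CV on prefixes at each checkpoint (default
grid 5, 10, …, r_max), so the curve at n depends only on the first n
seeds and no re-simulation occurs.  Convergence is declared at the
first checkpoint where `window` (default 2) consecutive curve
transitions each change the CV by at most `tol` (default 0.01,
absolute) — an explicit criterion replacing by-eye judgement of when
the curve "stops moving".

## Calibration

Cost building blocks: the categorical criterion (0 inside an inclusive
acceptance interval, 1 outside) and distance costs (SSE, RMSE, and
NRMSD — RMSE divided by the *range* of the reference series, chosen
over the mean-normalised form because it remains meaningful when the
reference crosses zero).  `easy_calibration` samples the factor space
by Latin hypercube, averages each cost over replications, and ranks
ascending; several named costs are combined by unweighted sum for the
ranking while per-cost columns are preserved, and ties keep design
order (stable sort).  The search is deliberately pure sampling — it
maps the cost surface rather than descending it.

## Predation model (wolf–sheep–grass)

Defaults: 50 wolves, 100 sheep, energy gains 20 (wolf) and 4 (sheep),
reproduction 5% and 4% per tick, grass regrowth 30 ticks.  The classic
demo conventions fill in what the bare parameter list leaves open:
initial energy uniform on [0, 2·gain), movement (1 unit per tick in a
uniformly random heading on the periodic 50 × 50 plane) costs 1 energy,
reproduction halves the parent's energy and passes the other half to
the offspring, and "patch" means the unit cell containing the
continuous position.  Wolves eat one uniformly chosen sheep sharing
their cell; a grazed patch regrows `grassregrowthtime` ticks later.
Half the patches start grown, the rest with a uniform residual
countdown.  Agents act in a freshly shuffled order with the per-agent
sequence move → eat → reproduce → die; newborns first act on the next
tick.  The fixed-step RK4 Lotka–Volterra integrator provides the
aggregated two-species counterpart (prey x, predator y with negative
predator base rate), and its conserved quantity
c4·x + c2·ln x + c3·y − c1·ln y is used to validate the integration.

## Conjugation common-pool model

Defaults, each a deliberate choice where only the process structure is
prescribed: plasmid-free doubling time 40 min (one tick = 1 min);
conjugation probability per cell cycle `p1P` = 0.5; plasmid costs
`p1Cost` = 0.10 and `p2Cost` = 0.05 (the cheater is cheaper — it
expresses no machinery); 100 founder cells in a 10 µm disc at the
centre of the 100 × 100 µm periodic lattice; initial infection
disjoint, 25% P1-only and 25% P2-only; 120 nutrient particles per
lattice site with uptake 1 particle per cell per tick, so a stationary
cell can sustain full-speed growth for two hours and crowded
neighbourhoods compete for what is left; division mass drawn from
N(1.0, 0.05²) arbitrary units truncated at ±3σ; daughters displaced
0.5 µm in a random heading; the transferred plasmid of a doubly
infected donor is P2 with probability `hijack` = 0.5 (uniform
competition for the shared apparatus, adjustable).  Growth multiplies
mass by exp(φ ln2 / G_eff) per tick, where φ is the obtained fraction
of the uptake quantum and G_eff = doublingTime · (1 + p1·p1Cost +
p2·p2Cost); mass is capped at the division trigger.  Conjugation
eligibility requires carrying P1 and mass ≥ 0.70 × division mass
(inclusive); the per-cycle Bernoulli is drawn once at first
eligibility and, while pending, one random cell within 1.5 µm is
probed per tick until a transfer succeeds or the cell divides.  Cells
may overlap (no shoving), do not move apart from daughter displacement
(an explicit modelling choice; a diffusion step was considered and
omitted as the colony is surface-attached), do not die, and never lose
a plasmid — so the census partition is exact, the population count is
non-decreasing, and each lineage's plasmid state is monotone, all of
which the tests assert.

## What the test subjects show — and what they do not

The analytic fixtures verify the estimators exactly or against closed
forms; they are deterministic and carry no replication noise.  The two
simulators add the features real applications have — stochasticity,
interactions, integer-valued factors — but they remain small: desk-
scale screening (k = 7, p = 5, r = 10, 200 ticks, 2 replications) and
desk-scale decomposition (k = 4, N = 64, 100 ticks, 2 replications)
finish in minutes on one CPU, and the stability demonstration uses
5 parameter sets × 50 replications × 100 ticks.  These sizes are the
package's recommended starting points, not converged analyses: at
N = 64 first-order indices routinely go slightly negative, and a
production study would raise N, r and the replication count until the
bootstrap bounds and CV curves say otherwise.  Passing tests show the
machinery is correct and the qualitative rankings stable (e.g. the
grazing gain dominating the prey output in most master seeds), not
that any particular biological conclusion is settled.

## Numerical conventions

CSV output uses shortest round-trip float formatting; designs, plans
and experiment tables are bit-reproducible for a given master seed
across processes and platforms.  Integer parameters are rounded
half-up (`floor(x + 0.5)`).  Boolean defaults are rounded to the
nearest truth value if ever swept.  Error types are specific
(degenerate variance, undefined CV, duplicate factor, …) so callers
can distinguish contract violations from numerical pathologies.

## Known limitations

Only uniform, uncorrelated factor distributions; no quasi-random
(low-discrepancy) sequences; no second-order Sobol' indices beyond the
total-order aggregate; no optimised trajectory selection or factor
groups for Morris; no iterative optimisers for calibration; single-
process execution.  The simulators are deliberately minimal: the
predation model omits the fixed-energy sheep variant and spatial
output maps, and the conjugation model omits pili-count state,
repression, conjugation cost penalties, segregational loss and cell
death.
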