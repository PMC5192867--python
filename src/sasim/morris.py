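"""Morris elementary-effects screening.

The method perturbs one factor at a time along randomized trajectories on
a ``p``-level grid over the unit cube.  For each factor the ``r`` signed
finite differences (elementary effects) form a distribution whose mean
``mu``, mean absolute value ``mu_star`` and dispersion ``sigma`` rank the
factor's influence: ``mu_star`` measures overall importance, ``sigma``
flags nonlinearity or interactions, and ``|mu| << mu_star`` signals
effects of opposite signs (nonmonotonicity).

Effects are computed in unit-cube coordinates, so factors with different
physical units are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignMatrix, FactorTable
from .errors import InvalidLevels, InvalidRange, ShapeError
from .experiment import (
    ExperimentResult,
    Model,
    Objective,
    RunSpec,
    aggregate_output,
    run_experiment,
)

__all__ = [
    "MorrisPlan",
    "ElementaryEffectSet",
    "MorrisIndices",
    "MorrisResult",
    "morris_delta",
    "morris_design",
    "elementary_effects",
    "morris_metrics",
    "easy_morris",
]


def morris_delta(p: int, mode: str = "standard") -> float:
    """Grid step on the unit cube.

    ``standard`` is ``p / (2(p - 1))`` and requires an even number of
    levels; ``alternative`` is ``1 / (p - 1)`` (a single grid spacing),
    which can reveal nonmonotonic responses the standard step folds away.
    """
    if p < 2:
        raise InvalidLevels("p must be >= 2")
    if mode == "standard":
        if p % 2 != 0:
            raise InvalidLevels("standard step requires an even level count p")
        return p / (2.0 * (p - 1))
    if mode == "alternative":
        return 1.0 / (p - 1)
    raise InvalidRange(f"unknown delta mode {mode!r}")


@dataclass(frozen=True)
class MorrisPlan:
    """A trajectory design: ``r`` blocks of ``k + 1`` unit-cube points.

    ``steps[t][j] = (factor_index, direction)`` describes the j-th
    within-trajectory transition of trajectory ``t``; consecutive points
    differ in exactly that coordinate by ``direction * delta``.
    """

    table: FactorTable
    p: int
    delta: float
    r: int
    trajectories: tuple[np.ndarray, ...]
    steps: tuple[tuple[tuple[int, int], ...], ...]
    design: DesignMatrix

    @property
    def k(self) -> int:
        return self.table.k

    @property
    def n_rows(self) -> int:
        return self.r * (self.k + 1)


@dataclass(frozen=True)
class ElementaryEffectSet:
    """Per output, an ``(r, k)`` array of signed elementary effects."""

    factor_names: tuple[str, ...]
    effects: dict[str, np.ndarray]

    @property
    def r(self) -> int:
        return next(iter(self.effects.values())).shape[0]


@dataclass(frozen=True)
class MorrisIndices:
    """Tidy per-(output, factor) table of mu, mu_star, sigma."""

    table: pd.DataFrame  # columns: output, factor, mu, mu_star, sigma

    def for_output(self, output: str) -> pd.DataFrame:
        sub = self.table[self.table["output"] == output]
        if sub.empty:
            raise KeyError(f"no indices for output {output!r}")
        return sub.set_index("factor")[["mu", "mu_star", "sigma"]]


def _resolve_delta(p: int, delta_mode: str) -> float:
    # "auto" keeps the recommended standard step when p is even and falls
    # back to the single-spacing step for odd p (where the standard
    # formula does not apply).
    if delta_mode == "auto":
        return morris_delta(p, "standard" if p % 2 == 0 else "alternative")
    return morris_delta(p, delta_mode)


def morris_design(
    table: FactorTable,
    p: int = 5,
    r: int = 10,
    delta_mode: str = "auto",
    rng: np.random.Generator | int | None = None,
) -> MorrisPlan:
    """Randomized-orientation one-at-a-time trajectories.

    Each trajectory starts at a random point of the ``p``-level grid,
    then moves every factor exactly once, in random order, by
    ``+/- delta`` — the direction is drawn at random among those keeping
    the point inside ``[0, 1]``.  The design stacks the ``r`` trajectories
    into ``r * (k + 1)`` rows.
    """
    if p < 2:
        raise InvalidLevels("p must be >= 2")
    if r < 2:
        raise InvalidRange("r must be >= 2")
    if table.k == 0:
        raise InvalidRange("factor table is empty")
    delta = _resolve_delta(p, delta_mode)
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    k = table.k
    grid = np.linspace(0.0, 1.0, p)
    eps = 1e-12
    up_ok = grid <= 1.0 - delta + eps
    down_ok = grid >= delta - eps
    assert up_ok.any() and down_ok.any(), "infeasible step for this grid"

    trajectories: list[np.ndarray] = []
    steps: list[tuple[tuple[int, int], ...]] = []
    for _ in range(r):
        directions = np.where(gen.random(k) < 0.5, 1, -1)
        base = np.empty(k)
        for i in range(k):
            feasible = grid[up_ok] if directions[i] == 1 else grid[down_ok]
            base[i] = feasible[gen.integers(len(feasible))]
        order = gen.permutation(k)
        pts = np.empty((k + 1, k))
        pts[0] = base
        for j, fac in enumerate(order):
            pts[j + 1] = pts[j]
            pts[j + 1, fac] = pts[j, fac] + directions[fac] * delta
        trajectories.append(pts)
        steps.append(tuple((int(f), int(directions[f])) for f in order))

    unit = np.vstack(trajectories)
    design = DesignMatrix.from_unit(table, unit)
    return MorrisPlan(
        table=table,
        p=p,
        delta=delta,
        r=r,
        trajectories=tuple(trajectories),
        steps=tuple(steps),
        design=design,
    )


def _as_output_frame(y, n_rows: int) -> pd.DataFrame:
    if isinstance(y, pd.DataFrame):
        df = y
    else:
        arr = np.asarray(y, dtype=float)
        if arr.ndim == 1:
            df = pd.DataFrame({"y": arr})
        else:
            df = pd.DataFrame(arr, columns=[f"y{i}" for i in range(arr.shape[1])])
    if len(df) != n_rows:
        raise ShapeError(
            f"expected one aggregated scalar per design row ({n_rows}), got {len(df)}"
        )
    return df


def elementary_effects(plan: MorrisPlan, aggregated_outputs) -> ElementaryEffectSet:
    """Finite-difference effects from the per-design-point scalars.

    For each transition where factor ``i`` moved, the effect is
    ``(y(upper point) - y(lower point)) / delta`` where "upper" is the
    point with the larger i-th coordinate — the estimator is therefore
    independent of the direction the trajectory happened to walk.
    """
    df = _as_output_frame(aggregated_outputs, plan.n_rows)
    k, r = plan.k, plan.r
    effects = {
        str(col): np.full((r, k), np.nan) for col in df.columns
    }
    values = {str(col): df[col].to_numpy(dtype=float) for col in df.columns}
    for t in range(r):
        offset = t * (k + 1)
        for j, (fac, direction) in enumerate(plan.steps[t]):
            lo_row, hi_row = offset + j, offset + j + 1
            if direction < 0:
                lo_row, hi_row = hi_row, lo_row
            for col, vals in values.items():
                effects[col][t, fac] = (vals[hi_row] - vals[lo_row]) / plan.delta
    return ElementaryEffectSet(factor_names=plan.table.names, effects=effects)


def morris_metrics(
    ee: ElementaryEffectSet, sigma_divisor: str = "r"
) -> MorrisIndices:
    """mu, mu_star and sigma of the elementary-effect distributions.

    ``sigma`` uses the population divisor ``r`` by default;
    ``sigma_divisor="r-1"`` switches to the sample form for
    compatibility with other toolkits.
    """
    if sigma_divisor not in ("r", "r-1"):
        raise InvalidRange("sigma_divisor must be 'r' or 'r-1'")
    rows = []
    for output, arr in ee.effects.items():
        r = arr.shape[0]
        ddof = 0 if sigma_divisor == "r" else 1
        mu = arr.mean(axis=0)
        mu_star = np.abs(arr).mean(axis=0)
        sigma = arr.std(axis=0, ddof=ddof)
        for i, name in enumerate(ee.factor_names):
            rows.append(
                {
                    "output": output,
                    "factor": name,
                    "mu": mu[i],
                    "mu_star": mu_star[i],
                    "sigma": sigma[i],
                }
            )
    return MorrisIndices(table=pd.DataFrame(rows))


@dataclass
class MorrisResult:
    plan: MorrisPlan
    experiment: ExperimentResult
    effects: ElementaryEffectSet
    indices: MorrisIndices


def easy_morris(
    model: Model,
    table: FactorTable,
    p: int = 5,
    r: int = 10,
    ticks: int = 300,
    replications: int = 1,
    objective: Objective | None = None,
    master_seed: int = 0,
    delta_mode: str = "auto",
) -> MorrisResult:
    """Complete screening pipeline: design, runs, effects, metrics.

    Stochastic models are smoothed by averaging the objective over
    ``replications`` seeded repetitions before effects are computed.
    """
    plan = morris_design(
        table, p=p, r=r, delta_mode=delta_mode, rng=np.random.default_rng(master_seed)
    )
    spec = RunSpec(ticks=ticks, replications=replications, master_seed=master_seed)
    experiment = run_experiment(model, plan.design, spec, objective)
    agg = aggregate_output(experiment, "mean").drop(columns="run")
    effects = elementary_effects(plan, agg)
    indices = morris_metrics(effects)
    return MorrisResult(plan=plan, experiment=experiment, effects=effects, indices=indices)
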