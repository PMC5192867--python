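"""Variance-decomposition (Sobol') sensitivity indices.

The sampling plan is the classic A/B/AB_i scheme: two independent
``N x k`` base matrices A and B plus, for every factor ``i``, the hybrid
matrix AB_i (A with column ``i`` taken from B), giving ``N (k + 2)``
model evaluations in total.

Estimators:

* total variance ``V(Y)``: sample variance of the pooled A and B
  evaluations (divisor ``2N - 1``);
* first-order contribution ``V_i``: ``mean(f_B * (f_ABi - f_A))``
  (Saltelli 2010);
* total-order numerator: ``mean((f_A - f_ABi)^2) / 2`` (Jansen 1999).

``S_i = V_i / V(Y)`` measures the variance explained by factor ``i``
alone; ``ST_i`` additionally counts every interaction involving it.
Estimates can be slightly negative at small N; they are reported as
computed, never clamped — a negative index is a useful small-sample
diagnostic, and the remedy is a larger N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import (
    DesignMatrix,
    FactorTable,
    sample_latin_hypercube,
    sample_random,
)
from .errors import DegenerateVariance, InvalidRange, InvalidSampleSize, ShapeError
from .experiment import (
    ExperimentResult,
    Model,
    Objective,
    RunSpec,
    aggregate_output,
    run_experiment,
)

__all__ = [
    "SobolPlan",
    "SobolIndices",
    "SobolResult",
    "sobol_design",
    "sobol_indices",
    "easy_sobol",
]


@dataclass(frozen=True)
class SobolPlan:
    """A/B/AB_i evaluation plan with rows ordered A, B, AB_1..AB_k."""

    table: FactorTable
    N: int
    A: np.ndarray
    B: np.ndarray
    design: DesignMatrix

    @property
    def k(self) -> int:
        return self.table.k

    @property
    def n_rows(self) -> int:
        return self.N * (self.k + 2)


def sobol_design(
    table: FactorTable,
    N: int,
    sampler: str = "random",
    rng: np.random.Generator | int | None = None,
) -> SobolPlan:
    """Build the evaluation plan from two independent base samples."""
    if table.k == 0:
        raise InvalidRange("factor table is empty")
    if N < 2:
        raise InvalidSampleSize("base sample size N must be >= 2")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if sampler == "random":
        draw = lambda: sample_random(N, table, gen).unit_rows  # noqa: E731
    elif sampler == "lhs":
        draw = lambda: sample_latin_hypercube(N, table, gen).unit_rows  # noqa: E731
    else:
        raise InvalidRange(f"unknown sampler {sampler!r}")
    A = draw()
    B = draw()
    blocks = [A, B]
    for i in range(table.k):
        ab = A.copy()
        ab[:, i] = B[:, i]
        blocks.append(ab)
    unit = np.vstack(blocks)
    return SobolPlan(table=table, N=N, A=A, B=B, design=DesignMatrix.from_unit(table, unit))


@dataclass(frozen=True)
class SobolIndices:
    """Tidy per-(output, factor) table of S, ST plus the total variance."""

    table: pd.DataFrame  # columns: output, factor, S, ST [, S_lo, S_hi, ST_lo, ST_hi]
    variance: dict[str, float]
    N: int

    def for_output(self, output: str) -> pd.DataFrame:
        sub = self.table[self.table["output"] == output]
        if sub.empty:
            raise KeyError(f"no indices for output {output!r}")
        return sub.set_index("factor").drop(columns="output")


def _split_blocks(values: np.ndarray, N: int, k: int):
    fA = values[:N]
    fB = values[N : 2 * N]
    fAB = [values[(2 + i) * N : (3 + i) * N] for i in range(k)]
    return fA, fB, fAB


def _estimate(fA, fB, fAB_i):
    vy = np.var(np.concatenate([fA, fB]), ddof=1)
    vi = np.mean(fB * (fAB_i - fA))
    et = 0.5 * np.mean((fA - fAB_i) ** 2)
    return vy, vi, et


def sobol_indices(
    plan: SobolPlan,
    aggregated_outputs,
    n_boot: int = 0,
    ci: float = 0.95,
    rng: np.random.Generator | int | None = None,
) -> SobolIndices:
    """First- and total-order indices from the per-design-point scalars.

    Parameters
    ----------
    aggregated_outputs : DataFrame or 1-D array
        One scalar per design row per output, in plan row order.
    n_boot : int
        If > 0, percentile bootstrap confidence bounds are added by
        resampling the N sample indices jointly across A, B and AB_i.

    Raises
    ------
    DegenerateVariance
        If an output is constant over the pooled A and B points.
    """
    N, k = plan.N, plan.k
    if isinstance(aggregated_outputs, pd.DataFrame):
        df = aggregated_outputs
    else:
        arr = np.asarray(aggregated_outputs, dtype=float)
        df = pd.DataFrame({"y": arr}) if arr.ndim == 1 else pd.DataFrame(arr)
    if len(df) != plan.n_rows:
        raise ShapeError(
            f"expected {plan.n_rows} aggregated scalars (N(k+2)), got {len(df)}"
        )

    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    rows = []
    variance: dict[str, float] = {}
    for col in df.columns:
        values = df[col].to_numpy(dtype=float)
        fA, fB, fAB = _split_blocks(values, N, k)
        vy = np.var(np.concatenate([fA, fB]), ddof=1)
        if vy == 0.0:
            raise DegenerateVariance(
                f"output {col!r} is constant over the base sample; "
                "sensitivity indices are undefined"
            )
        variance[str(col)] = float(vy)
        for i, name in enumerate(plan.table.names):
            _, vi, et = _estimate(fA, fB, fAB[i])
            s_i = vi / vy
            st_i = et / vy
            row = {"output": str(col), "factor": name, "S": s_i, "ST": st_i}
            if n_boot > 0:
                s_bs = np.empty(n_boot)
                st_bs = np.empty(n_boot)
                for b in range(n_boot):
                    idx = gen.integers(0, N, size=N)
                    vy_b, vi_b, et_b = _estimate(fA[idx], fB[idx], fAB[i][idx])
                    if vy_b == 0.0:
                        s_bs[b] = np.nan
                        st_bs[b] = np.nan
                    else:
                        s_bs[b] = vi_b / vy_b
                        st_bs[b] = et_b / vy_b
                lo, hi = (1 - ci) / 2 * 100, (1 + ci) / 2 * 100
                row["S_lo"], row["S_hi"] = np.nanpercentile(s_bs, [lo, hi])
                row["ST_lo"], row["ST_hi"] = np.nanpercentile(st_bs, [lo, hi])
            rows.append(row)
        if any(r["S"] < 0 for r in rows if r["output"] == str(col)):
            warnings.warn(
                f"negative first-order index for output {col!r}: "
                "the base sample N is too small for a stable estimate",
                stacklevel=2,
            )
    return SobolIndices(table=pd.DataFrame(rows), variance=variance, N=N)


@dataclass
class SobolResult:
    plan: SobolPlan
    experiment: ExperimentResult
    indices: SobolIndices


def easy_sobol(
    model: Model,
    table: FactorTable,
    N: int = 1024,
    ticks: int = 300,
    replications: int = 1,
    objective: Objective | None = None,
    master_seed: int = 0,
    sampler: str = "random",
    n_boot: int = 0,
) -> SobolResult:
    """Complete variance-decomposition pipeline on a simulation model."""
    plan = sobol_design(table, N, sampler=sampler, rng=np.random.default_rng(master_seed))
    spec = RunSpec(ticks=ticks, replications=replications, master_seed=master_seed)
    experiment = run_experiment(model, plan.design, spec, objective)
    agg = aggregate_output(experiment, "mean").drop(columns="run")
    indices = sobol_indices(
        plan, agg, n_boot=n_boot, rng=np.random.default_rng(master_seed + 1)
    )
    return SobolResult(plan=plan, experiment=experiment, indices=indices)
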