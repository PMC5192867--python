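"""Objective-function building blocks and sampling-based calibration.

Calibration compares simulated outputs against reference values through a
cost (objective) function that is zero for a perfect fit and grows with
the discrepancy.  Two standard building blocks are provided: a
categorical criterion (inside/outside an acceptance interval) and
range-normalised root-mean-square deviation.  ``easy_calibration``
searches for the lowest-cost parameter set by pure Latin-hypercube
sampling of the factor space — no iterative optimisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .design import FactorTable, sample_latin_hypercube
from .errors import DegenerateReference, InvalidRange, ShapeError
from .experiment import (
    ExperimentResult,
    Model,
    Objective,
    RunSpec,
    aggregate_output,
    run_experiment,
)

__all__ = [
    "AcceptanceRange",
    "CalibrationResult",
    "categorical_cost",
    "nrmsd",
    "distance_cost",
    "easy_calibration",
]


@dataclass(frozen=True)
class AcceptanceRange:
    """Inclusive reference interval for an output value."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise InvalidRange("acceptance range requires lower <= upper")


def categorical_cost(y: float, range_: AcceptanceRange) -> int:
    """0 if ``y`` falls inside the (inclusive) acceptance interval, else 1."""
    return 0 if range_.lower <= y <= range_.upper else 1


def _check_pair(simulated, reference) -> tuple[np.ndarray, np.ndarray]:
    sim = np.asarray(simulated, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if sim.shape != ref.shape or sim.ndim != 1 or sim.size < 1:
        raise ShapeError("simulated and reference must be equal-length 1-D series")
    return sim, ref


def nrmsd(simulated, reference) -> float:
    """Root-mean-square deviation normalised by the reference range.

    The normaliser is ``max(reference) - min(reference)``, which stays
    meaningful when the reference crosses zero (a mean-based normaliser
    would not).
    """
    sim, ref = _check_pair(simulated, reference)
    span = ref.max() - ref.min()
    if span == 0.0:
        raise DegenerateReference("reference series is constant")
    return float(np.sqrt(np.mean((sim - ref) ** 2)) / span)


def distance_cost(simulated, reference, metric: str = "nrmsd") -> float:
    """Distance between series: zero iff equal, positive otherwise."""
    sim, ref = _check_pair(simulated, reference)
    if metric == "nrmsd":
        return nrmsd(sim, ref)
    if metric == "rmse":
        return float(np.sqrt(np.mean((sim - ref) ** 2)))
    if metric == "sse":
        return float(np.sum((sim - ref) ** 2))
    raise InvalidRange(f"unknown metric {metric!r}")


@dataclass
class CalibrationResult:
    """Parameter sets ranked by aggregated cost (ascending; ties keep
    design order).  ``best`` is the first row's parameter values."""

    experiment: ExperimentResult
    ranked: pd.DataFrame
    best: dict


def easy_calibration(
    model: Model,
    table: FactorTable,
    n_samples: int = 100,
    replications: int = 1,
    ticks: int = 300,
    objective: Objective | None = None,
    master_seed: int = 0,
) -> CalibrationResult:
    """Sample the cost surface and rank parameter sets by total cost.

    The objective must return one or more named costs (lower is better,
    zero is a perfect fit).  Costs are averaged over replications per
    design point; when the objective returns several scalars the ranking
    key is their unweighted sum, with the per-scalar values kept in the
    ranked table.
    """
    if objective is None:
        raise InvalidRange("calibration requires a cost objective")
    if n_samples < 1:
        raise InvalidRange("n_samples must be >= 1")
    design = sample_latin_hypercube(
        n_samples, table, np.random.default_rng(master_seed)
    )
    spec = RunSpec(ticks=ticks, replications=replications, master_seed=master_seed)
    experiment = run_experiment(model, design, spec, objective)
    agg = aggregate_output(experiment, "mean")
    cost_cols = list(experiment.objective_names)
    agg["total_cost"] = agg[cost_cols].sum(axis=1)
    merged = experiment.paramset.merge(agg, on="run")
    ranked = merged.sort_values("total_cost", kind="stable").reset_index(drop=True)
    ranked.insert(1, "rank", np.arange(1, len(ranked) + 1))
    best = ranked.iloc[0][list(design.factor_names)].to_dict()
    return CalibrationResult(experiment=experiment, ranked=ranked, best=best)
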