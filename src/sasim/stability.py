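"""Replication-count determination by coefficient-of-variation convergence.

Stochastic simulations must be replicated until summary outputs are
stable.  The approach here runs a handful of parameter sets (sampled by
Latin hypercube from the declared factor ranges) with a large number of
seeded replications, then tracks the coefficient of variation (CV) of
each monitored output as a function of the number of replications used.
The replication count after which the CV stops changing is the minimum
needed for robust results.

Replications are simulated once per parameter set; checkpoint CVs reuse
prefixes of that single set of runs, so the curve at n depends only on
the first n seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .design import FactorTable, build_parameter_set, sample_latin_hypercube
from .errors import InsufficientSamples, InvalidRange, UndefinedCV
from .experiment import Model, Objective, RunSpec, run_replicates

__all__ = [
    "StabilityResult",
    "coefficient_of_variation",
    "stability_curves",
    "detect_convergence",
    "easy_stability",
]


def coefficient_of_variation(samples: Sequence[float]) -> float:
    """Sample standard deviation (divisor n-1) over the absolute mean."""
    arr = np.asarray(samples, dtype=float)
    if arr.size < 2:
        raise InsufficientSamples("CV needs at least 2 samples")
    mean = arr.mean()
    if mean == 0.0:
        raise UndefinedCV("CV undefined for zero mean")
    return float(arr.std(ddof=1) / abs(mean))


def _default_checkpoints(r_max: int) -> list[int]:
    return list(range(5, r_max + 1, 5)) or [r_max]


def _per_replication_values(
    series_list, params, objective: Objective | None
) -> pd.DataFrame:
    """One row per replication, one column per monitored output.

    With no objective, each raw output column is summarised by its time
    average so a single scalar per replication remains.
    """
    rows = []
    for series in series_list:
        if objective is None:
            rows.append(
                {c: float(series[c].mean()) for c in series.columns if c != "tick"}
            )
        else:
            rows.append({str(k): float(v) for k, v in dict(objective(params, series)).items()})
    return pd.DataFrame(rows)


def stability_curves(
    model: Model,
    table: FactorTable,
    s: int,
    r_max: int,
    checkpoints: Sequence[int] | None = None,
    ticks: int = 300,
    objective: Objective | None = None,
    master_seed: int = 0,
) -> pd.DataFrame:
    """CV-versus-replications curves for ``s`` LHS-sampled parameter sets.

    Returns a tidy frame with columns ``set``, ``output``, ``n``, ``cv``.
    A CV is recorded as NaN where the prefix mean is zero.
    """
    if s < 1:
        raise InvalidRange("need at least one parameter set")
    if r_max < 2:
        raise InvalidRange("r_max must be >= 2")
    if checkpoints is None:
        checkpoints = _default_checkpoints(r_max)
    checkpoints = sorted(int(c) for c in checkpoints)
    if checkpoints[0] < 2 or checkpoints[-1] > r_max:
        raise InvalidRange("checkpoints must lie in [2, r_max]")

    design = sample_latin_hypercube(s, table, np.random.default_rng(master_seed))
    paramsets = build_parameter_set(design, model.declared_parameters())
    spec = RunSpec(ticks=ticks, replications=r_max, master_seed=master_seed)

    records = []
    for set_id, params in enumerate(paramsets, start=1):
        series_list = run_replicates(model, params, spec)
        values = _per_replication_values(series_list, params, objective)
        for output in values.columns:
            col = values[output].to_numpy()
            for n in checkpoints:
                prefix = col[:n]
                mean = prefix.mean()
                cv = np.nan if mean == 0.0 else prefix.std(ddof=1) / abs(mean)
                records.append(
                    {"set": set_id, "output": output, "n": n, "cv": cv}
                )
    return pd.DataFrame(records)


def detect_convergence(
    curve: pd.DataFrame, tol: float = 0.01, window: int = 2
) -> pd.DataFrame:
    """Flag, per (set, output), the checkpoint where the CV settles.

    The CV is considered settled at the first checkpoint ``n*`` such that
    the ``window`` consecutive curve transitions ending at ``n*`` and
    later all change the CV by at most ``tol`` (absolute).  Returns a
    frame with columns ``set``, ``output``, ``converged``, ``n_star``
    (NaN when no checkpoint qualifies).
    """
    if window < 1:
        raise InvalidRange("window must be >= 1")
    reports = []
    for (set_id, output), grp in curve.groupby(["set", "output"], sort=True):
        grp = grp.sort_values("n")
        ns = grp["n"].to_numpy()
        cvs = grp["cv"].to_numpy(dtype=float)
        diffs = np.abs(np.diff(cvs))  # diffs[i] ends at checkpoint ns[i + 1]
        n_star = np.nan
        converged = False
        if len(diffs) >= window and not np.isnan(cvs).any():
            ok = diffs <= tol
            for start in range(len(diffs) - window + 1):
                if ok[start : start + window].all():
                    n_star = float(ns[start + 1])
                    converged = True
                    break
        reports.append(
            {"set": set_id, "output": output, "converged": converged, "n_star": n_star}
        )
    return pd.DataFrame(reports)


@dataclass
class StabilityResult:
    paramsets: pd.DataFrame
    curve: pd.DataFrame
    report: pd.DataFrame


def easy_stability(
    model: Model,
    table: FactorTable,
    s: int = 1,
    r_max: int = 100,
    ticks: int = 300,
    objective: Objective | None = None,
    master_seed: int = 0,
    checkpoints: Sequence[int] | None = None,
    tol: float = 0.01,
    window: int = 2,
) -> StabilityResult:
    """Sample parameter sets, replicate, and report CV convergence."""
    design = sample_latin_hypercube(s, table, np.random.default_rng(master_seed))
    paramset = design.to_frame()
    paramset.insert(0, "set", np.arange(1, len(paramset) + 1))
    curve = stability_curves(
        model,
        table,
        s=s,
        r_max=r_max,
        checkpoints=checkpoints,
        ticks=ticks,
        objective=objective,
        master_seed=master_seed,
    )
    report = detect_convergence(curve, tol=tol, window=window)
    return StabilityResult(paramsets=paramset, curve=curve, report=report)
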