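"""Model contract, seeded replication and the experiment engine.

A *model* is anything implementing :class:`Model`: it declares its
parameters with defaults, and ``setup(params, seed)`` returns a run
handle whose ``run(ticks)`` method produces an *observation series* — a
:class:`pandas.DataFrame` with an integer ``tick`` column starting at 1
and one or more named numeric output columns.  Two runs with identical
``(params, seed, ticks)`` must produce identical series; all model
randomness must come from the seeded generator created at setup.

``run_experiment`` executes a design (one parameter set per row, each
replicated with its own seed), evaluates a user objective per replication
and returns the triple of tables (``paramset`` / ``output`` /
``dataset``) that all analysis methods consume.
"""

from __future__ import annotations

import abc
import hashlib
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import DesignMatrix, build_parameter_set
from .errors import (
    InvalidRange,
    ModelExecutionError,
    ObjectiveContractError,
    ShapeError,
)

__all__ = [
    "Model",
    "ModelRun",
    "RunSpec",
    "ExperimentResult",
    "Objective",
    "mean_outputs_objective",
    "derive_seeds",
    "run_replicates",
    "run_experiment",
    "aggregate_output",
    "save_experiment",
    "validate_series",
]

#: An objective maps (parameter set, observation series) to one or more
#: named scalars.  It must return the same names on every call.
Objective = Callable[[Mapping[str, Any], pd.DataFrame], Mapping[str, float]]


class ModelRun(abc.ABC):
    """A configured, seeded model instance ready to be run once."""

    @abc.abstractmethod
    def run(self, ticks: int) -> pd.DataFrame:
        """Simulate ``ticks`` steps and return the observation series."""


class Model(abc.ABC):
    """Contract every simulator and analytic fixture implements."""

    #: registry name; set by subclasses
    name: str = ""

    @abc.abstractmethod
    def declared_parameters(self) -> dict[str, Any]:
        """Full mapping of parameter name to default value (a fresh copy)."""

    @abc.abstractmethod
    def setup(self, params: Mapping[str, Any], seed: int) -> ModelRun:
        """Validate ``params`` and return a seeded run handle."""


def validate_series(df: pd.DataFrame) -> pd.DataFrame:
    """Check the observation-series contract (tick column, equal lengths)."""
    if "tick" not in df.columns:
        raise ShapeError("observation series must have a 'tick' column")
    ticks = df["tick"].to_numpy()
    if len(ticks) == 0:
        raise ShapeError("observation series must have at least one row")
    if np.any(np.diff(ticks) <= 0):
        raise ShapeError("tick values must be strictly increasing")
    return df


def derive_seeds(master_seed: int, replications: int) -> list[int]:
    """Derive ``replications`` distinct per-replication seeds.

    ``seed_i`` is the low 63 bits of a counter-keyed BLAKE2b hash of
    ``(master_seed, i)``; the derivation is stable across platforms and
    releases.  Collisions (astronomically unlikely) are resolved by
    bumping the counter.
    """
    if replications < 1:
        raise InvalidRange("replications must be >= 1")
    seeds: list[int] = []
    seen: set[int] = set()
    for i in range(replications):
        counter = 0
        while True:
            digest = hashlib.blake2b(
                f"{master_seed}:{i}:{counter}".encode(), digest_size=8
            ).digest()
            s = int.from_bytes(digest, "big") & ((1 << 63) - 1)
            if s not in seen:
                break
            counter += 1
        seen.add(s)
        seeds.append(s)
    return seeds


@dataclass(frozen=True)
class RunSpec:
    """How to replicate a single design point.

    Parameters
    ----------
    ticks : int
        Simulated steps per run (default 300).
    replications : int
        Independent seeded repetitions per parameter set.
    master_seed : int
        Root of the seed derivation when ``seeds`` is not given.
    seeds : sequence of int, optional
        Explicit per-replication seeds; must have exactly ``replications``
        distinct entries.
    """

    ticks: int = 300
    replications: int = 1
    master_seed: int = 0
    seeds: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.ticks < 1:
            raise InvalidRange("ticks must be >= 1")
        if self.replications < 1:
            raise InvalidRange("replications must be >= 1")
        if self.seeds is not None:
            object.__setattr__(self, "seeds", tuple(int(s) for s in self.seeds))
            if len(self.seeds) != self.replications:
                raise InvalidRange("seeds must have one entry per replication")
            if len(set(self.seeds)) != len(self.seeds):
                raise InvalidRange("explicit seeds must be distinct")

    def resolve_seeds(self) -> list[int]:
        if self.seeds is not None:
            return list(self.seeds)
        return derive_seeds(self.master_seed, self.replications)


@dataclass
class ExperimentResult:
    """The paramset / output / dataset result triple.

    ``paramset``: one row per design point (run id + swept parameters, as
    actually passed to the model, i.e. after integer rounding).
    ``output``: one row per design point x replication with the objective
    scalars.  ``dataset``: all observation series concatenated, tagged
    with run and replication ids.
    """

    paramset: pd.DataFrame
    output: pd.DataFrame
    dataset: pd.DataFrame
    objective_names: tuple[str, ...] = field(default_factory=tuple)


def mean_outputs_objective(
    params: Mapping[str, Any], series: pd.DataFrame
) -> dict[str, float]:
    """Default objective: time-average of every output column."""
    return {
        c: float(series[c].mean()) for c in series.columns if c != "tick"
    }


def run_replicates(
    model: Model, params: Mapping[str, Any], spec: RunSpec
) -> list[pd.DataFrame]:
    """Run ``spec.replications`` seeded repetitions of one parameter set."""
    seeds = spec.resolve_seeds()
    series = []
    for i, seed in enumerate(seeds):
        try:
            handle = model.setup(params, seed)
            df = handle.run(spec.ticks)
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise ModelExecutionError(
                f"model {model.name!r} failed (replication {i}, seed {seed}): {exc}"
            ) from exc
        series.append(validate_series(df))
    return series


def _objective_row(
    objective: Objective,
    params: Mapping[str, Any],
    series: pd.DataFrame,
    expected: tuple[str, ...] | None,
) -> tuple[dict[str, float], tuple[str, ...]]:
    raw = objective(params, series)
    try:
        row = {str(k): float(v) for k, v in dict(raw).items()}
    except (TypeError, ValueError) as exc:
        raise ObjectiveContractError(
            f"objective must return a mapping of named scalars, got {raw!r}"
        ) from exc
    if not row:
        raise ObjectiveContractError("objective returned no scalars")
    names = tuple(row)
    if expected is not None and names != expected:
        raise ObjectiveContractError(
            f"objective names changed between calls: {expected} -> {names}"
        )
    return row, names


def run_experiment(
    model: Model,
    design: DesignMatrix,
    spec: RunSpec,
    objective: Objective | None = None,
) -> ExperimentResult:
    """Execute a full design: every row replicated, objective per run.

    Execution order is deterministic: design-major, replication-minor.
    The same per-replication seeds are reused for every design point
    (common random numbers across the sweep).
    """
    if objective is None:
        objective = mean_outputs_objective
    defaults = model.declared_parameters()
    paramsets = build_parameter_set(design, defaults)
    seeds = spec.resolve_seeds()

    paramset_rows = []
    output_rows = []
    dataset_parts = []
    expected: tuple[str, ...] | None = None
    for run_id, params in enumerate(paramsets, start=1):
        paramset_rows.append(
            {"run": run_id, **{nm: params[nm] for nm in design.factor_names}}
        )
        for rep, seed in enumerate(seeds, start=1):
            try:
                handle = model.setup(params, seed)
                series = validate_series(handle.run(spec.ticks))
            except (ObjectiveContractError, ShapeError):
                raise
            except Exception as exc:  # noqa: BLE001
                raise ModelExecutionError(
                    f"model {model.name!r} failed at design point {run_id}, "
                    f"replication {rep} (seed {seed}): {exc}"
                ) from exc
            row, expected = _objective_row(objective, params, series, expected)
            output_rows.append(
                {"run": run_id, "replication": rep, "seed": seed, **row}
            )
            tagged = series.copy()
            tagged.insert(0, "replication", rep)
            tagged.insert(0, "run", run_id)
            dataset_parts.append(tagged)

    return ExperimentResult(
        paramset=pd.DataFrame(paramset_rows),
        output=pd.DataFrame(output_rows),
        dataset=pd.concat(dataset_parts, ignore_index=True),
        objective_names=expected or (),
    )


def aggregate_output(
    result: ExperimentResult, statistic: str = "mean"
) -> pd.DataFrame:
    """Per-design-point summary of the objective scalars.

    Returns one row per run id with each objective scalar replaced by its
    mean or median over replications.
    """
    if statistic not in ("mean", "median"):
        raise InvalidRange("statistic must be 'mean' or 'median'")
    cols = list(result.objective_names)
    grouped = result.output.groupby("run", sort=True)[cols]
    agg = grouped.mean() if statistic == "mean" else grouped.median()
    return agg.reset_index()


def save_experiment(result: ExperimentResult, prefix: str) -> list[str]:
    """Write the result triple as ``{prefix}_{paramset,output,dataset}.csv``."""
    paths = []
    for part in ("paramset", "output", "dataset"):
        path = f"{prefix}_{part}.csv"
        getattr(result, part).to_csv(path, index=False)
        paths.append(path)
    return paths
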