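"""Factor declaration and experimental designs.

A *factor* is a model input parameter varied over a numeric range.  An
ordered collection of factors (:class:`FactorTable`) spans the sweep space;
the sampling functions in this module generate :class:`DesignMatrix`
objects whose rows live both on the physical scale of the parameters and
on the unit hypercube ``[0, 1]^k`` used by the sensitivity methods.

Only uniform marginals are supported: each factor is swept uniformly over
its ``[lower, upper]`` interval (bounds inclusive).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateFactor,
    EmptyFactorTable,
    InvalidLevels,
    InvalidRange,
    ShapeError,
    UnknownParameter,
)

__all__ = [
    "FactorSpec",
    "FactorTable",
    "DesignMatrix",
    "add_factor",
    "sample_random",
    "sample_latin_hypercube",
    "design_full_factorial",
    "build_parameter_set",
]


@dataclass(frozen=True)
class FactorSpec:
    """A named factor with an inclusive numeric range in physical units."""

    name: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.name or not isinstance(self.name, str):
            raise InvalidRange("factor name must be a non-empty string")
        if not (float(self.lower) < float(self.upper)):
            raise InvalidRange(
                f"factor {self.name!r}: lower ({self.lower}) must be strictly "
                f"below upper ({self.upper})"
            )

    @property
    def width(self) -> float:
        return float(self.upper) - float(self.lower)


@dataclass(frozen=True)
class FactorTable:
    """Ordered, immutable collection of factors.

    Order is preserved and defines the column order of every design
    generated from the table.  Adding a factor returns a new table; the
    original is never modified.
    """

    factors: tuple[FactorSpec, ...] = field(default_factory=tuple)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def lowers(self) -> np.ndarray:
        return np.array([f.lower for f in self.factors], dtype=float)

    @property
    def uppers(self) -> np.ndarray:
        return np.array([f.upper for f in self.factors], dtype=float)

    def add(self, name: str, lower: float, upper: float) -> "FactorTable":
        if name in self.names:
            raise DuplicateFactor(f"factor {name!r} already declared")
        return FactorTable(self.factors + (FactorSpec(name, lower, upper),))

    def __len__(self) -> int:
        return len(self.factors)

    def __iter__(self):
        return iter(self.factors)


def add_factor(
    table: FactorTable | None, name: str, lower: float, upper: float
) -> FactorTable:
    """Append a factor to ``table`` (or start a new table if ``None``).

    Raises
    ------
    DuplicateFactor
        If ``name`` is already present.
    InvalidRange
        If ``lower >= upper``.
    """
    if table is None:
        table = FactorTable()
    return table.add(name, lower, upper)


@dataclass(frozen=True)
class DesignMatrix:
    """Rows of factor values plus their unit-cube preimage.

    ``rows = lower + unit_rows * (upper - lower)`` holds elementwise and
    exactly: the physical rows are always derived from ``unit_rows`` by
    this affine map, never sampled separately.
    """

    factor_names: tuple[str, ...]
    rows: np.ndarray
    unit_rows: np.ndarray

    def __post_init__(self) -> None:
        if self.rows.shape != self.unit_rows.shape:
            raise ShapeError("rows and unit_rows must have identical shape")
        if self.rows.ndim != 2 or self.rows.shape[1] != len(self.factor_names):
            raise ShapeError("design must be n x k with k = number of factors")

    @classmethod
    def from_unit(cls, table: FactorTable, unit_rows: np.ndarray) -> "DesignMatrix":
        unit_rows = np.asarray(unit_rows, dtype=float)
        if unit_rows.ndim != 2:
            raise ShapeError("unit_rows must be 2-dimensional")
        rows = table.lowers + unit_rows * (table.uppers - table.lowers)
        return cls(table.names, rows, unit_rows)

    @property
    def n(self) -> int:
        return self.rows.shape[0]

    @property
    def k(self) -> int:
        return self.rows.shape[1]

    def to_frame(self, unit: bool = False) -> pd.DataFrame:
        data = self.unit_rows if unit else self.rows
        return pd.DataFrame(data, columns=list(self.factor_names))


def _check_table(table: FactorTable) -> None:
    if table is None or table.k == 0:
        raise EmptyFactorTable("design requested over an empty factor table")


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def sample_random(
    n: int, table: FactorTable, rng: np.random.Generator | int | None = None
) -> DesignMatrix:
    """Monte-Carlo design: ``n`` i.i.d. uniform points on the unit cube."""
    _check_table(table)
    if n < 1:
        raise InvalidRange("sample size must be >= 1")
    unit = _as_rng(rng).random((n, table.k))
    return DesignMatrix.from_unit(table, unit)


def sample_latin_hypercube(
    n: int, table: FactorTable, rng: np.random.Generator | int | None = None
) -> DesignMatrix:
    """Latin hypercube design with ``n`` strata per factor.

    For each factor the ``n`` unit-interval values occupy the ``n`` equal
    strata ``[j/n, (j+1)/n)`` exactly once; the value is placed uniformly
    within its stratum and the strata-to-row assignment is an independent
    random permutation per factor.
    """
    _check_table(table)
    if n < 1:
        raise InvalidRange("sample size must be >= 1")
    gen = _as_rng(rng)
    unit = np.empty((n, table.k), dtype=float)
    for j in range(table.k):
        strata = gen.permutation(n)
        jitter = gen.random(n)
        unit[:, j] = (strata + jitter) / n
    return DesignMatrix.from_unit(table, unit)


def design_full_factorial(
    levels: int | Sequence[int], table: FactorTable
) -> DesignMatrix:
    """Full factorial grid; per-factor levels are evenly spaced and
    include both range endpoints.  Row count = product of level counts."""
    _check_table(table)
    if isinstance(levels, (int, np.integer)):
        per_factor = [int(levels)] * table.k
    else:
        per_factor = [int(v) for v in levels]
        if len(per_factor) != table.k:
            raise ShapeError("one level count required per factor")
    for lv in per_factor:
        if lv < 2:
            raise InvalidLevels(f"each factor needs >= 2 levels, got {lv}")
    grids = [np.linspace(0.0, 1.0, lv) for lv in per_factor]
    unit = np.array(list(itertools.product(*grids)), dtype=float)
    return DesignMatrix.from_unit(table, unit)


def _coerce(value: float, default: Any) -> Any:
    # Integer-valued parameters are swept on the continuous cube and
    # rounded half-up when the concrete parameter set is materialised.
    if isinstance(default, bool):
        return bool(round(value))
    if isinstance(default, (int, np.integer)):
        return int(np.floor(float(value) + 0.5))
    return float(value)


def build_parameter_set(
    design: DesignMatrix, defaults: Mapping[str, Any]
) -> list[dict[str, Any]]:
    """Merge a design with model defaults into full parameter sets.

    Returns one mapping per design row: swept names take the row value
    (cast to the default's type, integers rounded half-up), every other
    declared parameter keeps its default.

    Raises
    ------
    UnknownParameter
        If a design factor is not among ``defaults``.
    """
    unknown = [nm for nm in design.factor_names if nm not in defaults]
    if unknown:
        raise UnknownParameter(
            f"factors {unknown} are not declared model parameters "
            f"(declared: {sorted(defaults)})"
        )
    out: list[dict[str, Any]] = []
    for row in design.rows:
        ps = dict(defaults)
        for name, value in zip(design.factor_names, row):
            ps[name] = _coerce(value, defaults[name])
        out.append(ps)
    return out
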