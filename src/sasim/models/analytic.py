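"""Analytic models with known sensitivity structure.

These deterministic functions satisfy the model contract (one-tick
observation series with a single column ``y``) so the whole experiment
pipeline can be exercised end to end, and they come with closed-form
variance decompositions that serve as estimator oracles.
"""

from __future__ import annotations

import math
from typing import Any, Callable, Mapping

import numpy as np
import pandas as pd

from ..errors import ParameterError
from ..experiment import Model, ModelRun

__all__ = [
    "AnalyticModel",
    "linear_model",
    "constant_model",
    "product_model",
    "ishigami_model",
    "ishigami_analytic_indices",
]


class _AnalyticRun(ModelRun):
    def __init__(self, value: float):
        self._value = value

    def run(self, ticks: int) -> pd.DataFrame:
        # Deterministic point evaluation: a single-tick series regardless
        # of the requested duration.
        return pd.DataFrame({"tick": [1], "y": [self._value]})


class AnalyticModel(Model):
    """Deterministic function of k inputs exposed as a model.

    ``func`` must be vectorised: it receives an ``(n, k)`` array of
    physical-scale points and returns ``n`` values.  ``bounds`` give the
    natural domain of each input (used as default factor ranges).
    """

    def __init__(
        self,
        name: str,
        k: int,
        func: Callable[[np.ndarray], np.ndarray],
        bounds: tuple[float, float] = (0.0, 1.0),
    ):
        self.name = name
        self.k = k
        self.func = func
        self.bounds = bounds

    def declared_parameters(self) -> dict[str, Any]:
        mid = 0.5 * (self.bounds[0] + self.bounds[1])
        return {f"x{i + 1}": float(mid) for i in range(self.k)}

    def evaluate_matrix(self, points: np.ndarray) -> np.ndarray:
        """Vectorised evaluation over an ``(n, k)`` array of points."""
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != self.k:
            raise ParameterError(f"{self.name}: expected an (n, {self.k}) array")
        return np.asarray(self.func(pts), dtype=float)

    def setup(self, params: Mapping[str, Any], seed: int) -> ModelRun:
        try:
            x = np.array(
                [[float(params[f"x{i + 1}"]) for i in range(self.k)]], dtype=float
            )
        except KeyError as exc:
            raise ParameterError(f"{self.name}: missing input {exc}") from exc
        return _AnalyticRun(float(self.evaluate_matrix(x)[0]))


def linear_model(coeffs=(3.0, 5.0)) -> AnalyticModel:
    """f(x) = sum_i c_i x_i on the unit cube."""
    c = np.asarray(coeffs, dtype=float)
    if c.size < 1:
        raise ParameterError("need at least one coefficient")
    return AnalyticModel("fx_linear", len(c), lambda x: x @ c, bounds=(0.0, 1.0))


def constant_model(value: float = 7.0) -> AnalyticModel:
    """f(x) = constant; useful for degenerate-variance handling tests."""
    return AnalyticModel(
        "fx_constant", 1, lambda x: np.full(x.shape[0], float(value)), bounds=(0.0, 1.0)
    )


def product_model() -> AnalyticModel:
    """f(x) = x1 * x2 on the unit square — a purely interacting pair."""
    return AnalyticModel("fx_product", 2, lambda x: x[:, 0] * x[:, 1], bounds=(0.0, 1.0))


def ishigami_model(a: float = 7.0, b: float = 0.1) -> AnalyticModel:
    """Ishigami benchmark on [-pi, pi]^3.

    f(x) = sin x1 + a sin^2 x2 + b x3^4 sin x1.  Strongly nonlinear and
    nonmonotonic, with an x1-x3 interaction and a third input whose
    first-order index is exactly zero.
    """

    def f(x: np.ndarray) -> np.ndarray:
        return (
            np.sin(x[:, 0])
            + a * np.sin(x[:, 1]) ** 2
            + b * x[:, 2] ** 4 * np.sin(x[:, 0])
        )

    return AnalyticModel("fx_ishigami", 3, f, bounds=(-math.pi, math.pi))


def ishigami_analytic_indices(a: float = 7.0, b: float = 0.1) -> dict[str, float]:
    """Closed-form variance decomposition of the Ishigami function.

    With inputs independent uniform on [-pi, pi]:
    V(Y) = a^2/8 + b pi^4/5 + b^2 pi^8/18 + 1/2,
    V1 = (1 + b pi^4/5)^2 / 2, V2 = a^2/8, V3 = 0,
    V13 = b^2 pi^8 (1/18 - 1/50).
    """
    pi = math.pi
    vy = a**2 / 8 + b * pi**4 / 5 + b**2 * pi**8 / 18 + 0.5
    v1 = (1 + b * pi**4 / 5) ** 2 / 2
    v2 = a**2 / 8
    v13 = b**2 * pi**8 * (1 / 18 - 1 / 50)
    return {
        "VY": vy,
        "S1": v1 / vy,
        "S2": v2 / vy,
        "S3": 0.0,
        "ST1": (v1 + v13) / vy,
        "ST2": v2 / vy,
        "ST3": v13 / vy,
    }
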