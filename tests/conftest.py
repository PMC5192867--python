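"""Shared fixtures: tiny models exercising the engine contracts."""

from __future__ import annotations

from typing import Any, Mapping

import numpy as np
import pandas as pd
import pytest

from sasim.experiment import Model, ModelRun


class _SeriesRun(ModelRun):
    def __init__(self, frame_builder):
        self._build = frame_builder

    def run(self, ticks: int) -> pd.DataFrame:
        return self._build(ticks)


class LinearTickModel(Model):
    """Deterministic y = 2a at every tick; exercises engine bookkeeping."""

    name = "linear_tick"

    def declared_parameters(self) -> dict[str, Any]:
        return {"a": 1.0, "b": 2.0}

    def setup(self, params: Mapping[str, Any], seed: int) -> ModelRun:
        value = 2.0 * float(params["a"])

        def build(ticks: int) -> pd.DataFrame:
            return pd.DataFrame(
                {"tick": np.arange(1, ticks + 1), "y": np.full(ticks, value)}
            )

        return _SeriesRun(build)


class ConstantModel(Model):
    """Constant output 7.0 regardless of parameters or seed."""

    name = "constant7"

    def declared_parameters(self) -> dict[str, Any]:
        return {"a": 0.0}

    def setup(self, params: Mapping[str, Any], seed: int) -> ModelRun:
        def build(ticks: int) -> pd.DataFrame:
            return pd.DataFrame(
                {"tick": np.arange(1, ticks + 1), "y": np.full(ticks, 7.0)}
            )

        return _SeriesRun(build)


class GaussianOutputModel(Model):
    """Stochastic fixture: one normal deviate per run, constant over ticks.

    The per-replication summary of output ``y`` is then exactly
    N(mean, sd^2), so the replication CV has the known value sd/mean.
    """

    name = "synthetic_gaussian"

    def declared_parameters(self) -> dict[str, Any]:
        return {"mean": 10.0, "sd": 2.0}

    def setup(self, params: Mapping[str, Any], seed: int) -> ModelRun:
        rng = np.random.default_rng(seed)
        value = float(params["mean"]) + float(params["sd"]) * rng.standard_normal()

        def build(ticks: int) -> pd.DataFrame:
            return pd.DataFrame(
                {"tick": np.arange(1, ticks + 1), "y": np.full(ticks, value)}
            )

        return _SeriesRun(build)


@pytest.fixture
def linear_tick_model() -> LinearTickModel:
    return LinearTickModel()


@pytest.fixture
def constant_model() -> ConstantModel:
    return ConstantModel()


@pytest.fixture
def gaussian_model() -> GaussianOutputModel:
    return GaussianOutputModel()
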