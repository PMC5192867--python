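"""Wolf-sheep-grass predation model on a 50 x 50 periodic plane.

Wolves and sheep move in continuous space; grass lives on the unit-cell
grid.  Each animal carries an energy reserve: moving costs one unit per
tick, grazing (sheep) or predation (wolves) replenishes it, and an agent
dies when its energy reaches zero.  Reproduction is probabilistic and
halves the parent's energy, handing the other half to the offspring.
An eaten grass patch regrows after ``grassregrowthtime`` ticks.

Per tick, agents act in a freshly shuffled order; each agent runs the
sequence move -> eat -> reproduce -> die, and patch regrowth is applied
after all agents.  A wolf preys on one sheep (uniformly chosen) sharing
its current unit cell.  Outputs per tick: ``wolves``, ``sheep``,
``grass`` (counts after the tick).

A fixed-step Lotka-Volterra integrator (`lv_reference`) is included as
the aggregated ODE counterpart of the individual-based model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np
import pandas as pd

from ..errors import ParameterError
from ..experiment import Model, ModelRun

__all__ = ["PredatorPreyModel", "pp_model", "LVParams", "lv_reference"]

_SIZE = 50
_NCELLS = _SIZE * _SIZE
_TWO_PI = 2.0 * math.pi

def _remove_by_identity(lst: list, rec: list) -> None:
    # records are mutable lists; two animals can compare equal by value,
    # so membership must be resolved by identity (swap-pop, O(cell size))
    for i, other in enumerate(lst):
        if other is rec:
            lst[i] = lst[-1]
            lst.pop()
            return
    raise AssertionError("agent missing from its cell list")


_DEFAULTS: dict[str, Any] = {
    "initialnumberofwolves": 50,
    "initialnumberofsheep": 100,
    "wolfgainfromfood": 20.0,
    "wolfreproduce": 5.0,
    "sheepgainfromfood": 4.0,
    "sheepreproduce": 4.0,
    "grassregrowthtime": 30,
}


def _validate(params: Mapping[str, Any]) -> dict[str, Any]:
    p = {}
    for name, default in _DEFAULTS.items():
        value = params.get(name, default)
        num = float(value)
        if num < 0:
            raise ParameterError(f"{name} must be >= 0, got {value}")
        if name in ("wolfreproduce", "sheepreproduce") and num > 100:
            raise ParameterError(f"{name} is a percentage per tick, got {value}")
        if isinstance(default, int):
            num = int(round(num))
        p[name] = num
    return p


class _PPRun(ModelRun):
    """One seeded realisation.  State is kept in plain lists for speed:
    wolf record = [x, y, energy]; sheep record = [x, y, energy, cell,
    alive]."""

    def __init__(self, params: Mapping[str, Any], seed: int):
        p = _validate(params)
        self.params = p
        self._rng = np.random.default_rng(seed)
        rng = self._rng

        def spawn(n: int, gain: float, is_sheep: bool) -> list[list]:
            pos = rng.random((n, 2)) * _SIZE
            energy = rng.random(n) * 2.0 * gain
            if is_sheep:
                return [
                    [x, y, e, int(x) + _SIZE * int(y), True]
                    for x, y, e in zip(pos[:, 0], pos[:, 1], energy)
                ]
            return [[x, y, e] for x, y, e in zip(pos[:, 0], pos[:, 1], energy)]

        self.wolves = spawn(p["initialnumberofwolves"], p["wolfgainfromfood"], False)
        self.sheep = spawn(p["initialnumberofsheep"], p["sheepgainfromfood"], True)
        self._cells: dict[int, list] = {}
        for rec in self.sheep:
            self._cells.setdefault(rec[3], []).append(rec)

        # Half the patches start grown; the rest are part-way through
        # regrowth with a uniformly drawn countdown.
        T = p["grassregrowthtime"]
        grown_mask = rng.random(_NCELLS) < 0.5
        self._grown = bytearray(int(g) for g in grown_mask)
        self.grass_count = int(grown_mask.sum())
        self._regrow: dict[int, list[int]] = {}
        if T >= 1:
            countdown = rng.integers(1, T + 1, size=_NCELLS)
            for idx in np.flatnonzero(~grown_mask):
                self._regrow.setdefault(int(countdown[idx]), []).append(int(idx))
        else:
            for idx in np.flatnonzero(~grown_mask):
                self._grown[int(idx)] = 1
            self.grass_count = _NCELLS
        self._t = 0

    def step(self) -> tuple[int, int, int]:
        """Advance one tick; returns (wolves, sheep, grass) counts."""
        self._t += 1
        t = self._t
        rng = self._rng
        p = self.params
        wolves, sheep, cells = self.wolves, self.sheep, self._cells
        grown, regrow = self._grown, self._regrow
        wolf_gain = p["wolfgainfromfood"]
        sheep_gain = p["sheepgainfromfood"]
        w_rate = p["wolfreproduce"] / 100.0
        s_rate = p["sheepreproduce"] / 100.0
        T = p["grassregrowthtime"]
        regrow_tick = t + T - 1 if T >= 1 else t
        cos, sin = math.cos, math.sin

        combined = wolves + sheep
        n_wolves = len(wolves)
        n = len(combined)
        new_wolves: list[list] = []
        new_sheep: list[list] = []
        if n:
            order = rng.permutation(n)
            headings = rng.random(n) * _TWO_PI
            repro = rng.random(n)
            for i in order:
                rec = combined[i]
                if i < n_wolves:
                    h = headings[i]
                    x = (rec[0] + cos(h)) % _SIZE
                    y = (rec[1] + sin(h)) % _SIZE
                    e = rec[2] - 1.0
                    cell = int(x) + _SIZE * int(y)
                    prey = cells.get(cell)
                    if prey:
                        j = rng.integers(len(prey)) if len(prey) > 1 else 0
                        victim = prey[j]
                        victim[4] = False
                        prey[j] = prey[-1]
                        prey.pop()
                        e += wolf_gain
                    if repro[i] < w_rate:
                        e *= 0.5
                        new_wolves.append([x, y, e])
                    rec[0], rec[1], rec[2] = x, y, e
                else:
                    if not rec[4]:
                        continue  # eaten earlier this tick
                    h = headings[i]
                    x = (rec[0] + cos(h)) % _SIZE
                    y = (rec[1] + sin(h)) % _SIZE
                    e = rec[2] - 1.0
                    cell = int(x) + _SIZE * int(y)
                    old = rec[3]
                    if cell != old:
                        _remove_by_identity(cells[old], rec)
                        cells.setdefault(cell, []).append(rec)
                        rec[3] = cell
                    if grown[cell]:
                        grown[cell] = 0
                        self.grass_count -= 1
                        regrow.setdefault(regrow_tick, []).append(cell)
                        e += sheep_gain
                    if repro[i] < s_rate:
                        e *= 0.5
                        child = [x, y, e, cell, True]
                        new_sheep.append(child)
                        cells.setdefault(cell, []).append(child)
                    if e <= 0.0:
                        rec[4] = False
                        _remove_by_identity(cells[cell], rec)
                    rec[0], rec[1], rec[2] = x, y, e

        self.wolves = [w for w in wolves if w[2] > 0.0] + new_wolves
        self.sheep = [s for s in sheep if s[4] and s[2] > 0.0] + new_sheep

        for idx in regrow.pop(t, ()):  # patch regrowth after all agents
            if not grown[idx]:
                grown[idx] = 1
                self.grass_count += 1
        return len(self.wolves), len(self.sheep), self.grass_count

    def run(self, ticks: int) -> pd.DataFrame:
        rows = np.empty((ticks, 3), dtype=np.int64)
        for i in range(ticks):
            rows[i] = self.step()
        return pd.DataFrame(
            {
                "tick": np.arange(1, ticks + 1),
                "wolves": rows[:, 0],
                "sheep": rows[:, 1],
                "grass": rows[:, 2],
            }
        )


class PredatorPreyModel(Model):
    name = "predator_prey"

    def declared_parameters(self) -> dict[str, Any]:
        return dict(_DEFAULTS)

    def setup(self, params: Mapping[str, Any], seed: int) -> _PPRun:
        return _PPRun(params, seed)


def pp_model() -> PredatorPreyModel:
    return PredatorPreyModel()


@dataclass(frozen=True)
class LVParams:
    """Rate constants and initial state of the Lotka-Volterra system
    dx/dt = c1 x - c3 x y, dy/dt = c2 y + c4 x y (prey x, predator y;
    c2 is negative for a decaying predator)."""

    c1: float
    c2: float
    c3: float
    c4: float
    x0: float
    y0: float


def lv_reference(params: LVParams, t_end: float, dt: float) -> pd.DataFrame:
    """Classic 4th-order Runge-Kutta integration with a fixed step."""
    if dt <= 0:
        raise ParameterError("dt must be positive")
    c1, c2, c3, c4 = params.c1, params.c2, params.c3, params.c4

    def deriv(x: float, y: float) -> tuple[float, float]:
        return c1 * x - c3 * x * y, c2 * y + c4 * x * y

    steps = int(round(t_end / dt))
    ts = np.empty(steps + 1)
    xs = np.empty(steps + 1)
    ys = np.empty(steps + 1)
    x, y = params.x0, params.y0
    ts[0], xs[0], ys[0] = 0.0, x, y
    for i in range(1, steps + 1):
        k1x, k1y = deriv(x, y)
        k2x, k2y = deriv(x + 0.5 * dt * k1x, y + 0.5 * dt * k1y)
        k3x, k3y = deriv(x + 0.5 * dt * k2x, y + 0.5 * dt * k2y)
        k4x, k4y = deriv(x + dt * k3x, y + dt * k3y)
        x += dt * (k1x + 2 * k2x + 2 * k3x + k4x) / 6.0
        y += dt * (k1y + 2 * k2y + 2 * k3y + k4y) / 6.0
        ts[i], xs[i], ys[i] = i * dt, x, y
    return pd.DataFrame({"t": ts, "x": xs, "y": ys})
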