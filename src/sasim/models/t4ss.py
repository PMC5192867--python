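"""Two plasmids sharing one conjugation apparatus in a growing colony.

Bacterial cells live on a 100 x 100 um periodic surface with a lattice
nutrient layer.  Plasmid P1 is fully conjugative (it encodes the type IV
secretion system, T4SS); plasmid P2 is a *cheater* that lost those genes
and can only be transferred horizontally by hijacking the machinery of a
co-resident P1.  Each plasmid imposes a fractional growth cost, so the
model probes how large a cost advantage the cheater needs to dominate.

Cell cycle per tick (1 simulated minute), cells acting in shuffled order:

* uptake: remove up to ``uptake`` nutrient particles from the cell's
  lattice site; the obtained fraction phi scales growth this tick;
* growth: mass grows exponentially, ``mass *= exp(phi ln2 / G_eff)``
  with ``G_eff = doublingTime * (1 + p1*p1Cost + p2*p2Cost)`` — carrying
  plasmids lengthens the effective doubling time;
* division: at ``mass >= division_mass`` the cell splits into two cells
  of half mass; both inherit the plasmid state, redraw their division
  mass from a truncated normal deviate, and reset their conjugation
  state; the daughter is displaced 0.5 um in a random heading;
* conjugation: a cell carrying P1 becomes eligible once its mass reaches
  70% of its division mass.  At first eligibility in a cycle it draws a
  single Bernoulli with success probability ``p1P`` ("conjugates at
  least once this cycle").  While the attempt is pending, each tick it
  picks one random cell within 1.5 um; if that cell lacks the chosen
  plasmid the plasmid is copied over (donor keeps its copy) and the
  attempt completes, otherwise it retries next tick.  A donor carrying
  both plasmids transfers P2 with probability ``hijack`` (the cheater
  competing for the shared apparatus), else P1.

There is no death and no segregative loss: the population size never
decreases and a lineage's plasmid state never reverts.  Outputs per
tick: ``free``, ``P1``, ``P2``, ``Both``, ``total`` cell counts.
"""

from __future__ import annotations

import math
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from ..errors import ParameterError
from ..experiment import Model, ModelRun

__all__ = ["T4SSModel", "t4_model", "t4_census", "t4_eligible"]

_SIZE = 100.0
_BIN = 2.0  # neighbour-search bin width (um); radius 1.5 < BIN
_NBINS = int(_SIZE / _BIN)
_RADIUS2 = 1.5 * 1.5
_TWO_PI = 2.0 * math.pi

# cell record indices
_X, _Y, _MASS, _DM, _P1, _P2, _RESOLVED, _PENDING = range(8)

_DEFAULTS: dict[str, Any] = {
    "doublingTime": 40.0,  # minutes, plasmid-free
    "p1P": 0.5,            # P(conjugates at least once per cycle)
    "p1Cost": 0.10,        # fractional growth penalty of P1
    "p2Cost": 0.05,        # fractional growth penalty of P2
    "n0": 100,             # initial cells
    "f1": 0.25,            # initial fraction carrying only P1
    "f2": 0.25,            # initial fraction carrying only P2
    "nutrient": 120,       # particles per lattice site
    "uptake": 1,           # particles removable per cell per tick
    "hijack": 0.5,         # P(transferred plasmid is P2 | donor has both)
    "colony_radius": 10.0, # um, initial placement disc
}

_CLASS_NAMES = ("free", "P1", "P2", "Both")


def _validate(params: Mapping[str, Any]) -> dict[str, Any]:
    p = dict(_DEFAULTS)
    p.update({k: params[k] for k in _DEFAULTS if k in params})
    if float(p["doublingTime"]) <= 0:
        raise ParameterError("doublingTime must be positive")
    for key in ("p1P", "hijack", "f1", "f2"):
        if not 0.0 <= float(p[key]) <= 1.0:
            raise ParameterError(f"{key} must lie in [0, 1]")
    if float(p["f1"]) + float(p["f2"]) > 1.0 + 1e-9:
        raise ParameterError("f1 + f2 must not exceed 1")
    for key in ("p1Cost", "p2Cost", "colony_radius"):
        if float(p[key]) < 0:
            raise ParameterError(f"{key} must be >= 0")
    for key in ("n0", "nutrient", "uptake"):
        if int(round(float(p[key]))) < 0:
            raise ParameterError(f"{key} must be >= 0")
        p[key] = int(round(float(p[key])))
    for key in ("doublingTime", "p1P", "p1Cost", "p2Cost", "hijack", "f1", "f2", "colony_radius"):
        p[key] = float(p[key])
    return p


def t4_eligible(cell) -> bool:
    """Conjugation eligibility: carries P1 and mass >= 0.70 x division mass."""
    if isinstance(cell, Mapping):
        p1, mass, dm = cell["p1"], cell["mass"], cell["division_mass"]
    else:
        p1, mass, dm = cell[_P1], cell[_MASS], cell[_DM]
    return bool(p1) and mass >= 0.70 * dm


def t4_census(population: Sequence) -> dict[str, int]:
    """Exact partition of a population by plasmid state."""
    counts = [0, 0, 0, 0]
    for cell in population:
        if isinstance(cell, Mapping):
            cls = int(bool(cell["p1"])) + 2 * int(bool(cell["p2"]))
        else:
            cls = cell[_P1] + 2 * cell[_P2]
        counts[cls] += 1
    out = dict(zip(_CLASS_NAMES, counts))
    out["total"] = len(population)
    return out


class _T4Run(ModelRun):
    def __init__(self, params: Mapping[str, Any], seed: int):
        p = _validate(params)
        self.params = p
        self._rng = np.random.default_rng(seed)
        rng = self._rng
        n0 = p["n0"]

        # plasmid assignment: fixed fractions, randomly permuted
        n1 = int(round(p["f1"] * n0))
        n2 = int(round(p["f2"] * n0))
        states = [(1, 0)] * n1 + [(0, 1)] * n2 + [(0, 0)] * (n0 - n1 - n2)
        order = rng.permutation(n0)

        cx = cy = _SIZE / 2.0
        radius = p["colony_radius"]
        self.cells: list[list] = []
        self._bins: dict[tuple[int, int], list] = {}
        self._counts = [0, 0, 0, 0]
        for i in range(n0):
            r = radius * math.sqrt(rng.random())
            theta = rng.random() * _TWO_PI
            x = (cx + r * math.cos(theta)) % _SIZE
            y = (cy + r * math.sin(theta)) % _SIZE
            dm = self._draw_division_mass()
            mass = dm * (0.5 + 0.45 * rng.random())
            p1, p2 = states[order[i]]
            rec = [x, y, mass, dm, p1, p2, False, False]
            self.cells.append(rec)
            self._bin_insert(rec)
            self._counts[p1 + 2 * p2] += 1

        self.nutrient = np.full((int(_SIZE), int(_SIZE)), p["nutrient"], dtype=np.int64)
        self.initial_nutrient = int(self.nutrient.sum())
        self.consumed = 0
        self._t = 0

    def _draw_division_mass(self) -> float:
        # normal(mean 1.0, sd 0.05) truncated at +/- 3 sd by rejection
        rng = self._rng
        while True:
            v = 1.0 + 0.05 * rng.standard_normal()
            if 0.85 <= v <= 1.15:
                return v

    def _bin_insert(self, rec: list) -> None:
        key = (int(rec[_X] / _BIN), int(rec[_Y] / _BIN))
        self._bins.setdefault(key, []).append(rec)

    def _pick_neighbour(self, rec: list):
        bx, by = int(rec[_X] / _BIN), int(rec[_Y] / _BIN)
        x0, y0 = rec[_X], rec[_Y]
        candidates = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                lst = self._bins.get(((bx + dx) % _NBINS, (by + dy) % _NBINS))
                if not lst:
                    continue
                for other in lst:
                    if other is rec:
                        continue
                    ddx = abs(other[_X] - x0)
                    if ddx > _SIZE / 2:
                        ddx = _SIZE - ddx
                    ddy = abs(other[_Y] - y0)
                    if ddy > _SIZE / 2:
                        ddy = _SIZE - ddy
                    if ddx * ddx + ddy * ddy <= _RADIUS2:
                        candidates.append(other)
        if not candidates:
            return None
        if len(candidates) == 1:
            return candidates[0]
        return candidates[self._rng.integers(len(candidates))]

    def step(self) -> dict[str, int]:
        self._t += 1
        rng = self._rng
        p = self.params
        cells = self.cells
        nutrient = self.nutrient
        counts = self._counts
        u = p["uptake"]
        ln2 = math.log(2.0)
        g_base = p["doublingTime"]
        c1, c2 = p["p1Cost"], p["p2Cost"]
        p1p, hijack = p["p1P"], p["hijack"]

        n = len(cells)
        newborn: list[list] = []
        if n:
            order = rng.permutation(n)
            for i in order:
                rec = cells[i]
                # uptake
                phi = 0.0
                if u > 0:
                    sx, sy = int(rec[_X]), int(rec[_Y])
                    avail = nutrient[sx, sy]
                    got = u if avail >= u else int(avail)
                    if got:
                        nutrient[sx, sy] = avail - got
                        self.consumed += got
                        phi = got / u
                # growth (costs lengthen the effective doubling time)
                if phi > 0.0:
                    g_eff = g_base * (1.0 + rec[_P1] * c1 + rec[_P2] * c2)
                    mass = rec[_MASS] * math.exp(phi * ln2 / g_eff)
                    dm = rec[_DM]
                    rec[_MASS] = dm if mass > dm else mass
                # division
                if rec[_MASS] >= rec[_DM]:
                    half = rec[_MASS] / 2.0
                    rec[_MASS] = half
                    rec[_DM] = self._draw_division_mass()
                    rec[_RESOLVED] = False
                    rec[_PENDING] = False
                    heading = rng.random() * _TWO_PI
                    child = [
                        (rec[_X] + 0.5 * math.cos(heading)) % _SIZE,
                        (rec[_Y] + 0.5 * math.sin(heading)) % _SIZE,
                        half,
                        self._draw_division_mass(),
                        rec[_P1],
                        rec[_P2],
                        False,
                        False,
                    ]
                    newborn.append(child)
                    self._bin_insert(child)
                    counts[child[_P1] + 2 * child[_P2]] += 1
                # conjugation
                if rec[_P1] and rec[_MASS] >= 0.70 * rec[_DM]:
                    if not rec[_RESOLVED]:
                        rec[_RESOLVED] = True
                        rec[_PENDING] = rng.random() < p1p
                    if rec[_PENDING]:
                        other = self._pick_neighbour(rec)
                        if other is not None:
                            if rec[_P2]:
                                plasmid = _P2 if rng.random() < hijack else _P1
                            else:
                                plasmid = _P1
                            if not other[plasmid]:
                                counts[other[_P1] + 2 * other[_P2]] -= 1
                                other[plasmid] = 1  # donor keeps its copy
                                counts[other[_P1] + 2 * other[_P2]] += 1
                                rec[_PENDING] = False
        cells.extend(newborn)
        out = dict(zip(_CLASS_NAMES, counts))
        out["total"] = len(cells)
        return out

    def run(self, ticks: int) -> pd.DataFrame:
        rows = []
        for _ in range(ticks):
            rows.append(self.step())
        df = pd.DataFrame(rows)
        df.insert(0, "tick", np.arange(1, ticks + 1))
        return df


class T4SSModel(Model):
    name = "t4ss_pool"

    def declared_parameters(self) -> dict[str, Any]:
        return dict(_DEFAULTS)

    def setup(self, params: Mapping[str, Any], seed: int) -> _T4Run:
        return _T4Run(params, seed)


def t4_model() -> T4SSModel:
    return T4SSModel()
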