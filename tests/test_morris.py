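import numpy as np
import pytest

from sasim import (
    FactorTable,
    add_factor,
    easy_morris,
    elementary_effects,
    morris_delta,
    morris_design,
    morris_metrics,
)
from sasim.errors import InvalidLevels, ShapeError
from sasim.models import linear_model
from sasim.morris import ElementaryEffectSet


def _unit_table(k):
    table = FactorTable()
    for i in range(k):
        table = table.add(f"x{i + 1}", 0.0, 1.0)
    return table


class TestMorrisDelta:
    @pytest.mark.parametrize(
        "p,mode,expected",
        [(4, "standard", 2 / 3), (4, "alternative", 1 / 3), (2, "standard", 1.0)],
    )
    def test_printed_formulas(self, p, mode, expected):
        assert morris_delta(p, mode) == pytest.approx(expected, abs=1e-15)

    def test_odd_p_rejected_in_standard_mode(self):
        with pytest.raises(InvalidLevels):
            morris_delta(5, "standard")


class TestMorrisDesign:
    def test_row_count(self):
        plan = morris_design(_unit_table(3), p=4, r=10, rng=0)
        assert plan.design.n == 10 * (3 + 1)

    def test_paper_screening_size(self):
        # k=7 factors at five levels with ten trajectories -> 80 rows
        plan = morris_design(_unit_table(7), p=5, r=10, rng=1)
        assert plan.design.n == 80

    @pytest.mark.parametrize("p,mode", [(4, "standard"), (5, "auto"), (8, "alternative")])
    def test_transition_structure(self, p, mode):
        k, r = 4, 6
        plan = morris_design(_unit_table(k), p=p, r=r, delta_mode=mode, rng=2)
        for t, pts in enumerate(plan.trajectories):
            moved = set()
            for j, (fac, direction) in enumerate(plan.steps[t]):
                diff = pts[j + 1] - pts[j]
                assert abs(diff[fac] - direction * plan.delta) < 1e-12
                off_axis = np.delete(diff, fac)
                assert np.all(off_axis == 0.0)
                moved.add(fac)
            assert moved == set(range(k))  # each factor moves exactly once
            assert np.all(pts >= -1e-12) and np.all(pts <= 1 + 1e-12)

    def test_seed_reproducibility(self):
        a = morris_design(_unit_table(3), p=4, r=5, rng=7)
        b = morris_design(_unit_table(3), p=4, r=5, rng=7)
        np.testing.assert_array_equal(a.design.unit_rows, b.design.unit_rows)


class TestElementaryEffects:
    def test_linear_function_exact_slope(self):
        plan = morris_design(_unit_table(2), p=4, r=8, rng=3)
        y = 3.0 * plan.design.unit_rows[:, 0]
        ee = elementary_effects(plan, y)
        np.testing.assert_allclose(ee.effects["y"][:, 0], 3.0, atol=1e-12)
        np.testing.assert_allclose(ee.effects["y"][:, 1], 0.0, atol=1e-12)

    def test_constant_function_zero_effects(self):
        plan = morris_design(_unit_table(3), p=4, r=5, rng=4)
        ee = elementary_effects(plan, np.full(plan.design.n, 5.0))
        for arr in ee.effects.values():
            np.testing.assert_array_equal(arr, 0.0)

    def test_quadratic_effects_match_direct_recompute(self):
        # independent oracle: recompute each effect straight from the
        # design rows, locating the moved coordinate by diffing
        plan = morris_design(_unit_table(1), p=4, r=10, delta_mode="standard", rng=5)
        u = plan.design.unit_rows[:, 0]
        y = u**2
        ee = elementary_effects(plan, y)
        for t in range(plan.r):
            lo_row, hi_row = 2 * t, 2 * t + 1
            if u[lo_row] > u[hi_row]:
                lo_row, hi_row = hi_row, lo_row
            expected = (u[hi_row] ** 2 - u[lo_row] ** 2) / plan.delta
            assert ee.effects["y"][t, 0] == pytest.approx(expected, abs=1e-12)
            if u[lo_row] == 0.0:  # hand-checked value: (4/9 - 0) / (2/3)
                assert ee.effects["y"][t, 0] == pytest.approx(2 / 3, abs=1e-12)

    def test_output_length_mismatch_rejected(self):
        plan = morris_design(_unit_table(2), p=4, r=4, rng=0)
        with pytest.raises(ShapeError):
            elementary_effects(plan, np.zeros(plan.design.n - 1))


class TestMorrisMetrics:
    @pytest.mark.parametrize(
        "effects,mu,mu_star,sigma",
        [
            ([3.0, 3.0, 3.0], 3.0, 3.0, 0.0),
            ([-2.0, 2.0], 0.0, 2.0, 2.0),
            ([1.0, 3.0], 2.0, 2.0, 1.0),
        ],
    )
    def test_hand_computed_metrics(self, effects, mu, mu_star, sigma):
        ee = ElementaryEffectSet(
            factor_names=("f",), effects={"y": np.array(effects).reshape(-1, 1)}
        )
        idx = morris_metrics(ee).for_output("y")
        assert idx.loc["f", "mu"] == pytest.approx(mu)
        assert idx.loc["f", "mu_star"] == pytest.approx(mu_star)
        assert idx.loc["f", "sigma"] == pytest.approx(sigma)

    def test_sample_divisor_option(self):
        ee = ElementaryEffectSet(
            factor_names=("f",), effects={"y": np.array([[1.0], [3.0]])}
        )
        idx = morris_metrics(ee, sigma_divisor="r-1").for_output("y")
        assert idx.loc["f", "sigma"] == pytest.approx(np.sqrt(2))


class TestEasyMorris:
    @pytest.mark.parametrize("p,r", [(4, 5), (6, 20), (8, 5)])
    def test_affine_model_is_exact(self, p, r):
        """For affine responses every elementary effect equals the
        unit-cube slope, so mu = mu* = slope and sigma vanishes."""
        model = linear_model((3.0, 5.0))
        table = _unit_table(2)
        res = easy_morris(model, table, p=p, r=r, ticks=1, master_seed=11)
        idx = res.indices.for_output("y")
        assert idx.loc["x1", "mu_star"] == pytest.approx(3.0, abs=1e-9)
        assert idx.loc["x2", "mu_star"] == pytest.approx(5.0, abs=1e-9)
        assert idx.loc["x1", "mu"] == pytest.approx(3.0, abs=1e-9)
        assert np.all(idx["sigma"] <= 1e-9)

    def test_mu_star_bounds_abs_mu(self):
        plan = morris_design(_unit_table(2), p=6, r=30, rng=1)
        y = np.sin(6 * plan.design.unit_rows[:, 0]) + plan.design.unit_rows[:, 1]
        idx = morris_metrics(elementary_effects(plan, y)).for_output("y")
        assert np.all(idx["mu_star"] >= np.abs(idx["mu"]) - 1e-12)

    def test_nonmonotone_signature(self):
        """sin(2 pi x) has cancelling effects: mu collapses, mu* does not.
        The single-spacing step resolves the oscillation."""
        plan = morris_design(
            _unit_table(1), p=8, r=50, delta_mode="alternative", rng=21
        )
        y = np.sin(2 * np.pi * plan.design.unit_rows[:, 0])
        idx = morris_metrics(elementary_effects(plan, y)).for_output("y")
        assert idx.loc["x1", "mu_star"] >= 5.0 * abs(idx.loc["x1", "mu"])
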