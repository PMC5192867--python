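import math

import numpy as np
import pytest

from sasim import FactorTable, easy_sobol, sobol_design, sobol_indices
from sasim.errors import DegenerateVariance, InvalidSampleSize, ShapeError
from sasim.models import (
    constant_model,
    ishigami_analytic_indices,
    ishigami_model,
    linear_model,
    product_model,
)


def _unit_table(k):
    table = FactorTable()
    for i in range(k):
        table = table.add(f"x{i + 1}", 0.0, 1.0)
    return table


def _ishigami_table():
    table = FactorTable()
    for i in range(3):
        table = table.add(f"x{i + 1}", -math.pi, math.pi)
    return table


class TestSobolDesign:
    def test_row_count(self):
        plan = sobol_design(_unit_table(4), 100, rng=0)
        assert plan.design.n == 100 * (4 + 2)

    def test_hybrid_block_structure(self):
        plan = sobol_design(_unit_table(3), 50, rng=1)
        N = plan.N
        ab2 = plan.design.unit_rows[(2 + 1) * N : (3 + 1) * N]
        np.testing.assert_array_equal(ab2[:, 1], plan.B[:, 1])
        np.testing.assert_array_equal(ab2[:, [0, 2]], plan.A[:, [0, 2]])

    def test_seed_reproducibility(self):
        a = sobol_design(_unit_table(2), 32, rng=9)
        b = sobol_design(_unit_table(2), 32, rng=9)
        np.testing.assert_array_equal(a.design.unit_rows, b.design.unit_rows)

    def test_small_sample_rejected(self):
        with pytest.raises(InvalidSampleSize):
            sobol_design(_unit_table(2), 1, rng=0)


class TestSobolIndices:
    def test_single_active_factor(self):
        plan = sobol_design(_unit_table(2), 4096, sampler="lhs", rng=2)
        y = plan.design.unit_rows[:, 0]
        idx = sobol_indices(plan, y).for_output("y")
        assert idx.loc["x1", "S"] == pytest.approx(1.0, abs=0.02)
        assert idx.loc["x2", "S"] == pytest.approx(0.0, abs=0.02)
        assert idx.loc["x2", "ST"] == pytest.approx(0.0, abs=0.02)

    def test_additive_symmetric_model(self):
        plan = sobol_design(_unit_table(2), 4096, rng=3)
        y = plan.design.unit_rows.sum(axis=1)
        idx = sobol_indices(plan, y).for_output("y")
        assert idx.loc["x1", "S"] == pytest.approx(0.5, abs=0.03)
        assert idx.loc["x2", "S"] == pytest.approx(0.5, abs=0.03)
        assert idx["S"].sum() == pytest.approx(1.0, abs=0.05)
        assert np.all(np.abs(idx["ST"] - idx["S"]) < 0.05)

    def test_ishigami_closed_form_recovery(self):
        truth = ishigami_analytic_indices(7.0, 0.1)
        plan = sobol_design(_ishigami_table(), 8192, rng=4)
        y = ishigami_model().evaluate_matrix(plan.design.rows)
        idx = sobol_indices(plan, y).for_output("y")
        for i in (1, 2, 3):
            assert idx.loc[f"x{i}", "S"] == pytest.approx(truth[f"S{i}"], abs=0.05)
            assert idx.loc[f"x{i}", "ST"] == pytest.approx(truth[f"ST{i}"], abs=0.05)

    def test_interacting_pair_total_exceeds_first(self):
        # closed form for f = x1 x2 on U[0,1]^2: V = 7/144, V1 = V2 = 1/48
        # so S = 3/7 and ST = 4/7 for both factors
        plan = sobol_design(_unit_table(2), 8192, rng=5)
        y = product_model().evaluate_matrix(plan.design.rows)
        idx = sobol_indices(plan, y).for_output("y")
        for f in ("x1", "x2"):
            assert idx.loc[f, "S"] == pytest.approx(3 / 7, abs=0.05)
            assert idx.loc[f, "ST"] == pytest.approx(4 / 7, abs=0.05)
            assert idx.loc[f, "ST"] - idx.loc[f, "S"] > 0.05

    def test_constant_output_degenerate(self):
        plan = sobol_design(_unit_table(2), 64, rng=6)
        with pytest.raises(DegenerateVariance):
            sobol_indices(plan, np.full(plan.n_rows, 3.0))

    def test_length_mismatch_rejected(self):
        plan = sobol_design(_unit_table(2), 64, rng=6)
        with pytest.raises(ShapeError):
            sobol_indices(plan, np.zeros(plan.n_rows + 1))

    def test_monte_carlo_consistency(self):
        """Estimation error shrinks with N on the Ishigami oracle."""
        truth = ishigami_analytic_indices(7.0, 0.1)
        model = ishigami_model()
        wins = 0
        for seed in range(10):
            errs = {}
            for N in (512, 8192):
                plan = sobol_design(_ishigami_table(), N, rng=seed)
                y = model.evaluate_matrix(plan.design.rows)
                idx = sobol_indices(plan, y).for_output("y")
                errs[N] = sum(
                    abs(idx.loc[f"x{i}", "S"] - truth[f"S{i}"]) for i in (1, 2, 3)
                )
            wins += errs[8192] < errs[512]
        assert wins >= 9

    def test_bootstrap_bounds_bracket_estimate(self):
        plan = sobol_design(_unit_table(2), 512, rng=7)
        y = plan.design.unit_rows.sum(axis=1)
        idx = sobol_indices(plan, y, n_boot=200, rng=8).for_output("y")
        assert {"S_lo", "S_hi", "ST_lo", "ST_hi"} <= set(idx.columns)
        assert np.all(idx["S_lo"] <= idx["S"] + 1e-9)
        assert np.all(idx["S_hi"] >= idx["S"] - 1e-9)


class TestEasySobol:
    def test_pipeline_matches_direct_estimate(self):
        """The engine path must agree exactly with direct vectorised
        evaluation of the same plan."""
        model = linear_model((3.0, 5.0))
        table = _unit_table(2)
        res = easy_sobol(model, table, N=128, ticks=1, master_seed=13)
        plan = sobol_design(table, 128, rng=np.random.default_rng(13))
        y = model.evaluate_matrix(plan.design.rows)
        direct = sobol_indices(plan, y).for_output("y")
        got = res.indices.for_output("y")
        np.testing.assert_allclose(got["S"], direct["S"], atol=1e-10)
        np.testing.assert_allclose(got["ST"], direct["ST"], atol=1e-10)

    def test_constant_model_surfaces_degeneracy(self):
        with pytest.raises(DegenerateVariance):
            easy_sobol(constant_model(), _unit_table(1), N=16, ticks=1, master_seed=0)
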