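import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sasim import (
    FactorTable,
    add_factor,
    build_parameter_set,
    design_full_factorial,
    sample_latin_hypercube,
    sample_random,
)
from sasim.errors import (
    DuplicateFactor,
    EmptyFactorTable,
    InvalidLevels,
    InvalidRange,
    UnknownParameter,
)


@pytest.fixture
def two_factor_table() -> FactorTable:
    return FactorTable().add("a", 0.0, 1.0).add("b", -5.0, 5.0)


class TestAddFactor:
    def test_append_to_empty(self):
        table = add_factor(None, "sheepgainfromfood", 2, 8)
        assert table.names == ("sheepgainfromfood",)
        assert table.factors[0].lower == 2 and table.factors[0].upper == 8

    def test_is_persistent_not_mutating(self, two_factor_table):
        bigger = add_factor(two_factor_table, "c", 0, 1)
        assert two_factor_table.k == 2 and bigger.k == 3
        assert bigger.names[:2] == two_factor_table.names

    def test_duplicate_name_rejected(self):
        table = add_factor(None, "p1Cost", 0, 1)
        with pytest.raises(DuplicateFactor):
            add_factor(table, "p1Cost", 0, 2)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(InvalidRange):
            add_factor(None, "G", 40, 40)
        with pytest.raises(InvalidRange):
            add_factor(None, "G", 41, 40)


class TestRandomSampling:
    def test_deterministic_under_seed(self, two_factor_table):
        d1 = sample_random(100, two_factor_table, rng=42)
        d2 = sample_random(100, two_factor_table, rng=42)
        np.testing.assert_array_equal(d1.rows, d2.rows)

    def test_column_means_converge(self):
        table = add_factor(None, "u", 0.0, 1.0)
        d = sample_random(10000, table, rng=7)
        assert abs(d.rows[:, 0].mean() - 0.5) < 0.02

    def test_single_row_within_ranges(self, two_factor_table):
        d = sample_random(1, two_factor_table, rng=0)
        assert d.rows.shape == (1, 2)
        assert np.all(d.rows >= two_factor_table.lowers)
        assert np.all(d.rows <= two_factor_table.uppers)

    def test_empty_table_rejected(self):
        with pytest.raises(EmptyFactorTable):
            sample_random(10, FactorTable(), rng=0)


class TestLatinHypercube:
    @pytest.mark.parametrize("n,k", [(10, 2), (50, 4), (1, 3)])
    def test_one_point_per_stratum(self, n, k):
        table = FactorTable()
        for i in range(k):
            table = table.add(f"f{i}", 0.0, 1.0)
        d = sample_latin_hypercube(n, table, rng=3)
        for j in range(k):
            strata = np.floor(d.unit_rows[:, j] * n).astype(int)
            assert sorted(strata) == list(range(n))

    def test_deterministic_under_seed(self, two_factor_table):
        d1 = sample_latin_hypercube(16, two_factor_table, rng=5)
        d2 = sample_latin_hypercube(16, two_factor_table, rng=5)
        np.testing.assert_array_equal(d1.unit_rows, d2.unit_rows)


class TestFullFactorial:
    def test_three_by_three(self, two_factor_table):
        d = design_full_factorial(3, two_factor_table)
        assert d.n == 9

    def test_endpoints_included(self):
        table = add_factor(None, "x", 0.0, 10.0)
        d = design_full_factorial(2, table)
        assert sorted(d.rows[:, 0]) == [0.0, 10.0]

    def test_mixed_levels_product_and_uniqueness(self):
        table = FactorTable().add("a", 0, 1).add("b", 0, 1).add("c", 0, 1)
        d = design_full_factorial((2, 3, 4), table)
        assert d.n == 2 * 3 * 4
        assert len({tuple(r) for r in d.rows}) == 24

    def test_levels_below_two_rejected(self, two_factor_table):
        with pytest.raises(InvalidLevels):
            design_full_factorial(1, two_factor_table)


class TestBuildParameterSet:
    def test_fixed_parameters_filled(self):
        table = add_factor(None, "a", 0, 10)
        d = sample_random(5, table, rng=0)
        sets = build_parameter_set(d, {"a": 1.0, "b": 2.0})
        assert len(sets) == 5
        assert all(ps["b"] == 2.0 for ps in sets)

    def test_empty_design_gives_empty_list(self, two_factor_table):
        d = sample_random(1, two_factor_table, rng=0)
        empty = type(d)(d.factor_names, d.rows[:0], d.unit_rows[:0])
        assert build_parameter_set(empty, {"a": 1, "b": 2}) == []

    def test_unknown_parameter_rejected(self):
        table = add_factor(None, "zz", 0, 1)
        d = sample_random(2, table, rng=0)
        with pytest.raises(UnknownParameter):
            build_parameter_set(d, {"a": 1})

    def test_integer_defaults_rounded_half_up(self):
        table = add_factor(None, "n", 0, 10)
        d = sample_random(1, table, rng=0)
        object.__setattr__(d, "rows", np.array([[2.5]]))
        sets = build_parameter_set(d, {"n": 5})
        assert sets[0]["n"] == 3 and isinstance(sets[0]["n"], int)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    n=st.integers(1, 40),
    k=st.integers(1, 5),
    seed=st.integers(0, 2**31 - 1),
    lo=st.floats(-100, 100),
    width=st.floats(0.01, 1000),
)
def test_affine_consistency_and_stratification(n, k, seed, lo, width):
    """unit_rows and physical rows interconvert exactly; LHS strata exact."""
    table = FactorTable()
    for i in range(k):
        table = table.add(f"f{i}", lo, lo + width)
    d = sample_latin_hypercube(n, table, rng=seed)
    expected = table.lowers + d.unit_rows * (table.uppers - table.lowers)
    np.testing.assert_array_equal(d.rows, expected)
    assert np.all(d.unit_rows >= 0) and np.all(d.unit_rows < 1 + 1e-12)
    for j in range(k):
        assert sorted(np.floor(d.unit_rows[:, j] * n).astype(int)) == list(range(n))
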