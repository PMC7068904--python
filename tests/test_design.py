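"""Orthogonal-array construction, validation, and design instantiation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tkaopt as tk
from tkaopt.design import DEFAULT_FACTORS, FactorSpec, decode_combination


def brute_force_pair_counts(cells, col_a, col_b):
    """Independent oracle: enumerate every ordered level pair in two columns."""
    counts = {}
    for row in cells:
        pair = (int(row[col_a]), int(row[col_b]))
        counts[pair] = counts.get(pair, 0) + 1
    return counts


class TestBuildOrthogonalArray:
    def test_canonical_l9_rows(self):
        arr = tk.build_orthogonal_array(3, 3)
        assert arr.runs == 9
        assert arr.designation == "L9(3^4)"
        assert tuple(arr.cells[0][:3]) == (1, 1, 1)
        assert tuple(arr.cells[1][:3]) == (1, 2, 2)
        assert tuple(arr.cells[8][:3]) == (3, 3, 2)

    def test_column_balance(self):
        arr = tk.build_orthogonal_array(3, 4)
        for j in range(arr.columns):
            col = arr.cells[:, j]
            assert all(np.sum(col == lv) == 3 for lv in (1, 2, 3))

    def test_every_ordered_pair_once_in_first_two_columns(self):
        arr = tk.build_orthogonal_array(3, 3)
        counts = brute_force_pair_counts(arr.cells, 0, 1)
        assert counts == {(a, b): 1 for a in (1, 2, 3) for b in (1, 2, 3)}

    @pytest.mark.parametrize("levels,factors", [(2, 2), (3, 5), (4, 3), (3, 0)])
    def test_unsupported_requests_error(self, levels, factors):
        with pytest.raises(ValueError, match="L9"):
            tk.build_orthogonal_array(levels, factors)


class TestValidateOrthogonality:
    def test_canonical_l9_passes(self):
        report = tk.validate_orthogonality(tk.build_orthogonal_array(3, 4))
        assert report.passed
        assert report.failures == []

    def test_any_single_cell_perturbation_fails(self):
        base = tk.build_orthogonal_array(3, 4)
        for i, j in itertools.product(range(base.runs), range(base.columns)):
            cells = base.cells.copy()
            cells[i, j] = cells[i, j] % 3 + 1  # change to a different level
            report = tk.validate_orthogonality(tk.OrthogonalArray("broken", cells))
            assert not report.passed
            assert any(f"column {j + 1}" in msg for msg in report.failures)

    def test_perturbation_report_names_column_and_pair(self):
        cells = tk.build_orthogonal_array(3, 3).cells.copy()
        cells[0, 0] = 2  # run 1 factor A: level 1 -> 2
        report = tk.validate_orthogonality(tk.OrthogonalArray("broken", cells))
        assert any("column 1 unbalanced" in msg for msg in report.failures)
        assert any("column pair (1, 2)" in msg for msg in report.failures)

    def test_full_factorial_27_run_design_is_orthogonal(self):
        cells = np.array(list(itertools.product((1, 2, 3), repeat=3)))
        report = tk.validate_orthogonality(tk.OrthogonalArray("3^3", cells))
        assert report.passed
        # each ordered pair appears 27 / 9 = 3 times in every column pair
        for a, b in itertools.combinations(range(3), 2):
            counts = brute_force_pair_counts(cells, a, b)
            assert set(counts.values()) == {3}


class TestInstantiateDesign:
    def test_run_2_and_run_8_decode_to_the_printed_angles(self, l9_design):
        run2 = l9_design.iloc[1]
        assert run2["combination"] == "A1B2C2"
        assert (run2["varus_deg"], run2["slope_deg"], run2["rotation_deg"]) == (0.0, 2.0, 4.0)
        run8 = l9_design.iloc[7]
        assert run8["combination"] == "A3B2C1"
        assert (run8["varus_deg"], run8["slope_deg"], run8["rotation_deg"]) == (-3.0, 2.0, 3.0)

    def test_l9_reproduces_all_nine_reference_triples(self, l9_design, table3):
        cols = ["run_id", "combination", "varus_deg", "slope_deg", "rotation_deg"]
        pd.testing.assert_frame_equal(
            l9_design[cols].astype({"run_id": int}),
            table3[cols].astype({"run_id": int}),
        )

    def test_level_count_mismatch_errors(self):
        arr = tk.build_orthogonal_array(3, 3)
        bad = FactorSpec(name="varus angle", symbol="A", levels=(0.0, 3.0))
        with pytest.raises(ValueError, match="levels"):
            tk.instantiate_design(arr, (bad,) + DEFAULT_FACTORS[1:])

    def test_too_many_factors_errors(self):
        arr = tk.build_orthogonal_array(3, 4)
        extra = tuple(
            FactorSpec(name=f"f{i}", symbol=s, levels=(1.0, 2.0, 3.0))
            for i, s in enumerate("ABCDE")
        )
        with pytest.raises(ValueError, match="columns"):
            tk.instantiate_design(arr, extra)


class TestFullFactorial:
    def test_reference_factors_need_27_runs(self, factors):
        assert len(tk.full_factorial(factors)) == 27

    def test_single_factor(self):
        f = FactorSpec(name="varus angle", symbol="A", levels=(0.0, 3.0, -3.0), column="varus_deg")
        design = tk.full_factorial([f])
        assert len(design) == 3
        assert list(design["varus_deg"]) == [0.0, 3.0, -3.0]

    def test_two_factors_cover_every_pair_once(self, factors):
        design = tk.full_factorial(factors[:2])
        assert len(design) == 9
        pairs = set(zip(design["varus_deg"], design["slope_deg"]))
        assert len(pairs) == 9

    @given(ns=st.lists(st.integers(min_value=2, max_value=4), min_size=1, max_size=3))
    @settings(max_examples=25, deadline=None)
    def test_run_count_is_product_of_level_counts(self, ns):
        specs = tuple(
            FactorSpec(name=f"f{i}", symbol=chr(ord("A") + i), levels=tuple(float(v) for v in range(n)))
            for i, n in enumerate(ns)
        )
        assert len(tk.full_factorial(specs)) == int(np.prod(ns))


class TestFactorsAndLabels:
    def test_factor_invariants(self):
        with pytest.raises(ValueError):
            FactorSpec(name="x", symbol="A", levels=(1.0,))
        with pytest.raises(ValueError):
            FactorSpec(name="x", symbol="A", levels=(1.0, 1.0))
        with pytest.raises(ValueError):
            FactorSpec(name="x", symbol="AB", levels=(1.0, 2.0))

    def test_label_round_trip(self, factors, l9_design):
        for _, row in l9_design.iterrows():
            decoded = decode_combination(row["combination"], factors)
            for f in factors:
                assert row[f.column] == f.levels[decoded[f.symbol] - 1]

    def test_malformed_labels_rejected(self, factors):
        for bad in ("A1B2", "A1B2C9", "B1A2C3", "A1-B2C2"):
            with pytest.raises(ValueError):
                decode_combination(bad, factors)

    def test_design_export_round_trip(self, l9_design, tmp_path):
        from tkaopt.design import read_design, write_design

        path = tmp_path / "design.csv"
        write_design(l9_design, path)
        assert path.read_text().splitlines()[0] == "run_id,combination,varus_deg,slope_deg,rotation_deg"
        pd.testing.assert_frame_equal(read_design(path), l9_design)
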