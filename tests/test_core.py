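import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvsignal.core import (
    DrugEventTable,
    Hierarchy,
    Level,
    Method,
    SignalDecision,
    TwoByTwo,
    aggregate_to_soc,
    hierarchy_from_codes,
    parse_whoart_code,
    read_hierarchy,
    read_pairs,
    write_hierarchy,
    write_pairs,
)


class TestTwoByTwo:
    def test_uniform_table(self):
        t = TwoByTwo(5, 10, 10, 20)
        assert (t.n_ij, t.n_i_dot, t.n_dot_j, t.n_dot_dot) == (5, 10, 10, 20)
        assert t.other_cell == 5 and t.expected == 5.0

    def test_degenerate_single_cell(self):
        t = TwoByTwo(7, 7, 7, 7)
        assert t.ae_other_drugs == 0 and t.other_aes_drug == 0 and t.other_cell == 0

    @pytest.mark.parametrize(
        "cells",
        [(6, 5, 10, 20), (5, 10, 4, 20), (5, 10, 10, 14), (-1, 5, 5, 20)],
    )
    def test_inconsistent_margins_rejected(self, cells):
        with pytest.raises(ValueError):
            TwoByTwo(*cells)

    def test_all_derived_cells_nonnegative_on_random_table(self, random_table):
        for ae in random_table.ae_ids:
            for drug in random_table.drug_ids:
                t = random_table.two_by_two(ae, drug)
                assert min(t.n_ij, t.ae_other_drugs, t.other_aes_drug, t.other_cell) >= 0


class TestWhoArtCodes:
    @pytest.mark.parametrize(
        "code,expected",
        [
            ("100.0001.001", ("100", "0001", "001")),
            ("100.0001", ("100", "0001", None)),
            ("100", ("100", None, None)),
            ("600_285", ("600", "285", None)),
        ],
    )
    def test_parse(self, code, expected):
        assert tuple(parse_whoart_code(code)) == expected

    @pytest.mark.parametrize("bad", ["abc", "100.0001.001.5", "100.", "1_2_3", ""])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_whoart_code(bad)

    def test_level_inference(self):
        assert parse_whoart_code("100").level == "soc"
        assert parse_whoart_code("100.0001").level == "pt"
        assert parse_whoart_code("100.0001.001").level == "it"

    def test_hierarchy_from_codes(self):
        tree = hierarchy_from_codes(["100.0001", "100.0002", "200_003"])
        assert tree.soc_ids == ("100", "200")
        assert tree.parent["200_003"] == "200"


class TestPairListIO:
    def test_dedupe_counts_repeated_pairs_once(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        p.write_text("drug\tae_code\nd1\t100.0001\nd1\t100.0001\nd2\t100.0002\n")
        table = read_pairs(p, dedupe=True)
        assert table.two_by_two("100.0001", "d1").n_ij == 1
        assert table.two_by_two("100.0002", "d2").n_ij == 1
        assert table.total == 2

    def test_counts_sum_without_dedupe(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        p.write_text("drug\tae_code\tcount\nd1\t100.0001\t2\nd1\t100.0001\t3\n")
        assert read_pairs(p, dedupe=False).two_by_two("100.0001", "d1").n_ij == 5

    def test_empty_file_gives_empty_table(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        p.write_text("drug\tae_code\n")
        table = read_pairs(p)
        assert table.total == 0 and table.shape[0] == 0

    def test_negative_count_rejected(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        p.write_text("drug\tae_code\tcount\nd1\t100.0001\t-2\n")
        with pytest.raises(ValueError, match="negative count"):
            read_pairs(p)

    def test_missing_field_names_line(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        p.write_text("drug\tae_code\nd1\t100.0001\nd2\t\n")
        with pytest.raises(ValueError, match="line 3"):
            read_pairs(p)

    def test_causality_filter_drops_unassessable(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        p.write_text(
            "drug\tae_code\tcausality\n"
            "d1\t100.0001\tCertain\nd1\t100.0001\tUnassessable\nd1\t100.0002\tpossible\n"
        )
        table = read_pairs(p)
        assert table.total == 2

    def test_round_trip(self, tmp_path, random_table):
        path = tmp_path / "out.tsv"
        write_pairs(random_table, path)
        back = read_pairs(path)
        a = random_table.to_frame().loc[back.ae_ids, back.drug_ids]
        assert (a.to_numpy() == back.counts).all()
        assert back.total == random_table.total

    def test_hierarchy_round_trip(self, tmp_path, small_tree):
        path = tmp_path / "tree.tsv"
        write_hierarchy(small_tree, path)
        back = read_hierarchy(path)
        assert back.parent == small_tree.parent


class TestHierarchy:
    def test_orphan_pt_rejected(self):
        with pytest.raises(ValueError, match="parent"):
            Hierarchy(soc_ids=("100",), pt_ids=("100.1", "200.1"), parent={"100.1": "100"})

    def test_childless_soc_rejected(self):
        with pytest.raises(ValueError, match="children"):
            Hierarchy(
                soc_ids=("100", "200"), pt_ids=("100.1",), parent={"100.1": "100"}
            )

    def test_membership_matrix_rows_partition_leaves(self, small_tree):
        m = small_tree.membership_matrix()
        assert m.shape == (3, 7)
        assert (m.sum(axis=0) == 1).all()


class TestSocAggregation:
    def test_two_pts_one_soc(self):
        tree = Hierarchy(("100",), ("100.1", "100.2"), {"100.1": "100", "100.2": "100"})
        table = DrugEventTable([[3, 4], [1, 0]], ["100.1", "100.2"], ["d1", "d2"])
        soc = aggregate_to_soc(table, tree)
        assert soc.counts.tolist() == [[4, 4]]
        assert soc.level == Level.SOC

    def test_identity_tree_is_relabelling(self, rng):
        tree = Hierarchy(("1", "2"), ("1.1", "2.1"), {"1.1": "1", "2.1": "2"})
        counts = rng.integers(0, 9, size=(2, 3))
        table = DrugEventTable(counts, ["1.1", "2.1"], ["a", "b", "c"])
        soc = aggregate_to_soc(table, tree)
        assert (soc.counts == counts).all()

    def test_margins_and_total_preserved(self, random_table, small_tree):
        soc = aggregate_to_soc(random_table, small_tree)
        # direct summation oracle
        expected = {
            s: random_table.to_frame().loc[
                [p for p in small_tree.pt_ids if small_tree.parent[p] == s]
            ].sum(axis=0)
            for s in small_tree.soc_ids
        }
        for s in small_tree.soc_ids:
            assert (soc.to_frame().loc[s] == expected[s]).all()
        assert (soc.drug_margins == random_table.drug_margins).all()
        assert soc.total == random_table.total

    def test_soc_column_consistency_with_two_by_two(self, random_table, small_tree):
        soc = aggregate_to_soc(random_table, small_tree)
        for drug in random_table.drug_ids:
            for s in small_tree.soc_ids:
                kids = [p for p in small_tree.pt_ids if small_tree.parent[p] == s]
                total = sum(random_table.two_by_two(p, drug).n_ij for p in kids)
                assert soc.two_by_two(s, drug).n_ij == total

    def test_orphan_pt_reported(self, random_table):
        tree = Hierarchy(("100",), ("100.0001",), {"100.0001": "100"})
        with pytest.raises(KeyError, match="missing"):
            aggregate_to_soc(random_table, tree)


class TestTwoByTwoProperties:
    """Any four non-negative raw cells (a, b, c, d) form a valid 2x2."""

    @settings(max_examples=100, derandomize=True)
    @given(
        a=st.integers(0, 1000), b=st.integers(0, 1000),
        c=st.integers(0, 1000), d=st.integers(0, 1000),
    )
    def test_margins_round_trip_to_cells(self, a, b, c, d):
        t = TwoByTwo(a, a + b, a + c, a + b + c + d)
        assert (t.ae_other_drugs, t.other_aes_drug, t.other_cell) == (b, c, d)
        assert 0 <= t.expected <= t.n_dot_dot or t.n_dot_dot == 0

    @settings(max_examples=100, derandomize=True)
    @given(
        soc=st.integers(1, 9999), pt=st.integers(0, 9999),
        it=st.integers(0, 999) | st.none(),
    )
    def test_dotted_code_round_trip(self, soc, pt, it):
        code = f"{soc}.{pt:04d}" + (f".{it:03d}" if it is not None else "")
        parsed = parse_whoart_code(code)
        assert parsed.dotted == code
        assert parsed.level == ("pt" if it is None else "it")


class TestSignalDecision:
    def test_bound_methods_signal_above_cutoff(self):
        d = SignalDecision(Method.ROR, Level.PT, "x", estimate=3.0, bound=2.5, cutoff=2.0)
        assert d.is_signal
        d = SignalDecision(Method.ROR, Level.PT, "x", estimate=3.0, bound=1.5, cutoff=2.0)
        assert not d.is_signal

    def test_pvalue_methods_signal_below_cutoff(self):
        d = SignalDecision(Method.LRT, Level.PT, "x", estimate=9.0, bound=0.01, cutoff=0.05)
        assert d.is_signal
        d = SignalDecision(Method.TREESCAN, Level.SOC, "x", estimate=9.0, bound=0.2, cutoff=0.05)
        assert not d.is_signal

    def test_undefined_bound_never_signals(self):
        d = SignalDecision(Method.ROR, Level.PT, "x", estimate=float("nan"),
                           bound=float("nan"), cutoff=2.0)
        assert not d.is_signal
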