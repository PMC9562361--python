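"""Chain filters, clonotype assembly, clonality, dynamics, top clonotypes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cribsc import synth, tcr


def _chains(rows):
    return pd.DataFrame(rows, columns=["barcode", "chain", "cdr3_nt",
                                       "productive", "condition"])


def _table_from_counts(counts: dict[str, tuple[int, int]]) -> tcr.ClonotypeTable:
    """Build a ClonotypeTable directly from {clonotype: (n_benign, n_tumor)}."""
    rows = []
    cell_rows = []
    for i, (cid, (nb, nt)) in enumerate(sorted(counts.items())):
        key = (("TRA", f"seq{i}"), ("TRB", f"seq{i}b"))
        rows.append({"clonotype": cid, "key": key, "n_cells": nb + nt,
                     "n_tra": 1, "n_trb": 1, "flag_2a2b": False,
                     "n_benign": nb, "n_tumor": nt})
        for j in range(nb):
            cell_rows.append({"barcode": f"{cid}_b{j}", "condition": "benign",
                              "clonotype": cid})
        for j in range(nt):
            cell_rows.append({"barcode": f"{cid}_t{j}", "condition": "tumor",
                              "clonotype": cid})
    cells = pd.DataFrame(cell_rows).set_index("barcode") if cell_rows else \
        pd.DataFrame(columns=["condition", "clonotype"])
    return tcr.ClonotypeTable(
        clonotypes=pd.DataFrame(rows).set_index("clonotype"), cells=cells)


class TestFilterCells:
    def test_five_productive_removed(self):
        rows = [("c1", "TRA", f"s{i}", True, "benign") for i in range(5)]
        rows += [("c2", "TRA", "x", True, "benign"),
                 ("c2", "TRB", "y", True, "benign")]
        out = tcr.filter_cells(_chains(rows))
        assert set(out["barcode"]) == {"c2"}

    def test_nonproductive_chains_not_counted(self):
        rows = [("c1", "TRA", f"s{i}", True, "benign") for i in range(4)]
        rows += [("c1", "TRA", f"n{i}", False, "benign") for i in range(2)]
        out = tcr.filter_cells(_chains(rows))
        assert set(out["barcode"]) == {"c1"}

    def test_standard_pair_retained(self):
        rows = [("c1", "TRA", "x", True, "benign"),
                ("c1", "TRB", "y", True, "benign")]
        assert len(tcr.filter_cells(_chains(rows))) == 2


class TestAssembleClonotypes:
    def test_identical_keys_share_clonotype(self):
        rows = [("c1", "TRA", "x", True, "benign"),
                ("c1", "TRB", "y", True, "benign"),
                ("c2", "TRA", "x", True, "tumor"),
                ("c2", "TRB", "y", True, "tumor")]
        table = tcr.assemble_clonotypes(_chains(rows))
        assert len(table.clonotypes) == 1
        assert table.clonotypes["n_cells"].iloc[0] == 2
        assert table.clonotypes["n_benign"].iloc[0] == 1
        assert table.clonotypes["n_tumor"].iloc[0] == 1

    def test_two_alpha_one_beta_valid(self):
        rows = [("c1", "TRA", "x", True, "benign"),
                ("c1", "TRA", "x2", True, "benign"),
                ("c1", "TRB", "y", True, "benign")]
        table = tcr.assemble_clonotypes(_chains(rows))
        assert len(table.clonotypes) == 1
        assert not table.clonotypes["flag_2a2b"].iloc[0]

    def test_exact_key_grouping_distinguishes(self):
        rows = [("c1", "TRA", "x", True, "benign"),
                ("c1", "TRB", "y", True, "benign"),
                ("c2", "TRA", "x", True, "benign"),
                ("c2", "TRB", "z", True, "benign")]
        table = tcr.assemble_clonotypes(_chains(rows))
        assert len(table.clonotypes) == 2

    def test_2a2b_retained_but_flagged(self):
        rows = [("c1", "TRA", "x", True, "benign"),
                ("c1", "TRA", "x2", True, "benign"),
                ("c1", "TRB", "y", True, "benign"),
                ("c1", "TRB", "y2", True, "benign")]
        table = tcr.assemble_clonotypes(_chains(rows))
        assert table.clonotypes["flag_2a2b"].iloc[0]

    def test_nonproductive_ignored_in_key(self):
        rows = [("c1", "TRA", "x", True, "benign"),
                ("c1", "TRB", "y", True, "benign"),
                ("c1", "TRB", "junk", False, "benign"),
                ("c2", "TRA", "x", True, "benign"),
                ("c2", "TRB", "y", True, "benign")]
        table = tcr.assemble_clonotypes(_chains(rows))
        assert len(table.clonotypes) == 1

    def test_barcode_in_exactly_one_clonotype(self):
        chains, _ = synth.generate_tcr([0.4, 0.3, 0.3], [0.3, 0.3, 0.4],
                                       {"benign": 100, "tumor": 100}, seed=4)
        table = tcr.assemble_clonotypes(tcr.filter_cells(chains))
        assert table.cells.index.is_unique
        assert table.clonotypes["n_cells"].sum() == len(table.cells)


class TestSimpsonClonality:
    def test_monoclonal_is_one(self):
        assert tcr.simpson_clonality([1.0]) == 1.0

    @pytest.mark.parametrize("k", [2, 4, 9, 16])
    def test_uniform_is_inverse_sqrt_k(self, k):
        assert tcr.simpson_clonality([1 / k] * k) == pytest.approx(
            k ** -0.5, abs=1e-12)

    def test_three_clonotype_oracle(self):
        # sqrt(0.5^2 + 0.25^2 + 0.25^2) = sqrt(0.375)
        got = tcr.simpson_clonality([0.5, 0.25, 0.25])
        assert got == pytest.approx(np.sqrt(0.375), abs=1e-12)
        assert got == pytest.approx(0.612372, abs=1e-6)

    def test_errors(self):
        with pytest.raises(ValueError):
            tcr.simpson_clonality([])
        with pytest.raises(ValueError):
            tcr.simpson_clonality([0.5, 0.4])

    @given(st.lists(st.integers(1, 50), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_bounds(self, counts):
        p = np.asarray(counts) / np.sum(counts)
        c = tcr.simpson_clonality(p)
        k = len(counts)
        assert k ** -0.5 - 1e-12 <= c <= 1.0 + 1e-12

    @given(st.lists(st.integers(1, 50), min_size=2, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_merging_never_decreases(self, counts):
        n = np.sum(counts)
        p = np.asarray(counts) / n
        merged = np.r_[p[0] + p[1], p[2:]]
        assert tcr.simpson_clonality(merged) >= tcr.simpson_clonality(p) - 1e-12


class TestRichness:
    def test_all_singletons(self):
        t = _table_from_counts({f"c{i}": (1, 0) for i in range(10)})
        assert tcr.richness(t, "benign") == 100.0

    def test_single_clonotype(self):
        t = _table_from_counts({"c0": (10, 0)})
        assert tcr.richness(t, "benign") == 10.0

    def test_mixed(self):
        t = _table_from_counts({"a": (4, 0), "b": (2, 0), "c": (1, 0), "d": (1, 0)})
        assert tcr.richness(t, "benign") == 50.0

    def test_empty_errors(self):
        t = _table_from_counts({"c0": (5, 0)})
        with pytest.raises(ValueError):
            tcr.richness(t, "tumor")


class TestClassifyDynamics:
    def test_boundary_exactly_double_is_expanded(self):
        # freq_tumor = 2 x freq_benign exactly (10/100 vs 5/100)
        t = _table_from_counts({"c0": (5, 10), "pad": (95, 90)})
        dyn = tcr.classify_dynamics(t)
        assert dyn.loc["c0", "class"] == "expanded"

    def test_boundary_exactly_half_is_contracted(self):
        t = _table_from_counts({"c0": (10, 5), "pad": (90, 95)})
        dyn = tcr.classify_dynamics(t)
        assert dyn.loc["c0", "class"] == "contracted"

    def test_exclusive_with_two_cells(self):
        t = _table_from_counts({"tum2": (0, 2), "ben2": (2, 0), "pad": (50, 50)})
        dyn = tcr.classify_dynamics(t)
        assert dyn.loc["tum2", "class"] == "expanded"
        assert dyn.loc["ben2", "class"] == "contracted"

    def test_exclusive_single_cell_unclassified(self):
        t = _table_from_counts({"tum1": (0, 1), "ben1": (1, 0), "pad": (50, 50)})
        dyn = tcr.classify_dynamics(t)
        assert dyn.loc["tum1", "class"] == "unclassified"
        assert dyn.loc["ben1", "class"] == "unclassified"

    def test_in_between_unchanged(self):
        t = _table_from_counts({"c0": (40, 50), "pad": (960, 950)})
        dyn = tcr.classify_dynamics(t)
        assert dyn.loc["c0", "class"] == "unchanged"

    def test_antisymmetry_under_condition_swap(self, rng):
        swap = {"expanded": "contracted", "contracted": "expanded",
                "unchanged": "unchanged", "unclassified": "unclassified"}
        for _ in range(100):
            k = int(rng.integers(2, 15))
            nb = rng.integers(0, 20, size=k)
            nt = rng.integers(0, 20, size=k)
            alive = (nb + nt) > 0
            nb, nt = nb[alive], nt[alive]
            if len(nb) == 0 or nb.sum() == 0 or nt.sum() == 0:
                continue
            fwd = tcr.classify_dynamics(_table_from_counts(
                {f"c{i}": (int(nb[i]), int(nt[i])) for i in range(len(nb))}))
            rev = tcr.classify_dynamics(_table_from_counts(
                {f"c{i}": (int(nt[i]), int(nb[i])) for i in range(len(nb))}))
            assert (fwd["class"].map(swap) == rev["class"]).all()


class TestTopClonotypes:
    def test_tie_order_deterministic(self):
        t = _table_from_counts({"a": (2, 3), "b": (1, 4), "c": (2, 1)})
        top = tcr.top_clonotypes(t, n=2)
        # sizes: a=5, b=5, c=3; tie a/b broken by tumor cells desc -> b first
        assert top.index.tolist() == ["b", "a"]

    def test_n_beyond_count_returns_all(self):
        t = _table_from_counts({f"c{i}": (1, 1) for i in range(10)})
        assert len(tcr.top_clonotypes(t, n=20)) == 10

    def test_matches_bruteforce_sort(self, rng):
        counts = {f"c{i:02d}": (int(rng.integers(0, 30)), int(rng.integers(0, 30)))
                  for i in range(40)}
        counts = {k: v for k, v in counts.items() if sum(v) > 0}
        t = _table_from_counts(counts)
        top = tcr.top_clonotypes(t, n=15)
        oracle = sorted(counts.items(),
                        key=lambda kv: (-(kv[1][0] + kv[1][1]), -kv[1][1], kv[0]))
        assert top.index.tolist() == [k for k, _ in oracle[:15]]

    def test_cluster_counts_sum_to_size(self):
        t = _table_from_counts({"a": (2, 2), "b": (1, 0)})
        clusters = pd.Series(
            {bc: ("t1" if i % 2 else "t2") for i, bc in enumerate(t.cells.index)})
        top = tcr.top_clonotypes(t, n=5, clusters=clusters)
        cl_cols = [c for c in top.columns if c.startswith("cluster_")]
        assert (top[cl_cols].sum(axis=1) == top["n_cells"]).all()


class TestParameterRecovery:
    def test_fourfold_shifts_recovered(self):
        """>= 95% of >=4-fold shifted clonotypes classified correctly."""
        rng = np.random.default_rng(99)
        k = 40
        base = np.full(k, 1.0 / k)
        shift = np.ones(k)
        shift[:5] = 4.0
        shift[5:10] = 0.25
        ft = base * shift
        ft /= ft.sum()
        fb = base
        chains, truth = synth.generate_tcr(
            fb, ft, {"benign": 1000, "tumor": 1000},
            nonproductive_rate=0.0, seed=17)
        table = tcr.assemble_clonotypes(chains)
        dyn = tcr.classify_dynamics(table)
        # map generator clonotype index -> assembled id via the cells table
        joined = table.cells.join(truth[["clonotype"]], rsuffix="_true")
        id_map = joined.groupby("clonotype_true")["clonotype"].first()
        correct = 0
        for idx, expected in [(i, "expanded") for i in range(5)] + \
                             [(i, "contracted") for i in range(5, 10)]:
            cid = id_map.get(idx)
            correct += cid is not None and dyn.loc[cid, "class"] == expected
        assert correct / 10 >= 0.95
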