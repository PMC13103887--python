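import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from datediag import (
    TopologyMismatchError,
    UndatedTree,
    ValidationError,
    attach_dates,
    match_branches,
    parse_newick,
    split_root_substitutions,
    tree_summary_stats,
    write_newick,
)
from datediag.phylo import dates_from_labels, matched_branch_values
from datediag.simulate import sim_coalescent_constant, uniform_dates


class TestParseNewick:
    def test_three_tip_tree(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        assert t.n_tips == 3
        assert len(t.children[t.root]) == 2
        assert sorted(t.tip_labels) == ["A", "B", "C"]

    def test_two_tip_tree(self):
        t = parse_newick("(A:1,B:2);")
        assert t.n_tips == 2
        a, b = (t.tip_labels.index(x) for x in "AB")
        assert t.lengths[a] == 1 and t.lengths[b] == 2

    def test_negative_branch_length_rejected(self):
        with pytest.raises(ValidationError):
            parse_newick("(A:1,B:-2);")

    def test_malformed_string_rejected(self):
        from datediag import NewickParseError

        with pytest.raises(NewickParseError):
            parse_newick("((A:1,B:1:1,C")

    @pytest.mark.parametrize("seed", range(20))
    def test_roundtrip_random_coalescent_trees(self, seed):
        """write o parse preserves topology and branch lengths to 1e-9."""
        rng = np.random.default_rng(seed)
        D = sim_coalescent_constant(uniform_dates(12, 2000, 2010, rng), 1.0, rng)
        s = write_newick(D)
        t2 = parse_newick(s, unit="years")
        assert sorted(t2.tip_labels) == sorted(D.tip_labels)
        # compare branch lengths via leaf-set identification
        d1 = {lab: float(D.lengths[i]) for i, lab in enumerate(D.tip_labels)}
        d2 = {lab: float(t2.lengths[i]) for i, lab in enumerate(t2.tip_labels)}
        for lab in d1:
            assert abs(d1[lab] - d2[lab]) < 1e-9
        # and the full tree round-trips again identically
        assert write_newick(t2) == s


class TestAttachDates:
    def test_two_tip_consistent(self):
        t = parse_newick("(A:1,B:2);", unit="years")
        D = attach_dates(t, {"A": 2011, "B": 2012})
        assert D.dates[D.root] == pytest.approx(2010)

    def test_inconsistent_dates_rejected(self):
        t = parse_newick("(A:1,B:2);", unit="years")
        with pytest.raises(ValidationError):
            attach_dates(t, {"A": 2011, "B": 2011})

    def test_missing_tip_date_rejected(self):
        t = parse_newick("(A:1,B:2);", unit="years")
        with pytest.raises(ValidationError):
            attach_dates(t, {"A": 2011})

    def test_simulated_tree_roundtrips_node_dates(self, rng):
        D = sim_coalescent_constant(uniform_dates(15, 2005, 2015, rng), 1.0, rng)
        t = parse_newick(write_newick(D), unit="years")
        dates = {lab: float(D.dates[i]) for i, lab in enumerate(D.tip_labels)}
        D2 = attach_dates(t, dates)
        assert D2.dates[D2.root] == pytest.approx(D.dates[D.root], abs=1e-8)

    def test_dates_from_labels(self):
        assert dates_from_labels(["x|2011.5", "y|2012"]) == {
            "x|2011.5": 2011.5,
            "y|2012": 2012.0,
        }


def _undated_like(D):
    """Copy the topology of a dated tree into an undated tree with its lengths."""
    return UndatedTree(D.parent, np.where(D.parent >= 0, D.lengths, np.nan), D.tip_labels)


class TestMatchBranches:
    def test_identical_topology_full_match(self, rng):
        D = sim_coalescent_constant(uniform_dates(10, 2000, 2010, rng), 1.0, rng)
        L = _undated_like(D)
        corr = match_branches(D, L)
        assert corr.n_branches == 2 * 10 - 2
        assert len(corr.pairs) == 2 * 10 - 4

    def test_child_order_permutation_invariant(self, rng):
        D = sim_coalescent_constant(uniform_dates(8, 2000, 2010, rng), 1.0, rng)
        L = _undated_like(D)
        for v in range(L.n_nodes):
            L.children[v] = L.children[v][::-1]
        corr = match_branches(D, L)
        assert corr.n_branches == 2 * 8 - 2

    def test_nni_move_detected(self, rng):
        # D = ((A,B),(C,D)); L = ((A,C),(B,D)) is one NNI away
        D = attach_dates(
            parse_newick("((A:1,B:1):1,(C:1,D:1):1);", unit="years"),
            {"A": 2, "B": 2, "C": 2, "D": 2},
        )
        L = parse_newick("((A:1,C:1):1,(B:1,D:1):1);")
        with pytest.raises(TopologyMismatchError) as exc:
            match_branches(D, L)
        assert len(exc.value.bipartitions) >= 1

    def test_leaf_set_mismatch(self, rng):
        D = attach_dates(
            parse_newick("((A:1,B:1):1,C:2);", unit="years"), {"A": 2, "B": 2, "C": 2}
        )
        L = parse_newick("((A:1,B:1):1,X:2);")
        with pytest.raises(TopologyMismatchError):
            match_branches(D, L)

    def test_root_pair_substitutions_pooled(self):
        D = attach_dates(
            parse_newick("((A:1,B:1):1,C:2);", unit="years"), {"A": 2, "B": 2, "C": 2}
        )
        L = parse_newick("((A:3,B:4):5,C:6);")
        corr = match_branches(D, L)
        assert corr.root_x_subs == pytest.approx(11.0)  # 5 + 6


class TestSplitRoot:
    @pytest.mark.parametrize(
        "l_x,d_a,d_b,expected",
        [(10, 3, 7, (3, 7)), (5, 2, 2, (2.5, 2.5)), (0, 1, 9, (0, 0)), (4, 0, 0, (2, 2))],
    )
    def test_examples(self, l_x, d_a, d_b, expected):
        assert split_root_substitutions(l_x, d_a, d_b) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            split_root_substitutions(-1, 1, 1)

    @given(
        l_x=st.floats(0, 1e6),
        d_a=st.floats(0, 1e3),
        d_b=st.floats(0, 1e3),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_conserves_total(self, l_x, d_a, d_b):
        l_a, l_b = split_root_substitutions(l_x, d_a, d_b)
        assert l_a + l_b == pytest.approx(l_x, rel=1e-12, abs=1e-12)
        assert l_a >= 0 and l_b >= 0


class TestSummaryStats:
    def test_three_tip_stemminess(self):
        # internal branch lengths sum to 2, total 10
        t = parse_newick("((A:2,B:3):2,C:3);")
        s = tree_summary_stats(t)
        assert s["stemminess"] == pytest.approx(0.2)

    def test_constant_branches(self):
        t = parse_newick("((A:3,B:3):3,C:3);")
        s = tree_summary_stats(t)
        assert s["mean"] == pytest.approx(3)
        assert s["variance"] == pytest.approx(0)
        assert s["max"] == pytest.approx(3)

    def test_zero_total_rejected(self):
        t = parse_newick("((A:0,B:0):0,C:0);")
        with pytest.raises(ValidationError):
            tree_summary_stats(t)

    @pytest.mark.parametrize("seed", range(25))
    def test_against_edge_list_oracle(self, seed):
        """Stats recomputed independently from the flat edge list agree."""
        rng = np.random.default_rng(seed)
        D = sim_coalescent_constant(uniform_dates(10, 2000, 2010, rng), 1.0, rng)
        s = tree_summary_stats(D)
        edges = [
            (int(v), float(D.lengths[v]), bool(v >= D.n_tips))
            for v in range(D.n_nodes)
            if D.parent[v] >= 0
        ]
        lens = [e[1] for e in edges]
        internal = sum(e[1] for e in edges if e[2])
        assert s["mean"] == pytest.approx(np.mean(lens))
        assert s["variance"] == pytest.approx(np.var(lens, ddof=1))
        assert s["max"] == pytest.approx(max(lens))
        assert s["stemminess"] == pytest.approx(internal / sum(lens))


def test_matched_branch_values_cover_all_branches(rng):
    D = sim_coalescent_constant(uniform_dates(10, 2000, 2010, rng), 1.0, rng)
    L = _undated_like(D)
    nodes, d_vals, l_vals = matched_branch_values(D, L)
    assert len(nodes) == 2 * 10 - 2
    assert np.all(d_vals >= 0) and np.all(l_vals >= 0)
    # total substitutions conserved through the root split
    assert l_vals.sum() == pytest.approx(np.nansum(L.lengths))
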