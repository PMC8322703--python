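import itertools

import networkx as nx
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cernet.cerna import (
    attach_circrnas,
    build_network,
    coverage_filter,
    intersect_three_dbs,
    load_table3,
    rank_cerna_mcc,
    validate_directions,
)


def _targets(rows):
    return pd.DataFrame(rows, columns=["mirna", "mrna", "source"])


class TestIntersectThreeDbs:
    def test_intersection_semantics(self):
        rows = [("m1", "g1", s) for s in ("db1", "db2", "db3")] + \
               [("m2", "g2", s) for s in ("db1", "db2")] + \
               [("m3", "g3", "db3")]
        assert intersect_three_dbs(_targets(rows)) == {("m1", "g1")}

    def test_toy_tables_two_common(self):
        common = [("mA", "gA"), ("mB", "gB")]
        rows = []
        extra = {"db1": 3, "db2": 2, "db3": 1}
        for db, n in extra.items():
            rows += [(m, g, db) for m, g in common]
            rows += [(f"x{db}{i}", f"y{db}{i}", db) for i in range(n)]
        assert intersect_three_dbs(_targets(rows)) == set(common)

    def test_fewer_than_three_sources_errors(self):
        with pytest.raises(ValueError, match="3"):
            intersect_three_dbs(_targets([("m", "g", "db1"),
                                          ("m", "g", "db2")]))


class TestValidateDirections:
    DEMIS = {"miDown": "down", "miUp": "up"}

    def test_opposite_direction_kept(self):
        kept = validate_directions({("miDown", "G")}, self.DEMIS, {"G": "up"})
        assert kept == {("miDown", "G")}

    def test_same_direction_dropped(self):
        assert validate_directions({("miUp", "G")}, self.DEMIS,
                                   {"G": "up"}) == set()

    def test_mirna_absent_from_demis_dropped(self):
        assert validate_directions({("miGhost", "G")}, self.DEMIS,
                                   {"G": "up"}) == set()

    @given(st.lists(st.tuples(st.sampled_from(["up", "down"]),
                              st.sampled_from(["up", "down"])), max_size=20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_never_outputs_same_direction_pair(self, dirs):
        pairs = {(f"mi{i}", f"g{i}") for i in range(len(dirs))}
        demis = {f"mi{i}": d[0] for i, d in enumerate(dirs)}
        genes = {f"g{i}": d[1] for i, d in enumerate(dirs)}
        kept = validate_directions(pairs, demis, genes)
        for mi, g in kept:
            assert demis[mi] != genes[g]


class TestAttachCircrnas:
    def test_gene_without_circ_supported_mirna_dropped(self):
        pairs = {("mi1", "G1"), ("mi2", "G2")}
        circ = [("c1", "mi2")]
        kept, candidates, dropped = attach_circrnas(pairs, circ)
        assert kept == {"G2"} and dropped == {"G1"}
        assert candidates == {"c1"}

    def test_gene_with_one_supported_mirna_kept(self):
        pairs = {("mi1", "G"), ("mi2", "G")}
        kept, _, dropped = attach_circrnas(pairs, [("c1", "mi2")])
        assert kept == {"G"} and not dropped

    def test_toy_three_genes_one_dropped(self):
        pairs = {("m1", "g1"), ("m2", "g2"), ("m3", "g3")}
        circ = [("c1", "m1"), ("c2", "m2")]
        kept, _, dropped = attach_circrnas(pairs, circ)
        assert len(dropped) == 1 and dropped == {"g3"}


class TestCoverageFilter:
    def test_full_cover_retained_partial_dropped(self):
        pairs = {("m1", "g1"), ("m2", "g2"), ("m3", "g3")}
        circ = [("cAll", "m1"), ("cAll", "m2"), ("cAll", "m3"),
                ("cTwo", "m1"), ("cTwo", "m2")]
        kept, candidates, _ = attach_circrnas(pairs, circ)
        retained = coverage_filter(candidates, kept, pairs, circ)
        assert retained == {"cAll"}

    def test_single_mrna_any_touching_circ_retained(self):
        pairs = {("m1", "G"), ("m2", "G")}
        circ = [("c1", "m1")]
        retained = coverage_filter({"c1"}, {"G"}, pairs, circ)
        assert retained == {"c1"}

    def test_empty_circ_table_retains_nothing(self):
        assert coverage_filter(set(), {"G"}, {("m", "G")}, []) == set()

    @given(st.integers(1, 4), st.integers(1, 4), st.integers(2, 5),
           st.integers(0, 2 ** 16 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_exhaustive_oracle(self, n_circ, n_mrna, n_mi, bits):
        """Random instances: the filter equals a double loop over all
        (circRNA, mRNA) combinations checking for a shared miRNA."""
        import random
        r = random.Random(bits)
        mis = [f"m{i}" for i in range(n_mi)]
        pairs = {(m, f"g{j}") for j in range(n_mrna)
                 for m in r.sample(mis, r.randint(1, n_mi))}
        circ = {(f"c{i}", m) for i in range(n_circ)
                for m in r.sample(mis, r.randint(0, n_mi))}
        kept, candidates, _ = attach_circrnas(pairs, circ)
        got = coverage_filter(candidates, kept, pairs, circ)
        expected = set()
        for c in candidates:
            c_mis = {m for cc, m in circ if cc == c}
            covers_all = True
            for g in kept:
                g_mis = {m for m, gg in pairs if gg == g}
                if not (c_mis & g_mis):
                    covers_all = False
            if covers_all:
                expected.add(c)
        assert got == expected


class TestBuildNetwork:
    def test_toy_counts(self):
        pairs = {("m1", "g1"), ("m2", "g2")}
        circ = [("c1", "m1"), ("c1", "m2")]
        net = build_network({"c1"}, {"g1", "g2"}, pairs, circ)
        assert net.number_of_nodes() == 5
        assert net.number_of_edges() == 4

    def test_mirna_without_retained_circ_excluded(self):
        pairs = {("m1", "g1"), ("mLoose", "g1")}
        circ = [("c1", "m1")]
        net = build_network({"c1"}, {"g1"}, pairs, circ)
        assert "mLoose" not in net

    def test_kinds_partition_and_no_forbidden_edges(self):
        pairs = {("m1", "g1"), ("m2", "g1"), ("m2", "g2")}
        circ = [("c1", "m1"), ("c1", "m2"), ("c2", "m2")]
        net = build_network({"c1", "c2"}, {"g1", "g2"}, pairs, circ,
                            dirs={"g1": "up", "g2": "down"})
        kinds = nx.get_node_attributes(net, "kind")
        assert set(kinds.values()) <= {"circRNA", "miRNA", "mRNA"}
        for a, b in net.edges:
            assert {kinds[a], kinds[b]} in ({"circRNA", "miRNA"},
                                            {"miRNA", "mRNA"})


class TestRankCernaMcc:
    def test_tree_mcc_equals_degree(self):
        pairs = {("m1", "g1"), ("m1", "g2"), ("m2", "g3")}
        circ = [("c1", "m1"), ("c1", "m2")]
        net = build_network({"c1"}, {"g1", "g2", "g3"}, pairs, circ)
        from cernet.centrality import centrality
        mcc = centrality(net, "MCC")
        deg = dict(net.degree)
        assert mcc == {v: float(d) for v, d in deg.items()}

    def test_hub_mirna_ranks_first(self):
        pairs = {("hubmi", f"g{i}") for i in range(4)}
        circ = [("c1", "hubmi")]
        net = build_network({"c1"}, {f"g{i}" for i in range(4)}, pairs, circ)
        assert rank_cerna_mcc(net)[0] == "hubmi"

    def test_top_larger_than_graph_gives_full_ordering(self):
        net = build_network({"c"}, {"g"}, {("m", "g")}, [("c", "m")])
        assert len(rank_cerna_mcc(net, top=99)) == 3


class TestTable3:
    def test_fixture_has_45_pairs_14_mrnas(self):
        t3 = load_table3()
        assert len(t3) == 45
        assert t3["mrna"].nunique() == 14
        assert not t3.duplicated(["mirna", "mrna"]).any()

    def test_direction_validation_reproduces_all_45_pairs(self):
        """A prediction set matching the published table, with every miRNA
        differentially expressed opposite to its target, validates to
        exactly the 45 published pairs."""
        t3 = load_table3()
        pairs = set(zip(t3["mirna"], t3["mrna"]))
        dirs = dict(zip(t3["mrna"], t3["direction"]))
        opposite = {"up": "down", "down": "up"}
        demis = {mi: opposite[dirs[g]] for mi, g in pairs}
        assert validate_directions(pairs, demis, dirs) == pairs
        assert len(validate_directions(pairs, demis, dirs)) == 45

    def test_circ_support_rule_drops_cst4_and_ctsg(self):
        """With hsa-miR-1293 and hsa-miR-3664-5p lacking circRNA partners
        (each the sole miRNA of its gene) and every other miRNA supported,
        exactly CST4 and CTSG fall out, leaving 12 mRNA nodes."""
        t3 = load_table3()
        pairs = set(zip(t3["mirna"], t3["mrna"]))
        unsupported = {"hsa-miR-1293", "hsa-miR-3664-5p"}
        circ = [(f"circ_{i}", mi) for i, mi in
                enumerate(sorted(set(t3["mirna"]) - unsupported))]
        kept, _, dropped = attach_circrnas(pairs, circ)
        assert dropped == {"CST4", "CTSG"}
        assert len(kept) == 12
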