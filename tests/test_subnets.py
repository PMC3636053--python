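import networkx as nx
import numpy as np
import pytest

from oracles import flood_fill_components
from pspnet.datatypes import DetectionProfile, PathwayGraph
from pspnet.subnets import candidate_proteins, extract_pds, pds_catalogue


def _profiles(spec):
    """spec: {class_label: [detected-set, ...]}"""
    out = []
    for lab, sets in spec.items():
        for i, s in enumerate(sets):
            out.append(DetectionProfile(f"{lab}{i}", lab, frozenset(s)))
    return out


def _pathway(pid, edges, nodes=()):
    g = nx.Graph()
    g.add_edges_from(edges)
    g.add_nodes_from(nodes)
    return PathwayGraph(pid, pid, g)


class TestCandidates:
    def test_at_least_half_is_ceiling(self):
        # X in 3/5 of class A only: included (ceil(5/2) = 3)
        spec = {
            "A": [{"X"}, {"X"}, {"X"}, {"Y"}, {"Y"}],
            "B": [{"Z"}] * 7,
        }
        cands = candidate_proteins(_profiles(spec))
        assert "X" in cands and "Z" in cands

    def test_below_half_in_both_classes_excluded(self):
        spec = {
            "A": [{"X"}, {"X"}, set("Q"), set("Q"), set("Q")],
            "B": [{"X"}, {"X"}, {"X"}, {"Q"}, {"Q"}, {"Q"}, {"Q"}],
        }
        # X: 2/5 of A (needs 3) and 3/7 of B (needs 4) -> excluded
        assert "X" not in candidate_proteins(_profiles(spec))

    def test_single_patient_class_keeps_everything(self):
        spec = {"A": [{"X", "Y"}], "B": [{"Z"}]}
        assert candidate_proteins(_profiles(spec)) == {"X", "Y", "Z"}

    def test_requires_two_classes(self):
        with pytest.raises(ValueError):
            candidate_proteins(_profiles({"A": [{"X"}, {"Y"}]}))


class TestExtract:
    def test_path_graph_induction(self):
        pw = _pathway("P", [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")])
        (pds,) = extract_pds(pw, {"A", "B", "C", "D"})
        assert pds.members == frozenset("ABCD")
        assert pds.kind == "pds" and pds.source_pathway == "P"

    def test_min_size_four_drops_three_node_component(self):
        pw = _pathway("P", [("A", "B"), ("B", "C"), ("C", "D"),
                            ("X", "Y"), ("Y", "Z")])
        out = extract_pds(pw, set("ABCDXYZ"))
        assert [f.members for f in out] == [frozenset("ABCD")]

    def test_no_candidates_empty_result(self):
        pw = _pathway("P", [("A", "B")])
        assert extract_pds(pw, {"Q"}) == []

    def test_star_graph_single_component(self):
        pw = _pathway("P", [("H", x) for x in "ABCDE"])
        (pds,) = extract_pds(pw, set("HABCDE"))
        assert pds.size == 6

    def test_members_subset_of_candidates_and_connected(self):
        rng = np.random.default_rng(5)
        pw = _pathway("P", [(f"n{a}", f"n{b}")
                            for a, b in rng.integers(0, 30, size=(60, 2))
                            if a != b])
        cands = {f"n{i}" for i in rng.choice(30, size=18, replace=False)}
        for pds in extract_pds(pw, cands):
            assert pds.members <= cands
            assert nx.is_connected(pw.graph.subgraph(pds.members))

    def test_monotone_under_candidate_growth(self):
        # enlarging the candidate set may merge/grow components, never split
        rng = np.random.default_rng(11)
        for _ in range(20):
            edges = [(int(a), int(b))
                     for a, b in rng.integers(0, 20, size=(30, 2)) if a != b]
            pw = _pathway("P", edges)
            nodes = sorted(pw.nodes)
            small = {n for n in nodes if rng.random() < 0.4}
            large = small | {n for n in nodes if rng.random() < 0.4}
            comps_small = extract_pds(pw, small, min_size=1)
            comps_large = extract_pds(pw, large, min_size=1)
            for c in comps_small:
                containers = [d for d in comps_large if c.members <= d.members]
                assert len(containers) == 1


class TestCatalogue:
    def test_counts_table(self):
        pws = [
            _pathway("P1", [("A", "B"), ("B", "C"), ("C", "D")]),
            _pathway("P2", [("E", "F"), ("F", "G"), ("G", "H")]),
        ]
        feats, table = pds_catalogue(pws, set("ABCDEFGH"))
        assert len(feats) == 2
        assert table["n_pds"].tolist() == [1, 1]

    def test_duplicate_pathway_ids_rejected(self):
        pws = [_pathway("P1", [("A", "B")]), _pathway("P1", [("C", "D")])]
        with pytest.raises(ValueError, match="duplicate"):
            pds_catalogue(pws, set("ABCD"))

    def test_agrees_with_flood_fill_oracle_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for trial in range(100):
            n = int(rng.integers(5, 25))
            p_edge = rng.uniform(0.05, 0.4)
            g = nx.gnp_random_graph(n, p_edge, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes})
            pw = PathwayGraph("P", "P", g)
            cands = {f"g{i}" for i in range(n) if rng.random() < 0.6}
            got = {f.members for f in extract_pds(pw, cands, min_size=1)}
            kept_nodes = pw.nodes & cands
            kept_edges = [tuple(e) for e in g.edges
                          if e[0] in cands and e[1] in cands]
            expect = set(flood_fill_components(kept_nodes, kept_edges))
            assert got == expect, f"trial {trial}"

    def test_components_partition_induced_nodes(self):
        rng = np.random.default_rng(3)
        g = nx.gnp_random_graph(30, 0.1, seed=9)
        g = nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes})
        pw = PathwayGraph("P", "P", g)
        cands = {f"g{i}" for i in rng.choice(30, 20, replace=False)}
        comps = extract_pds(pw, cands, min_size=1)
        union = set()
        for c in comps:
            assert not union & c.members  # pairwise disjoint
            union |= c.members
        assert union == pw.nodes & cands
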