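import numpy as np
import pytest
from scipy.stats import hypergeom

from oracles import transitive_ancestor_closure
from pspnet.datatypes import FeatureSet, Ontology, Term
from pspnet.ontology import (
    category_overlap,
    fcs_association,
    hypergeom_enrichment,
    informative_terms,
    propagate_annotations,
)


def _ontology(parent_map, annotations):
    terms = {t: Term(t, t, "biological_process", frozenset(ps))
             for t, ps in parent_map.items()}
    return Ontology(terms, {p: set(ts) for p, ts in annotations.items()})


class TestPropagation:
    def test_chain_counts_for_all_ancestors(self):
        ont = _ontology({"A": {"B"}, "B": {"C"}, "C": set()}, {"p1": {"A"}})
        prop = propagate_annotations(ont)
        assert prop["A"] == prop["B"] == prop["C"] == {"p1"}

    def test_diamond_counts_once(self):
        ont = _ontology(
            {"D": {"B", "C"}, "B": {"A"}, "C": {"A"}, "A": set()},
            {"p1": {"D"}},
        )
        prop = propagate_annotations(ont)
        assert prop["A"] == {"p1"}

    def test_matches_transitive_closure_oracle_on_random_dags(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = 50
            names = [f"T{i}" for i in range(n)]
            parent_map = {
                names[i]: {names[j] for j in range(i + 1, n) if rng.random() < 0.08}
                for i in range(n)
            }
            annotations = {
                f"p{k}": {names[int(rng.integers(0, n))]} for k in range(30)
            }
            ont = _ontology(parent_map, annotations)
            prop = propagate_annotations(ont)
            closure = transitive_ancestor_closure(parent_map)
            for protein, tids in annotations.items():
                covered = set()
                for t in tids:
                    covered |= {t} | closure[t]
                for term in names:
                    assert (protein in prop[term]) == (term in covered)

    def test_cycle_rejected(self):
        ont = _ontology({"A": {"B"}, "B": set()}, {})
        ont.terms["B"] = Term("B", "B", "", frozenset({"A"}))
        with pytest.raises(ValueError, match="cycle"):
            propagate_annotations(ont)


class TestInformative:
    def _with_counts(self, root_n, child_ns):
        parent_map = {"ROOT": set()}
        annotations = {}
        k = 0
        for i, cn in enumerate(child_ns):
            parent_map[f"C{i}"] = {"ROOT"}
            for _ in range(cn):
                annotations[f"p{k}"] = {f"C{i}"}
                k += 1
        extra = root_n - sum(child_ns)
        for _ in range(extra):
            annotations[f"p{k}"] = {"ROOT"}
            k += 1
        return _ontology(parent_map, annotations)

    def test_boundary_child_at_exactly_threshold_keeps_parent(self):
        ont = self._with_counts(70, [30, 10])
        assert "ROOT" in informative_terms(ont, min_count=30)

    def test_count_below_threshold_not_informative(self):
        ont = self._with_counts(29, [])
        assert "ROOT" not in informative_terms(ont, min_count=30)

    def test_child_above_threshold_disqualifies(self):
        ont = self._with_counts(100, [31, 20])
        terms = informative_terms(ont, min_count=30)
        assert "ROOT" not in terms and "C0" in terms

    def test_frontier_has_no_over_threshold_descendant(self):
        rng = np.random.default_rng(1)
        n = 40
        names = [f"T{i}" for i in range(n)]
        parent_map = {
            names[i]: ({names[int(rng.integers(i + 1, n))]} if i + 1 < n else set())
            for i in range(n)
        }
        annotations = {f"p{k}": {names[int(rng.integers(0, n))]} for k in range(400)}
        ont = _ontology(parent_map, annotations)
        prop = propagate_annotations(ont)
        info = informative_terms(ont, min_count=30, propagated=prop)
        for t in info:
            assert len(prop[t]) >= 30
            assert all(len(prop[c]) <= 30 for c in ont.children(t))


class TestHypergeom:
    def test_hand_computed_tail(self):
        # N=10, K=5, n=4, k=4 -> C(5,4)*C(5,0)/C(10,4) = 5/210
        background = {f"p{i}" for i in range(10)}
        annotated = {f"p{i}" for i in range(5)}
        feature = FeatureSet("F", {"p0", "p1", "p2", "p3"})
        res = hypergeom_enrichment(feature, "T", background, {"T": annotated})
        assert res["p_raw"] == pytest.approx(5 / 210)

    def test_zero_hits_and_empty_term_give_one(self):
        background = {f"p{i}" for i in range(10)}
        feature = FeatureSet("F", {"p0", "p1", "p2", "p3"})
        assert hypergeom_enrichment(feature, "T", background, {"T": set()})["p_raw"] == 1.0
        res0 = hypergeom_enrichment(
            FeatureSet("F2", {"p5", "p6"}), "T", background, {"T": {"p0"}})
        assert res0["k"] == 0 and res0["p_raw"] == 1.0

    def test_bonferroni_caps_at_one(self):
        background = {f"p{i}" for i in range(6)}
        feature = FeatureSet("F", {"p0", "p1"})
        res = hypergeom_enrichment(feature, "T", background, {"T": {"p5"}},
                                   n_terms_tested=50)
        assert res["p_bonferroni"] == 1.0


class TestFCS:
    def _setup(self, n_universe, n_listed):
        universe = {f"u{i}" for i in range(n_universe)}
        listed_proteins = {f"u{i}" for i in range(n_listed)}
        ont = _ontology({"L": set()}, {p: {"L"} for p in sorted(listed_proteins)})
        return universe, ont

    def test_saturated_hit_rate_gives_zero_p(self):
        universe, ont = self._setup(10, 4)
        feature = FeatureSet("F", {"u0", "u1"})
        assoc = fcs_association(feature, {"L"}, ont, universe, n_rand=200, seed=0)
        assert assoc.hit_rate == 1.0 and assoc.p_fcs == 0.0

    def test_zero_hit_rate_matches_hypergeometric_complement(self):
        universe, ont = self._setup(12, 5)
        feature = FeatureSet("F", {"u8", "u9", "u10"})
        assoc = fcs_association(feature, {"L"}, ont, universe, n_rand=4000, seed=1)
        expect = 1.0 - float(hypergeom.pmf(0, 12, 5, 3))
        se = np.sqrt(expect * (1 - expect) / 4000)
        assert abs(assoc.p_fcs - expect) < 3 * se

    def test_enumerable_universe_exact_tail(self):
        # universe of 6, 3 annotated, feature of 2 with a=1:
        # p converges to P(random a = 2) = C(3,2)/C(6,2) = 0.2
        universe, ont = self._setup(6, 3)
        feature = FeatureSet("F", {"u0", "u5"})  # one listed member
        assoc = fcs_association(feature, {"L"}, ont, universe, n_rand=6000, seed=2)
        assert assoc.a == 1
        se = np.sqrt(0.2 * 0.8 / 6000)
        assert abs(assoc.p_fcs - 0.2) < 3 * se

    def test_feature_outside_universe_rejected(self):
        universe, ont = self._setup(6, 3)
        with pytest.raises(ValueError):
            fcs_association(FeatureSet("F", {"zz"}), {"L"}, ont, universe, n_rand=10)


def test_category_overlap_regions_sum_to_union():
    sets = {
        "BP": {"a", "b", "c", "d"},
        "CC": {"c", "d", "e"},
        "MF": {"d", "e", "f"},
    }
    res = category_overlap(sets)
    region_keys = [k for k in res if k != "union"]
    assert sum(res[k] for k in region_keys) == res["union"] == 6
    assert res["BP&CC&MF"] == 1
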