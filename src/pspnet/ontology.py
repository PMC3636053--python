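"""Ontology-based analyses: informative terms, enrichment, term-set association.

Annotations are propagated from each term to all of its is_a/part_of
ancestors before counting. Informative terms form a frontier of the
ontology: propagated count at or above a threshold with no child exceeding
it — a resolution-matched vocabulary for enrichment. Enrichment of a
feature against a term uses the upper-tail hypergeometric with a
Bonferroni multiplier equal to the number of terms actually tested.

Association of a feature with a curated term list (e.g. lipid-related
terms) follows a functional-class-scoring scheme: the observed hit rate
a/n (members annotated to at least one listed term over feature size) is
compared against hit rates of random same-size protein sets drawn from the
universe; the p-value is the fraction of random sets scoring strictly
higher.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Set

import networkx as nx
import numpy as np
from scipy.stats import hypergeom

from .datatypes import FeatureSet, Ontology


def propagate_annotations(ontology: Ontology) -> Dict[str, Set[str]]:
    """Map every term to the proteins annotated to it or any descendant.

    A protein directly annotated to a term counts for all ancestors
    reachable through is_a/part_of links (set semantics — once per term no
    matter how many paths a diamond offers). Raises on a cyclic parent
    graph.
    """
    g = ontology.parent_graph()
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"ontology parent graph contains a cycle: {cycle}")
    proteins_of: Dict[str, Set[str]] = {t: set() for t in ontology.terms}
    # child -> parent edges, so topological order visits children first
    order = list(nx.topological_sort(g))
    for protein, tids in ontology.annotations.items():
        for t in tids:
            proteins_of[t].add(protein)
    for term in order:
        for parent in g.successors(term):
            proteins_of[parent] |= proteins_of[term]
    return proteins_of


def informative_terms(ontology: Ontology, min_count: int = 30,
                      propagated: Optional[Dict[str, Set[str]]] = None,
                      direct_only: bool = False) -> Set[str]:
    """Terms with >= ``min_count`` annotated proteins and no child above it.

    The child condition is strict: a child annotated to exactly
    ``min_count`` proteins does not disqualify its parent. ``direct_only``
    counts direct annotations instead of propagated ones.
    """
    if direct_only:
        counts: Dict[str, int] = {t: 0 for t in ontology.terms}
        for tids in ontology.annotations.values():
            for t in tids:
                counts[t] += 1
    else:
        if propagated is None:
            propagated = propagate_annotations(ontology)
        counts = {t: len(ps) for t, ps in propagated.items()}
    out = set()
    for term_id in ontology.terms:
        if counts.get(term_id, 0) < min_count:
            continue
        children = ontology.children(term_id)
        if all(counts.get(c, 0) <= min_count for c in children):
            out.add(term_id)
    return out


def hypergeom_enrichment(feature: FeatureSet, term_id: str, background: Set[str],
                         term_proteins: Dict[str, Set[str]],
                         n_terms_tested: int = 1) -> dict:
    """Upper-tail hypergeometric enrichment of a feature for one term.

    With N = |background|, K = proteins of the term in the background,
    n = |feature| and k = annotated members, p = P(X >= k); the Bonferroni
    value multiplies by the number of terms tested for this feature, capped
    at 1. K = 0 gives p = 1.
    """
    if not feature.members <= background:
        raise ValueError(
            f"feature {feature.feature_id!r} has members outside the background"
        )
    n_bg = len(background)
    annotated = term_proteins.get(term_id, set()) & background
    k_bg = len(annotated)
    n = feature.size
    k = len(feature.members & annotated)
    if k_bg == 0:
        p = 1.0
    else:
        p = float(hypergeom.sf(k - 1, n_bg, k_bg, n))
    return {
        "feature_id": feature.feature_id,
        "term_id": term_id,
        "N": n_bg,
        "K": k_bg,
        "n": n,
        "k": k,
        "p_raw": p,
        "p_bonferroni": min(1.0, p * max(1, n_terms_tested)),
    }


@dataclass(frozen=True)
class TermAssociation:
    """FCS-style association of one feature with a curated term list."""

    feature_id: str
    a: int  # members annotated to >= 1 listed term
    n: int  # feature size
    p_fcs: float
    n_rand: int

    @property
    def hit_rate(self) -> float:
        return self.a / self.n


def _listed_proteins(term_list: Set[str], ontology: Ontology,
                     propagated: Optional[Dict[str, Set[str]]],
                     include_descendants: bool) -> Set[str]:
    """Proteins annotated (after propagation) to any listed term."""
    if include_descendants:
        if propagated is None:
            propagated = propagate_annotations(ontology)
        out: Set[str] = set()
        for t in term_list:
            out |= propagated.get(t, set())
        return out
    out = set()
    for protein, tids in ontology.annotations.items():
        if tids & term_list:
            out.add(protein)
    return out


def fcs_association(feature: FeatureSet, term_list: Set[str], ontology: Ontology,
                    universe: Set[str], n_rand: int = 10000,
                    seed: Optional[int] = None,
                    propagated: Optional[Dict[str, Set[str]]] = None,
                    include_descendants: bool = True) -> TermAssociation:
    """Monte-Carlo term-list association of a feature (random same-size sets).

    ``universe`` is the pool random sets are drawn from (without
    replacement); a sensible default is every protein carrying at least one
    annotation. The p-value counts random hit rates strictly greater than
    the observed one, so a feature at hit rate 1 always gets p = 0.
    ``include_descendants`` treats descendants of listed terms as listed
    (closure under the ontology).
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    universe = set(universe)
    if not feature.members <= universe:
        raise ValueError("feature members must lie inside the universe")
    n = feature.size
    if n > len(universe):
        raise ValueError("feature larger than the universe")

    listed = _listed_proteins(term_list, ontology, propagated, include_descendants)
    a = len(feature.members & listed)
    observed = a / n

    pool = np.array(sorted(universe))
    is_listed = np.isin(pool, np.array(sorted(listed)) if listed else np.array([], dtype=pool.dtype))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_rand):
        idx = rng.choice(len(pool), size=n, replace=False)
        if is_listed[idx].sum() / n > observed:
            exceed += 1
    return TermAssociation(feature.feature_id, a, n, exceed / n_rand, n_rand)


def category_overlap(sets_by_namespace: Dict[str, Set[str]]) -> Dict[str, int]:
    """Venn bookkeeping for (up to three) per-namespace significant sets.

    Returns counts for every non-empty namespace combination (keys like
    ``"BP"``, ``"BP&CC"``, ``"BP&CC&MF"``) over disjoint regions, plus
    ``"union"``; the disjoint regions sum to the union by construction.
    """
    names = sorted(sets_by_namespace)
    universe: Set[str] = set()
    for s in sets_by_namespace.values():
        universe |= s
    out: Dict[str, int] = {}
    for item_mask in range(1, 2 ** len(names)):
        members = [names[i] for i in range(len(names)) if item_mask >> i & 1]
        region = set(universe)
        for nm in names:
            if nm in members:
                region &= sets_by_namespace[nm]
            else:
                region -= sets_by_namespace[nm]
        out["&".join(members)] = len(region)
    out["union"] = len(universe)
    return out
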