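"""Pathway-derived subnet (PDS) extraction.

A PDS is a connected component, of at least ``min_size`` proteins, of the
subgraph a pathway induces on the candidate proteins. Candidates are the
proteins detected in at least half of the patients of either cohort class;
removing everything else fragments the pathway into the subnets where
between-class variation is expected to concentrate.
"""

from __future__ import annotations

import math
from typing import Iterable, List, Set, Tuple

import networkx as nx
import pandas as pd

from .datatypes import DetectionProfile, FeatureSet, PathwayGraph


def candidate_proteins(profiles: Iterable[DetectionProfile]) -> Set[str]:
    """Proteins detected in at least half the patients of either class.

    "At least half" with an odd class size rounds up (ceil(n/2): at least
    half of 5 patients means 3 or more). The candidate set is the union of
    the two per-class selections, so proteins characteristic of either class
    are retained.
    """
    profiles = list(profiles)
    labels = sorted({p.class_label for p in profiles})
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 class labels, found {labels}")
    out: Set[str] = set()
    for lab in labels:
        group = [p for p in profiles if p.class_label == lab]
        threshold = math.ceil(len(group) / 2)
        counts: dict = {}
        for p in group:
            for protein in p.detected:
                counts[protein] = counts.get(protein, 0) + 1
        out |= {protein for protein, c in counts.items() if c >= threshold}
    return out


def extract_pds(pathway: PathwayGraph, candidates: Set[str],
                min_size: int = 4) -> List[FeatureSet]:
    """Fragment one pathway on the candidate set and keep components >= min_size.

    Feature IDs are deterministic: ``<pathway_id>.pds<k>`` with components
    ordered by descending size, ties broken by lexicographically smallest
    member (a reproducibility convention; nothing downstream depends on it).
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    sub = pathway.graph.subgraph(pathway.nodes & set(candidates))
    components = [set(c) for c in nx.connected_components(sub)]
    components = [c for c in components if len(c) >= min_size]
    components.sort(key=lambda c: (-len(c), min(c)))
    return [
        FeatureSet(
            feature_id=f"{pathway.pathway_id}.pds{k + 1}",
            members=frozenset(comp),
            kind="pds",
            source_pathway=pathway.pathway_id,
        )
        for k, comp in enumerate(components)
    ]


def pds_catalogue(pathways: Iterable[PathwayGraph], candidates: Set[str],
                  min_size: int = 4) -> Tuple[List[FeatureSet], pd.DataFrame]:
    """Extract PDSs from every pathway and tally per-pathway contributions.

    Returns the concatenated PDS list plus a table (pathway_id, n_pds)
    covering all pathways, including those contributing none.
    """
    pathways = list(pathways)
    ids = [pw.pathway_id for pw in pathways]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate pathway IDs: {dupes}")
    features: List[FeatureSet] = []
    counts = []
    for pw in pathways:
        pds = extract_pds(pw, candidates, min_size=min_size)
        features.extend(pds)
        counts.append((pw.pathway_id, len(pds)))
    table = pd.DataFrame(counts, columns=["pathway_id", "n_pds"])
    return features, table
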