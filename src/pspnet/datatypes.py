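"""Core domain containers shared across the package.

The pipeline moves through a small number of in-memory shapes: per-patient
detection profiles, pathway graphs, feature sets (protein complexes or
pathway-derived subnets), the patients x features hit-rate matrix, an
ontology with protein annotations, and a bootstrap-annotated dendrogram.
Everything downstream (clustering, feature selection, co-location and
ontology scoring) consumes these.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import networkx as nx
import numpy as np
import pandas as pd

#: Minimum feature size used for profiling; smaller sets produce hit rates
#: too coarse to be informative and are excluded (with a warning) upstream.
MIN_FEATURE_SIZE = 4


@dataclass(frozen=True)
class DetectionProfile:
    """One patient's detected-protein set with its cohort class label.

    Parameters
    ----------
    patient_id : str
    class_label : str
        One of exactly two labels per cohort (e.g. ``"mod"`` / ``"poor"``).
    detected : frozenset of str
        Protein identifiers detected in this patient. Must be non-empty.
    ratios : dict, optional
        iTRAQ-style abundance ratios (tumour vs control) for a subset of the
        detected proteins. All values must be positive; every key must be a
        detected protein.
    """

    patient_id: str
    class_label: str
    detected: frozenset
    ratios: Optional[Mapping[str, float]] = None

    def __post_init__(self):
        object.__setattr__(self, "detected", frozenset(self.detected))
        if not self.detected:
            raise ValueError(f"patient {self.patient_id!r} has an empty detection set")
        if self.ratios is not None:
            ratios = dict(self.ratios)
            extra = set(ratios) - self.detected
            if extra:
                raise ValueError(
                    f"patient {self.patient_id!r}: ratios for undetected proteins {sorted(extra)[:5]}"
                )
            bad = {p: r for p, r in ratios.items() if not r > 0}
            if bad:
                raise ValueError(
                    f"patient {self.patient_id!r}: non-positive ratios {bad}"
                )
            object.__setattr__(self, "ratios", ratios)


@dataclass
class PathwayGraph:
    """An undirected pathway graph (nodes are gene/protein IDs).

    Edges are unordered gene pairs; duplicate and reversed pairs collapse to
    a single edge and self-loops are dropped at load time.
    """

    pathway_id: str
    name: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set:
        return {frozenset(e) for e in self.graph.edges}

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


@dataclass(frozen=True)
class FeatureSet:
    """A profiling feature: a protein complex or a pathway-derived subnet (PDS).

    ``kind`` is ``"complex"`` or ``"pds"``; a PDS always records the pathway
    it was extracted from in ``source_pathway``.
    """

    feature_id: str
    members: frozenset
    kind: str = "complex"
    source_pathway: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "members", frozenset(self.members))
        if self.kind not in ("complex", "pds"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "pds" and not self.source_pathway:
            raise ValueError(f"PDS {self.feature_id!r} lacks a source pathway")
        if not self.members:
            raise ValueError(f"feature {self.feature_id!r} has no members")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def below_min_size(self) -> bool:
        return self.size < MIN_FEATURE_SIZE


@dataclass(frozen=True)
class Term:
    """A single ontology term (name, namespace, direct parents)."""

    term_id: str
    name: str = ""
    namespace: str = ""
    parents: frozenset = frozenset()  # is_a / part_of parents


@dataclass
class Ontology:
    """An ontology (terms + is_a/part_of parent links) with direct annotations.

    ``annotations`` maps protein -> set of directly annotated term IDs;
    propagation to ancestors is an explicit, separate operation
    (:func:`pspnet.ontology.propagate_annotations`).
    """

    terms: dict  # term_id -> Term
    annotations: dict  # protein_id -> set of term_ids

    def __post_init__(self):
        for term in self.terms.values():
            missing = [p for p in term.parents if p not in self.terms]
            if missing:
                raise ValueError(
                    f"term {term.term_id} references unknown parents {missing}"
                )
        for protein, tids in self.annotations.items():
            unknown = [t for t in tids if t not in self.terms]
            if unknown:
                raise ValueError(
                    f"protein {protein} annotated to unknown terms {unknown}"
                )

    def parent_graph(self) -> nx.DiGraph:
        """Directed graph with an edge child -> parent for every parent link."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for term in self.terms.values():
            for parent in term.parents:
                g.add_edge(term.term_id, parent)
        return g

    def children(self, term_id: str) -> set:
        return {
            t.term_id for t in self.terms.values() if term_id in t.parents
        }


class SignatureMatrix:
    """Patients x features hit-rate matrix — the proteomics signature profile.

    Thin wrapper around a :class:`pandas.DataFrame` (rows = patients, columns
    = features, values = exact hit rates in [0, 1]) that also carries the
    per-patient class labels and the feature sets the columns came from.
    """

    def __init__(self, values: pd.DataFrame, class_labels: pd.Series,
                 features: Optional[Iterable[FeatureSet]] = None):
        if not values.index.equals(class_labels.index):
            raise ValueError("class labels must be indexed by the matrix patients")
        arr = values.to_numpy(dtype=float)
        if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1):
            raise ValueError("hit rates must lie in [0, 1]")
        self.values = values
        self.class_labels = class_labels
        self.features = {f.feature_id: f for f in features} if features else {}

    @property
    def patient_ids(self) -> list:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list:
        return list(self.values.columns)

    @property
    def shape(self):
        return self.values.shape

    def classes(self) -> list:
        """The distinct class labels, in first-appearance order."""
        seen = []
        for lab in self.class_labels:
            if lab not in seen:
                seen.append(lab)
        return seen

    def to_frame(self) -> pd.DataFrame:
        """Matrix with the class label inserted as the first column."""
        out = self.values.copy()
        out.insert(0, "class_label", self.class_labels)
        return out

    def __repr__(self):
        n, p = self.values.shape
        return f"<SignatureMatrix {n} patients x {p} features>"


class BootTree:
    """A patient dendrogram with per-node AU/BP bootstrap confidence.

    Attributes
    ----------
    linkage : ndarray
        SciPy linkage matrix (Ward on Euclidean distances).
    labels : list of str
        Patient IDs in leaf order (row order of the clustered matrix).
    table : pandas.DataFrame
        One row per internal node: ``node`` (0-based internal-node index),
        ``leaves`` (semicolon-joined patient IDs), ``au``, ``bp`` (0-100, or
        NaN when AU could not be fitted) and ``flag``.
    """

    def __init__(self, linkage: np.ndarray, labels: list, table: pd.DataFrame):
        self.linkage = np.asarray(linkage, dtype=float)
        self.labels = list(labels)
        self.table = table

    def leaf_sets(self) -> list:
        """Leaf-ID frozensets for every internal node, in merge order."""
        n = len(self.labels)
        sets: list = [frozenset([lab]) for lab in self.labels]
        out = []
        for a, b, *_ in self.linkage:
            merged = sets[int(a)] | sets[int(b)]
            sets.append(merged)
            out.append(merged)
        return out

    def node_confidence(self, leaves: Iterable[str]):
        """(AU, BP) for the internal node with exactly this leaf set."""
        target = ";".join(sorted(leaves))
        row = self.table[self.table["leaves"] == target]
        if row.empty:
            raise KeyError(f"no internal node with leaves {target}")
        r = row.iloc[0]
        return float(r["au"]), float(r["bp"])

    def to_newick(self) -> str:
        """Newick string with ``[AU=..,BP=..]`` comments on internal nodes."""
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}
        newick = {i: lab for i, lab in enumerate(self.labels)}
        conf = {
            frozenset(r["leaves"].split(";")): (r["au"], r["bp"])
            for _, r in self.table.iterrows()
        }
        sets = [frozenset([lab]) for lab in self.labels]
        for k, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            node = n + k
            merged = sets[a] | sets[b]
            sets.append(merged)
            la = max(h - heights[a], 0.0)
            lb = max(h - heights[b], 0.0)
            au, bp = conf.get(merged, (float("nan"), float("nan")))
            comment = f"[AU={au:.1f},BP={bp:.1f}]" if au == au else ""
            newick[node] = f"({newick[a]}:{la:.6g},{newick[b]}:{lb:.6g}){comment}"
            heights[node] = h
        root = n + len(self.linkage) - 1
        return newick[root] + ";"
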