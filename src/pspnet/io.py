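"""Readers and writers for the external file formats.

All tabular inputs are UTF-8 TSV with a header row. Pathways are 4-column
TSV edge lists (pathway_id, name, gene_a, gene_b), complexes are GMT,
ontologies OBO 1.2 + GAF 2.x. A single protein/gene identifier namespace is
assumed across all files; no ID mapping is performed here (identifier
conversion, e.g. UniProt to Ensembl, is an upstream concern).
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, List, Optional

import networkx as nx
import obonet
import pandas as pd
from Bio.UniProt.GOA import gafiterator

from .datatypes import DetectionProfile, FeatureSet, Ontology, PathwayGraph, Term

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# detections / ratios
# ---------------------------------------------------------------------------

def read_detections(path, class_column: str = "class_label") -> List[DetectionProfile]:
    """Read per-patient detection lists (one row per detected protein).

    Expected columns: ``patient_id``, *class_column*, ``protein_id`` and an
    optional ``ratio`` column with positive iTRAQ-style abundance ratios.
    Duplicate (patient, protein) rows collapse by set semantics. Exactly two
    distinct class labels must be present across the cohort.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"patient_id", class_column, "protein_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"detections file is missing columns {sorted(missing)}")
    labels = sorted(df[class_column].dropna().unique())
    if len(labels) != 2:
        raise ValueError(
            f"expected exactly 2 class labels, found {len(labels)}: {labels}"
        )
    if df["protein_id"].isna().any() or (df["protein_id"].str.strip() == "").any():
        raise ValueError("blank protein_id in detections file")

    profiles = []
    for pid in sorted(df["patient_id"].unique()):
        sub = df[df["patient_id"] == pid]
        classes = sub[class_column].unique()
        if len(classes) != 1:
            raise ValueError(f"patient {pid!r} carries multiple class labels: {sorted(classes)}")
        detected = frozenset(sub["protein_id"])
        ratios = None
        if "ratio" in df.columns:
            with_ratio = sub.dropna(subset=["ratio"])
            if len(with_ratio):
                ratios = {
                    r.protein_id: float(r.ratio) for r in with_ratio.itertuples()
                }
        profiles.append(
            DetectionProfile(pid, str(classes[0]), detected, ratios)
        )
    return profiles


def write_detections(profiles: Iterable[DetectionProfile], path,
                     class_column: str = "class_label") -> None:
    """Inverse of :func:`read_detections` (round-trips profiles exactly)."""
    rows = []
    for p in profiles:
        for protein in sorted(p.detected):
            ratio = ""
            if p.ratios and protein in p.ratios:
                ratio = repr(p.ratios[protein])
            rows.append((p.patient_id, p.class_label, protein, ratio))
    df = pd.DataFrame(rows, columns=["patient_id", class_column, "protein_id", "ratio"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pathways
# ---------------------------------------------------------------------------

def read_pathways(path) -> List[PathwayGraph]:
    """Read an undirected pathway edge list (pathway_id, name, gene_a, gene_b).

    Edges are unordered; duplicate/reversed rows collapse. Self-loop rows are
    dropped with a warning but their node is retained. Blank gene IDs raise.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"pathway_id", "name", "gene_a", "gene_b"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pathway file is missing columns {sorted(missing)}")
    for col in ("gene_a", "gene_b"):
        if df[col].isna().any() or (df[col].str.strip() == "").any():
            raise ValueError(f"blank gene ID in column {col!r}")

    pathways = []
    for pw_id in sorted(df["pathway_id"].unique()):
        sub = df[df["pathway_id"] == pw_id]
        name = sub["name"].iloc[0]
        g = nx.Graph()
        n_self = 0
        for row in sub.itertuples():
            if row.gene_a == row.gene_b:
                g.add_node(row.gene_a)
                n_self += 1
            else:
                g.add_edge(row.gene_a, row.gene_b)
        if n_self:
            log.warning("pathway %s: dropped %d self-loop row(s)", pw_id, n_self)
        pathways.append(PathwayGraph(pw_id, name, g))
    return pathways


def write_pathways(pathways: Iterable[PathwayGraph], path) -> None:
    rows = []
    for pw in pathways:
        written = False
        for a, b in sorted(tuple(sorted(e)) for e in pw.graph.edges):
            rows.append((pw.pathway_id, pw.name, a, b))
            written = True
        if not written:  # edgeless pathway: keep nodes via self-pair-free rows
            for node in sorted(pw.graph.nodes):
                rows.append((pw.pathway_id, pw.name, node, node))
    pd.DataFrame(rows, columns=["pathway_id", "name", "gene_a", "gene_b"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# complexes (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path) -> List[FeatureSet]:
    """Read a GMT gene-set file as complex feature sets.

    Sets with fewer than 4 members load normally but are flagged
    (``FeatureSet.below_min_size``) and excluded later from profiling.
    Duplicate set names raise.
    """
    features = []
    seen = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name, _desc, *members = parts
            if name in seen:
                raise ValueError(f"duplicate feature id {name!r} in GMT")
            seen.add(name)
            members = [m for m in members if m.strip()]
            features.append(FeatureSet(name, frozenset(members), kind="complex"))
    return features


def write_gmt(features: Iterable[FeatureSet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for f in features:
            fh.write("\t".join([f.feature_id, f.kind] + sorted(f.members)) + "\n")


# ---------------------------------------------------------------------------
# ontology (OBO 1.2 + GAF 2.x)
# ---------------------------------------------------------------------------

def read_obo_gaf(obo_path, gaf_path) -> Ontology:
    """Load an OBO 1.2 ontology and GAF 2.x annotations.

    Only ``is_a`` and ``part_of`` parent links are kept. Obsolete terms are
    excluded (obonet default); annotations to unknown/obsolete terms are
    dropped with a warning count, as are NOT-qualified rows (standard GAF
    semantics). Annotations here are *direct*; ancestor propagation is
    :func:`pspnet.ontology.propagate_annotations`.
    """
    graph = obonet.read_obo(obo_path)
    terms = {}
    for term_id, data in graph.nodes(data=True):
        parents = set(data.get("is_a", []))
        for rel in data.get("relationship", []):
            try:
                rel_type, target = rel.split(" ", 1)
            except ValueError:
                continue
            if rel_type == "part_of":
                parents.add(target.strip())
        # keep only parents that exist (targets outside the file are dropped)
        terms[term_id] = (data.get("name", ""), data.get("namespace", ""), parents)
    known = set(terms)
    term_objs = {
        tid: Term(tid, name, ns, frozenset(p & known))
        for tid, (name, ns, p) in terms.items()
    }

    annotations: dict = {}
    n_dropped = 0
    with open(gaf_path, encoding="utf-8") as fh:
        for rec in gafiterator(fh):
            if "NOT" in rec.get("Qualifier", []):
                continue
            protein = rec["DB_Object_ID"]
            term = rec["GO_ID"]
            if term not in known:
                n_dropped += 1
                continue
            annotations.setdefault(protein, set()).add(term)
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} annotation(s) to unknown or obsolete terms"
        )
    return Ontology(term_objs, annotations)


def read_term_list(path) -> set:
    """Read a curated flat list of term IDs (one per line, '#' comments)."""
    out = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line.split()[0])
    return out


# ---------------------------------------------------------------------------
# matrices, stats tables, trees
# ---------------------------------------------------------------------------

def write_matrix(matrix, path) -> None:
    """Write a signature matrix as TSV (patients as rows, class label first)."""
    matrix.to_frame().to_csv(path, sep="\t", index=True, index_label="patient_id")


def read_matrix(path):
    from .datatypes import SignatureMatrix

    df = pd.read_csv(path, sep="\t", index_col="patient_id", comment="#")
    labels = df.pop("class_label")
    return SignatureMatrix(df, labels)


def write_feature_table(table: pd.DataFrame, path, header_comment: Optional[str] = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", index=False)


def write_newick(tree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(tree.to_newick() + "\n")


def coverage_summary(profiles, features) -> pd.DataFrame:
    """Per-patient count of detected proteins not covered by any feature set.

    The source data never guarantees that detected proteins appear in any
    pathway or complex; this reports how much of each detection list the
    chosen feature collection can see.
    """
    covered = set()
    for f in features:
        covered |= f.members
    rows = []
    for p in profiles:
        n = len(p.detected)
        n_cov = len(p.detected & covered)
        rows.append((p.patient_id, p.class_label, n, n_cov, n - n_cov))
    return pd.DataFrame(
        rows,
        columns=["patient_id", "class_label", "n_detected", "n_covered", "n_uncovered"],
    )
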