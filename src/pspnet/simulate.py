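"""Synthetic cohorts, pathways, complexes, ratios and ontologies.

The generators emulate the regime the profiling method was designed for:
two patient classes whose per-patient detection lists are highly variable
(low inter-patient overlap — with a background detection probability of
0.3, two patients share only ~18% of their detected proteins, and almost
no protein is detected in every patient of a class), with designated
signal features whose members are detected class-dependently. Detection is
independent across proteins by default, which is a simplification of real
co-detection structure; a per-patient coverage factor
(``coverage_sigma``) can induce patient-level correlation.

Defaults mirror the target study conditions: a 5 + 7 two-class cohort over
a proteome of ~1500 proteins, background detection probability 0.3, signal
detection probabilities 0.9 / 0.2, log-normal iTRAQ-style ratios (sigma =
0.25) centred at 1 with a x1.5 shift for signal proteins. All generators
are byte-for-byte deterministic under a fixed seed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .datatypes import DetectionProfile, FeatureSet, Ontology, PathwayGraph, Term


def _protein_names(n: int, prefix: str = "P") -> List[str]:
    width = max(5, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


# ---------------------------------------------------------------------------
# pathways / complexes
# ---------------------------------------------------------------------------

def gen_pathways(n_pathways: int = 20, size_range: Tuple[int, int] = (8, 40),
                 extra_edge_prob: float = 0.05, proteome: Optional[Sequence[str]] = None,
                 shared_fraction: float = 0.5,
                 seed: Optional[int] = None) -> List[PathwayGraph]:
    """Random connected pathways: spanning tree plus Bernoulli extra edges.

    Each pathway draws ``shared_fraction`` of its nodes from a common pool
    (so pathways overlap, as real databases do) and the rest from
    pathway-private identifiers. ``extra_edge_prob = 1`` yields complete
    graphs; ``0`` leaves pure trees.
    """
    rng = np.random.default_rng(seed)
    lo, hi = size_range
    if lo < 2:
        raise ValueError("pathway size must be >= 2")
    if proteome is None:
        proteome = _protein_names(max(200, n_pathways * hi))
    proteome = list(proteome)
    out = []
    fresh = 0
    for k in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        n_shared = int(round(shared_fraction * size))
        shared = list(rng.choice(len(proteome), size=n_shared, replace=False))
        nodes = [proteome[i] for i in shared]
        while len(nodes) < size:
            nodes.append(f"X{fresh:05d}")
            fresh += 1
        order = list(rng.permutation(len(nodes)))
        nodes = [nodes[i] for i in order]
        g = nx.Graph()
        g.add_node(nodes[0])
        for i in range(1, len(nodes)):
            j = int(rng.integers(0, i))  # random attachment => spanning tree
            g.add_edge(nodes[i], nodes[j])
        if extra_edge_prob > 0:
            for i in range(len(nodes)):
                for j in range(i + 1, len(nodes)):
                    if not g.has_edge(nodes[i], nodes[j]) and rng.random() < extra_edge_prob:
                        g.add_edge(nodes[i], nodes[j])
        out.append(PathwayGraph(f"PW{k:04d}", f"synthetic pathway {k}", g))
    return out


def gen_complexes(n_complexes: int = 50, size_range: Tuple[int, int] = (4, 15),
                  proteome: Optional[Sequence[str]] = None,
                  seed: Optional[int] = None,
                  prefix: str = "CPX") -> List[FeatureSet]:
    """Random protein complexes (uniform sizes, members sampled without replacement)."""
    rng = np.random.default_rng(seed)
    if proteome is None:
        proteome = _protein_names(1500)
    proteome = list(proteome)
    lo, hi = size_range
    out = []
    for k in range(n_complexes):
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(proteome), size=size, replace=False)
        out.append(
            FeatureSet(f"{prefix}{k:04d}", frozenset(proteome[i] for i in idx),
                       kind="complex")
        )
    return out


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def gen_cohort(n_a: int = 5, n_b: int = 7, proteome_size: int = 1500,
               background_p: float = 0.3,
               signal_features: Iterable[FeatureSet] = (),
               p_detect_a: float = 0.9, p_detect_b: float = 0.2,
               ratio_sigma: float = 0.25, signal_ratio_shift: float = 1.5,
               coverage_sigma: float = 0.0,
               class_labels: Tuple[str, str] = ("mod", "poor"),
               proteome: Optional[Sequence[str]] = None,
               seed: Optional[int] = None) -> List[DetectionProfile]:
    """Simulate a two-class cohort of detection profiles with iTRAQ-style ratios.

    Every protein is detected independently per patient with probability
    ``background_p``, except members of the signal features, which use
    ``p_detect_a`` / ``p_detect_b`` according to the patient's class.
    Ratios for detected proteins are log-normal centred at 1 (sigma =
    ``ratio_sigma``), multiplied by ``signal_ratio_shift`` for signal
    proteins. ``coverage_sigma > 0`` scales each patient's detection
    probabilities by a log-normal per-patient coverage factor.
    """
    for p in (background_p, p_detect_a, p_detect_b):
        if not 0.0 <= p <= 1.0:
            raise ValueError("detection probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if proteome is None:
        proteome = _protein_names(proteome_size)
    proteome = list(proteome)
    signal: set = set()
    for f in signal_features:
        signal |= f.members
    extra = sorted(signal - set(proteome))
    proteome = proteome + extra  # signal members always part of the proteome
    arr = np.array(proteome)
    is_signal = np.isin(arr, sorted(signal)) if signal else np.zeros(len(arr), bool)

    profiles = []
    specs = [(class_labels[0], n_a, p_detect_a), (class_labels[1], n_b, p_detect_b)]
    for label, count, p_sig in specs:
        for i in range(count):
            p_vec = np.where(is_signal, p_sig, background_p)
            if coverage_sigma > 0:
                p_vec = np.clip(p_vec * rng.lognormal(0.0, coverage_sigma), 0.0, 1.0)
            hit = rng.random(len(arr)) < p_vec
            if not hit.any():  # profiles must be non-empty; prefer background
                pool = np.flatnonzero(~is_signal) if (~is_signal).any() \
                    else np.arange(len(arr))
                hit[pool[int(rng.integers(0, len(pool)))]] = True
            detected = arr[hit]
            ratios = rng.lognormal(0.0, ratio_sigma, size=int(hit.sum()))
            shift = np.where(is_signal[hit], signal_ratio_shift, 1.0)
            ratios = ratios * shift
            profiles.append(
                DetectionProfile(
                    f"{label}{i + 1:02d}", label, frozenset(detected),
                    dict(zip(detected.tolist(), ratios.tolist())),
                )
            )
    return profiles


# ---------------------------------------------------------------------------
# ontology
# ---------------------------------------------------------------------------

def gen_ontology(n_filler_terms: int = 20, n_informative: int = 3,
                 informative_count: int = 31,
                 proteins: Optional[Sequence[str]] = None,
                 namespace: str = "biological_process",
                 seed: Optional[int] = None) -> Tuple[Ontology, List[str]]:
    """Random ontology with a planted frontier of informative terms.

    The DAG has a root, ``n_informative`` planted terms directly annotated
    to ``informative_count`` proteins each (children of the root, no
    children of their own), and ``n_filler_terms`` sparse filler terms in
    small branches. With the default ``informative_count = 31`` (> 30) the
    planted terms are exactly the informative frontier at the conventional
    threshold of 30: the root is disqualified by a child above the
    threshold, fillers by their low counts.

    Returns (ontology, planted_term_ids).
    """
    rng = np.random.default_rng(seed)
    need = n_informative * informative_count + n_filler_terms * 3
    if proteins is None:
        proteins = _protein_names(need, prefix="Q")
    proteins = list(proteins)
    if len(proteins) < need:
        raise ValueError(f"need at least {need} proteins")

    terms = {"T:ROOT": Term("T:ROOT", "root", namespace, frozenset())}
    annotations: dict = {}
    cursor = 0
    planted = []
    for k in range(n_informative):
        tid = f"T:INF{k:03d}"
        planted.append(tid)
        terms[tid] = Term(tid, f"planted {k}", namespace, frozenset({"T:ROOT"}))
        for _ in range(informative_count):
            annotations.setdefault(proteins[cursor], set()).add(tid)
            cursor += 1
    filler_parents = ["T:ROOT"]
    for k in range(n_filler_terms):
        tid = f"T:FIL{k:03d}"
        parent = filler_parents[int(rng.integers(0, len(filler_parents)))]
        terms[tid] = Term(tid, f"filler {k}", namespace, frozenset({parent}))
        filler_parents.append(tid)
        for _ in range(int(rng.integers(0, 4))):
            annotations.setdefault(proteins[cursor], set()).add(tid)
            cursor += 1
    return Ontology(terms, annotations), planted


# ---------------------------------------------------------------------------
# OBO / GAF writers (minimal but standard-conforming for round-trips)
# ---------------------------------------------------------------------------

def write_obo(ontology: Ontology, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n")
        for tid in sorted(ontology.terms):
            t = ontology.terms[tid]
            fh.write(f"\n[Term]\nid: {tid}\nname: {t.name}\n")
            if t.namespace:
                fh.write(f"namespace: {t.namespace}\n")
            for parent in sorted(t.parents):
                fh.write(f"is_a: {parent} ! {ontology.terms[parent].name}\n")


def write_gaf(ontology: Ontology, path, aspect: str = "P") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("!gaf-version: 2.1\n")
        for protein in sorted(ontology.annotations):
            for tid in sorted(ontology.annotations[protein]):
                cols = [
                    "SYN", protein, protein, "", tid, "PMID:0", "IEA", "",
                    aspect, "", "", "protein", "taxon:9606", "20110423",
                    "SYN", "", "",
                ]
                fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# preset
# ---------------------------------------------------------------------------

def hcc_like(seed: int = 0, out_dir: Optional[str] = None) -> dict:
    """The default study-condition preset: everything each stage needs.

    A 5 + 7 two-class cohort over a ~1500-protein proteome with background
    detection 0.3, 20 pathways, 50 complexes of which 8 and 6 PDS-bearing
    pathway cores act as class-linked signal features (detection 0.9 vs
    0.2), plus a small planted-frontier ontology. With ``out_dir`` set, all
    standard input files (pathways TSV, GMT, detections TSV, OBO, GAF,
    curated term list) are written there.
    """
    rng = np.random.default_rng(seed)
    child = [int(s) for s in rng.integers(0, 2 ** 31 - 1, size=5)]
    proteome = _protein_names(1500)
    pathways = gen_pathways(n_pathways=20, proteome=proteome, seed=child[0])
    complexes = gen_complexes(n_complexes=50, proteome=proteome, seed=child[1])
    signal = complexes[:8]
    profiles = gen_cohort(
        n_a=5, n_b=7, proteome=proteome, signal_features=signal, seed=child[2]
    )
    ontology, planted = gen_ontology(proteins=proteome, seed=child[3])
    result = {
        "proteome": proteome,
        "pathways": pathways,
        "complexes": complexes,
        "signal_features": signal,
        "profiles": profiles,
        "ontology": ontology,
        "planted_terms": planted,
        "seed": seed,
    }
    if out_dir is not None:
        from . import io

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_pathways(pathways, out / "pathways.tsv")
        io.write_gmt(complexes, out / "complexes.gmt")
        io.write_detections(profiles, out / "detections.tsv")
        write_obo(ontology, out / "ontology.obo")
        write_gaf(ontology, out / "annotations.gaf")
        with open(out / "curated_terms.txt", "w", encoding="utf-8") as fh:
            for tid in planted:
                fh.write(tid + "\n")
    return result


def expected_pairwise_jaccard(p: float) -> float:
    """Analytic expected Jaccard of two independent detection sets.

    With every protein detected independently at probability p in both
    patients, a protein lies in the union with probability 1-(1-p)^2 and in
    the intersection with probability p^2, so the expected ratio tends to
    p / (2 - p) for large proteomes.
    """
    return p / (2.0 - p)
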