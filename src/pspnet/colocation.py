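"""Co-location of significant complexes and significant PDSs on pathways.

A pathway is *involved* when it gave rise to at least one significant PDS.
Three questions are quantified here: are involved pathways more likely than
non-involved ones to overlap a significant complex (enrichment ratio); how
much do co-located PDS/complex pairs actually share (Jaccard overlap
distribution — small overlaps mean co-location is not an artefact of shared
members); and do the per-class ranking scores of co-located pairs
correlate (simple regression with an outlier report).
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from .datatypes import FeatureSet, PathwayGraph

#: Returned when an enrichment denominator is empty.
UNDEFINED = float("nan")


def involved_pathways(sig_pds: Iterable[FeatureSet]) -> Set[str]:
    """Distinct source pathways of the significant PDSs."""
    out = set()
    for f in sig_pds:
        if f.kind != "pds":
            raise ValueError(f"{f.feature_id!r} is not a PDS")
        out.add(f.source_pathway)
    return out


def overlap_enrichment(involved: Set[str], all_pathways: Sequence[PathwayGraph],
                       sig_complexes: Iterable[FeatureSet],
                       min_shared: int = 1) -> dict:
    """How much more likely is an involved pathway to overlap a significant complex.

    A pathway overlaps a complex when they share at least ``min_shared``
    proteins. Returns the overlapping fraction among involved and
    non-involved pathways and their ratio (NaN when a denominator or the
    non-involved fraction is zero).
    """
    ids = {pw.pathway_id for pw in all_pathways}
    if not involved <= ids:
        raise ValueError(f"unknown involved pathways: {sorted(involved - ids)}")
    sig_complexes = list(sig_complexes)

    def overlaps(pw: PathwayGraph) -> bool:
        nodes = pw.nodes
        return any(len(nodes & c.members) >= min_shared for c in sig_complexes)

    inv = [pw for pw in all_pathways if pw.pathway_id in involved]
    non = [pw for pw in all_pathways if pw.pathway_id not in involved]
    k_inv = sum(overlaps(pw) for pw in inv)
    k_non = sum(overlaps(pw) for pw in non)
    frac_inv = k_inv / len(inv) if inv else UNDEFINED
    frac_non = k_non / len(non) if non else UNDEFINED
    if frac_non and frac_non == frac_non:
        ratio = frac_inv / frac_non
    else:
        ratio = UNDEFINED
    return {
        "n_involved": len(inv),
        "n_noninvolved": len(non),
        "k_involved": k_inv,
        "k_noninvolved": k_non,
        "frac_involved": frac_inv,
        "frac_noninvolved": frac_non,
        "ratio": ratio,
    }


def colocated_pairs(pds_features: Iterable[FeatureSet],
                    complexes: Iterable[FeatureSet],
                    pathways: Sequence[PathwayGraph],
                    min_shared: int = 1) -> List[Tuple[FeatureSet, FeatureSet]]:
    """(PDS, complex) pairs sharing a pathway (complex overlaps the PDS's source)."""
    by_id = {pw.pathway_id: pw for pw in pathways}
    pairs = []
    for pds in pds_features:
        pw = by_id.get(pds.source_pathway)
        if pw is None:
            continue
        for cx in complexes:
            if len(pw.nodes & cx.members) >= min_shared:
                pairs.append((pds, cx))
    return pairs


def jaccard(a: Set[str], b: Set[str]) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def jaccard_overlaps(pairs: Iterable[Tuple[FeatureSet, FeatureSet]],
                     threshold: float = 0.2) -> dict:
    """Jaccard score per co-located pair plus the fraction below ``threshold``."""
    scores = [jaccard(set(p.members), set(c.members)) for p, c in pairs]
    frac = (
        float(np.mean([s < threshold for s in scores])) if scores else UNDEFINED
    )
    return {"scores": scores, "threshold": threshold, "frac_below": frac}


def score_regression(pds_scores: Sequence[float], complex_scores: Sequence[float],
                     drop: Optional[Sequence[int]] = None,
                     studentised_cutoff: float = 3.0) -> dict:
    """OLS of complex ranking score on PDS ranking score for co-located pairs.

    Reports slope/intercept (both regression directions for the slope — R²
    and the F-test p are direction-invariant for a simple regression),
    R², the F-test p-value, and indices whose externally studentised
    residual exceeds ``studentised_cutoff`` in magnitude. ``drop`` re-fits
    with the listed pair indices removed (e.g. visually identified
    outliers).
    """
    x = np.asarray(pds_scores, dtype=float)
    y = np.asarray(complex_scores, dtype=float)
    if x.shape != y.shape:
        raise ValueError("score vectors differ in length")
    keep = np.ones(len(x), dtype=bool)
    if drop is not None:
        keep[list(drop)] = False
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 pairs to regress")

    fit = sm.OLS(y, sm.add_constant(x, has_constant="add")).fit()
    fit_rev = sm.OLS(x, sm.add_constant(y, has_constant="add")).fit()
    try:
        student = OLSInfluence(fit).resid_studentized_external
        outliers = [int(i) for i in np.flatnonzero(np.abs(student) > studentised_cutoff)]
    except Exception:  # degenerate fits (e.g. constant y)
        outliers = []
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "slope_reverse": float(fit_rev.params[1]),
        "r_squared": float(fit.rsquared) if np.isfinite(fit.rsquared) else 0.0,
        "p_value": float(fit.f_pvalue) if np.isfinite(fit.f_pvalue) else UNDEFINED,
        "n": int(len(x)),
        "outlier_indices": outliers,
    }
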