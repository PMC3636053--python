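"""Hierarchical clustering of patient profiles with bootstrap confidence.

Patients are clustered on Euclidean distances between their signature
profiles using Ward linkage. Confidence in each cluster comes from
multiscale bootstrap resampling of the features: at each scale r the
features are resampled with replacement to round(r * n_features) columns,
the tree is rebuilt, and the per-cluster containment frequency BP_r is
recorded. Fitting the probit-transformed frequencies against v*sqrt(r) +
c/sqrt(r) by weighted least squares separates the signed distance v from
the curvature c of the cluster boundary, giving the approximately unbiased
value AU = 100 * (1 - Phi(v - c)); BP is the plain bootstrap probability at
r = 1. Both are reported on the conventional 0-100 scale.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from scipy.stats import norm

from .datatypes import BootTree, SignatureMatrix

#: Default multiscale grid (straddles r = 1, as the AU fit requires).
DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 10))


def cluster_patients(matrix: SignatureMatrix) -> np.ndarray:
    """Ward/Euclidean linkage over the patients of a signature matrix."""
    x = matrix.values.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 patients to cluster")
    return linkage(pdist(x, metric="euclidean"), method="ward")


def _cluster_sets(z: np.ndarray, n: int) -> list:
    """Leaf-index frozensets of the internal nodes of a linkage matrix."""
    sets = [frozenset([i]) for i in range(n)]
    out = []
    for a, b, *_ in z:
        merged = sets[int(a)] | sets[int(b)]
        sets.append(merged)
        out.append(merged)
    return out


def multiscale_bootstrap(matrix: SignatureMatrix,
                         scales: Sequence[float] = DEFAULT_SCALES,
                         n_boot: int = 1000,
                         seed: Optional[int] = None) -> BootTree:
    """Cluster patients and attach AU/BP confidence to every internal node.

    Parameters
    ----------
    scales : sequence of float
        Resampling scale grid; must straddle 1.0. With fewer than two
        distinct scales the AU fit is impossible: plain BP is still
        reported and AU is NaN.
    n_boot : int
        Bootstrap replicates per scale (>= 100).
    seed : int, optional
        Seeds the single feature-resampling stream.

    Notes
    -----
    BP_r values are clamped to [1/(B+1), B/(B+1)] before the probit
    transform; weighted least squares uses the binomial variance of each
    BP_r, falling back to ordinary least squares when the weights
    degenerate. A cluster contained in every replicate at every scale is
    saturated at AU = 100 (and all-zero containment gives AU = 0, flagged
    ``never_observed``) without going through the fit.
    """
    scales = sorted(float(r) for r in scales)
    if not scales:
        raise ValueError("empty scale grid")
    if not (min(scales) <= 1.0 <= max(scales)):
        raise ValueError("scale grid must straddle 1.0")
    if n_boot < 100:
        raise ValueError("need at least 100 bootstrap replicates per scale")

    x = matrix.values.to_numpy(dtype=float)
    n_pat, n_feat = x.shape
    z = cluster_patients(matrix)
    observed = _cluster_sets(z, n_pat)
    fit_au = len(set(scales)) >= 2

    rng = np.random.default_rng(seed)
    counts = np.zeros((len(observed), len(scales)), dtype=np.int64)
    index = {c: i for i, c in enumerate(observed)}
    for si, r in enumerate(scales):
        n_r = max(2, int(round(r * n_feat)))
        for _ in range(n_boot):
            cols = rng.integers(0, n_feat, size=n_r)
            xb = x[:, cols]
            zb = linkage(pdist(xb, metric="euclidean"), method="ward")
            for cl in _cluster_sets(zb, n_pat):
                i = index.get(cl)
                if i is not None:
                    counts[i, si] += 1

    bp_r = counts / n_boot
    r_arr = np.asarray(scales)
    design = np.column_stack([np.sqrt(r_arr), 1.0 / np.sqrt(r_arr)])
    i_one = int(np.argmin(np.abs(r_arr - 1.0)))

    labels = matrix.patient_ids
    rows = []
    for i, cl in enumerate(observed):
        bp = 100.0 * bp_r[i, i_one]
        flag = ""
        if np.all(counts[i] == n_boot):
            au = 100.0
            flag = "saturated"
        elif np.all(counts[i] == 0):
            au = 0.0
            flag = "never_observed"
        elif not fit_au:
            au = np.nan
            flag = "bp_only"
        else:
            clamped = np.clip(bp_r[i], 1.0 / (n_boot + 1), n_boot / (n_boot + 1))
            zq = norm.ppf(1.0 - clamped)
            w = n_boot * norm.pdf(zq) ** 2 / (clamped * (1.0 - clamped))
            if not np.all(np.isfinite(w)) or np.all(w <= 0):
                w = np.ones_like(w)
            wd = design * np.sqrt(w)[:, None]
            wz = zq * np.sqrt(w)
            coef, *_ = np.linalg.lstsq(wd, wz, rcond=None)
            v, c = coef
            au = float(np.clip(100.0 * (1.0 - norm.cdf(v - c)), 0.0, 100.0))
        leaves = ";".join(sorted(labels[j] for j in cl))
        rows.append((i, leaves, len(cl), au, bp, flag))

    table = pd.DataFrame(
        rows, columns=["node", "leaves", "n_leaves", "au", "bp", "flag"]
    )
    return BootTree(z, labels, table)
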