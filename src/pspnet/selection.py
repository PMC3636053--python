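"""Differential-feature selection and iTRAQ-ratio ranking scores.

For each feature, the two per-class hit-rate lists are compared with a
pooled-variance two-sample t-statistic. Because hit rates need not follow a
t-distribution, significance comes from an empirical null built by label
swapping: group-size-preserving relabellings of the patients, exhaustively
enumerated when the balanced-assignment space is small enough, Monte-Carlo
sampled otherwise.

Two empirical p-value conventions are offered. ``alternative="signed"`` is
the sign-adaptive single tail (the fraction of null t-scores beyond the
observed one, on the side matching its sign, strict inequality). As a test
at level alpha this rule has size ~2*alpha under a symmetric null — each
tail rejects with probability alpha and the events are disjoint — so
``alternative="two-sided"`` (the adaptive tail doubled, capped at 1) is
provided and is what the calibration-sensitive analyses (false-positive
protocol, synthetic parameter recovery) use, together with
``tie_policy="mid"`` (ties between null and observed t at half weight),
the standard remedy for the heavily tied nulls that discrete hit-rate
columns produce. See docs/methods.md.

Significant features are ranked per class with an iTRAQ-ratio score: every
reported (member protein, patient) ratio r contributes max(r, 1/r) - 1, and
the summed score is normalised by the number of distinct member proteins
reported in that class.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datatypes import DetectionProfile, FeatureSet, SignatureMatrix

__all__ = [
    "t_statistic",
    "t_matrix",
    "balanced_masks",
    "permutation_pvalue",
    "bh_adjust",
    "rank_score",
    "rank_score_sum",
    "select_features",
]


def t_statistic(ha: Sequence[float], hb: Sequence[float]) -> float:
    """Pooled-variance two-sample t-score between hit-rate lists HA and HB.

    t = (mean(HA) - mean(HB)) / (S_pooled * sqrt(1/n + 1/m)) with the usual
    pooled standard deviation (sample variances, m-1 / n-1 denominators).
    Degenerate inputs: zero pooled variance yields 0 when the means agree
    and a signed-infinity sentinel otherwise (resolved downstream by the
    permutation null).
    """
    ha = np.asarray(ha, dtype=float)
    hb = np.asarray(hb, dtype=float)
    m, n = len(ha), len(hb)
    if m < 2 or n < 2:
        raise ValueError("both groups need at least 2 observations")
    diff = ha.mean() - hb.mean()
    sp2 = ((m - 1) * ha.var(ddof=1) + (n - 1) * hb.var(ddof=1)) / (m + n - 2)
    denom = math.sqrt(sp2) * math.sqrt(1.0 / n + 1.0 / m)
    if denom == 0.0:
        if diff == 0.0:
            return 0.0
        return math.inf if diff > 0 else -math.inf
    return diff / denom


def t_matrix(x: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Pooled t-scores for many group-A index masks at once.

    ``x`` is patients x features, ``masks`` is assignments x patients
    (True = group A). Returns an assignments x features array; zero-variance
    cells follow the same 0 / signed-infinity convention as
    :func:`t_statistic`.
    """
    x = np.asarray(x, dtype=float)
    masks = np.asarray(masks, dtype=float)
    n_pat = x.shape[0]
    m = masks.sum(axis=1, keepdims=True)
    n = n_pat - m
    if np.any(m < 2) or np.any(n < 2):
        raise ValueError("each group needs at least 2 patients")
    tot = x.sum(axis=0, keepdims=True)
    tot2 = (x ** 2).sum(axis=0, keepdims=True)
    sa = masks @ x
    qa = masks @ (x ** 2)
    sb = tot - sa
    qb = tot2 - qa
    diff = sa / m - sb / n
    ssa = np.maximum(qa - sa ** 2 / m, 0.0)
    ssb = np.maximum(qb - sb ** 2 / n, 0.0)
    sp2 = (ssa + ssb) / (m + n - 2)
    denom = np.sqrt(sp2) * np.sqrt(1.0 / n + 1.0 / m)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    zero = denom == 0.0
    if np.any(zero):
        t = np.where(zero & (diff == 0.0), 0.0, t)
        t = np.where(zero & (diff > 0.0), np.inf, t)
        t = np.where(zero & (diff < 0.0), -np.inf, t)
    return t


def balanced_masks(n_patients: int, m: int, n_perm: int,
                   rng: Optional[np.random.Generator] = None,
                   max_exhaustive: Optional[int] = None) -> Tuple[np.ndarray, bool]:
    """Group-size-preserving label assignments as boolean masks.

    When the number of distinct balanced assignments C(n, m) does not exceed
    ``n_perm`` (or ``max_exhaustive`` if given), all of them are enumerated
    — including the identity — giving an exact permutation null. Otherwise
    ``n_perm`` uniform random assignments are drawn. Returns (masks,
    exhaustive_flag).
    """
    total = math.comb(n_patients, m)
    cap = n_perm if max_exhaustive is None else max_exhaustive
    if total <= cap:
        masks = np.zeros((total, n_patients), dtype=bool)
        for i, combo in enumerate(itertools.combinations(range(n_patients), m)):
            masks[i, list(combo)] = True
        return masks, True
    if rng is None:
        rng = np.random.default_rng()
    keys = rng.random((n_perm, n_patients))
    order = np.argpartition(keys, m - 1, axis=1)[:, :m]
    masks = np.zeros((n_perm, n_patients), dtype=bool)
    np.put_along_axis(masks, order, True, axis=1)
    return masks, False


#: t-scores are rounded to this many decimals before tie comparisons, so
#: that mathematically equal permutations compare equal regardless of
#: floating-point summation order.
TIE_DECIMALS = 9


def _empirical_p(t_obs: float, t_null: np.ndarray, alternative: str,
                 pseudocount: bool, tie_policy: str = "strict") -> float:
    t_obs = np.round(t_obs, TIE_DECIMALS)
    t_null = np.round(t_null, TIE_DECIMALS)
    big = t_null.size
    if t_obs < 0:
        b = int(np.sum(t_null < t_obs))
    else:
        b = int(np.sum(t_null > t_obs))
    n_tied = int(np.sum(t_null == t_obs))
    if tie_policy == "strict":
        num = float(b)
    elif tie_policy == "mid":
        num = b + 0.5 * n_tied
    elif tie_policy == "inclusive":
        num = float(b + n_tied)
    else:
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    if pseudocount:
        p = (num + 1) / (big + 1)
    else:
        p = num / big
    if alternative == "two-sided":
        p = min(1.0, 2.0 * p)
    elif alternative != "signed":
        raise ValueError(f"unknown alternative {alternative!r}")
    return p


def permutation_pvalue(feature_column: Sequence[float], labels: Sequence[str],
                       n_perm: int = 10000, seed=None,
                       alternative: str = "signed",
                       pseudocount: bool = False,
                       tie_policy: str = "strict") -> float:
    """Empirical p-value for one feature by class-label swapping.

    Labels must contain exactly two classes with at least two patients each.
    Exhaustive enumeration replaces Monte-Carlo sampling whenever the
    balanced-assignment space fits inside ``n_perm`` (exact p). ``seed`` may
    be an int, a SeedSequence or a Generator.
    """
    x = np.asarray(feature_column, dtype=float)[:, None]
    labels = list(labels)
    classes = list(dict.fromkeys(labels))
    if len(classes) != 2:
        raise ValueError(f"expected 2 classes, found {classes}")
    mask_obs = np.array([lab == classes[0] for lab in labels])
    m = int(mask_obs.sum())
    if m < 2 or len(labels) - m < 2:
        raise ValueError("each class needs at least 2 patients")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    masks, _ = balanced_masks(len(labels), m, n_perm, rng)
    t_null = t_matrix(x, masks)[:, 0]
    t_obs = t_matrix(x, mask_obs[None, :])[0, 0]
    return _empirical_p(t_obs, t_null, alternative, pseudocount, tie_policy)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues.copy()
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvalues, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# iTRAQ-ratio ranking score
# ---------------------------------------------------------------------------

def _single_class(profiles: Iterable[DetectionProfile],
                  class_label: Optional[str]) -> List[DetectionProfile]:
    profiles = list(profiles)
    if class_label is not None:
        profiles = [p for p in profiles if p.class_label == class_label]
    labels = {p.class_label for p in profiles}
    if len(labels) > 1:
        raise ValueError(f"profiles span multiple classes: {sorted(labels)}")
    return profiles


def rank_score_sum(feature: FeatureSet, profiles: Iterable[DetectionProfile],
                   class_label: Optional[str] = None) -> Tuple[float, int]:
    """Unnormalised ratio score S and the unique-reported-protein count u.

    Every (member protein, patient) pair with a reported ratio r contributes
    adj - 1 where adj = r if r >= 1 else 1/r (fold change away from 1, so a
    ratio and its reciprocal contribute identically; r = 1 contributes 0).
    u counts the distinct member proteins reported by at least one patient
    of the class.
    """
    profiles = _single_class(profiles, class_label)
    s = 0.0
    reported = set()
    for p in profiles:
        if not p.ratios:
            continue
        for protein in feature.members & set(p.ratios):
            r = p.ratios[protein]
            if r <= 0:
                raise ValueError(f"non-positive ratio {r} for {protein}")
            adj = r if r >= 1 else 1.0 / r
            s += adj - 1.0
            reported.add(protein)
    return s, len(reported)


def rank_score(feature: FeatureSet, profiles: Iterable[DetectionProfile],
               class_label: Optional[str] = None) -> float:
    """Per-class ranking score: S normalised by unique reported proteins.

    Normalising by u (not by feature size) stops large features from
    dominating on the back of a single strongly deregulated member. Zero
    when no member protein is reported at all.
    """
    s, u = rank_score_sum(feature, profiles, class_label)
    return s / u if u else 0.0


# ---------------------------------------------------------------------------
# whole-matrix driver
# ---------------------------------------------------------------------------

def select_features(matrix: SignatureMatrix, n_perm: int = 10000,
                    seed: Optional[int] = None, alternative: str = "signed",
                    pseudocount: bool = False, alpha: float = 0.05,
                    profiles: Optional[Iterable[DetectionProfile]] = None,
                    tie_policy: str = "strict") -> pd.DataFrame:
    """Permutation t-test every feature of a signature matrix.

    Returns one row per feature: ``t_score``, ``p_perm``, ``q_bh``
    (Benjamini-Hochberg over all features), ``significant`` (raw p <=
    ``alpha``), ``constant`` (feature identical across all patients, where
    the strict-inequality rule degenerates to p = 0), ``n_perm_used`` and,
    when ``profiles`` with ratios are supplied, one ranking-score column per
    class.

    In the exhaustive regime every feature shares the same enumerated
    assignment space, so the null is computed in one vectorised pass; in the
    Monte-Carlo regime each feature gets an independent, reproducible
    permutation stream spawned from ``seed``.
    """
    x = matrix.values.to_numpy(dtype=float)
    labels = list(matrix.class_labels)
    classes = matrix.classes()
    if len(classes) != 2:
        raise ValueError(f"expected 2 classes, found {classes}")
    mask_obs = np.array([lab == classes[0] for lab in labels])
    m = int(mask_obs.sum())
    n_pat = len(labels)
    if m < 2 or n_pat - m < 2:
        raise ValueError("each class needs at least 2 patients")

    total = math.comb(n_pat, m)
    feature_ids = matrix.feature_ids
    t_obs = t_matrix(x, mask_obs[None, :])[0]
    constant = np.array([np.all(col == col[0]) for col in x.T])

    pvals = np.empty(len(feature_ids))
    if total <= n_perm:
        masks, _ = balanced_masks(n_pat, m, n_perm)
        t_null = t_matrix(x, masks)
        for j in range(len(feature_ids)):
            pvals[j] = _empirical_p(t_obs[j], t_null[:, j], alternative,
                                    pseudocount, tie_policy)
        n_used = total
    else:
        streams = np.random.SeedSequence(seed).spawn(len(feature_ids))
        for j in range(len(feature_ids)):
            rng = np.random.default_rng(streams[j])
            masks, _ = balanced_masks(n_pat, m, n_perm, rng)
            t_null = t_matrix(x[:, j:j + 1], masks)[:, 0]
            pvals[j] = _empirical_p(t_obs[j], t_null, alternative,
                                    pseudocount, tie_policy)
        n_used = n_perm

    out = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "t_score": t_obs,
            "p_perm": pvals,
            "q_bh": bh_adjust(pvals),
            "significant": pvals <= alpha,
            "constant": constant,
            "n_perm_used": n_used,
        }
    )
    if profiles is not None:
        profiles = list(profiles)
        fsets = matrix.features
        for lab in classes:
            scores = []
            for fid in feature_ids:
                feature = fsets.get(fid)
                if feature is None:
                    scores.append(np.nan)
                else:
                    scores.append(rank_score(feature, profiles, class_label=lab))
            out[f"score_{lab}"] = scores
    return out
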