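"""Empirical false-positive analysis by pseudo-group splitting.

A single homogeneous patient class is repeatedly split at random into two
pseudo-groups (sizes floor(n/2) / ceil(n/2), every patient used each
round), the differential-feature machinery is run on the split, and the
number of "significant" features — all false positives by construction —
is recorded. The count distribution is compared against the nominal
expectation n_features * alpha.

Because that comparison is about the nominal level, the defaults here use
the calibrated two-sided mid-p convention (ties at half weight; see
:mod:`pspnet.selection`): the sign-adaptive single-tail rule would reject
null features at roughly twice the nominal rate, and with the heavily tied
nulls of discrete hit-rate columns the strict and inclusive tie counts are
anti-conservative and conservative respectively, so the expected-count
yardstick would not apply.

When the balanced-split space is enumerable the permutation null is exact
and shared across rounds (every round's null is the full split space);
otherwise each round draws its own Monte-Carlo inner null.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import DetectionProfile, FeatureSet
from .selection import TIE_DECIMALS, balanced_masks, bh_adjust, t_matrix
from .signature import build_matrix


@dataclass
class FPResult:
    """Distribution of per-round false-positive counts."""

    counts: np.ndarray  # one significant-feature count per completed round
    n_features: int
    n_skipped: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.counts)) if self.counts.size else float("nan")

    @property
    def median(self) -> float:
        return float(np.median(self.counts)) if self.counts.size else float("nan")

    @property
    def mode(self):
        """Smallest modal count (all ties via :meth:`mode_ties`)."""
        ties = self.mode_ties()
        return ties[0] if ties else None

    def mode_ties(self) -> list:
        if not self.counts.size:
            return []
        values, freq = np.unique(self.counts, return_counts=True)
        return sorted(int(v) for v in values[freq == freq.max()])

    def histogram(self) -> pd.DataFrame:
        """Absolute and to-1-normalised count histogram."""
        values, freq = np.unique(self.counts, return_counts=True)
        return pd.DataFrame(
            {
                "count": values.astype(int),
                "absolute": freq,
                "normalised": freq / freq.sum(),
            }
        )

    def summary(self) -> dict:
        return {
            "n_rounds": int(self.counts.size),
            "n_skipped": int(self.n_skipped),
            "n_features": int(self.n_features),
            "mean": self.mean,
            "median": self.median,
            "mode": self.mode,
            "mode_ties": self.mode_ties(),
        }


def _tail_counts(t: np.ndarray):
    """Per column: rows strictly above / strictly below / tied with each entry."""
    n = t.shape[0]
    r_max = rankdata(t, method="max", axis=0)
    r_min = rankdata(t, method="min", axis=0)
    b_hi = n - r_max
    b_lo = r_min - 1
    ties = r_max - r_min + 1  # includes the entry itself
    return b_hi, b_lo, ties


def _tie_adjusted(b, ties, tie_policy):
    if tie_policy == "strict":
        return b.astype(float)
    if tie_policy == "mid":
        return b + 0.5 * ties
    if tie_policy == "inclusive":
        return (b + ties).astype(float)
    raise ValueError(f"unknown tie_policy {tie_policy!r}")


def _pvalues_from_null(t_obs: np.ndarray, t_null: np.ndarray, alternative: str,
                       pseudocount: bool, tie_policy: str = "mid") -> np.ndarray:
    big = t_null.shape[0]
    t_obs = np.round(t_obs, TIE_DECIMALS)
    t_null = np.round(t_null, TIE_DECIMALS)
    b_hi = (t_null > t_obs[None, :]).sum(axis=0)
    b_lo = (t_null < t_obs[None, :]).sum(axis=0)
    ties = (t_null == t_obs[None, :]).sum(axis=0)
    b = _tie_adjusted(np.where(t_obs < 0, b_lo, b_hi), ties, tie_policy)
    p = (b + 1) / (big + 1) if pseudocount else b / big
    if alternative == "two-sided":
        p = np.minimum(1.0, 2.0 * p)
    return p


def fp_distribution_matrix(x: np.ndarray, n_rounds: int = 10000,
                           alpha: float = 0.05, bh: bool = True,
                           alternative: str = "two-sided",
                           pseudocount: bool = False,
                           tie_policy: str = "mid",
                           n_inner: int = 1000,
                           max_exhaustive: int = 20000,
                           seed: Optional[int] = None) -> FPResult:
    """Run the random-bipartition protocol on a raw patients x features array.

    Each round assigns the patients to pseudo-groups of sizes floor(n/2) and
    ceil(n/2) uniformly at random and counts features with (optionally
    BH-adjusted) empirical p <= alpha.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    x = np.asarray(x, dtype=float)
    n_pat, n_feat = x.shape
    m = n_pat // 2
    if m < 2:
        warnings.warn(
            f"class of {n_pat} patients cannot be split into groups of >= 2; "
            "all rounds skipped"
        )
        return FPResult(np.array([], dtype=int), n_feat, n_skipped=n_rounds)

    rng = np.random.default_rng(seed)
    total = math.comb(n_pat, m)
    counts = np.empty(n_rounds, dtype=int)

    if total <= max_exhaustive:
        masks, _ = balanced_masks(n_pat, m, total)
        t = np.round(t_matrix(x, masks), TIE_DECIMALS)  # all splits x features
        b_hi, b_lo, ties = _tail_counts(t)
        b = _tie_adjusted(np.where(t < 0, b_lo, b_hi), ties, tie_policy)
        p_all = (b + 1) / (total + 1) if pseudocount else b / total
        if alternative == "two-sided":
            p_all = np.minimum(1.0, 2.0 * p_all)
        draws = rng.integers(0, total, size=n_rounds)
        unique, inverse = np.unique(draws, return_inverse=True)
        per_row = np.empty(unique.size, dtype=int)
        for k, i in enumerate(unique):
            p = bh_adjust(p_all[i]) if bh else p_all[i]
            per_row[k] = int(np.sum(p <= alpha))
        counts = per_row[inverse]
    else:
        for r in range(n_rounds):
            obs_mask = np.zeros(n_pat, dtype=bool)
            obs_mask[rng.permutation(n_pat)[:m]] = True
            t_obs = t_matrix(x, obs_mask[None, :])[0]
            null_masks, _ = balanced_masks(n_pat, m, n_inner, rng,
                                           max_exhaustive=n_inner)
            t_null = t_matrix(x, null_masks)
            p = _pvalues_from_null(t_obs, t_null, alternative, pseudocount,
                                   tie_policy)
            if bh:
                p = bh_adjust(p)
            counts[r] = int(np.sum(p <= alpha))
    return FPResult(counts, n_feat)


def fp_distribution(profiles: Iterable[DetectionProfile],
                    features: Iterable[FeatureSet],
                    n_rounds: int = 10000, alpha: float = 0.05,
                    bh: bool = True, alternative: str = "two-sided",
                    pseudocount: bool = False, tie_policy: str = "mid",
                    n_inner: int = 1000,
                    max_exhaustive: int = 20000,
                    seed: Optional[int] = None) -> FPResult:
    """Random-bipartition false-positive distribution for one patient class."""
    profiles = list(profiles)
    labels = {p.class_label for p in profiles}
    if len(labels) != 1:
        raise ValueError(f"profiles must come from a single class, found {sorted(labels)}")
    matrix = build_matrix(features, profiles)
    return fp_distribution_matrix(
        matrix.values.to_numpy(dtype=float), n_rounds=n_rounds, alpha=alpha,
        bh=bh, alternative=alternative, pseudocount=pseudocount,
        tie_policy=tie_policy, n_inner=n_inner,
        max_exhaustive=max_exhaustive, seed=seed,
    )
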