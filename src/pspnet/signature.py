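"""Hit-rate signature profiles.

The hit rate of feature C in patient i is |C ∩ D_i| / |C|, the fraction of
the feature's member proteins the patient detected. The vector of hit rates
across a feature collection is the patient's signature profile; stacking
patients gives the signature matrix every downstream analysis operates on.
Hit rates are kept as exact fractions in floating point — no binarisation.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd

from .datatypes import DetectionProfile, FeatureSet, SignatureMatrix


def hit_rate(feature: FeatureSet, profile: DetectionProfile) -> float:
    """Fraction of the feature's members detected in this patient."""
    if not feature.members:
        raise ValueError(f"feature {feature.feature_id!r} is empty")
    return len(feature.members & profile.detected) / len(feature.members)


def build_matrix(features: Iterable[FeatureSet],
                 profiles: Iterable[DetectionProfile],
                 min_size: int = 4) -> SignatureMatrix:
    """Assemble the patients x features hit-rate matrix.

    Input order is preserved for both rows and columns. Features below
    ``min_size`` members are excluded with a warning (tiny sets make hit
    rates jump in large, uninformative steps). Patients detecting nothing in
    any feature are retained as all-zero rows.
    """
    features = list(features)
    profiles = list(profiles)
    if not features:
        raise ValueError("no features supplied")
    if len(profiles) < 2:
        raise ValueError("need at least 2 patients")

    small = [f.feature_id for f in features if f.size < min_size]
    if small:
        warnings.warn(
            f"excluding {len(small)} feature(s) below min size {min_size}: "
            f"{small[:5]}{'...' if len(small) > 5 else ''}"
        )
        features = [f for f in features if f.size >= min_size]
    if not features:
        raise ValueError("all features fell below the minimum size")

    pids = [p.patient_id for p in profiles]
    if len(pids) != len(set(pids)):
        raise ValueError("duplicate patient IDs")

    values = np.empty((len(profiles), len(features)))
    for j, f in enumerate(features):
        size = len(f.members)
        for i, p in enumerate(profiles):
            values[i, j] = len(f.members & p.detected) / size
    df = pd.DataFrame(values, index=pids, columns=[f.feature_id for f in features])
    labels = pd.Series([p.class_label for p in profiles], index=pids, name="class_label")
    return SignatureMatrix(df, labels, features)
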