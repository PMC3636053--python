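"""Model/Results front-end for signature-profile analysis.

``PSPModel`` binds a two-class cohort to a feature collection (complexes
and/or pathway-derived subnets), holding the hit-rate signature matrix.
``fit`` runs the permutation t-test over every feature and returns a
``PSPResults`` carrying t-scores, empirical and BH-adjusted p-values,
per-class iTRAQ ranking scores and a text ``summary()``. Bootstrap
clustering of the patients hangs off the model as ``cluster()``.

Example
-------
>>> from pspnet import simulate, PSPModel
>>> data = simulate.hcc_like(seed=1)
>>> model = PSPModel.from_profiles(data["profiles"], data["complexes"])
>>> res = model.fit(seed=1)
>>> res.significant().shape[0]  # doctest: +SKIP
8
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import pandas as pd

from . import cluster as _cluster
from . import selection as _selection
from .datatypes import BootTree, DetectionProfile, FeatureSet, SignatureMatrix
from .signature import build_matrix


class PSPModel:
    """Hit-rate signature-profile model for a two-class proteomics cohort.

    Parameters
    ----------
    matrix : SignatureMatrix
        Patients x features hit-rate matrix (see
        :func:`pspnet.signature.build_matrix`).
    profiles : sequence of DetectionProfile, optional
        The underlying detection profiles; required for ratio-based ranking
        scores.
    """

    def __init__(self, matrix: SignatureMatrix,
                 profiles: Optional[Sequence[DetectionProfile]] = None):
        if len(matrix.classes()) != 2:
            raise ValueError(
                f"cohort must have exactly 2 classes, found {matrix.classes()}"
            )
        self.matrix = matrix
        self.profiles = list(profiles) if profiles is not None else None

    @classmethod
    def from_profiles(cls, profiles: Iterable[DetectionProfile],
                      features: Iterable[FeatureSet],
                      min_size: int = 4) -> "PSPModel":
        """Build the signature matrix from raw profiles and feature sets."""
        profiles = list(profiles)
        matrix = build_matrix(features, profiles, min_size=min_size)
        return cls(matrix, profiles)

    @property
    def endog_names(self):
        return self.matrix.feature_ids

    def fit(self, n_perm: int = 10000, seed: Optional[int] = None,
            alternative: str = "signed", pseudocount: bool = False,
            alpha: float = 0.05, tie_policy: str = "strict") -> "PSPResults":
        """Permutation t-test every feature; returns a results object."""
        table = _selection.select_features(
            self.matrix, n_perm=n_perm, seed=seed, alternative=alternative,
            pseudocount=pseudocount, alpha=alpha, profiles=self.profiles,
            tie_policy=tie_policy,
        )
        return PSPResults(self, table, alpha=alpha, alternative=alternative,
                          n_perm=n_perm)

    def cluster(self, scales=_cluster.DEFAULT_SCALES, n_boot: int = 1000,
                seed: Optional[int] = None) -> BootTree:
        """Ward/Euclidean dendrogram with multiscale-bootstrap AU/BP values."""
        return _cluster.multiscale_bootstrap(
            self.matrix, scales=scales, n_boot=n_boot, seed=seed
        )


class PSPResults:
    """Fitted feature-selection results.

    Attributes
    ----------
    feature_table : pandas.DataFrame
        One row per feature: t_score, p_perm, q_bh, significance flags and
        (when ratios were available) per-class ranking scores.
    """

    def __init__(self, model: PSPModel, feature_table: pd.DataFrame,
                 alpha: float, alternative: str, n_perm: int):
        self.model = model
        self.feature_table = feature_table
        self.alpha = alpha
        self.alternative = alternative
        self.n_perm = n_perm

    # -- statsmodels-flavoured accessors ------------------------------------
    @property
    def tvalues(self) -> pd.Series:
        return self.feature_table.set_index("feature_id")["t_score"]

    @property
    def pvalues(self) -> pd.Series:
        return self.feature_table.set_index("feature_id")["p_perm"]

    @property
    def qvalues(self) -> pd.Series:
        return self.feature_table.set_index("feature_id")["q_bh"]

    def significant(self, alpha: Optional[float] = None,
                    adjusted: bool = False) -> pd.DataFrame:
        """Rows passing the threshold (raw p by default, BH q on request)."""
        alpha = self.alpha if alpha is None else alpha
        col = "q_bh" if adjusted else "p_perm"
        return self.feature_table[self.feature_table[col] <= alpha].copy()

    def significant_features(self, alpha: Optional[float] = None,
                             adjusted: bool = False):
        """The significant rows as FeatureSet objects (when known)."""
        fsets = self.model.matrix.features
        rows = self.significant(alpha=alpha, adjusted=adjusted)
        return [fsets[fid] for fid in rows["feature_id"] if fid in fsets]

    def summary(self, max_rows: int = 20) -> str:
        """Plain-text summary in the spirit of a regression results table."""
        mat = self.model.matrix
        classes = mat.classes()
        n_by = mat.class_labels.value_counts()
        n_sig = int(self.feature_table["significant"].sum())
        lines = [
            "Proteomics Signature Profile — permutation t-test",
            "=" * 58,
            f"patients: {mat.shape[0]:>4}   ({classes[0]}: {n_by[classes[0]]}, "
            f"{classes[1]}: {n_by[classes[1]]})",
            f"features: {mat.shape[1]:>4}   permutations: {self.n_perm} "
            f"({self.alternative})",
            f"significant at raw p <= {self.alpha}: {n_sig}",
            "-" * 58,
        ]
        cols = [c for c in self.feature_table.columns
                if c not in ("constant", "n_perm_used")]
        top = self.feature_table.sort_values("p_perm").head(max_rows)
        lines.append(top[cols].to_string(index=False,
                                         float_format=lambda v: f"{v:.4g}"))
        if len(self.feature_table) > max_rows:
            lines.append(f"... ({len(self.feature_table) - max_rows} more)")
        return "\n".join(lines)

    def __repr__(self):
        return (f"<PSPResults {len(self.feature_table)} features, "
                f"{int(self.feature_table['significant'].sum())} significant>")
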