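"""QC-plot data for the differential-expression stage.

The differential test itself (negative-binomial model, shrinkage,
independent filtering) is done by an external engine whose result table is
consumed here; this module derives the plot-layer data from it: a PCA of
the samples over the normalised matrix, the volcano classification
(up / down / not significant) at user cutoffs, and the MA-plot points.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .consensus_matrix import SignalMatrix
from .errors import FormatError, ValidationError

DE_COLUMNS = ["feature_id", "baseMean", "log2FoldChange", "padj"]


@dataclass
class PCAResult:
    coordinates: np.ndarray          # samples x n_components
    variance_explained: np.ndarray   # fraction per component, non-increasing
    sample_ids: list[str]

    def __post_init__(self) -> None:
        ve = np.asarray(self.variance_explained, dtype=float)
        if np.any(ve < -1e-12) or np.any(ve > 1 + 1e-9):
            raise ValidationError("variance_explained fractions must be in [0, 1]")
        if np.any(np.diff(ve) > 1e-9):
            raise ValidationError("variance_explained must be non-increasing")
        if ve.sum() > 1 + 1e-9:
            raise ValidationError("variance_explained must sum to <= 1")


def load_de_table(path: str | Path) -> pd.DataFrame:
    """Read an externally produced differential-expression result table.

    Expected TSV columns: feature_id, baseMean, log2FoldChange, padj
    (padj may be empty/NA for features removed by independent filtering).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"DE table lacks columns {missing}", path=str(path))
    if df["feature_id"].duplicated().any():
        dupes = df.loc[df["feature_id"].duplicated(), "feature_id"].tolist()[:5]
        raise FormatError(f"duplicate feature ids, e.g. {dupes}", path=str(path))
    if (df["baseMean"] < 0).any():
        raise FormatError("baseMean must be >= 0", path=str(path))
    padj = df["padj"]
    bad = padj.notna() & ((padj < 0) | (padj > 1))
    if bad.any():
        raise FormatError("padj values must lie in [0, 1] or be missing", path=str(path))
    return df.set_index("feature_id", drop=False)


def pca_samples(matrix: SignalMatrix, n_components: int = 2) -> PCAResult:
    """PCA of samples (observations) over features (variables), mean-centred."""
    n_samples = len(matrix.sample_ids)
    n_features = len(matrix.feature_ids)
    if not 1 <= n_components <= min(n_samples, n_features):
        raise ValidationError(
            f"n_components must be in [1, {min(n_samples, n_features)}], "
            f"got {n_components}"
        )
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(matrix.values.T)
    return PCAResult(
        coordinates=coords,
        variance_explained=pca.explained_variance_ratio_,
        sample_ids=list(matrix.sample_ids),
    )


def volcano_classify(
    table: pd.DataFrame, lfc_cut: float = 1.0, padj_cut: float = 0.05
) -> pd.Series:
    """Label every feature up / down / ns at inclusive cutoffs.

    up:   log2FC >= lfc_cut  and padj <= padj_cut
    down: log2FC <= -lfc_cut and padj <= padj_cut
    ns:   everything else, including features with missing padj.
    """
    if lfc_cut < 0:
        raise ValidationError(f"lfc_cut must be >= 0, got {lfc_cut}")
    if not 0 < padj_cut <= 1:
        raise ValidationError(f"padj_cut must be in (0, 1], got {padj_cut}")
    lfc = table["log2FoldChange"]
    padj = table["padj"]
    significant = padj.notna() & (padj <= padj_cut)
    labels = pd.Series("ns", index=table.index, name="volcano_label")
    labels[significant & (lfc >= lfc_cut)] = "up"
    labels[significant & (lfc <= -lfc_cut)] = "down"
    return labels


def ma_points(
    table: pd.DataFrame, lfc_cut: float = 1.0, padj_cut: float = 0.05
) -> pd.DataFrame:
    """MA-plot points: A = log10(baseMean + 1), M = log2 fold change.

    The significance flag is exactly the volcano rule's non-ns outcome, so
    the two plots always agree on which features are highlighted.
    """
    labels = volcano_classify(table, lfc_cut=lfc_cut, padj_cut=padj_cut)
    return pd.DataFrame(
        {
            "feature_id": table["feature_id"],
            "A": np.log10(table["baseMean"] + 1.0),
            "M": table["log2FoldChange"],
            "significant": labels != "ns",
        },
        index=table.index,
    )
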