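"""Tissue-specificity display statistics for a candidate gene list.

Per-gene expression across a panel of tissues is robust-scaled (subtract the
median, divide by the median absolute deviation), clustered hierarchically
with a Pearson-correlation metric, and summarized by a brain-vs-rest
specificity score.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


def robust_scale(row, center: str = "median", spread: str = "mad") -> np.ndarray:
    """(x - median) / MAD per row; a constant row maps to all zeros.

    ``spread="mean_ad"`` divides by the mean absolute deviation from the
    median instead.  No consistency constant is applied: this is a display
    scaling, not a variance estimate.  Affine equivariant:
    ``robust_scale(a*x + b) == sign(a) * robust_scale(x)``.
    """
    x = np.asarray(row, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values")
    med = np.median(x)
    dev = np.abs(x - med)
    scale = np.median(dev) if spread == "mad" else np.mean(dev)
    if scale == 0:
        return np.zeros_like(x)
    return (x - med) / scale


def scale_matrix(matrix: pd.DataFrame, spread: str = "mad") -> pd.DataFrame:
    """Row-wise :func:`robust_scale` of a gene x tissue matrix."""
    scaled = np.vstack([robust_scale(matrix.loc[g].to_numpy(), spread=spread)
                        for g in matrix.index])
    return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns)


def correlation_cluster(matrix: pd.DataFrame, method: str = "average"):
    """Hierarchical clustering of rows under the 1 - Pearson r metric.

    Zero-variance rows cannot be correlated and are dropped with a warning;
    if nothing variable remains the clustering is refused.  Rows are ordered
    by label before linkage so the result is deterministic under input
    permutation.  Returns ``(linkage_matrix, leaf_labels)``.
    """
    variances = matrix.var(axis=1, ddof=0)
    dropped = list(matrix.index[variances == 0])
    if dropped:
        logger.warning("dropping %d zero-variance rows: %s", len(dropped), dropped[:5])
    kept = matrix.loc[variances > 0].sort_index()
    if len(kept) < 2:
        raise ValueError("clustering refused: fewer than two variable rows")
    corr = np.corrcoef(kept.to_numpy())
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # symmetrize fp noise
    linkage = hierarchy.linkage(squareform(dist, checks=False), method=method)
    order = hierarchy.leaves_list(linkage)
    leaves = [kept.index[i] for i in order]
    return linkage, leaves


def brain_specificity_summary(scaled: pd.DataFrame, brain_flags: pd.Series) -> pd.Series:
    """Per-gene score: mean scaled value in brain tissues minus the rest.

    Positive scores mean preferential brain expression.  ``brain_flags`` is a
    boolean Series over the tissue columns; both tissue classes must be
    non-empty.  Returned sorted descending.
    """
    flags = brain_flags.reindex(scaled.columns)
    if flags.isna().any():
        raise ValueError("brain flag missing for some tissues")
    flags = flags.astype(bool)
    if not flags.any() or flags.all():
        raise ValueError("need at least one brain and one non-brain tissue")
    score = scaled.loc[:, flags].mean(axis=1) - scaled.loc[:, ~flags].mean(axis=1)
    return score.sort_values(ascending=False).rename("brain_specificity")
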