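"""Quality control and normalization.

Outlier removal flags samples outside the 95% Hotelling confidence
ellipse of the first two principal components of unit-variance-scaled
data.  Normalization for the network and classification stages is the
rank-based inverse normal transform (INT) with Blom's offset k = 3/8;
the univariate stage uses a square-root variance-stabilizing transform
of the raw (post-QC) abundances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

from .data_io import AbundanceMatrix

__all__ = [
    "OutlierReport",
    "detect_outliers",
    "remove_outliers",
    "blom_transform",
    "blom_transform_matrix",
    "sqrt_transform",
]


@dataclass
class OutlierReport:
    removed_sample_ids: list[str]
    per_group_removed_counts: dict[str, int]
    scores_2d: pd.DataFrame  # n_samples x 2 PC scores
    ellipse_center: np.ndarray  # always ~0 (scores are centered)
    ellipse_shape: np.ndarray  # 2x2 score covariance
    confidence: float
    threshold: float  # Mahalanobis^2 cutoff on the score plane


def _pca_scores_2d(values: np.ndarray, columns) -> tuple[np.ndarray, list]:
    """Unit-variance scale, drop constant columns, return PC1-2 scores."""
    sd = values.std(axis=0, ddof=1)
    # relative tolerance: a column whose spread is at rounding level is constant
    keep = sd > 1e-12 * np.maximum(np.abs(values.mean(axis=0)), 1.0)
    if not keep.all():
        dropped = [c for c, k in zip(columns, keep) if not k]
        warnings.warn(f"dropping constant metabolites before scaling: {dropped}")
    x = values[:, keep]
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    # SVD of the centered, scaled matrix; PCs are right singular vectors
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :2] * s[:2]
    return scores, [c for c, k in zip(columns, keep) if k]


def detect_outliers(data: AbundanceMatrix, confidence: float = 0.95) -> OutlierReport:
    """Flag samples outside the Hotelling ellipse on the PC1-2 plane.

    The statistic is ``d2 = (t - mean)' S^-1 (t - mean)`` on the 2-D
    scores ``t``, compared to ``2 (n-1) / (n-2) * F_conf(2, n-2)`` — the
    standard two-component Hotelling T-squared ellipse.  PCA is computed
    once on all groups pooled, on unit-variance-scaled data, and is not
    re-fit after removal.  ``confidence=1.0`` flags nothing.
    """
    n = data.n_samples
    if n <= 4:
        raise ValueError("need more than 4 samples for a 2-PC ellipse")
    if not (0.0 < confidence <= 1.0):
        raise ValueError("confidence must be in (0, 1]")
    vals = data.values.to_numpy()
    if np.isnan(vals).any():
        raise ValueError("impute missing values before outlier detection")
    scores, _ = _pca_scores_2d(vals, data.metabolite_names)
    center = scores.mean(axis=0)  # ~0 up to rounding
    cov = np.cov(scores - center, rowvar=False, ddof=1)
    d2 = np.einsum("ij,jk,ik->i", scores - center, np.linalg.inv(cov), scores - center)
    if confidence >= 1.0:
        threshold = np.inf
    else:
        threshold = 2.0 * (n - 1) / (n - 2) * stats.f.ppf(confidence, 2, n - 2)
    flagged = d2 > threshold
    ids = np.asarray(data.sample_ids)
    removed = ids[flagged].tolist()
    counts = {
        g: int(np.sum(flagged & (data.groups.to_numpy() == g)))
        for g in data.group_labels
    }
    return OutlierReport(
        removed_sample_ids=removed,
        per_group_removed_counts=counts,
        scores_2d=pd.DataFrame(scores, index=data.values.index, columns=["PC1", "PC2"]),
        ellipse_center=center,
        ellipse_shape=cov,
        confidence=confidence,
        threshold=float(threshold),
    )


def remove_outliers(
    data: AbundanceMatrix, confidence: float = 0.95
) -> tuple[AbundanceMatrix, OutlierReport]:
    """Detect and drop ellipse outliers in one pass."""
    report = detect_outliers(data, confidence)
    return data.drop_samples(report.removed_sample_ids), report


def blom_transform(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform of one variable.

    Maps each value to ``probit((rank - k) / (n - 2k + 1))`` with Blom's
    offset k = 3/8 by default; ties receive average ranks.  The output is
    monotone in the input ranks, so Spearman correlations are unchanged.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("blom_transform expects a 1-D vector")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in input")
    if np.all(x == x[0]):
        raise ValueError("all values identical; ranks are undefined")
    ranks = stats.rankdata(x, method="average")
    return ndtri((ranks - offset) / (n - 2.0 * offset + 1.0))


def blom_transform_matrix(data: AbundanceMatrix, offset: float = 3.0 / 8.0) -> AbundanceMatrix:
    """Apply the Blom transform to every metabolite column."""
    vals = data.values.to_numpy()
    if np.isnan(vals).any():
        raise ValueError("impute missing values before the INT transform")
    out = np.column_stack([blom_transform(vals[:, j], offset) for j in range(vals.shape[1])])
    return data.with_values(
        pd.DataFrame(out, index=data.values.index, columns=data.values.columns),
        scale="int",
    )


def sqrt_transform(data: AbundanceMatrix) -> AbundanceMatrix:
    """Element-wise square root (variance stabilization for count-like MS data)."""
    vals = data.values.to_numpy()
    if np.nanmin(vals, initial=np.inf) < 0:
        raise ValueError("sqrt transform needs non-negative values")
    return data.with_values(np.sqrt(data.values), scale="sqrt")
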