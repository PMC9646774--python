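"""Shannon-entropy heterogeneity statistics (natural log, nats).

Two statistics: a per-cell inter-sample (mixing) entropy over the
sample-of-origin proportions among each cell's K nearest neighbors, and a
per-sample intratumoral entropy over the proportions of its abnormal-cell
clusters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import ValidationError
from .clustering import _knn_indices


def shannon_entropy(p: np.ndarray) -> float:
    """-sum p ln p with the 0*ln(0) = 0 convention."""
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def intersample_entropy(
    X: np.ndarray,
    sample_ids: np.ndarray,
    K: int | None = None,
) -> np.ndarray:
    """Per-cell entropy of sample proportions among K nearest neighbors.

    ``K`` defaults to ``n_samples - 1``; the cell itself is excluded from
    its neighbor set.
    """
    X = np.asarray(X, dtype=float)
    sample_ids = np.asarray(sample_ids)
    n = X.shape[0]
    if sample_ids.shape != (n,):
        raise ValidationError("sample_ids must align with rows of X")
    samples = pd.unique(sample_ids)
    if len(samples) < 2:
        raise ValidationError("need at least 2 samples")
    if K is None:
        K = len(samples) - 1
    if K < 1:
        raise ValidationError("K must be >= 1")
    if K >= n:
        raise ValidationError(f"K={K} must be < n_cells={n}")
    _, codes = np.unique(sample_ids, return_inverse=True)
    nbrs = _knn_indices(X, K)
    out = np.empty(n)
    n_codes = codes.max() + 1
    for i in range(n):
        counts = np.bincount(codes[nbrs[i]], minlength=n_codes)
        out[i] = shannon_entropy(counts / K)
    return out


def intratumoral_entropy(proportions: np.ndarray) -> float:
    """Entropy of one sample's abnormal-cluster proportions.

    Proportions must be nonnegative and sum to 1 over the sample's abnormal
    clusters; a single cluster gives exactly 0.
    """
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0):
        raise ValidationError("proportions must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(f"proportions sum to {p.sum():.12g}, not 1")
    return shannon_entropy(p)


def per_sample_intratumoral_entropy(
    sample_ids: np.ndarray,
    cluster_labels: np.ndarray,
    abnormal_mask: np.ndarray,
) -> pd.Series:
    """Intratumoral entropy per sample over its abnormal cells.

    ``abnormal_mask`` flags abnormal cells; samples with no abnormal cells
    get NaN (no clonal compartment to score).
    """
    sample_ids = np.asarray(sample_ids)
    cluster_labels = np.asarray(cluster_labels)
    abnormal_mask = np.asarray(abnormal_mask, dtype=bool)
    if not (sample_ids.shape == cluster_labels.shape == abnormal_mask.shape):
        raise ValidationError("inputs must align")
    out = {}
    for s in pd.unique(sample_ids):
        m = (sample_ids == s) & abnormal_mask
        if not m.any():
            out[s] = float("nan")
            continue
        _, counts = np.unique(cluster_labels[m], return_counts=True)
        out[s] = intratumoral_entropy(counts / counts.sum())
    return pd.Series(out, name="intratumoral_entropy")
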