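"""Metaclustering of fine clusters and marker-panel reduction.

Fine clusters are collapsed by hierarchical clustering (Ward by default) of
their median marker profiles; the number of metaclusters is selected by the
gap statistic with a uniform-box reference distribution and the one-
standard-error rule.  Markers are ranked by their Kruskal-Wallis H for
discriminating tumor types, yielding a cumulative "information share" curve
for panel-reduction reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import kruskal

from .core import ValidationError


def cluster_medians(X: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Per-cluster, per-column median; index = sorted cluster ids."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.shape[0] != labels.shape[0]:
        raise ValidationError("labels must align with rows of X")
    ids = np.unique(labels)
    rows = []
    for c in ids:
        member = X[labels == c]
        if member.shape[0] == 0:
            raise ValidationError(f"cluster {c} is empty")
        rows.append(np.median(member, axis=0))
    return pd.DataFrame(np.vstack(rows), index=ids)


def _pooled_within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    """Sum over clusters of within-cluster sum of squared distances to the
    centroid (equals sum_r D_r / (2 n_r) with D_r the pairwise form)."""
    total = 0.0
    for c in np.unique(labels):
        member = X[labels == c]
        if member.shape[0] > 1:
            total += float(((member - member.mean(axis=0)) ** 2).sum())
    return total


def _hier_cut(X: np.ndarray, k: int, method: str) -> np.ndarray:
    Z = hierarchy.linkage(X, method=method)
    return hierarchy.fcluster(Z, t=k, criterion="maxclust")


@dataclass
class GapCurve:
    k: np.ndarray
    gap: np.ndarray
    se: np.ndarray
    log_w: np.ndarray
    chosen_k: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.k, "gap": self.gap, "se": self.se, "log_w": self.log_w}
        )


def gap_statistic(
    X: np.ndarray,
    k_max: int,
    B: int = 50,
    seed: int = 0,
    method: str = "ward",
) -> GapCurve:
    """Gap statistic over hierarchical k-cuts, uniform-box reference.

    ``Gap(k) = mean_b log W*_kb - log W_k`` with ``se_k = sd_b * sqrt(1 + 1/B)``;
    the chosen k is the smallest with ``Gap(k) >= Gap(k+1) - se_{k+1}``
    (falling back to ``k_max`` if the inequality never holds).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k_max >= n:
        raise ValidationError(f"k_max={k_max} must be < n_rows={n}")
    if k_max < 1:
        raise ValidationError("k_max must be >= 1")
    if B < 1:
        raise ValidationError("B must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)

    def dispersions(Y: np.ndarray) -> np.ndarray:
        out = np.empty(k_max)
        for k in range(1, k_max + 1):
            lab = np.ones(Y.shape[0]) if k == 1 else _hier_cut(Y, k, method)
            out[k - 1] = _pooled_within_dispersion(Y, lab)
        return out

    log_w = np.log(np.maximum(dispersions(X), 1e-300))
    ref = np.empty((B, k_max))
    for b in range(B):
        Yb = rng.uniform(lo, hi, size=X.shape)
        ref[b] = np.log(np.maximum(dispersions(Yb), 1e-300))
    gap = ref.mean(axis=0) - log_w
    se = ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)

    chosen = k_max
    for k in range(1, k_max):
        if gap[k - 1] >= gap[k] - se[k]:
            chosen = k
            break
    return GapCurve(
        k=np.arange(1, k_max + 1), gap=gap, se=se, log_w=log_w, chosen_k=chosen
    )


@dataclass
class MetaclusterModel:
    medians: pd.DataFrame          # clusters x markers
    linkage: np.ndarray
    gap_curve: GapCurve | None
    chosen_k: int
    mc_map: dict                   # cluster id -> metacluster id (0-based)

    def metacluster_of(self, cluster) -> int:
        if cluster not in self.mc_map:
            raise ValidationError(f"cluster {cluster!r} missing from metacluster map")
        return self.mc_map[cluster]


def fit_metaclusters(
    medians: pd.DataFrame,
    k: int | None = None,
    k_max: int | None = None,
    B: int = 50,
    seed: int = 0,
    method: str = "ward",
) -> MetaclusterModel:
    """Hierarchically metacluster median profiles.

    If ``k`` is None the number of metaclusters is selected by the gap
    statistic scanned up to ``k_max`` (default ``n_clusters - 1``).
    """
    X = medians.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValidationError("median profiles contain non-finite values")
    n = X.shape[0]
    Z = hierarchy.linkage(X, method=method) if n > 1 else np.empty((0, 4))
    curve = None
    if k is None:
        if n == 1:
            k = 1
        else:
            k_max = min(k_max if k_max is not None else n - 1, n - 1)
            curve = gap_statistic(X, k_max=k_max, B=B, seed=seed, method=method)
            k = curve.chosen_k
    if not (1 <= k <= n):
        raise ValidationError(f"k={k} out of range for {n} clusters")
    flat = (
        np.ones(n, dtype=int)
        if k == 1
        else hierarchy.fcluster(Z, t=k, criterion="maxclust")
    )
    mc_map = {cid: int(mc - 1) for cid, mc in zip(medians.index, flat)}
    return MetaclusterModel(
        medians=medians, linkage=Z, gap_curve=curve, chosen_k=int(k), mc_map=mc_map
    )


def assign_metaclusters(model: MetaclusterModel, labels: np.ndarray) -> np.ndarray:
    """Per-cell metacluster id via the fitted cluster -> metacluster map."""
    labels = np.asarray(labels)
    return np.array([model.metacluster_of(c) for c in labels], dtype=np.int64)


@dataclass
class MarkerRanking:
    scores: pd.Series              # per-marker H statistic, original order
    order: list                    # marker names in descending-score order
    cumulative_share: np.ndarray   # along `order`

    def panel(self, m: int) -> tuple[list, float]:
        """Top-m markers and the information share they retain."""
        if not (1 <= m <= len(self.order)):
            raise ValidationError(f"panel size {m} out of range")
        return self.order[:m], float(self.cumulative_share[m - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": self.order,
                "score": self.scores[self.order].to_numpy(),
                "cumulative_share": self.cumulative_share,
            }
        )


def rank_markers(sample_profiles: pd.DataFrame, types: pd.Series) -> MarkerRanking:
    """Rank markers by Kruskal-Wallis H across tumor types.

    ``sample_profiles`` is samples x markers (e.g. per-sample clonal-cell
    medians); ``types`` assigns each sample a type label.  Markers identical
    across all samples score 0.
    """
    types = pd.Series(types).reindex(sample_profiles.index)
    if types.isna().any():
        raise ValidationError("every sample needs a type label")
    groups = types.unique()
    if len(groups) < 2:
        raise ValidationError("need at least 2 types")
    for g in groups:
        if (types == g).sum() < 2:
            raise ValidationError(f"type {g!r} has fewer than 2 samples")
    scores = {}
    for marker in sample_profiles.columns:
        vals = [sample_profiles.loc[types == g, marker].to_numpy() for g in groups]
        flat = np.concatenate(vals)
        if np.allclose(flat, flat[0]):
            scores[marker] = 0.0
            continue
        h, _ = kruskal(*vals)
        scores[marker] = float(h)
    s = pd.Series(scores)
    order = list(s.sort_values(ascending=False, kind="stable").index)
    total = s.sum()
    if total == 0:
        share = np.linspace(1 / len(order), 1.0, len(order))  # degenerate: uniform
    else:
        share = np.cumsum(s[order].to_numpy()) / total
    return MarkerRanking(scores=s, order=order, cumulative_share=share)
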