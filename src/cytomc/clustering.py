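"""Consensus graph clustering.

Cells are clustered by building an exact k-nearest-neighbor graph
(Euclidean, ties broken by cell index), reweighting edges by the Jaccard
overlap of neighbor sets, and maximizing modularity with multilevel Louvain.
The procedure is repeated R times with distinct seeds; the run with the
highest mean pairwise adjusted Rand index against all other runs (mean NMI,
then lowest run index, as tie-breaks) is kept as the consensus labeling.
Clusters holding less than a minimum fraction of a sample's cells are
flagged for removal sample-by-sample.

ARI and NMI are implemented here from the contingency table rather than
delegated, so they can be verified against exhaustive pair-counting /
entropy oracles.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import igraph as ig
import numpy as np
from scipy import sparse

from .core import ValidationError


# ---------------------------------------------------------------------------
# partition agreement metrics
# ---------------------------------------------------------------------------

def _contingency(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    u = np.asarray(u)
    v = np.asarray(v)
    if u.shape != v.shape or u.ndim != 1:
        raise ValidationError("label vectors must be 1-D and equal length")
    _, ui = np.unique(u, return_inverse=True)
    _, vi = np.unique(v, return_inverse=True)
    table = np.zeros((ui.max() + 1, vi.max() + 1), dtype=np.int64)
    np.add.at(table, (ui, vi), 1)
    return table


def adjusted_rand_index(u, v) -> float:
    """Chance-corrected pair-counting agreement between two labelings."""
    table = _contingency(u, v)
    n = table.sum()
    if n < 2:
        raise ValidationError("need at least 2 items")

    def comb2(x):
        return x * (x - 1) / 2.0

    index = comb2(table).sum()
    a = comb2(table.sum(axis=1)).sum()
    b = comb2(table.sum(axis=0)).sum()
    expected = a * b / comb2(n)
    maximum = (a + b) / 2.0
    if maximum == expected:  # both partitions degenerate (all-singleton or single cluster)
        return 1.0
    return float((index - expected) / (maximum - expected))


def normalized_mutual_information(u, v, variant: str = "sqrt") -> float:
    """Mutual information normalized by partition entropies.

    ``variant`` selects the normalizer: ``sqrt`` (geometric mean of the two
    entropies, the default), ``max`` or ``arithmetic``.  If exactly one
    partition has a single cluster the score is defined as 0; if both do,
    the partitions are identical and the score is 1.
    """
    table = _contingency(u, v).astype(float)
    n = table.sum()
    pu = table.sum(axis=1) / n
    pv = table.sum(axis=0) / n
    hu = -np.sum(pu * np.log(pu, where=pu > 0, out=np.zeros_like(pu)))
    hv = -np.sum(pv * np.log(pv, where=pv > 0, out=np.zeros_like(pv)))
    if hu == 0 and hv == 0:
        return 1.0
    if hu == 0 or hv == 0:
        return 0.0
    pij = table / n
    outer = np.outer(pu, pv)
    nz = pij > 0
    mi = float(np.sum(pij[nz] * np.log(pij[nz] / outer[nz])))
    if variant == "sqrt":
        denom = np.sqrt(hu * hv)
    elif variant == "max":
        denom = max(hu, hv)
    elif variant == "arithmetic":
        denom = (hu + hv) / 2.0
    else:
        raise ValidationError(f"unknown NMI variant {variant!r}")
    return float(max(0.0, min(1.0, mi / denom)))


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def _knn_indices(X: np.ndarray, k: int, chunk: int = 1024) -> np.ndarray:
    """Exact k-NN (self excluded), ties broken by index; deterministic."""
    n = X.shape[0]
    sq = np.einsum("ij,ij->i", X, X)
    out = np.empty((n, k), dtype=np.int64)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d2 = sq[start:stop, None] + sq[None, :] - 2.0 * (X[start:stop] @ X.T)
        rows = np.arange(start, stop)
        d2[np.arange(stop - start), rows] = np.inf  # exclude self
        # argsort is stable on the secondary index axis after rounding guard
        part = np.argpartition(d2, k, axis=1)[:, : k + 8]
        for r in range(stop - start):
            cand = part[r]
            orderd = d2[r, cand]
            sel = cand[np.lexsort((cand, orderd))][:k]
            out[start + r] = sel
    return out


def knn_jaccard_graph(X: np.ndarray, k_neighbors: int) -> ig.Graph:
    """Jaccard-weighted k-NN graph (PhenoGraph-style).

    Edge weight between cells i and j is ``|N(i) ∩ N(j)| / |N(i) ∪ N(j)|``
    over their k-neighbor sets (self excluded); candidate pairs are those
    appearing in each other's neighbor lists, and zero-weight edges are
    dropped.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k_neighbors < 1:
        raise ValidationError("k_neighbors must be >= 1")
    if k_neighbors >= n:
        raise ValidationError(f"k_neighbors={k_neighbors} must be < n_cells={n}")
    nbrs = _knn_indices(X, k_neighbors)
    rows = np.repeat(np.arange(n), k_neighbors)
    A = sparse.csr_matrix(
        (np.ones(n * k_neighbors), (rows, nbrs.ravel())), shape=(n, n)
    )
    inter = (A @ A.T).tocoo()  # |N(i) ∩ N(j)| for all pairs sharing a neighbor
    cand = ((A + A.T) > 0).tocoo()  # directed kNN pairs
    inter_d = {(i, j): v for i, j, v in zip(inter.row, inter.col, inter.data) if i < j}
    edges, weights = [], []
    for i, j in zip(cand.row, cand.col):
        if i >= j:
            continue
        shared = inter_d.get((i, j), 0.0)
        if shared > 0:
            w = shared / (2 * k_neighbors - shared)
            edges.append((int(i), int(j)))
            weights.append(float(w))
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


# ---------------------------------------------------------------------------
# Louvain + consensus
# ---------------------------------------------------------------------------

@dataclass
class ClusteringRun:
    labels: np.ndarray
    seed: int
    k_neighbors: int
    modularity: float


@dataclass
class ConsensusResult:
    runs: list[ClusteringRun]
    ari: np.ndarray
    nmi: np.ndarray
    selected: int

    @property
    def labels(self) -> np.ndarray:
        return self.runs[self.selected].labels

    @property
    def mean_ari(self) -> float:
        return _mean_offdiag(self.ari)[self.selected]

    @property
    def mean_nmi(self) -> float:
        return _mean_offdiag(self.nmi)[self.selected]


def louvain_partition(graph: ig.Graph, seed: int, k_neighbors: int = 0) -> ClusteringRun:
    """Multilevel modularity maximization; deterministic given ``seed``."""
    if graph.vcount() == 0:
        raise ValidationError("empty graph")
    state = random.getstate()
    try:
        random.seed(seed)  # python-igraph draws randomness from the random module
        part = graph.community_multilevel(weights="weight" if "weight" in graph.es.attributes() else None)
    finally:
        random.setstate(state)
    labels = np.asarray(part.membership, dtype=np.int64)
    # contiguous ids from 0 in order of first appearance
    _, labels = np.unique(labels, return_inverse=True)
    return ClusteringRun(
        labels=labels,
        seed=seed,
        k_neighbors=k_neighbors,
        modularity=float(part.modularity),
    )


def _mean_offdiag(mat: np.ndarray) -> np.ndarray:
    r = mat.shape[0]
    return (mat.sum(axis=1) - np.diag(mat)) / (r - 1)


def consensus_cluster(
    X: np.ndarray,
    k_neighbors: int,
    R: int = 25,
    seed: int = 0,
    nmi_variant: str = "sqrt",
) -> ConsensusResult:
    """R Louvain runs on one Jaccard graph; pick the most agreeing run."""
    if R < 2:
        raise ValidationError("R must be >= 2")
    graph = knn_jaccard_graph(X, k_neighbors)
    runs = [louvain_partition(graph, seed + r, k_neighbors) for r in range(R)]
    ari = np.eye(R)
    nmi = np.eye(R)
    for i in range(R):
        for j in range(i + 1, R):
            ari[i, j] = ari[j, i] = adjusted_rand_index(runs[i].labels, runs[j].labels)
            nmi[i, j] = nmi[j, i] = normalized_mutual_information(
                runs[i].labels, runs[j].labels, variant=nmi_variant
            )
    selected = select_consensus_run(ari, nmi)
    return ConsensusResult(runs=runs, ari=ari, nmi=nmi, selected=selected)


def select_consensus_run(ari: np.ndarray, nmi: np.ndarray) -> int:
    """Index of the run maximizing mean off-diagonal ARI (ties: mean NMI,
    then lowest run index)."""
    mean_ari = _mean_offdiag(ari)
    mean_nmi = _mean_offdiag(nmi)
    best = np.flatnonzero(np.isclose(mean_ari, mean_ari.max()))
    if len(best) > 1:
        sub = mean_nmi[best]
        best = best[np.isclose(sub, sub.max())]
    return int(best[0])


def prune_rare_clusters(
    labels: np.ndarray,
    sample_ids: np.ndarray,
    min_fraction: float = 0.01,
) -> np.ndarray:
    """Mask of cells to retain: within each sample, a cell is kept iff its
    cluster holds at least ``min_fraction`` of that sample's cells
    (inclusive threshold)."""
    if not (0 < min_fraction < 1):
        raise ValidationError("min_fraction must be in (0, 1)")
    labels = np.asarray(labels)
    sample_ids = np.asarray(sample_ids)
    if labels.shape != sample_ids.shape:
        raise ValidationError("labels and sample_ids must align")
    keep = np.zeros(labels.shape[0], dtype=bool)
    for s in np.unique(sample_ids):
        m = sample_ids == s
        total = m.sum()
        vals, counts = np.unique(labels[m], return_counts=True)
        ok = {v for v, c in zip(vals, counts) if c / total >= min_fraction}
        keep[m] = np.isin(labels[m], list(ok))
    return keep


def subsample_per_sample(
    sample_ids: np.ndarray, max_cells: int, seed: int = 0
) -> np.ndarray:
    """Seeded per-sample subsampling mask (at most ``max_cells`` per sample)."""
    rng = np.random.default_rng(seed)
    sample_ids = np.asarray(sample_ids)
    keep = np.zeros(sample_ids.shape[0], dtype=bool)
    for s in np.unique(sample_ids):
        idx = np.flatnonzero(sample_ids == s)
        if idx.size > max_cells:
            idx = rng.choice(idx, size=max_cells, replace=False)
        keep[idx] = True
    return keep


def embed_umap(X: np.ndarray, min_dist: float = 0.4, n_neighbors: int = 30, seed: int = 0):
    """Optional 2-D embedding for plotting (no numerical contract)."""
    import umap  # deferred: plotting helper only

    return umap.UMAP(
        min_dist=min_dist, n_neighbors=n_neighbors, random_state=seed
    ).fit_transform(np.asarray(X, dtype=float))
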