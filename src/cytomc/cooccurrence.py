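"""Composition matrices, probabilistic co-occurrence, and sample clustering.

Presence/absence of each population per sample is thresholded from a
fractional composition matrix.  For every population pair the exact
hypergeometric distribution of the number of co-occupied samples (given the
two marginal presence counts) yields the expected overlap and the lower-
and upper-tail probabilities; pairs with a tail below alpha become signed
network edges.  Mutual exclusivity of two populations can additionally be
tested with an uncorrected Pearson chi-square on the 2x2 presence table.
Samples are clustered compositionally by Ward linkage on Jensen-Shannon
divergence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import chi2 as chi2_dist
from scipy.stats import hypergeom

from .core import ValidationError
from .entropy import shannon_entropy

DEFAULT_ALPHA = 0.05
DEFAULT_PRESENCE_THRESHOLD = 0.01


# ---------------------------------------------------------------------------
# composition and presence
# ---------------------------------------------------------------------------

def composition_matrix(
    sample_ids: np.ndarray,
    labels: np.ndarray,
    denominator_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Samples x clusters fractional abundance matrix (rows sum to 1).

    ``denominator_mask`` restricts both numerator and denominator to a cell
    subset (e.g. clonal B-cells); samples with no cells in the subset are
    dropped.
    """
    sample_ids = np.asarray(sample_ids)
    labels = np.asarray(labels)
    if sample_ids.shape != labels.shape:
        raise ValidationError("sample_ids and labels must align")
    if denominator_mask is not None:
        denominator_mask = np.asarray(denominator_mask, dtype=bool)
        sample_ids = sample_ids[denominator_mask]
        labels = labels[denominator_mask]
    df = pd.crosstab(pd.Series(sample_ids, name="sample"), pd.Series(labels, name="cluster"))
    df = df.loc[df.sum(axis=1) > 0]
    return df.div(df.sum(axis=1), axis=0)


def presence_matrix(
    comp: pd.DataFrame,
    threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    counts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Binary presence matrix.

    Fractional mode (default): present iff abundance is strictly greater
    than ``threshold``.  Count mode (``threshold`` a positive integer and
    ``counts`` given): present iff the absolute cell count is >= threshold.
    """
    if isinstance(threshold, (int, np.integer)) and not isinstance(threshold, bool) and threshold >= 1:
        if counts is None:
            raise ValidationError("count-mode threshold requires a counts matrix")
        return (counts >= int(threshold)).astype(int)
    if not (0 < float(threshold) < 1):
        raise ValidationError(f"fractional threshold must be in (0, 1), got {threshold}")
    return (comp > float(threshold)).astype(int)


# ---------------------------------------------------------------------------
# exact pairwise co-occurrence
# ---------------------------------------------------------------------------

@dataclass
class PairCooccurrence:
    i: object
    j: object
    N: int
    N1: int
    N2: int
    j_obs: int
    expected: float
    variance: float
    p_lt: float
    p_gt: float
    verdict: str  # positive | negative | none
    low_expectation: bool

    @property
    def score(self) -> float:
        """Signed standardized overlap (0 when the distribution is degenerate)."""
        if self.variance <= 0:
            return 0.0
        return (self.j_obs - self.expected) / float(np.sqrt(self.variance))


def pair_cooccurrence(
    N: int, N1: int, N2: int, j_obs: int, alpha: float = DEFAULT_ALPHA,
    i=None, j=None,
) -> PairCooccurrence:
    """Exact hypergeometric co-occurrence summary for one population pair.

    ``P(j) = C(N1, j) C(N - N1, N2 - j) / C(N, N2)`` over the support
    ``max(0, N1 + N2 - N) .. min(N1, N2)``; ``p_lt``/``p_gt`` are the
    inclusive lower/upper tails at the observed overlap ``j_obs``.
    """
    if not (0 <= N1 <= N and 0 <= N2 <= N):
        raise ValidationError("presence counts must lie in [0, N]")
    lo, hi = max(0, N1 + N2 - N), min(N1, N2)
    if not (lo <= j_obs <= hi):
        raise ValidationError(
            f"observed overlap {j_obs} outside hypergeometric support [{lo}, {hi}]"
        )
    dist = hypergeom(N, N1, N2)
    expected = N1 * N2 / N if N > 0 else 0.0
    variance = (
        N1 * N2 * (N - N1) * (N - N2) / (N * N * (N - 1)) if N > 1 else 0.0
    )
    p_lt = float(dist.cdf(j_obs))
    p_gt = float(dist.sf(j_obs - 1))
    if p_gt < alpha and p_gt <= p_lt:
        verdict = "positive"
    elif p_lt < alpha:
        verdict = "negative"
    else:
        verdict = "none"
    return PairCooccurrence(
        i=i, j=j, N=N, N1=N1, N2=N2, j_obs=int(j_obs),
        expected=float(expected), variance=float(variance),
        p_lt=p_lt, p_gt=p_gt, verdict=verdict,
        low_expectation=expected < 1.0,
    )


@dataclass
class CooccurrenceResult:
    pairs: list[PairCooccurrence]
    alpha: float
    clusters: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "i": [p.i for p in self.pairs],
                "j": [p.j for p in self.pairs],
                "N": [p.N for p in self.pairs],
                "N1": [p.N1 for p in self.pairs],
                "N2": [p.N2 for p in self.pairs],
                "observed": [p.j_obs for p in self.pairs],
                "expected": [p.expected for p in self.pairs],
                "p_lt": [p.p_lt for p in self.pairs],
                "p_gt": [p.p_gt for p in self.pairs],
                "verdict": [p.verdict for p in self.pairs],
                "low_expectation": [p.low_expectation for p in self.pairs],
            }
        )


def cooccurrence_analysis(
    presence: pd.DataFrame, alpha: float = DEFAULT_ALPHA
) -> CooccurrenceResult:
    """All-pairs exact co-occurrence over the presence matrix columns."""
    cols = list(presence.columns)
    N = presence.shape[0]
    P = presence.to_numpy(dtype=int)
    pairs = []
    for a in range(len(cols)):
        for b in range(a + 1, len(cols)):
            n1 = int(P[:, a].sum())
            n2 = int(P[:, b].sum())
            jobs = int((P[:, a] & P[:, b]).sum())
            pairs.append(
                pair_cooccurrence(N, n1, n2, jobs, alpha=alpha, i=cols[a], j=cols[b])
            )
    return CooccurrenceResult(pairs=pairs, alpha=alpha, clusters=cols)


def exclusivity_chi2(presence_i, presence_j) -> tuple[float, float]:
    """Uncorrected Pearson chi-square (1 df) on the 2x2 presence table."""
    pi = np.asarray(presence_i, dtype=int)
    pj = np.asarray(presence_j, dtype=int)
    if pi.shape != pj.shape or pi.ndim != 1:
        raise ValidationError("presence vectors must be 1-D and equal length")
    n = pi.shape[0]
    if n < 4:
        raise ValidationError("need at least 4 samples")
    a = int(((pi == 1) & (pj == 1)).sum())
    b = int(((pi == 1) & (pj == 0)).sum())
    c = int(((pi == 0) & (pj == 1)).sum())
    d = int(((pi == 0) & (pj == 0)).sum())
    return chi2_from_table(a, b, c, d)


def chi2_from_table(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square for the 2x2 table [[a, b], [c, d]], no correction."""
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValidationError("zero margin: chi-square statistic undefined")
    stat = n * (a * d - b * c) ** 2 / np.prod([float(m) for m in margins])
    p = float(chi2_dist.sf(stat, df=1))
    return float(stat), p


# ---------------------------------------------------------------------------
# compositional sample clustering
# ---------------------------------------------------------------------------

def jensen_shannon_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """JSD (natural log): H((P+Q)/2) - (H(P) + H(Q))/2, in [0, ln 2]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    for r in (p, q):
        if abs(r.sum() - 1.0) > 1e-9 or np.any(r < 0):
            raise ValidationError("JSD inputs must be probability vectors")
    m = (p + q) / 2.0
    return shannon_entropy(m) - (shannon_entropy(p) + shannon_entropy(q)) / 2.0


def jsd_cluster_samples(
    comp: pd.DataFrame, n_groups: int = 2
) -> tuple[np.ndarray, pd.Series]:
    """Ward linkage on sqrt-JSD distances between composition rows."""
    if comp.shape[0] < 3:
        raise ValidationError("need at least 3 samples")
    rows = comp.to_numpy(dtype=float)
    if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-9):
        raise ValidationError("composition rows must sum to 1")
    n = rows.shape[0]
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = np.sqrt(max(0.0, jensen_shannon_divergence(rows[i], rows[j])))
    Z = hierarchy.linkage(squareform(dm, checks=False), method="ward")
    groups = hierarchy.fcluster(Z, t=n_groups, criterion="maxclust")
    return Z, pd.Series(groups, index=comp.index, name="group")


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------

def build_network(result: CooccurrenceResult) -> nx.Graph:
    """Graph of significant associations; edge weight = exp(signed score)."""
    g = nx.Graph()
    g.add_nodes_from(str(c) for c in result.clusters)
    for p in result.pairs:
        if p.verdict == "none":
            continue
        sign = 1.0 if p.verdict == "positive" else -1.0
        score = abs(p.score) * sign
        g.add_edge(
            str(p.i),
            str(p.j),
            weight=float(np.exp(score)),
            sign="positive" if sign > 0 else "negative",
            score=float(score),
            p_lt=p.p_lt,
            p_gt=p.p_gt,
        )
    return g


def export_network(result: CooccurrenceResult, graphml_path: str | Path, tsv_path: str | Path | None = None) -> nx.Graph:
    g = build_network(result)
    nx.write_graphml(g, str(graphml_path))
    if tsv_path is not None:
        rows = [
            {"i": u, "j": v, **data}
            for u, v, data in g.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["i", "j", "weight", "sign", "score", "p_lt", "p_gt"]).to_csv(
            tsv_path, sep="\t", index=False
        )
    return g
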