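"""Graph-based clustering in pathway-score (or gene) space, marker genes,
and pro-embolic cluster identification.

Cells are embedded (PCA), connected into a shared-nearest-neighbor (SNN)
graph whose edge weights are Jaccard overlaps of k-neighborhoods (weak
edges pruned at 1/15), and grouped by seeded Louvain modularity
optimization.  Markers come from a cluster-vs-rest Wilcoxon rank-sum
test with Benjamini-Hochberg correction; clusters whose cells score
significantly high on the fibrin-clot pathways are called pro-embolic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from .preprocess import ExpressionMatrix
from .scoring import PathwayScoreMatrix

__all__ = [
    "ClusterLabels",
    "build_snn_graph",
    "cluster_graph",
    "SNNLouvain",
    "rank_sum_test",
    "find_markers",
    "identify_proembolic_clusters",
]


@dataclass
class ClusterLabels:
    """Per-cell cluster assignment; labels are contiguous from 0."""

    label: np.ndarray
    space: str = "pathway"
    resolution: float = 1.0
    k_neighbors: int | None = None

    def __post_init__(self) -> None:
        self.label = np.asarray(self.label, dtype=int)
        uniq = np.unique(self.label)
        if len(uniq) and (uniq[0] != 0 or uniq[-1] != len(uniq) - 1):
            raise ValueError("cluster labels must be contiguous from 0")

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.label))


def build_snn_graph(embedding: np.ndarray, k: int = 20,
                    prune: float = 1.0 / 15.0) -> nx.Graph:
    """Shared-nearest-neighbor graph on a cells x dims embedding.

    Neighborhoods of size ``k`` include the cell itself; edge weight is
    the Jaccard overlap of the two neighborhoods and weights below
    ``prune`` are removed.  Every cell is a node even if isolated.
    """
    X = np.atleast_2d(np.asarray(embedding, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells to build a graph")
    if k >= n:
        raise ValueError(f"k={k} must be < n_cells={n}")
    nn = NearestNeighbors(n_neighbors=k).fit(X)
    _, idx = nn.kneighbors(X)
    rows = np.repeat(np.arange(n), k)
    A = sp.csr_matrix(
        (np.ones(n * k), (rows, idx.ravel())), shape=(n, n)
    )
    shared = (A @ A.T).tocoo()
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    mask = shared.row < shared.col
    r, c, s = shared.row[mask], shared.col[mask], shared.data[mask]
    jac = s / (2 * k - s)
    keep = jac >= prune
    graph.add_weighted_edges_from(
        zip(r[keep].tolist(), c[keep].tolist(), jac[keep].tolist())
    )
    return graph


def cluster_graph(graph: nx.Graph, resolution: float = 1.0,
                  seed: int = 0) -> ClusterLabels:
    """Louvain modularity communities, relabeled by decreasing size.

    Deterministic under ``seed``; singleton components keep their own
    labels.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comms = nx.community.louvain_communities(
        graph, weight="weight", resolution=resolution, seed=int(seed)
    )
    comms = sorted(comms, key=lambda c: (-len(c), min(c)))
    labels = np.empty(graph.number_of_nodes(), dtype=int)
    for lab, comm in enumerate(comms):
        labels[list(comm)] = lab
    return ClusterLabels(labels, resolution=resolution)


class SNNLouvain:
    """SNN graph + Louvain clustering as a single fit_predict estimator."""

    def __init__(self, k: int = 20, resolution: float = 1.0,
                 prune: float = 1.0 / 15.0, random_state: int = 0):
        self.k = k
        self.resolution = resolution
        self.prune = prune
        self.random_state = random_state

    def fit_predict(self, X) -> np.ndarray:
        self.graph_ = build_snn_graph(X, k=self.k, prune=self.prune)
        clusters = cluster_graph(self.graph_, resolution=self.resolution,
                                 seed=self.random_state)
        clusters.k_neighbors = self.k
        self.labels_ = clusters.label
        self.clusters_ = clusters
        return self.labels_


def _tie_term(ranks_sorted_counts: np.ndarray) -> float:
    t = ranks_sorted_counts
    return float(np.sum(t**3 - t))


def rank_sum_test(x, y, alternative: str = "two-sided",
                  exact_max: int = 8) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) test of ``x`` vs ``y``.

    Uses the tie-corrected normal approximation, switching to exact
    enumeration when both groups have at most ``exact_max`` observations.
    Returns ``(U, p)`` where ``U`` counts pairs (x_i > y_j) plus half
    ties.  ``alternative='greater'`` tests whether x is stochastically
    larger than y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    if n1 <= exact_max and n2 <= exact_max:
        res = stats.mannwhitneyu(x, y, alternative=alternative, method="exact")
        return float(res.statistic), float(res.pvalue)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    R1 = ranks[:n1].sum()
    U = R1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie = _tie_term(counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if var == 0:
        return float(U), 1.0
    sd = np.sqrt(var)
    # continuity correction: U moves in half-integer steps
    if alternative == "two-sided":
        z = max(abs(U - mu) - 0.5, 0.0) / sd
        p = 2 * stats.norm.sf(z)
    elif alternative == "greater":
        p = stats.norm.sf((U - mu - 0.5) / sd)
    elif alternative == "less":
        p = stats.norm.cdf((U - mu + 0.5) / sd)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(U), float(min(p, 1.0))


def _wilcoxon_cluster_vs_rest(values: np.ndarray, in_cluster: np.ndarray) -> np.ndarray:
    """Vectorized two-sided tie-corrected normal-approximation p per gene."""
    n, _ = values.shape
    n1 = int(in_cluster.sum())
    n2 = n - n1
    ranks = stats.rankdata(values, axis=0)
    R1 = ranks[in_cluster].sum(axis=0)
    U = R1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction per gene
    tie = np.empty(values.shape[1])
    for j in range(values.shape[1]):
        _, counts = np.unique(values[:, j], return_counts=True)
        tie[j] = _tie_term(counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    z = np.zeros_like(U)
    ok = var > 0
    z[ok] = np.maximum(np.abs(U[ok] - mu) - 0.5, 0.0) / np.sqrt(var[ok])
    p = 2 * stats.norm.sf(np.abs(z))
    p[~ok] = 1.0
    return np.minimum(p, 1.0)


def find_markers(expr: ExpressionMatrix, labels: ClusterLabels,
                 fdr_threshold: float = 0.05, min_abs_logfc: float = 0.25,
                 min_cells: int = 3) -> pd.DataFrame:
    """Cluster-vs-rest marker genes.

    Per cluster and gene: two-sided Wilcoxon rank-sum p-value (normal
    approximation with tie correction), natural-log fold change of mean
    back-transformed expression (pseudocount 1e-9), and BH-adjusted FDR
    across genes within the cluster.  Rows failing ``fdr < 0.05`` or
    ``|log_fc| >= 0.25`` are dropped.  Clusters below ``min_cells`` are
    skipped with a warning.
    """
    if len(labels.label) != expr.n_cells:
        raise ValueError("labels do not cover the expression matrix")
    raw = np.expm1(expr.values)
    rows = []
    for cluster in np.unique(labels.label):
        mask = labels.label == cluster
        if mask.sum() < min_cells or (~mask).sum() < min_cells:
            warnings.warn(
                f"cluster {cluster} has fewer than {min_cells} cells on one "
                "side; skipped", stacklevel=2,
            )
            continue
        p = _wilcoxon_cluster_vs_rest(expr.values, mask)
        fdr = stats.false_discovery_control(p, method="bh")
        log_fc = np.log(
            (raw[mask].mean(axis=0) + 1e-9) / (raw[~mask].mean(axis=0) + 1e-9)
        )
        keep = (fdr < fdr_threshold) & (np.abs(log_fc) >= min_abs_logfc)
        for j in np.flatnonzero(keep):
            rows.append(
                (int(cluster), expr.gene_names[j], float(log_fc[j]),
                 float(p[j]), float(fdr[j]))
            )
    table = pd.DataFrame(rows, columns=["cluster", "gene", "log_fc", "p_value", "fdr"])
    table.attrs["fdr_threshold"] = fdr_threshold
    table.attrs["min_abs_logfc"] = min_abs_logfc
    return table


def identify_proembolic_clusters(embolic: PathwayScoreMatrix,
                                 labels: ClusterLabels,
                                 alpha: float = 0.05) -> set[int]:
    """Clusters whose cells score high on the fibrin-clot pathways.

    A cluster is pro-embolic iff the one-sided rank-sum test of its
    cells' mean embolic pathway score against all other cells is
    BH-significant at ``alpha`` and its median score exceeds the global
    median.
    """
    if embolic.scores.shape[0] != len(labels.label):
        raise ValueError("scores and labels cover different cells")
    cell_score = embolic.scores.mean(axis=1)
    clusters = np.unique(labels.label)
    if len(clusters) < 2:
        warnings.warn("fewer than 2 clusters; no pro-embolic call possible",
                      stacklevel=2)
        return set()
    global_median = np.median(cell_score)
    pvals, meds = [], []
    for c in clusters:
        mask = labels.label == c
        _, p = rank_sum_test(cell_score[mask], cell_score[~mask],
                             alternative="greater")
        pvals.append(p)
        meds.append(np.median(cell_score[mask]))
    qvals = stats.false_discovery_control(np.array(pvals), method="bh")
    return {
        int(c)
        for c, q, m in zip(clusters, qvals, meds)
        if q < alpha and m > global_median
    }
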