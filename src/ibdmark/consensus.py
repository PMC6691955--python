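"""Subgroup discovery by resampling-based consensus clustering.

Monti-style scheme: repeatedly subsample the cohort without replacement,
cluster each subsample with a base method (k-means on the most-variable
genes), and record for every sample pair how often it co-clusters among the
resamples in which it was co-sampled. The consensus matrix entry (i, j) is
that proportion. The number of clusters k is chosen by minimising the PAC
score — the proportion of off-diagonal consensus entries falling in an
ambiguous middle band — and final labels come from average-linkage
hierarchical clustering of the consensus dissimilarity 1 − M.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

__all__ = ["ConsensusResult", "consensus_cluster", "assign_subgroup_names", "pac"]


@dataclass
class ConsensusResult:
    consensus_matrix: pd.DataFrame      # samples x samples, entries in [0,1]
    chosen_k: int
    labels: pd.Series                   # integer cluster id in {1..chosen_k}
    k_scores: pd.Series                 # PAC per candidate k
    consensus_by_k: dict[int, np.ndarray]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.k_scores.index, "pac": self.k_scores.values,
             "chosen": self.k_scores.index == self.chosen_k}
        )


def pac(consensus: np.ndarray, lower: float = 0.1, upper: float = 0.9) -> float:
    """Proportion of ambiguous clustering over off-diagonal entries."""
    iu = np.triu_indices_from(consensus, k=1)
    vals = consensus[iu]
    return float(np.mean((vals > lower) & (vals < upper)))


def _top_variable_genes(matrix: pd.DataFrame, n_top: int) -> pd.DataFrame:
    if n_top >= matrix.shape[0]:
        return matrix
    order = matrix.var(axis=1).sort_values(ascending=False)
    return matrix.loc[order.index[:n_top]]


def consensus_cluster(
    matrix: pd.DataFrame,
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6),
    n_resamples: int = 250,
    subsample_fraction: float = 0.8,
    n_top_genes: int = 5000,
    pac_window: tuple[float, float] = (0.1, 0.9),
    seed: int = 0,
) -> ConsensusResult:
    """Consensus clustering of samples (columns) of a genes-by-samples matrix.

    Fully reproducible from (data, parameters, seed). A sample pair never
    co-sampled across the resamples is an error instructing a larger
    ``n_resamples``.
    """
    if n_resamples < 50:
        raise ValueError("n_resamples must be >= 50")
    if not 0.5 < subsample_fraction < 1.0:
        raise ValueError("subsample_fraction must lie in (0.5, 1)")

    rng = np.random.default_rng(seed)
    X = _top_variable_genes(matrix, n_top_genes).to_numpy(dtype=float).T  # samples x genes
    n = X.shape[0]
    m = max(2, int(round(subsample_fraction * n)))

    subsamples = [rng.choice(n, size=m, replace=False) for _ in range(n_resamples)]
    co_sampled = np.zeros((n, n))
    for idx in subsamples:
        co_sampled[np.ix_(idx, idx)] += 1
    if np.any(co_sampled == 0):
        raise ValueError(
            "some sample pairs were never co-sampled; increase n_resamples"
        )

    consensus_by_k: dict[int, np.ndarray] = {}
    scores = {}
    for k in k_range:
        co_clustered = np.zeros((n, n))
        for idx in subsamples:
            km = KMeans(
                n_clusters=k, n_init=3,
                random_state=int(rng.integers(0, 2**31 - 1)),
            ).fit(X[idx])
            lab = km.labels_
            same = lab[:, None] == lab[None, :]
            co_clustered[np.ix_(idx, idx)] += same
        M = co_clustered / co_sampled
        np.fill_diagonal(M, 1.0)
        consensus_by_k[k] = M
        scores[k] = pac(M, *pac_window)

    k_scores = pd.Series(scores).sort_index()
    chosen_k = int(k_scores.idxmin())  # ties -> smallest k via sorted index

    M = consensus_by_k[chosen_k]
    dist = 1.0 - M
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=chosen_k, criterion="maxclust")

    sample_ids = list(matrix.columns)
    return ConsensusResult(
        consensus_matrix=pd.DataFrame(M, index=sample_ids, columns=sample_ids),
        chosen_k=chosen_k,
        labels=pd.Series(labels, index=sample_ids, name="cluster"),
        k_scores=k_scores,
        consensus_by_k=consensus_by_k,
    )


def assign_subgroup_names(
    result: ConsensusResult,
    matrix: pd.DataFrame,
    marker_genes: list[str],
    high_marker_name: str = "IBD1",
    low_marker_name: str = "IBD2",
) -> pd.Series:
    """Orient the two clusters into named subgroups.

    The cluster with higher mean expression of ``marker_genes`` receives
    ``high_marker_name``. Equal marker means tie-break deterministically:
    the cluster containing the first sample (smallest column index) is
    named ``high_marker_name``.
    """
    if result.chosen_k != 2:
        raise ValueError(f"naming requires exactly 2 clusters, got {result.chosen_k}")
    marker = matrix.loc[marker_genes].mean(axis=0)
    means = marker.groupby(result.labels).mean()
    c1, c2 = sorted(means.index)
    if means[c1] > means[c2]:
        hi = c1
    elif means[c2] > means[c1]:
        hi = c2
    else:
        hi = result.labels.iloc[0]
    named = result.labels.map(
        lambda c: high_marker_name if c == hi else low_marker_name
    )
    named.name = "subgroup"
    return named
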