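"""Cluster-homogeneity evaluation: k-means on top PCs with K = sqrt(n).

A cluster is *homogeneous* iff every member carries the same population
label.  The two headline statistics are the percentage of homogeneous
clusters and the percentage of individuals living in them; mean sizes of
homogeneous vs non-homogeneous clusters are compared with a Kruskal-Wallis
test.  Singleton clusters are vacuously homogeneous and are counted as
such, but their number is reported because they inflate the metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from pcaudit.colors import Dataset
from pcaudit.pca import PCAResults

__all__ = ["ClusterReport", "auto_K", "homogeneity", "homogeneity_vs_pcs"]


def auto_K(n: int) -> int:
    """K = round(sqrt(n)), half away from zero, floored at 1."""
    n = int(n)
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return max(1, int(np.floor(np.sqrt(n) + 0.5)))


@dataclass
class ClusterReport:
    """k-means partition with per-cluster homogeneity flags and summaries."""

    K: int
    assignments: np.ndarray
    homogeneous_flags: np.ndarray  # length K
    cluster_sizes: np.ndarray  # length K
    pct_homogeneous_clusters: float
    pct_individuals_in_homogeneous: float
    mean_size_homogeneous: float
    mean_size_nonhomogeneous: float
    n_singleton_homogeneous: int
    pcs_used: tuple[int, ...]
    seed: int
    kruskal_statistic: float = float("nan")
    kruskal_p: float = float("nan")

    @property
    def n(self) -> int:
        return int(self.assignments.shape[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster": np.arange(self.K),
                "size": self.cluster_sizes,
                "homogeneous": self.homogeneous_flags,
            }
        )

    def summary(self) -> str:
        return (
            f"K={self.K} clusters on PCs {tuple(i + 1 for i in self.pcs_used)}: "
            f"{self.pct_homogeneous_clusters:.1f}% homogeneous clusters, "
            f"{self.pct_individuals_in_homogeneous:.1f}% of individuals in them "
            f"(mean sizes {self.mean_size_homogeneous:.1f} vs "
            f"{self.mean_size_nonhomogeneous:.1f}; "
            f"{self.n_singleton_homogeneous} vacuous singletons)"
        )


def _report_from_assignments(
    assignments: np.ndarray,
    labels: np.ndarray,
    K: int,
    pcs_used: tuple[int, ...],
    seed: int,
) -> ClusterReport:
    labels = np.asarray(labels, dtype=object)
    sizes = np.zeros(K, dtype=int)
    flags = np.zeros(K, dtype=bool)
    for c in range(K):
        members = labels[assignments == c]
        sizes[c] = members.shape[0]
        flags[c] = members.shape[0] > 0 and (members == members[0]).all()
    n = labels.shape[0]
    hom_sizes = sizes[flags]
    non_sizes = sizes[~flags]
    stat, p = float("nan"), float("nan")
    if hom_sizes.size and non_sizes.size:
        kw = stats.kruskal(hom_sizes, non_sizes)
        stat, p = float(kw.statistic), float(kw.pvalue)
    return ClusterReport(
        K=K,
        assignments=assignments,
        homogeneous_flags=flags,
        cluster_sizes=sizes,
        pct_homogeneous_clusters=100.0 * flags.mean(),
        pct_individuals_in_homogeneous=100.0 * hom_sizes.sum() / n,
        mean_size_homogeneous=float(hom_sizes.mean()) if hom_sizes.size else float("nan"),
        mean_size_nonhomogeneous=float(non_sizes.mean()) if non_sizes.size else float("nan"),
        n_singleton_homogeneous=int((sizes[flags] == 1).sum()),
        pcs_used=pcs_used,
        seed=seed,
        kruskal_statistic=stat,
        kruskal_p=p,
    )


def homogeneity(
    scores: np.ndarray,
    labels,
    K: int | str = "auto",
    seed: int = 0,
    restarts: int = 20,
    pcs_used: tuple[int, ...] = (0, 1),
) -> ClusterReport:
    """Best-of-restarts k-means on the provided score columns, with
    homogeneity flags against the population labels.

    ``scores`` are the score columns to cluster on (by convention the two
    top PCs).  K defaults to round(sqrt(n)).
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.ndim == 2 and scores.shape[0] == 1 and scores.shape[1] > 2:
        scores = scores.T
    labels = np.asarray(labels, dtype=object)
    n = scores.shape[0]
    if labels.shape[0] != n:
        raise ValueError("labels length does not match scores")
    if K == "auto":
        K = auto_K(n)
    K = int(K)
    if not (1 <= K <= n):
        raise ValueError(f"K must be in [1, {n}], got {K}")
    km = KMeans(n_clusters=K, n_init=int(restarts), random_state=int(seed))
    assignments = km.fit_predict(scores)
    return _report_from_assignments(assignments, labels, K, tuple(pcs_used), int(seed))


def homogeneity_vs_pcs(
    data: Dataset,
    results: PCAResults,
    pc_pairs: list[tuple[int, int]],
    K: int | str = "auto",
    seed: int = 0,
    restarts: int = 20,
) -> dict[tuple[int, int], ClusterReport]:
    """Homogeneity per PC pair (1-based indices), for profiles of cluster
    size and homogeneity across increasingly high components."""
    out: dict[tuple[int, int], ClusterReport] = {}
    for pair in pc_pairs:
        i, j = int(pair[0]), int(pair[1])
        if not (1 <= i <= results.r and 1 <= j <= results.r):
            raise ValueError(f"PC pair {pair} out of range (r={results.r})")
        cols = results.scores[:, [i - 1, j - 1]]
        out[(i, j)] = homogeneity(
            cols,
            data.sample_labels,
            K=K,
            seed=seed,
            restarts=restarts,
            pcs_used=(i - 1, j - 1),
        )
    return out
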