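"""Hierarchical clustering of the SS/N-GLYCO proteome feature matrix.

Rows (proteins with >=1 disulfide and >=1 N-glycosite) are compared with
Pearson-correlation distance (d = 1 - r across the feature columns) and
agglomerated with unweighted average linkage (UPGMA); the tree is cut into
k = 3 clusters, which on real data separates a TM-rich/PTM-poor class from
glycan-dominant and disulfide-dominant classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .types import FeatureKind, mean_quantile

logger = logging.getLogger(__name__)

#: Columns of the clustering matrix, in order.
MATRIX_COLUMNS = [
    "n_ss",
    "n_glyc",
    "n_tm",
    "n_cys",
    "n_sequon",
    "q_mean_ss",
    "q_mean_glyc",
    "q_mean_tm",
]


def build_feature_matrix(frame: pd.DataFrame) -> pd.DataFrame:
    """Clustering matrix for the SS/N-GLYCO proteome.

    Five raw counts plus, per feature in {SS, NGLYC, TM}, the weighted
    mean quantile index (1-4) of that feature's sites (0 when absent) —
    an 8-column matrix indexed by accession.
    """
    sub = frame[(frame["n_ss"] >= 1) & (frame["n_glyc"] >= 1)].copy()

    def qmean(feat: str) -> pd.Series:
        vecs = sub[[f"q_{feat}_{q}" for q in (1, 2, 3, 4)]].to_numpy(dtype=float)
        return pd.Series([mean_quantile(v) for v in vecs], index=sub.index)

    sub["q_mean_ss"] = qmean("ss")
    sub["q_mean_glyc"] = qmean("glyc")
    sub["q_mean_tm"] = qmean("tm")
    return sub.set_index("accession")[MATRIX_COLUMNS]


def pearson_distance(matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Condensed pairwise distances d(i,j) = 1 - Pearson r across columns.

    Rows with zero variance cannot carry a correlation; by convention they
    get distance 1 to every other row (logged). Distances lie in [0, 2].
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 columns for a row-wise correlation")
    std = X.std(axis=1)
    constant = std == 0
    if constant.any():
        logger.warning(
            "%d constant row(s) assigned distance 1 to all others", int(constant.sum())
        )
    n = X.shape[0]
    centered = X - X.mean(axis=1, keepdims=True)
    safe_std = np.where(constant, 1.0, std)
    Z = centered / (safe_std[:, None] * np.sqrt(X.shape[1]))
    corr = Z @ Z.T
    dist = 1.0 - corr
    dist[constant, :] = 1.0
    dist[:, constant] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 2.0)
    iu = np.triu_indices(n, k=1)
    return dist[iu]


def average_linkage(condensed: np.ndarray) -> np.ndarray:
    """UPGMA merge list: cluster distance = unweighted mean of cross pairs."""
    return sch.linkage(condensed, method="average")


def cut_tree(merges: np.ndarray, k: int = 3) -> np.ndarray:
    """Labels (1..k) from undoing the last k-1 merges."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n = merges.shape[0] + 1
    if k > n:
        raise ValueError(f"k={k} exceeds number of rows {n}")
    flat = sch.cut_tree(merges, n_clusters=k).ravel()
    return flat + 1


@dataclass(frozen=True)
class ClusterResult:
    merges: np.ndarray
    labels: Mapping[str, int]

    @property
    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for lab in self.labels.values():
            out[lab] = out.get(lab, 0) + 1
        return out

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"accession": list(self.labels), "cluster": list(self.labels.values())}
        )

    def merges_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merges, columns=["node_a", "node_b", "height", "size"]
        )


def cluster_proteome(matrix: pd.DataFrame, k: int = 3) -> ClusterResult:
    """Full pipeline: Pearson distance -> UPGMA -> cut into k clusters."""
    condensed = pearson_distance(matrix)
    merges = average_linkage(condensed)
    labels = cut_tree(merges, k=k)
    return ClusterResult(
        merges=merges, labels=dict(zip(matrix.index.astype(str), map(int, labels)))
    )


def cluster_centroids(matrix: pd.DataFrame, result: ClusterResult) -> pd.DataFrame:
    """Per-cluster column means, for inspecting the cluster signatures."""
    labs = pd.Series(result.labels)
    joined = matrix.join(labs.rename("cluster"))
    return joined.groupby("cluster").mean()
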