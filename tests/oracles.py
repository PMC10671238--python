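"""Independent brute-force oracles used only by the tests.

Each oracle re-derives a quantity by the most direct method available
(exhaustive scan, O(n^3) agglomeration, per-residue expansion), sharing no
code path with the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def naive_sequons(sequence: str) -> list[int]:
    """Triple-loop scan for N-X-S/T with X != P; 1-based Asn positions."""
    out = []
    for i in range(len(sequence) - 2):
        if (
            sequence[i] == "N"
            and sequence[i + 1] != "P"
            and sequence[i + 2] in ("S", "T")
        ):
            out.append(i + 1)
    return out


def naive_quantile(position: int, length: int) -> int:
    """Smallest q in 1..4 whose cumulative equal-part span covers position."""
    for q in (1, 2, 3, 4):
        if position <= math.ceil(q * length / 4):
            return q
    raise AssertionError("unreachable")


def naive_pearson_distance_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise 1 - r from the raw covariance formula, one pair at a time."""
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            xi, xj = X[i], X[j]
            cov = ((xi - xi.mean()) * (xj - xj.mean())).mean()
            denom = xi.std() * xj.std()
            r = cov / denom if denom else 0.0
            D[i, j] = D[j, i] = 1.0 - r
    return D


def naive_upgma_heights(D: np.ndarray) -> list[float]:
    """O(n^3) UPGMA agglomeration; returns the n-1 merge heights in order.

    Cluster distance is the unweighted mean of all cross-pair leaf
    distances, recomputed from the original matrix at every step.
    """
    clusters: list[list[int]] = [[i] for i in range(D.shape[0])]
    heights: list[float] = []
    while len(clusters) > 1:
        best = (math.inf, 0, 1)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = float(
                    np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
                )
                if d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return heights


def naive_venn_regions(
    counts: dict[str, dict[str, int]],
    ranges: dict[str, tuple[int, float]],
) -> dict[frozenset[str], set[str]]:
    """Assign each protein to its exclusive region by direct predicate tests.

    ``counts`` maps accession -> {feature name -> count}; proteins in no
    set are omitted.
    """
    regions: dict[frozenset[str], set[str]] = {}
    names = list(ranges)
    for acc, cnt in counts.items():
        membership = frozenset(
            name
            for name in names
            if ranges[name][0] <= cnt[name] <= ranges[name][1]
        )
        if membership:
            regions.setdefault(membership, set()).add(acc)
    return regions


def expand_topology_labels(topology) -> list:
    """Per-residue label list built by repeating each segment's label."""
    out = []
    for seg in topology.segments:
        out.extend([seg.label] * (seg.end - seg.start + 1))
    return out
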