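"""Distributional analyses over the per-protein feature table.

Length histograms with sliding-window peak intervals, feature-multiplicity
profiles, mean-count correlation curves, three-set Venn partitions over
count predicates, and length-quantile profiles. All operations consume the
feature-table DataFrame produced by :mod:`ptmtopo.sequence_features`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import FeatureKind

_COUNT_COLUMN = {
    FeatureKind.SS: "n_ss",
    FeatureKind.NGLYC: "n_glyc",
    FeatureKind.TM: "n_tm",
    FeatureKind.CYS: "n_cys",
    FeatureKind.SEQUON: "n_sequon",
}


# ---------------------------------------------------------------------------
# Proteome subsets (the paper-style proteome definitions)
# ---------------------------------------------------------------------------


def subset_proteome(frame: pd.DataFrame, name: str) -> pd.DataFrame:
    """Named proteome subsets: presence of >=1 of the respective feature.

    ``tm`` / ``non_tm`` split on predicted membrane segments; ``ss``,
    ``nglyco`` require >=1 annotated bond / N-glycosite; ``ss_nglyco`` is
    their intersection (>=1 of each); ``all`` is the identity.
    """
    if name == "all":
        return frame
    if name == "tm":
        return frame[frame["n_tm"] >= 1]
    if name == "non_tm":
        return frame[frame["n_tm"] == 0]
    if name == "ss":
        return frame[frame["n_ss"] >= 1]
    if name == "nglyco":
        return frame[frame["n_glyc"] >= 1]
    if name == "ss_nglyco":
        return frame[(frame["n_ss"] >= 1) & (frame["n_glyc"] >= 1)]
    raise ValueError(f"unknown proteome subset {name!r}")


# ---------------------------------------------------------------------------
# Length histogram with sliding-window peak
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LengthHistogram:
    bin_width: int
    bin_edges: np.ndarray
    counts: np.ndarray
    n: int
    mean_length: float
    peak_window: tuple[int, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1].astype(int),
                "bin_end": (self.bin_edges[1:] - 1).astype(int),
                "count": self.counts.astype(int),
            }
        )


def length_histogram(lengths: Sequence[int], bin_width: int = 100) -> LengthHistogram:
    """Fixed-width histogram plus the densest (bin_width+1)-wide interval.

    Bins start at the minimum length. The peak window slides an inclusive
    window of width ``bin_width + 1`` in steps of 1 over the length range
    and reports the earliest window with maximal membership — the form of
    the peak intervals reported for proteome length distributions.
    """
    arr = np.asarray(sorted(lengths), dtype=np.int64)
    if arr.size == 0:
        raise ValueError("empty length list")
    lo, hi = int(arr[0]), int(arr[-1])
    edges = np.arange(lo, hi + bin_width + 1, bin_width)
    counts, edges = np.histogram(arr, bins=edges)
    starts = np.arange(lo, max(lo, hi - bin_width) + 1)
    win = np.searchsorted(arr, starts + bin_width, side="right") - np.searchsorted(
        arr, starts, side="left"
    )
    best = int(starts[int(np.argmax(win))])
    return LengthHistogram(
        bin_width=bin_width,
        bin_edges=edges,
        counts=counts,
        n=int(arr.size),
        mean_length=float(arr.mean()),
        peak_window=(best, best + bin_width),
    )


# ---------------------------------------------------------------------------
# Multiplicity profiles
# ---------------------------------------------------------------------------


def _multiplicity_bin(count: int, max_single: int, bin_width: int) -> tuple[int, str]:
    """(sort key, label) for a feature multiplicity."""
    if count <= max_single:
        return count, str(count)
    lo = max_single + 1 + ((count - max_single - 1) // bin_width) * bin_width
    return lo, f"{lo}-{lo + bin_width - 1}"


def multiplicity_profile(
    frame: pd.DataFrame,
    kind: FeatureKind,
    max_single: int = 30,
    bin_width: int = 10,
    exclude: Iterable[str] = (),
) -> pd.DataFrame:
    """Protein counts, mean lengths and pooled rates per feature multiplicity.

    Restricted to proteins carrying >=1 of the feature. Multiplicities up
    to ``max_single`` are kept singly; larger ones are pooled into
    ``bin_width``-wide bins. For disulfides / N-glycosylation the pooled
    utilization column is sum(used)/sum(available) within each bin. The
    ``exclude`` list drops named accessions (outlier policy; default none).
    """
    col = _COUNT_COLUMN[kind]
    sub = frame[frame[col] >= 1]
    if exclude:
        sub = sub[~sub["accession"].isin(set(exclude))]
    if sub.empty:
        return pd.DataFrame(
            columns=["multiplicity", "protein_count", "mean_length", "pooled_rate"]
        )
    keys = sub[col].map(lambda c: _multiplicity_bin(int(c), max_single, bin_width))
    sub = sub.assign(_key=[k[0] for k in keys], multiplicity=[k[1] for k in keys])
    rows = []
    for key, grp in sub.groupby("_key", sort=True):
        rec = {
            "multiplicity": grp["multiplicity"].iloc[0],
            "protein_count": int(len(grp)),
            "mean_length": float(grp["length"].mean()),
            "pooled_rate": math.nan,
        }
        if kind is FeatureKind.SS:
            denom = grp["n_cys"].sum()
            rec["pooled_rate"] = grp["n_ss_cys"].sum() / denom if denom else math.nan
        elif kind is FeatureKind.NGLYC:
            denom = grp["n_sequon"].sum()
            rec["pooled_rate"] = (
                grp["n_glyc_on_sequon"].sum() / denom if denom else math.nan
            )
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pairwise feature-correlation curves
# ---------------------------------------------------------------------------


def feature_correlation_curve(
    frame: pd.DataFrame,
    x_kind: FeatureKind,
    y_kinds: Sequence[FeatureKind] = (FeatureKind.NGLYC, FeatureKind.TM),
) -> pd.DataFrame:
    """Mean count of each y feature per x-feature multiplicity.

    Operates on whichever subset the caller passes (typically the
    SS/N-GLYCO proteome). One row per observed x count, with the number of
    proteins and the mean of every requested y count.
    """
    xcol = _COUNT_COLUMN[x_kind]
    rows = []
    for x, grp in frame.groupby(xcol, sort=True):
        rec = {xcol: int(x), "n_proteins": int(len(grp))}
        for yk in y_kinds:
            rec[f"mean_{_COUNT_COLUMN[yk]}"] = float(grp[_COUNT_COLUMN[yk]].mean())
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Venn partition
# ---------------------------------------------------------------------------

_VENN_FEATURES = (FeatureKind.TM, FeatureKind.NGLYC, FeatureKind.SS)

#: The 7 disjoint regions, as frozensets of member feature names.
VENN_REGIONS: tuple[frozenset[str], ...] = tuple(
    frozenset(
        name
        for name, bit in zip(("TM", "NGLYC", "SS"), (4, 2, 1))
        if mask & bit
    )
    for mask in range(1, 8)
)


@dataclass(frozen=True)
class VennPartition:
    """Three-set Venn partition over count-range predicates."""

    ranges: Mapping[str, tuple[int, float]]
    regions: Mapping[frozenset[str], frozenset[str]]
    total_unique: int

    def size(self, *features: str) -> int:
        """Size of the exclusive region containing exactly these features."""
        return len(self.regions[frozenset(features)])

    def percentage(self, *features: str) -> float:
        if self.total_unique == 0:
            return 0.0
        return 100.0 * self.size(*features) / self.total_unique

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for region in VENN_REGIONS:
            members = sorted(self.regions[region])
            rows.append(
                {
                    "region": "&".join(sorted(region)),
                    "size": len(members),
                    "percentage": self.percentage(*region),
                    "accessions": ",".join(members),
                }
            )
        return pd.DataFrame(rows)


def venn_partition(
    frame: pd.DataFrame,
    tm_range: tuple[int, float] = (1, 1),
    nglyc_range: tuple[int, float] = (1, 1),
    ss_range: tuple[int, float] = (1, 1),
) -> VennPartition:
    """Partition proteins into the 7 exclusive Venn regions.

    A protein belongs to a feature's set when its count lies in the
    inclusive range (``hi`` may be ``math.inf``, e.g. ``(11, inf)`` for
    ">10"). Percentages are relative to the union of the three sets.
    """
    ranges = {"TM": tm_range, "NGLYC": nglyc_range, "SS": ss_range}
    for name, (lo, hi) in ranges.items():
        if lo > hi:
            raise ValueError(f"{name}: lo {lo} > hi {hi}")
    members: dict[str, set[str]] = {}
    for name, col in (("TM", "n_tm"), ("NGLYC", "n_glyc"), ("SS", "n_ss")):
        lo, hi = ranges[name]
        sel = frame[(frame[col] >= lo) & (frame[col] <= hi)]
        members[name] = set(sel["accession"])
    universe = members["TM"] | members["NGLYC"] | members["SS"]
    regions: dict[frozenset[str], frozenset[str]] = {}
    for region in VENN_REGIONS:
        inside = set(universe)
        for name in ("TM", "NGLYC", "SS"):
            if name in region:
                inside &= members[name]
            else:
                inside -= members[name]
        regions[region] = frozenset(inside)
    return VennPartition(ranges=ranges, regions=regions, total_unique=len(universe))


# ---------------------------------------------------------------------------
# Quantile profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuantileProfile:
    """Proteome-wide length-quantile totals and per-quantile PTM rates.

    ``counts[kind]`` is the column sum of the per-protein quantile vectors
    (disulfides in half-cystines). ``cys_utilization[q]`` is
    engaged-cysteines/cysteines within quantile q; ``sequon_occupancy[q]``
    is on-sequon-glycosites/sequons within q.
    """

    counts: Mapping[FeatureKind, tuple[float, float, float, float]]
    cys_utilization: tuple[float, float, float, float]
    sequon_occupancy: tuple[float, float, float, float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for kind, vec in self.counts.items():
            rows.append({"series": f"count_{kind.value}", **{f"q{i+1}": vec[i] for i in range(4)}})
        rows.append(
            {"series": "cys_utilization", **{f"q{i+1}": self.cys_utilization[i] for i in range(4)}}
        )
        rows.append(
            {"series": "sequon_occupancy", **{f"q{i+1}": self.sequon_occupancy[i] for i in range(4)}}
        )
        return pd.DataFrame(rows)


def quantile_profile(frame: pd.DataFrame) -> QuantileProfile:
    """Sum quantile vectors over a proteome and derive per-quantile rates."""

    def colsum(feat: str) -> tuple[float, float, float, float]:
        return tuple(float(frame[f"q_{feat}_{q}"].sum()) for q in (1, 2, 3, 4))

    counts = {
        FeatureKind.SS: colsum("ss"),
        FeatureKind.NGLYC: colsum("glyc"),
        FeatureKind.TM: colsum("tm"),
        FeatureKind.CYS: colsum("cys"),
        FeatureKind.SEQUON: colsum("sequon"),
    }
    on_seq = colsum("glyc_on_sequon")
    util = tuple(
        counts[FeatureKind.SS][q] / counts[FeatureKind.CYS][q]
        if counts[FeatureKind.CYS][q]
        else math.nan
        for q in range(4)
    )
    occ = tuple(
        on_seq[q] / counts[FeatureKind.SEQUON][q]
        if counts[FeatureKind.SEQUON][q]
        else math.nan
        for q in range(4)
    )
    return QuantileProfile(counts=counts, cys_utilization=util, sequon_occupancy=occ)
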