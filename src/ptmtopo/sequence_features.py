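"""Sequence-derived features and the per-protein feature table.

Detects N-glycosylation sequons (N-X-S/T, X != P) and cysteines from the
sequence, merges them with UniProt PTM annotations and predicted membrane
topology, and derives per-protein counts, utilization/occupancy rates and
length-quantile vectors — the ``FeatureRow`` consumed by every downstream
statistic.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .types import (
    MEMBRANE_LABELS,
    FeatureRow,
    ProteinAnnotations,
    ProteinRecord,
    ProteinTopology,
    QuantileVector,
    SequonSite,
)

logger = logging.getLogger(__name__)

# lookahead so overlapping sequons (e.g. NNTT) are all reported
_SEQUON_RE = re.compile(r"N(?=[^P][ST])")


def find_sequons(sequence: str) -> list[SequonSite]:
    """All canonical sequons N-X-S/T with X != P, overlapping included.

    No constraint is applied at position i+3; atypical (non-sequon)
    glycosylation is handled separately at the annotation level.
    """
    return [
        SequonSite(position=m.start() + 1, triplet=sequence[m.start() : m.start() + 3])
        for m in _SEQUON_RE.finditer(sequence)
    ]


def find_cysteines(sequence: str) -> list[int]:
    """1-based positions of every cysteine residue."""
    return [i + 1 for i, aa in enumerate(sequence) if aa == "C"]


def assign_quantile(position: int, length: int) -> int:
    """Length quantile (1-4) of a residue: four equal N-to-C slices.

    Equal parts are floor-based, remainder residues absorbed by later
    quantiles; position 1 is always Q1 and the C-terminus always Q4.
    """
    if not 1 <= position <= length:
        raise ValueError(f"position {position} outside 1..{length}")
    return min(4, 4 * (position - 1) // length + 1)


def rates(
    n_ss_cys: int, n_cys: int, n_glyc_on_sequon: int, n_sequon: int
) -> tuple[Optional[float], Optional[float]]:
    """(cysteine utilization, sequon occupancy); None when denominator is 0.

    Atypical glycosites (Asn not starting a canonical sequon) are excluded
    from the occupancy numerator by the caller.
    """
    if n_ss_cys > n_cys:
        raise ValueError(
            f"integrity error: {n_ss_cys} disulfide-engaged cysteines but "
            f"only {n_cys} cysteines"
        )
    util = n_ss_cys / n_cys if n_cys else None
    occ = n_glyc_on_sequon / n_sequon if n_sequon else None
    return util, occ


def _qvec(positions: Iterable[int], length: int) -> QuantileVector:
    v = [0.0, 0.0, 0.0, 0.0]
    for pos in positions:
        v[assign_quantile(pos, length) - 1] += 1.0
    return (v[0], v[1], v[2], v[3])


def build_feature_row(
    record: ProteinRecord,
    annotations: Optional[ProteinAnnotations] = None,
    topology: Optional[ProteinTopology] = None,
) -> FeatureRow:
    """Merge sequence, annotations and topology into one ``FeatureRow``.

    Annotation positions beyond the sequence, and disulfide positions that
    do not hold a cysteine, are logged and dropped. ``n_tm`` is 0 when no
    topology is supplied. Disulfide quantile mass is counted in
    half-cystines (each engaged cysteine at its own position); each
    membrane segment is assigned the quantile of its midpoint.
    """
    annotations = annotations or ProteinAnnotations()
    length = record.length
    sequence = record.sequence

    cysteines = find_cysteines(sequence)
    cys_set = set(cysteines)
    sequons = find_sequons(sequence)
    sequon_positions = {s.position for s in sequons}

    ss_positions: list[int] = []  # engaged cysteines, one entry each
    engaged: set[int] = set()
    n_ss = 0
    n_interchain = 0
    for bond in annotations.disulfides:
        kept_positions = []
        valid = True
        for pos in bond.positions:
            if pos > length:
                logger.warning(
                    "%s: disulfide position %d beyond length %d; dropped",
                    record.accession,
                    pos,
                    length,
                )
                valid = False
                break
            if pos not in cys_set:
                logger.warning(
                    "%s: disulfide position %d is %r, not cysteine; dropped",
                    record.accession,
                    pos,
                    sequence[pos - 1],
                )
                valid = False
                break
            kept_positions.append(pos)
        if not valid:
            continue
        n_ss += 1
        if bond.interchain or bond.pos_b is None:
            n_interchain += 1
        for pos in kept_positions:
            if pos not in engaged:
                engaged.add(pos)
                ss_positions.append(pos)

    glyc_positions: list[int] = []
    for site in annotations.glycosites:
        if site.position > length:
            logger.warning(
                "%s: glycosite %d beyond length %d; dropped",
                record.accession,
                site.position,
                length,
            )
            continue
        glyc_positions.append(site.position)
    glyc_on_sequon = [p for p in glyc_positions if p in sequon_positions]

    tm_midpoints: list[int] = []
    n_tm = 0
    if topology is not None:
        for seg in topology.segments:
            if seg.label in MEMBRANE_LABELS:
                n_tm += 1
                tm_midpoints.append((seg.start + seg.end) // 2)

    util, occ = rates(len(engaged), len(cysteines), len(glyc_on_sequon), len(sequons))

    return FeatureRow(
        accession=record.accession,
        length=length,
        n_tm=n_tm,
        n_ss=n_ss,
        n_ss_cys=len(engaged),
        n_ss_interchain=n_interchain,
        n_glyc=len(glyc_positions),
        n_glyc_on_sequon=len(glyc_on_sequon),
        n_glyc_atypical=len(glyc_positions) - len(glyc_on_sequon),
        n_cys=len(cysteines),
        n_sequon=len(sequons),
        cys_utilization=util,
        sequon_occupancy=occ,
        q_ss=_qvec(ss_positions, length),
        q_glyc=_qvec(glyc_positions, length),
        q_glyc_on_sequon=_qvec(glyc_on_sequon, length),
        q_tm=_qvec(tm_midpoints, length),
        q_cys=_qvec(cysteines, length),
        q_sequon=_qvec((s.position for s in sequons), length),
    )


def build_feature_table(
    records: Iterable[ProteinRecord],
    annotations: Optional[Mapping[str, ProteinAnnotations]] = None,
    topologies: Optional[Mapping[str, ProteinTopology]] = None,
) -> list[FeatureRow]:
    """One ``FeatureRow`` per protein, matching annotations/topology by accession."""
    annotations = annotations or {}
    topologies = topologies or {}
    return [
        build_feature_row(rec, annotations.get(rec.accession), topologies.get(rec.accession))
        for rec in records
    ]


#: Stable column order of features.tsv — the contract for downstream modules.
FEATURE_COLUMNS = [
    "accession",
    "length",
    "n_tm",
    "n_ss",
    "n_ss_cys",
    "n_ss_interchain",
    "n_glyc",
    "n_glyc_on_sequon",
    "n_glyc_atypical",
    "n_cys",
    "n_sequon",
    "cys_utilization",
    "sequon_occupancy",
] + [
    f"q_{feat}_{q}"
    for feat in ("ss", "glyc", "glyc_on_sequon", "tm", "cys", "sequon")
    for q in (1, 2, 3, 4)
]


def features_to_frame(rows: Iterable[FeatureRow]) -> pd.DataFrame:
    """Feature rows as a DataFrame in the documented column order."""
    data = []
    for r in rows:
        rec: dict = {
            "accession": r.accession,
            "length": r.length,
            "n_tm": r.n_tm,
            "n_ss": r.n_ss,
            "n_ss_cys": r.n_ss_cys,
            "n_ss_interchain": r.n_ss_interchain,
            "n_glyc": r.n_glyc,
            "n_glyc_on_sequon": r.n_glyc_on_sequon,
            "n_glyc_atypical": r.n_glyc_atypical,
            "n_cys": r.n_cys,
            "n_sequon": r.n_sequon,
            "cys_utilization": r.cys_utilization,
            "sequon_occupancy": r.sequon_occupancy,
        }
        for feat, vec in (
            ("ss", r.q_ss),
            ("glyc", r.q_glyc),
            ("glyc_on_sequon", r.q_glyc_on_sequon),
            ("tm", r.q_tm),
            ("cys", r.q_cys),
            ("sequon", r.q_sequon),
        ):
            for q in range(4):
                rec[f"q_{feat}_{q + 1}"] = vec[q]
        data.append(rec)
    return pd.DataFrame(data, columns=FEATURE_COLUMNS)


def write_features_tsv(rows: Iterable[FeatureRow], path: str | Path) -> None:
    features_to_frame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_features_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
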