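"""Compartment-rule conflict detection against predicted membrane topology.

Disulfide bonds and N-glycans form in the ER lumen and end up
extracellular (or lumenal) in the mature membrane protein. A disulfide
cysteine, glycosylated Asn, free cysteine or free sequon that the
predicted topology places in a cytosolic (INSIDE) or membrane-embedded
segment therefore contradicts the prediction; such sites are flagged as
conflicts, for predicted membrane proteins only (>=1 membrane segment).

SIGNAL residues are non-conflicting (the signal peptide is lumen-side and
cleaved); PERIPLASM is treated as OUTSIDE-equivalent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .sequence_features import find_cysteines, find_sequons
from .types import (
    MEMBRANE_LABELS,
    ConflictRecord,
    FeatureKind,
    ProteinAnnotations,
    ProteinRecord,
    ProteinTopology,
    SegmentLabel,
)

logger = logging.getLogger(__name__)

#: Kinds whose conflicts come from observed PTM annotations.
OBSERVED_KINDS = (FeatureKind.SS, FeatureKind.NGLYC)
ALL_KINDS = (
    FeatureKind.SS,
    FeatureKind.NGLYC,
    FeatureKind.FREE_CYS,
    FeatureKind.FREE_SEQUON,
)


def label_at(topology: ProteinTopology, position: int) -> SegmentLabel:
    """Topology label of the residue at a 1-based position."""
    return topology.label_at(position)


def _conflict_labels(membrane_is_conflict: bool) -> frozenset[SegmentLabel]:
    labels = {SegmentLabel.INSIDE}
    if membrane_is_conflict:
        labels |= set(MEMBRANE_LABELS)
    return frozenset(labels)


def detect_conflicts(
    record: ProteinRecord,
    annotations: Optional[ProteinAnnotations],
    topology: ProteinTopology,
    membrane_is_conflict: bool = True,
) -> list[ConflictRecord]:
    """Judge every feature site of one predicted membrane protein.

    Returns one record per disulfide bond (judged at both cysteines — a
    conflict if either sits inside or in the membrane), per N-glycosite
    (judged at the Asn), per free cysteine (not engaged in any annotated
    bond) and per free sequon (Asn carrying no glycosite). Proteins with
    no membrane segment yield no records. Sites beyond the topology length
    are logged and skipped.
    """
    if topology.tm_count() == 0:
        return []
    annotations = annotations or ProteinAnnotations()
    bad = _conflict_labels(membrane_is_conflict)
    length = topology.length
    out: list[ConflictRecord] = []

    def judge(kind: FeatureKind, positions: Sequence[int]) -> None:
        kept = []
        for pos in positions:
            if pos > length:
                logger.warning(
                    "%s: %s position %d beyond topology length %d; skipped",
                    record.accession,
                    kind.value,
                    pos,
                    length,
                )
                return
            kept.append(pos)
        labels = tuple(topology.label_at(p) for p in kept)
        out.append(
            ConflictRecord(
                accession=record.accession,
                feature_kind=kind,
                positions=tuple(kept),
                labels=labels,
                is_conflict=any(lab in bad for lab in labels),
            )
        )

    engaged: set[int] = set()
    for bond in annotations.disulfides:
        judge(FeatureKind.SS, bond.positions)
        engaged.update(bond.positions)

    glyc_positions = {g.position for g in annotations.glycosites}
    for pos in sorted(glyc_positions):
        judge(FeatureKind.NGLYC, (pos,))

    for pos in find_cysteines(record.sequence):
        if pos not in engaged:
            judge(FeatureKind.FREE_CYS, (pos,))

    for sequon in find_sequons(record.sequence):
        if sequon.position not in glyc_positions:
            judge(FeatureKind.FREE_SEQUON, (sequon.position,))

    return out


def detect_conflicts_proteome(
    records: Iterable[ProteinRecord],
    annotations: Mapping[str, ProteinAnnotations],
    topologies: Mapping[str, ProteinTopology],
    membrane_is_conflict: bool = True,
) -> list[ConflictRecord]:
    """Run conflict detection over every protein with a topology."""
    out: list[ConflictRecord] = []
    for rec in records:
        topo = topologies.get(rec.accession)
        if topo is None:
            continue
        out.extend(
            detect_conflicts(
                rec, annotations.get(rec.accession), topo, membrane_is_conflict
            )
        )
    return out


@dataclass(frozen=True)
class ConflictSummary:
    """Per-kind conflicts-per-protein histograms and headline fractions.

    The headline count (``n_conflicted_observed``) counts proteins with at
    least one conflict among the *observed* PTMs (disulfides and
    N-glycans); free-cysteine and free-sequon conflicts are reported
    separately.
    """

    histograms: Mapping[FeatureKind, Mapping[int, int]]
    n_predicted_mps: int
    n_conflicted_observed: int
    n_conflicted_any: int

    @property
    def fraction_conflicted(self) -> float:
        if self.n_predicted_mps == 0:
            return 0.0
        return self.n_conflicted_observed / self.n_predicted_mps

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for kind in ALL_KINDS:
            for n_conf, n_prot in sorted(self.histograms.get(kind, {}).items()):
                rows.append(
                    {
                        "feature_kind": kind.value,
                        "conflicts_per_protein": n_conf,
                        "protein_count": n_prot,
                    }
                )
        return pd.DataFrame(
            rows, columns=["feature_kind", "conflicts_per_protein", "protein_count"]
        )


def conflict_summary(
    records: Iterable[ConflictRecord], n_predicted_mps: int
) -> ConflictSummary:
    """Histogram conflicts per protein for each feature kind."""
    per_protein: dict[FeatureKind, dict[str, int]] = {k: {} for k in ALL_KINDS}
    observed_conflicted: set[str] = set()
    any_conflicted: set[str] = set()
    for rec in records:
        if not rec.is_conflict:
            continue
        counts = per_protein[rec.feature_kind]
        counts[rec.accession] = counts.get(rec.accession, 0) + 1
        any_conflicted.add(rec.accession)
        if rec.feature_kind in OBSERVED_KINDS:
            observed_conflicted.add(rec.accession)
    histograms: dict[FeatureKind, dict[int, int]] = {}
    for kind, counts in per_protein.items():
        hist: dict[int, int] = {}
        for n in counts.values():
            hist[n] = hist.get(n, 0) + 1
        histograms[kind] = hist
    return ConflictSummary(
        histograms=histograms,
        n_predicted_mps=n_predicted_mps,
        n_conflicted_observed=len(observed_conflicted),
        n_conflicted_any=len(any_conflicted),
    )


@dataclass(frozen=True)
class PredictorComparison:
    summary_a: ConflictSummary
    summary_b: ConflictSummary
    deltas: pd.DataFrame  # per-protein observed-conflict counts under a and b
    only_in_a: tuple[str, ...]
    only_in_b: tuple[str, ...]


def compare_predictors(
    topologies_a: Mapping[str, ProteinTopology],
    topologies_b: Mapping[str, ProteinTopology],
    records: Iterable[ProteinRecord],
    annotations: Mapping[str, ProteinAnnotations],
    membrane_is_conflict: bool = True,
) -> PredictorComparison:
    """Conflict summaries under two topology sources, plus per-protein deltas.

    Accessions present in only one topology set are reported and excluded
    from the delta table; both summaries are computed under identical
    rules over the shared accessions.
    """
    shared = set(topologies_a) & set(topologies_b)
    only_a = tuple(sorted(set(topologies_a) - shared))
    only_b = tuple(sorted(set(topologies_b) - shared))
    recs = [r for r in records if r.accession in shared]

    def observed_counts(conflicts: Iterable[ConflictRecord]) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in conflicts:
            if c.is_conflict and c.feature_kind in OBSERVED_KINDS:
                out[c.accession] = out.get(c.accession, 0) + 1
        return out

    results = []
    counts_ab = []
    for topos in (topologies_a, topologies_b):
        sub = {a: t for a, t in topos.items() if a in shared}
        n_mps = sum(1 for t in sub.values() if t.tm_count() >= 1)
        conflicts = detect_conflicts_proteome(recs, annotations, sub, membrane_is_conflict)
        results.append(conflict_summary(conflicts, n_mps))
        counts_ab.append(observed_counts(conflicts))
    accs = sorted(set(counts_ab[0]) | set(counts_ab[1]))
    deltas = pd.DataFrame(
        {
            "accession": accs,
            "conflicts_a": [counts_ab[0].get(a, 0) for a in accs],
            "conflicts_b": [counts_ab[1].get(a, 0) for a in accs],
        }
    )
    deltas["delta"] = deltas["conflicts_b"] - deltas["conflicts_a"]
    return PredictorComparison(
        summary_a=results[0],
        summary_b=results[1],
        deltas=deltas,
        only_in_a=only_a,
        only_in_b=only_b,
    )


def conflicts_to_frame(records: Iterable[ConflictRecord]) -> pd.DataFrame:
    """Flat table of conflict judgements (one row per judged site)."""
    rows = [
        {
            "accession": r.accession,
            "feature_kind": r.feature_kind.value,
            "positions": ",".join(map(str, r.positions)),
            "labels": ",".join(lab.value for lab in r.labels),
            "is_conflict": r.is_conflict,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows, columns=["accession", "feature_kind", "positions", "labels", "is_conflict"]
    )
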