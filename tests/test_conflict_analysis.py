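import numpy as np
import pytest

from ptmtopo import annotation_io
from ptmtopo.conflict_analysis import (
    compare_predictors,
    conflict_summary,
    detect_conflicts,
    detect_conflicts_proteome,
    label_at,
)
from ptmtopo.synthetic_data import SyntheticConfig, generate_proteome
from ptmtopo.types import (
    DisulfideAnnotation,
    FeatureKind,
    GlycosylationAnnotation,
    PredictedClass,
    ProteinAnnotations,
    ProteinRecord,
    ProteinTopology,
    SegmentLabel,
    TopologySegment,
)

from .oracles import expand_topology_labels


def _topology(acc="P1"):
    # SIGNAL 1-20 / OUTSIDE 21-100 / TM 101-123 / INSIDE 124-200
    return ProteinTopology(
        accession=acc,
        segments=(
            TopologySegment(SegmentLabel.SIGNAL, 1, 20),
            TopologySegment(SegmentLabel.OUTSIDE, 21, 100),
            TopologySegment(SegmentLabel.TM_HELIX, 101, 123),
            TopologySegment(SegmentLabel.INSIDE, 124, 200),
        ),
        predicted_class=PredictedClass.SP_TM,
    )


def _record(acc="P1"):
    seq = list("A" * 200)
    seq[29] = seq[139] = "C"  # bond (30, 140)
    return ProteinRecord(acc, "".join(seq))


# ---------------------------------------------------------------------------
# label_at
# ---------------------------------------------------------------------------


def test_label_at_examples():
    topo = _topology()
    assert label_at(topo, 105) == SegmentLabel.TM_HELIX
    assert label_at(topo, 150) == SegmentLabel.INSIDE
    assert label_at(topo, 50) == SegmentLabel.OUTSIDE
    with pytest.raises(ValueError):
        label_at(topo, 201)
    with pytest.raises(ValueError):
        label_at(topo, 0)


def test_label_at_matches_expansion_oracle(clean_proteome):
    rng = np.random.default_rng(1)
    topos = list(clean_proteome.topologies.values())[:40]
    for topo in topos:
        expanded = expand_topology_labels(topo)
        for pos in rng.integers(1, topo.length + 1, size=20):
            assert label_at(topo, int(pos)) is expanded[pos - 1]


# ---------------------------------------------------------------------------
# detect_conflicts
# ---------------------------------------------------------------------------


def test_glycosite_judged_at_asn():
    record, topo = _record(), _topology()
    annots = ProteinAnnotations(
        glycosites=(
            GlycosylationAnnotation(150, "N-linked"),  # INSIDE -> conflict
            GlycosylationAnnotation(50, "N-linked"),  # OUTSIDE -> fine
        )
    )
    records = [c for c in detect_conflicts(record, annots, topo) if c.feature_kind is FeatureKind.NGLYC]
    verdict = {c.positions[0]: c.is_conflict for c in records}
    assert verdict == {150: True, 50: False}


def test_disulfide_conflict_if_either_end_misplaced():
    record, topo = _record(), _topology()
    annots = ProteinAnnotations(disulfides=(DisulfideAnnotation(30, 140),))
    (ss,) = [c for c in detect_conflicts(record, annots, topo) if c.feature_kind is FeatureKind.SS]
    assert ss.is_conflict and ss.positions == (30, 140)
    assert ss.labels == (SegmentLabel.OUTSIDE, SegmentLabel.INSIDE)


def test_no_membrane_segment_yields_no_records():
    record = _record()
    topo = ProteinTopology(
        "P1",
        (TopologySegment(SegmentLabel.INSIDE, 1, 200),),
        PredictedClass.GLOB,
    )
    annots = ProteinAnnotations(glycosites=(GlycosylationAnnotation(150, "N-linked"),))
    assert detect_conflicts(record, annots, topo) == []


def test_membrane_embedded_site_configurable():
    record, topo = _record(), _topology()
    annots = ProteinAnnotations(glycosites=(GlycosylationAnnotation(110, "N-linked"),))
    (strict,) = [
        c
        for c in detect_conflicts(record, annots, topo, membrane_is_conflict=True)
        if c.feature_kind is FeatureKind.NGLYC
    ]
    (lenient,) = [
        c
        for c in detect_conflicts(record, annots, topo, membrane_is_conflict=False)
        if c.feature_kind is FeatureKind.NGLYC
    ]
    assert strict.is_conflict and not lenient.is_conflict


def test_signal_residues_non_conflicting():
    record, topo = _record(), _topology()
    annots = ProteinAnnotations(glycosites=(GlycosylationAnnotation(10, "N-linked"),))
    (rec,) = [c for c in detect_conflicts(record, annots, topo) if c.feature_kind is FeatureKind.NGLYC]
    assert rec.labels == (SegmentLabel.SIGNAL,) and not rec.is_conflict


def test_free_and_engaged_cysteines_partition(small_proteome):
    proteome, _ = small_proteome
    for rec in proteome.records:
        topo = proteome.topologies[rec.accession]
        if topo.tm_count() == 0:
            continue
        conflicts = detect_conflicts(rec, proteome.annotations[rec.accession], topo)
        free = [c for c in conflicts if c.feature_kind is FeatureKind.FREE_CYS]
        engaged = {
            p
            for b in proteome.annotations[rec.accession].disulfides
            for p in b.positions
        }
        n_cys = rec.sequence.count("C")
        assert len(free) + len(engaged) == n_cys


def test_records_identical_across_topology_dialects(small_proteome):
    proteome, paths = small_proteome
    t3 = {t.accession: t for t in annotation_io.read_deeptmhmm_3line(paths["deeptmhmm_3line"])}
    tg = {t.accession: t for t in annotation_io.read_deeptmhmm_gff3(paths["deeptmhmm_gff3"])}
    a = detect_conflicts_proteome(proteome.records, proteome.annotations, t3)
    b = detect_conflicts_proteome(proteome.records, proteome.annotations, tg)
    assert a == b


def test_injected_conflicts_recovered_exactly(small_proteome):
    proteome, _ = small_proteome
    found = detect_conflicts_proteome(
        proteome.records, proteome.annotations, proteome.topologies
    )
    detected = {
        (c.accession, c.feature_kind.value, tuple(sorted(c.positions)))
        for c in found
        if c.is_conflict
    }
    truth = set()
    for acc, g in proteome.ground_truth["proteins"].items():
        for pair in g["conflicts"]["SS"]:
            truth.add((acc, "SS", tuple(sorted(pair))))
        for kind in ("NGLYC", "FREE_CYS", "FREE_SEQUON"):
            for pos in g["conflicts"][kind]:
                truth.add((acc, kind, (pos,)))
    assert truth, "fixture must inject conflicts"
    assert detected == truth  # precision = recall = 1


# ---------------------------------------------------------------------------
# Summaries and predictor comparison
# ---------------------------------------------------------------------------


def test_conflict_summary_empty():
    summary = conflict_summary([], n_predicted_mps=10)
    assert summary.n_conflicted_observed == 0
    assert summary.fraction_conflicted == 0.0
    assert all(not h for h in summary.histograms.values())


def test_conflict_summary_counts_per_protein(small_proteome):
    proteome, _ = small_proteome
    found = detect_conflicts_proteome(
        proteome.records, proteome.annotations, proteome.topologies
    )
    n_mps = sum(1 for t in proteome.topologies.values() if t.tm_count() >= 1)
    summary = conflict_summary(found, n_mps)
    gt = proteome.ground_truth["proteins"]
    for kind, key in ((FeatureKind.NGLYC, "NGLYC"), (FeatureKind.FREE_CYS, "FREE_CYS")):
        per_protein = [
            len(g["conflicts"][key]) for g in gt.values() if g["conflicts"][key]
        ]
        expected: dict[int, int] = {}
        for n in per_protein:
            expected[n] = expected.get(n, 0) + 1
        assert dict(summary.histograms[kind]) == expected
    observed_expected = sum(
        1 for g in gt.values() if g["conflicts"]["SS"] or g["conflicts"]["NGLYC"]
    )
    assert summary.n_conflicted_observed == observed_expected
    assert 0.0 <= summary.fraction_conflicted <= 1.0


def test_compare_predictors_identical_sets_zero_deltas(small_proteome):
    proteome, _ = small_proteome
    cmp = compare_predictors(
        proteome.topologies, proteome.topologies, proteome.records, proteome.annotations
    )
    assert (cmp.deltas["delta"] == 0).all()
    assert cmp.summary_a.n_conflicted_observed == cmp.summary_b.n_conflicted_observed


def test_compare_predictors_flips_create_conflicts():
    cfg = SyntheticConfig(n_proteins=200, seed=13, tmhmm2_flip_rate=0.3)
    proteome = generate_proteome(cfg)
    cmp = compare_predictors(
        proteome.topologies,
        proteome.tmhmm2_topologies,
        proteome.records,
        proteome.annotations,
    )
    flipped = {
        acc
        for acc, g in proteome.ground_truth["proteins"].items()
        if g["flipped_in_tmhmm2"]
    }
    assert flipped
    # the flipped predictor can only add conflicts, and every protein whose
    # conflict count changed is one of the flipped ones
    changed = set(cmp.deltas[cmp.deltas["delta"] != 0]["accession"])
    assert changed <= flipped
    assert cmp.summary_b.n_conflicted_observed > cmp.summary_a.n_conflicted_observed


def test_compare_predictors_disjoint_accessions_reported(small_proteome):
    proteome, _ = small_proteome
    a = dict(proteome.topologies)
    removed = proteome.records[0].accession
    b = {k: v for k, v in proteome.topologies.items() if k != removed}
    cmp = compare_predictors(a, b, proteome.records, proteome.annotations)
    assert cmp.only_in_a == (removed,) and cmp.only_in_b == ()


def test_no_features_means_empty_summaries():
    seq = "A" * 60
    record = ProteinRecord("P1", seq)
    topo = ProteinTopology(
        "P1",
        (
            TopologySegment(SegmentLabel.OUTSIDE, 1, 20),
            TopologySegment(SegmentLabel.TM_HELIX, 21, 41),
            TopologySegment(SegmentLabel.INSIDE, 42, 60),
        ),
        PredictedClass.TM,
    )
    conflicts = detect_conflicts(record, None, topo)
    assert conflicts == []
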