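"""End-to-end orchestration and the protein-visualizer JSON export.

``run_all`` drives the whole pipeline from input files to the output
directory of TSV tables; ``export_visualizer_json`` builds the versioned
per-protein document (schema ``viz-v1``) consumed by an interactive
renderer: the 8 displayed feature groups are protein length, membrane
segments, internal loops, external loops, disulfide pairs (with pairing
ids so brackets/knots can be drawn), N-glycosites, free sequons and free
cysteines.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

from . import annotation_io, cluster_analysis, conflict_analysis, proteome_stats
from .sequence_features import (
    build_feature_table,
    features_to_frame,
    find_cysteines,
    find_sequons,
    write_features_tsv,
)
from .types import (
    MEMBRANE_LABELS,
    ProteinAnnotations,
    ProteinRecord,
    ProteinTopology,
    SegmentLabel,
)

logger = logging.getLogger(__name__)

VIZ_SCHEMA_VERSION = "viz-v1"

_VIZ_GROUPS = (
    "length",
    "tm_segments",
    "inside_loops",
    "outside_loops",
    "ss_pairs",
    "glycosites",
    "free_sequons",
    "free_cysteines",
)


def export_visualizer_json(
    record: ProteinRecord,
    annotations: Optional[ProteinAnnotations],
    topology: Optional[ProteinTopology],
) -> dict:
    """Build the viz-v1 document for one protein.

    Disulfide pairs are ordered by first position and carry pairing ids so
    a renderer can draw brackets; nesting and crossing relations are
    derivable from the position pairs. A protein without topology gets
    empty topology blocks and ``missing_topology: true``.
    """
    annotations = annotations or ProteinAnnotations()
    length = record.length
    tm_segments, inside_loops, outside_loops = [], [], []
    if topology is not None:
        for seg in topology.segments:
            entry = {"start": seg.start, "end": seg.end, "label": seg.label.value}
            if seg.label in MEMBRANE_LABELS:
                tm_segments.append(entry)
            elif seg.label is SegmentLabel.INSIDE:
                inside_loops.append(entry)
            elif seg.label in (SegmentLabel.OUTSIDE, SegmentLabel.PERIPLASM):
                outside_loops.append(entry)
    else:
        logger.warning("%s: no topology; emitting empty topology block", record.accession)

    engaged: set[int] = set()
    ss_pairs = []
    bonds = sorted(
        annotations.disulfides, key=lambda b: (b.pos_a, b.pos_b or b.pos_a)
    )
    for i, bond in enumerate(bonds, start=1):
        ss_pairs.append(
            {
                "pair_id": i,
                "positions": list(bond.positions),
                "interchain": bond.interchain or bond.pos_b is None,
            }
        )
        engaged.update(bond.positions)
    glycosites = sorted({g.position for g in annotations.glycosites})
    free_sequons = [
        s.position for s in find_sequons(record.sequence) if s.position not in glycosites
    ]
    free_cysteines = [p for p in find_cysteines(record.sequence) if p not in engaged]

    doc = {
        "schema_version": VIZ_SCHEMA_VERSION,
        "accession": record.accession,
        "missing_topology": topology is None,
        "length": length,
        "tm_segments": tm_segments,
        "inside_loops": inside_loops,
        "outside_loops": outside_loops,
        "ss_pairs": ss_pairs,
        "glycosites": glycosites,
        "free_sequons": free_sequons,
        "free_cysteines": free_cysteines,
        "summary": {
            "n_tm": len(tm_segments),
            "n_ss": len(ss_pairs),
            "n_glyc": len(glycosites),
            "n_free_sequon": len(free_sequons),
            "n_free_cys": len(free_cysteines),
        },
    }
    validate_visualizer_document(doc)
    return doc


def validate_visualizer_document(doc: Mapping) -> None:
    """Check the viz-v1 contract; raises ValueError on violation."""
    if doc.get("schema_version") != VIZ_SCHEMA_VERSION:
        raise ValueError("wrong or missing schema_version")
    for group in _VIZ_GROUPS:
        if group not in doc:
            raise ValueError(f"missing feature group {group!r}")
    length = doc["length"]
    if not isinstance(length, int) or length < 1:
        raise ValueError("length must be a positive integer")
    positions = list(doc["glycosites"]) + list(doc["free_sequons"]) + list(
        doc["free_cysteines"]
    )
    for pair in doc["ss_pairs"]:
        positions.extend(pair["positions"])
        if len(pair["positions"]) not in (1, 2):
            raise ValueError("ss pair must name 1 or 2 positions")
    for seg_group in ("tm_segments", "inside_loops", "outside_loops"):
        for seg in doc[seg_group]:
            positions.extend((seg["start"], seg["end"]))
    for pos in positions:
        if not 1 <= pos <= length:
            raise ValueError(f"position {pos} outside 1..{length}")
    ids = [p["pair_id"] for p in doc["ss_pairs"]]
    if len(ids) != len(set(ids)):
        raise ValueError("pair ids must be unique")


@dataclass
class RunConfig:
    """Validated configuration of an end-to-end run."""

    fasta: Path
    flatfile: Path
    topology: Path
    topology_format: str = "3line"  # 3line | gff3 | tmhmm2
    out_dir: Path = Path("ptmtopo_out")
    bin_width: int = 100
    venn_ranges: tuple[tuple[int, float], ...] = ((1, 1), (1, 3), (11, float("inf")))
    exclude: tuple[str, ...] = ()
    membrane_is_conflict: bool = True
    k_clusters: int = 3

    def __post_init__(self) -> None:
        self.fasta = Path(self.fasta)
        self.flatfile = Path(self.flatfile)
        self.topology = Path(self.topology)
        self.out_dir = Path(self.out_dir)
        for path in (self.fasta, self.flatfile, self.topology):
            if not path.exists():
                raise FileNotFoundError(path)
        if self.topology_format not in ("3line", "gff3", "tmhmm2"):
            raise ValueError(f"unknown topology format {self.topology_format!r}")
        if self.bin_width < 1:
            raise ValueError("bin_width must be >= 1")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d = {k: (str(v) if isinstance(v, Path) else v) for k, v in d.items()}
        d["venn_ranges"] = [[lo, "inf" if hi == float("inf") else hi] for lo, hi in self.venn_ranges]
        return json.dumps(d, indent=1, sort_keys=True)


def read_topologies(path: Path, fmt: str) -> dict[str, ProteinTopology]:
    reader = {
        "3line": annotation_io.read_deeptmhmm_3line,
        "gff3": annotation_io.read_deeptmhmm_gff3,
        "tmhmm2": annotation_io.read_tmhmm2_long,
    }[fmt]
    return {t.accession: t for t in reader(path)}


def run_all(config: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline; returns the map of written outputs.

    Stages: parse inputs -> features.tsv -> length histograms and
    multiplicity/correlation/quantile tables per proteome subset -> Venn
    partitions -> SS/N-GLYCO clustering -> conflict tables -> per-protein
    visualizer JSON for conflicted proteins.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(config.to_json() + "\n")

    records = annotation_io.read_fasta(config.fasta)
    annotations = annotation_io.read_uniprot_flatfile(config.flatfile)
    topologies = read_topologies(config.topology, config.topology_format)
    logger.info(
        "inputs: %d proteins, %d annotated entries, %d topologies",
        len(records),
        len(annotations),
        len(topologies),
    )

    rows = build_feature_table(records, annotations, topologies)
    frame = features_to_frame(rows)
    paths: dict[str, Path] = {"features": out / "features.tsv"}
    write_features_tsv(rows, paths["features"])

    for subset in ("tm", "non_tm", "nglyco", "ss"):
        sub = proteome_stats.subset_proteome(frame, subset)
        if sub.empty:
            logger.info("subset %s is empty; skipping histogram", subset)
            continue
        hist = proteome_stats.length_histogram(sub["length"].tolist(), config.bin_width)
        p = out / f"histogram_{subset}.tsv"
        hist.to_frame().to_csv(p, sep="\t", index=False)
        paths[f"histogram_{subset}"] = p
        logger.info(
            "subset %s: n=%d mean=%.2f peak=%s", subset, hist.n, hist.mean_length, hist.peak_window
        )

    from .types import FeatureKind

    for kind in (FeatureKind.SS, FeatureKind.NGLYC, FeatureKind.TM):
        table = proteome_stats.multiplicity_profile(frame, kind, exclude=config.exclude)
        p = out / f"multiplicity_{kind.value.lower()}.tsv"
        table.to_csv(p, sep="\t", index=False)
        paths[f"multiplicity_{kind.value.lower()}"] = p

    ss_nglyco = proteome_stats.subset_proteome(frame, "ss_nglyco")
    for x_kind in (FeatureKind.SS, FeatureKind.NGLYC):
        curve = proteome_stats.feature_correlation_curve(
            ss_nglyco,
            x_kind,
            [k for k in (FeatureKind.SS, FeatureKind.NGLYC, FeatureKind.TM) if k != x_kind],
        )
        p = out / f"correlation_x_{x_kind.value.lower()}.tsv"
        curve.to_csv(p, sep="\t", index=False)
        paths[f"correlation_x_{x_kind.value.lower()}"] = p

    for lo, hi in config.venn_ranges:
        venn = proteome_stats.venn_partition(
            ss_nglyco, tm_range=(lo, hi), nglyc_range=(lo, hi), ss_range=(lo, hi)
        )
        tag = f"{lo}-{'inf' if hi == float('inf') else int(hi)}"
        p = out / f"venn_{tag}.tsv"
        venn.to_frame().to_csv(p, sep="\t", index=False)
        paths[f"venn_{tag}"] = p

    profile = proteome_stats.quantile_profile(ss_nglyco if not ss_nglyco.empty else frame)
    paths["quantile_profile"] = out / "quantile_profile.tsv"
    profile.to_frame().to_csv(paths["quantile_profile"], sep="\t", index=False)

    matrix = cluster_analysis.build_feature_matrix(frame)
    if len(matrix) >= max(2, config.k_clusters):
        result = cluster_analysis.cluster_proteome(matrix, k=config.k_clusters)
        paths["cluster_labels"] = out / "cluster_labels.tsv"
        result.labels_frame().to_csv(paths["cluster_labels"], sep="\t", index=False)
        paths["merges"] = out / "merges.tsv"
        result.merges_frame().to_csv(paths["merges"], sep="\t", index=False)
        logger.info("cluster sizes: %s", result.sizes)
    else:
        logger.info("SS/N-GLYCO proteome too small to cluster (%d rows)", len(matrix))

    conflicts = conflict_analysis.detect_conflicts_proteome(
        records, annotations, topologies, config.membrane_is_conflict
    )
    paths["conflicts"] = out / "conflicts.tsv"
    conflict_analysis.conflicts_to_frame(conflicts).to_csv(
        paths["conflicts"], sep="\t", index=False
    )
    n_mps = sum(1 for t in topologies.values() if t.tm_count() >= 1)
    summary = conflict_analysis.conflict_summary(conflicts, n_mps)
    paths["conflict_histogram"] = out / "conflict_histogram.tsv"
    summary.to_frame().to_csv(paths["conflict_histogram"], sep="\t", index=False)
    logger.info(
        "conflicts: %d/%d predicted MPs (%.2f%%) with observed-PTM conflicts",
        summary.n_conflicted_observed,
        summary.n_predicted_mps,
        100 * summary.fraction_conflicted,
    )

    viz_dir = out / "viz"
    viz_dir.mkdir(exist_ok=True)
    conflicted = sorted(
        {c.accession for c in conflicts if c.is_conflict}
    )
    by_acc = {r.accession: r for r in records}
    for acc in conflicted:
        doc = export_visualizer_json(by_acc[acc], annotations.get(acc), topologies.get(acc))
        (viz_dir / f"{acc}.json").write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")
    paths["viz_dir"] = viz_dir
    return paths
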