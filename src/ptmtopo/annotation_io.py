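"""Readers and writers for every external format the pipeline touches.

Supported inputs:

* FASTA with UniProt-style (``db|ACC|NAME``) or bare headers;
* UniProtKB/Swiss-Prot flat text (``FT DISULFID`` / ``FT CARBOHYD``,
  ``AC`` and ``SQ`` lines), via :mod:`Bio.SwissProt`;
* DeepTMHMM 3-line topology output (``>ACC | CLASS`` / sequence /
  topology string over ``S I O M B P``);
* DeepTMHMM GFF3-like 4-column output;
* TMHMM 2.0 "long" output.

All positions are 1-based inclusive. Uncertain UniProt positions
(``?``, ``<``, ``>``) are dropped with a logged warning rather than
guessed; malformed flat-file records are warned about and skipped, never
aborting the whole file.
"""

from __future__ import annotations

import logging
from io import StringIO
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO, SwissProt
from Bio.SeqFeature import ExactPosition

from .types import (
    DisulfideAnnotation,
    GlycosylationAnnotation,
    PredictedClass,
    ProteinAnnotations,
    ProteinRecord,
    ProteinTopology,
    SegmentLabel,
    TopologySegment,
)

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _accession_from_header(header_id: str) -> str:
    """UniProt ``db|ACC|NAME`` -> ACC; otherwise the first token."""
    if "|" in header_id:
        parts = header_id.split("|")
        if len(parts) >= 2 and parts[1]:
            return parts[1]
    return header_id.split()[0]


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    The accession is the second pipe-delimited field of the header when a
    UniProt-style header is present, otherwise the first whitespace token.

    Raises
    ------
    ValueError
        On an empty file, a duplicate accession, or a character outside
        the amino-acid alphabet.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for seq_rec in SeqIO.parse(str(path), "fasta"):
        accession = _accession_from_header(seq_rec.id)
        if accession in seen:
            raise ValueError(f"duplicate accession {accession!r} in {path}")
        seen.add(accession)
        entry_name = None
        if "|" in seq_rec.id:
            parts = seq_rec.id.split("|")
            if len(parts) >= 3 and parts[2]:
                entry_name = parts[2]
        sequence = str(seq_rec.seq).upper().replace(" ", "")
        records.append(
            ProteinRecord(accession=accession, sequence=sequence, entry_name=entry_name)
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records with UniProt-style ``sp|ACC|NAME`` headers."""
    with open(path, "w") as fh:
        for rec in records:
            name = rec.entry_name or rec.accession
            fh.write(f">sp|{rec.accession}|{name}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# UniProt flat file
# ---------------------------------------------------------------------------


def _is_exact(position) -> bool:
    # UncertainPosition subclasses ExactPosition, so check the exact type
    return type(position) is ExactPosition


def _exact_site(feature) -> Optional[int]:
    """1-based position of a single-residue feature, or None if uncertain."""
    loc = feature.location
    if not _is_exact(loc.start) or not _is_exact(loc.end):
        return None
    return int(loc.end)


def _parse_swissprot_record(record) -> tuple[str, ProteinAnnotations]:
    accession = record.accessions[0]
    disulfides: list[DisulfideAnnotation] = []
    glycosites: list[GlycosylationAnnotation] = []
    for feat in record.features:
        note = str(feat.qualifiers.get("note", ""))
        if feat.type == "DISULFID":
            loc = feat.location
            exact_start = _is_exact(loc.start)
            exact_end = _is_exact(loc.end)
            interchain = "Interchain" in note
            start1 = int(loc.start) + 1 if exact_start else None
            end1 = int(loc.end) if exact_end else None
            if start1 is not None and end1 is not None and end1 > start1:
                # a..b span: an intrachain bond unless flagged interchain
                # (interchain a..b still names two residues of this chain)
                disulfides.append(
                    DisulfideAnnotation(pos_a=start1, pos_b=end1, interchain=interchain)
                )
            elif start1 is not None and end1 == start1:
                # single-residue record: partner in another chain
                disulfides.append(
                    DisulfideAnnotation(pos_a=start1, pos_b=None, interchain=True)
                )
            elif interchain and (start1 is not None or end1 is not None):
                pos = start1 if start1 is not None else end1
                disulfides.append(
                    DisulfideAnnotation(pos_a=pos, pos_b=None, interchain=True)
                )
            else:
                logger.warning(
                    "%s: dropping DISULFID with uncertain position (%s)",
                    accession,
                    loc,
                )
        elif feat.type == "CARBOHYD":
            if "N-linked" not in note:
                continue
            pos = _exact_site(feat)
            if pos is None:
                logger.warning(
                    "%s: dropping CARBOHYD with uncertain position (%s)",
                    accession,
                    feat.location,
                )
                continue
            glycosites.append(GlycosylationAnnotation(position=pos, note=note))
    return accession, ProteinAnnotations(
        disulfides=tuple(disulfides),
        glycosites=tuple(glycosites),
        declared_length=record.sequence_length,
    )


def read_uniprot_flatfile(path: str | Path) -> dict[str, ProteinAnnotations]:
    """Parse disulfide and N-glycosylation annotations from Swiss-Prot text.

    Returns a map ``accession -> ProteinAnnotations`` keyed by each entry's
    primary accession. Only ``FT CARBOHYD`` records whose note identifies
    N-linked glycosylation are retained. A malformed record is skipped with
    a warning; a record without an ``SQ`` line is an error for that record.
    """
    text = Path(path).read_text()
    if not text.strip():
        raise ValueError(f"empty flat file: {path}")
    out: dict[str, ProteinAnnotations] = {}
    # split into records so one malformed entry cannot abort the whole file
    chunks = [c for c in text.split("//\n") if c.strip()]
    for chunk in chunks:
        try:
            record = next(SwissProt.parse(StringIO(chunk + "//\n")))
        except Exception as exc:  # malformed record: warn + skip
            first = chunk.strip().splitlines()[0]
            logger.warning("skipping malformed flat-file record (%s): %s", first, exc)
            continue
        accession, annots = _parse_swissprot_record(record)
        if annots.declared_length in (None, 0):
            raise ValueError(f"{accession}: missing SQ/length information")
        out[accession] = annots
    return out


def write_uniprot_flatfile(
    entries: Mapping[str, tuple[ProteinRecord, ProteinAnnotations]],
    path: str | Path,
) -> None:
    """Write a minimal Swiss-Prot-style flat file (ID/AC/FT/SQ lines).

    Only the lines this pipeline consumes are emitted; the output parses
    back through :func:`read_uniprot_flatfile`.
    """
    with open(path, "w") as fh:
        for accession, (rec, annots) in entries.items():
            name = rec.entry_name or f"{accession}_SYNTH"
            fh.write(f"ID   {name:<24}Reviewed; {rec.length:>11} AA.\n")
            fh.write(f"AC   {accession};\n")
            for ss in annots.disulfides:
                if ss.pos_b is None:
                    fh.write(f"FT   DISULFID        {ss.pos_a}\n")
                    fh.write('FT                   /note="Interchain"\n')
                else:
                    fh.write(f"FT   DISULFID        {ss.pos_a}..{ss.pos_b}\n")
                    if ss.interchain:
                        fh.write('FT                   /note="Interchain"\n')
            for gly in annots.glycosites:
                fh.write(f"FT   CARBOHYD        {gly.position}\n")
                note = gly.note or "N-linked (GlcNAc...) asparagine"
                fh.write(f'FT                   /note="{note}"\n')
            fh.write(
                f"SQ   SEQUENCE   {rec.length} AA;  {rec.length * 110} MW;  "
                "0000000000000000 CRC64;\n"
            )
            seq = rec.sequence
            for i in range(0, len(seq), 60):
                chunk = seq[i : i + 60]
                blocks = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
                fh.write(f"     {blocks}\n")
            fh.write("//\n")


# ---------------------------------------------------------------------------
# Topology formats
# ---------------------------------------------------------------------------

_CHAR_TO_LABEL = {
    "S": SegmentLabel.SIGNAL,
    "I": SegmentLabel.INSIDE,
    "O": SegmentLabel.OUTSIDE,
    "M": SegmentLabel.TM_HELIX,
    "B": SegmentLabel.BETA_STRAND,
    "P": SegmentLabel.PERIPLASM,
}
_LABEL_TO_CHAR = {v: k for k, v in _CHAR_TO_LABEL.items()}

_GFF_TO_LABEL = {
    "signal": SegmentLabel.SIGNAL,
    "inside": SegmentLabel.INSIDE,
    "outside": SegmentLabel.OUTSIDE,
    "TMhelix": SegmentLabel.TM_HELIX,
    "Beta sheet": SegmentLabel.BETA_STRAND,
    "periplasm": SegmentLabel.PERIPLASM,
}
_LABEL_TO_GFF = {v: k for k, v in _GFF_TO_LABEL.items()}


def _rle_segments(topo_string: str, accession: str) -> tuple[TopologySegment, ...]:
    segments: list[TopologySegment] = []
    start = 1
    for i in range(1, len(topo_string) + 1):
        if i == len(topo_string) or topo_string[i] != topo_string[start - 1]:
            ch = topo_string[start - 1]
            if ch not in _CHAR_TO_LABEL:
                raise ValueError(
                    f"{accession}: unknown topology character {ch!r} at {start}"
                )
            segments.append(TopologySegment(_CHAR_TO_LABEL[ch], start, i))
            start = i + 1
    return tuple(segments)


def _infer_class(segments: Sequence[TopologySegment]) -> PredictedClass:
    labels = {s.label for s in segments}
    has_signal = SegmentLabel.SIGNAL in labels
    if SegmentLabel.BETA_STRAND in labels:
        return PredictedClass.BETA
    if SegmentLabel.TM_HELIX in labels:
        return PredictedClass.SP_TM if has_signal else PredictedClass.TM
    return PredictedClass.SP_GLOB if has_signal else PredictedClass.GLOB


def read_deeptmhmm_3line(path: str | Path) -> list[ProteinTopology]:
    """Parse DeepTMHMM 3-line output blocks.

    Each block is ``>ACC | CLASS``, the sequence, then the per-residue
    topology string. The topology string is run-length encoded into
    segments; its length must equal the sequence length.
    """
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ValueError(f"empty topology file: {path}")
    topologies: list[ProteinTopology] = []
    i = 0
    while i < len(lines):
        header = lines[i]
        if not header.startswith(">"):
            raise ValueError(f"{path}: expected header at line {i + 1}, got {header!r}")
        fields = [f.strip() for f in header[1:].split("|")]
        accession = fields[0]
        predicted_class = (
            PredictedClass(fields[1]) if len(fields) > 1 else PredictedClass.GLOB
        )
        if i + 2 >= len(lines):
            raise ValueError(f"{accession}: truncated 3-line block")
        sequence, topo_string = lines[i + 1], lines[i + 2]
        if len(topo_string) != len(sequence):
            raise ValueError(
                f"{accession}: topology string length {len(topo_string)} != "
                f"sequence length {len(sequence)}"
            )
        topologies.append(
            ProteinTopology(
                accession=accession,
                segments=_rle_segments(topo_string, accession),
                predicted_class=predicted_class,
            )
        )
        i += 3
    return topologies


def topology_string(topology: ProteinTopology) -> str:
    """Expand a topology back to its per-residue character string."""
    return "".join(_LABEL_TO_CHAR[s.label] * len(s) for s in topology.segments)


def write_deeptmhmm_3line(
    topologies: Iterable[ProteinTopology],
    path: str | Path,
    sequences: Optional[Mapping[str, str]] = None,
) -> None:
    """Write DeepTMHMM 3-line blocks; placeholder sequences if none given."""
    with open(path, "w") as fh:
        for topo in topologies:
            seq = (
                sequences[topo.accession]
                if sequences is not None
                else "X" * topo.length
            )
            if len(seq) != topo.length:
                raise ValueError(
                    f"{topo.accession}: sequence length {len(seq)} != "
                    f"topology length {topo.length}"
                )
            fh.write(f">{topo.accession} | {topo.predicted_class.value}\n")
            fh.write(seq + "\n")
            fh.write(topology_string(topo) + "\n")


def _segments_to_topology(
    accession: str,
    raw: list[tuple[SegmentLabel, int, int]],
    predicted_class: Optional[PredictedClass],
) -> ProteinTopology:
    raw_sorted = sorted(raw, key=lambda t: t[1])
    segments = tuple(TopologySegment(lbl, s, e) for lbl, s, e in raw_sorted)
    # ProteinTopology validates contiguity/coverage and raises naming position
    return ProteinTopology(
        accession=accession,
        segments=segments,
        predicted_class=predicted_class or _infer_class(segments),
    )


def read_deeptmhmm_gff3(path: str | Path) -> list[ProteinTopology]:
    """Parse DeepTMHMM's GFF3-like 4-column output.

    Lines are ``ACC <tab> feature <tab> start <tab> end`` with feature in
    {signal, inside, outside, TMhelix, Beta sheet, periplasm}; ``#``
    comment lines and ``//`` separators are ignored. Produces the same
    structures as :func:`read_deeptmhmm_3line` on matched files.
    """
    per_acc: dict[str, list[tuple[SegmentLabel, int, int]]] = {}
    order: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip()
        if not line or line.startswith("#") or line.startswith("//"):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            # tolerate space-separated fixtures: feature may contain a space
            tokens = line.split()
            if len(tokens) < 4:
                raise ValueError(f"{path}:{lineno}: malformed line {line!r}")
            parts = [tokens[0], " ".join(tokens[1:-2]), tokens[-2], tokens[-1]]
        acc, feature = parts[0], parts[1]
        if feature not in _GFF_TO_LABEL:
            raise ValueError(f"{path}:{lineno}: unknown feature {feature!r}")
        start, end = int(parts[2]), int(parts[3])
        if acc not in per_acc:
            per_acc[acc] = []
            order.append(acc)
        per_acc[acc].append((_GFF_TO_LABEL[feature], start, end))
    if not per_acc:
        raise ValueError(f"no topology lines found in {path}")
    return [_segments_to_topology(acc, per_acc[acc], None) for acc in order]


def write_deeptmhmm_gff3(topologies: Iterable[ProteinTopology], path: str | Path) -> None:
    with open(path, "w") as fh:
        for topo in topologies:
            fh.write(f"# {topo.accession} | {topo.predicted_class.value}\n")
            for seg in topo.segments:
                fh.write(
                    f"{topo.accession}\t{_LABEL_TO_GFF[seg.label]}\t{seg.start}\t{seg.end}\n"
                )
            fh.write("//\n")


_TMHMM2_TO_LABEL = {
    "inside": SegmentLabel.INSIDE,
    "outside": SegmentLabel.OUTSIDE,
    "TMhelix": SegmentLabel.TM_HELIX,
}


def read_tmhmm2_long(path: str | Path) -> list[ProteinTopology]:
    """Parse TMHMM 2.0 "long" output.

    Lines are ``ACC <tab> TMHMM2.0 <tab> {inside|outside|TMhelix} <tab>
    start <tab> end``; ``#`` lines are ignored. Predicted class is TM when
    any helix is present, else GLOB.
    """
    per_acc: dict[str, list[tuple[SegmentLabel, int, int]]] = {}
    order: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 5:
            raise ValueError(f"{path}:{lineno}: malformed line {line!r}")
        acc, kind = parts[0], parts[2]
        if kind not in _TMHMM2_TO_LABEL:
            raise ValueError(f"{path}:{lineno}: unknown region kind {kind!r}")
        if acc not in per_acc:
            per_acc[acc] = []
            order.append(acc)
        per_acc[acc].append((_TMHMM2_TO_LABEL[kind], int(parts[3]), int(parts[4])))
    if not per_acc:
        raise ValueError(f"no topology lines found in {path}")
    out = []
    for acc in order:
        has_tm = any(lbl == SegmentLabel.TM_HELIX for lbl, _, _ in per_acc[acc])
        cls = PredictedClass.TM if has_tm else PredictedClass.GLOB
        out.append(_segments_to_topology(acc, per_acc[acc], cls))
    return out


def write_tmhmm2_long(topologies: Iterable[ProteinTopology], path: str | Path) -> None:
    reverse = {v: k for k, v in _TMHMM2_TO_LABEL.items()}
    with open(path, "w") as fh:
        for topo in topologies:
            for seg in topo.segments:
                kind = reverse.get(seg.label)
                if kind is None:
                    # TMHMM2 has no signal/beta/periplasm vocabulary
                    kind = "outside" if seg.label != SegmentLabel.INSIDE else "inside"
                fh.write(f"{topo.accession}\tTMHMM2.0\t{kind}\t{seg.start}\t{seg.end}\n")
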