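"""Core domain types shared across the pipeline.

Coordinate convention: every residue position in this package is 1-based and
inclusive, matching both UniProt feature tables and DeepTMHMM segment output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

#: The 20 standard amino acids plus selenocysteine (U) and the ambiguity
#: codes UniProt allows in canonical sequences (X, B, Z).
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY") | set("UXBZ")


class SegmentLabel(str, Enum):
    """Per-residue topology labels in the DeepTMHMM vocabulary."""

    SIGNAL = "SIGNAL"
    INSIDE = "INSIDE"
    OUTSIDE = "OUTSIDE"
    TM_HELIX = "TM_HELIX"
    BETA_STRAND = "BETA_STRAND"
    PERIPLASM = "PERIPLASM"


#: Labels that span the membrane; used both for tm_count and conflict rules.
MEMBRANE_LABELS = frozenset({SegmentLabel.TM_HELIX, SegmentLabel.BETA_STRAND})


class PredictedClass(str, Enum):
    """DeepTMHMM whole-protein classes."""

    GLOB = "GLOB"
    SP_GLOB = "SP+GLOB"
    TM = "TM"
    SP_TM = "SP+TM"
    BETA = "BETA"


class FeatureKind(str, Enum):
    """The structural-feature vocabulary used by every downstream table."""

    SS = "SS"
    NGLYC = "NGLYC"
    TM = "TM"
    CYS = "CYS"
    SEQUON = "SEQUON"
    FREE_CYS = "FREE_CYS"
    FREE_SEQUON = "FREE_SEQUON"


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its identity.

    Parameters
    ----------
    accession : str
        Primary key, e.g. a UniProt accession.
    sequence : str
        Upper-case amino-acid sequence.
    entry_name : str, optional
        Secondary human-readable name (UniProt entry name).
    """

    accession: str
    sequence: str
    entry_name: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        for i, aa in enumerate(self.sequence, start=1):
            if aa not in AMINO_ACIDS:
                raise ValueError(
                    f"{self.accession}: non-amino-acid character "
                    f"{aa!r} at position {i}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DisulfideAnnotation:
    """One annotated disulfide bond.

    ``pos_b`` is ``None`` for interchain bonds whose partner residue lies in
    another chain. Intrachain positions are normalised so pos_a < pos_b.
    """

    pos_a: int
    pos_b: Optional[int] = None
    interchain: bool = False

    def __post_init__(self) -> None:
        if self.pos_a < 1:
            raise ValueError("pos_a must be >= 1")
        if self.pos_b is not None:
            if self.pos_b < 1:
                raise ValueError("pos_b must be >= 1")
            if self.pos_b == self.pos_a:
                raise ValueError("disulfide cannot join a residue to itself")
            if self.pos_b < self.pos_a:
                a, b = self.pos_b, self.pos_a
                object.__setattr__(self, "pos_a", a)
                object.__setattr__(self, "pos_b", b)

    @property
    def positions(self) -> tuple[int, ...]:
        """The known residue positions (1 or 2 of them)."""
        return (self.pos_a,) if self.pos_b is None else (self.pos_a, self.pos_b)


@dataclass(frozen=True)
class GlycosylationAnnotation:
    """One annotated N-linked glycosylation site (the modified Asn)."""

    position: int
    note: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")


@dataclass(frozen=True)
class ProteinAnnotations:
    """All PTM annotations parsed for one protein."""

    disulfides: tuple[DisulfideAnnotation, ...] = ()
    glycosites: tuple[GlycosylationAnnotation, ...] = ()
    declared_length: Optional[int] = None


@dataclass(frozen=True)
class TopologySegment:
    label: SegmentLabel
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid segment bounds {self.start}..{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ProteinTopology:
    """An ordered, gap-free segmentation of one protein.

    Segments are contiguous, non-overlapping and cover 1..length exactly;
    this is validated on construction.
    """

    accession: str
    segments: tuple[TopologySegment, ...]
    predicted_class: PredictedClass

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError(f"{self.accession}: topology has no segments")
        expected = 1
        for seg in self.segments:
            if seg.start != expected:
                kind = "gap" if seg.start > expected else "overlap"
                raise ValueError(
                    f"{self.accession}: {kind} in topology coverage at "
                    f"position {min(seg.start, expected)}"
                )
            expected = seg.end + 1

    @property
    def length(self) -> int:
        return self.segments[-1].end

    def tm_count(self) -> int:
        """Number of membrane-spanning segments (helices or strands)."""
        return sum(1 for s in self.segments if s.label in MEMBRANE_LABELS)

    def label_at(self, position: int) -> SegmentLabel:
        """Label of the residue at ``position`` (1-based)."""
        if not 1 <= position <= self.length:
            raise ValueError(
                f"{self.accession}: position {position} outside 1..{self.length}"
            )
        for seg in self.segments:
            if seg.start <= position <= seg.end:
                return seg.label
        raise AssertionError("unreachable: validated coverage")


@dataclass(frozen=True)
class SequonSite:
    """One N-X-S/T (X != P) motif occurrence; position indexes the Asn."""

    position: int
    triplet: str

    def __post_init__(self) -> None:
        t = self.triplet
        if len(t) != 3 or t[0] != "N" or t[1] == "P" or t[2] not in "ST":
            raise ValueError(f"not a canonical sequon triplet: {t!r}")


QuantileVector = tuple[float, float, float, float]

ZERO_Q: QuantileVector = (0.0, 0.0, 0.0, 0.0)


@dataclass
class FeatureRow:
    """Per-protein feature counts, rates and length-quantile vectors.

    The quantile vectors give, for each of the four equal-length slices of
    the protein (Q1 = N-terminal), how much of the feature falls there:

    * ``q_ss`` counts half-cystines (each disulfide-engaged cysteine at its
      own position), so it sums to ``n_ss_cys``;
    * ``q_glyc`` counts all annotated N-glycosites, ``q_glyc_on_sequon``
      only those sitting on a canonical sequon;
    * ``q_tm`` places each membrane segment at its midpoint;
    * ``q_cys`` / ``q_sequon`` count all cysteines / sequons.

    Rates are ``None`` (not 0) when the denominator is zero.
    """

    accession: str
    length: int
    n_tm: int = 0
    n_ss: int = 0
    n_ss_cys: int = 0
    n_ss_interchain: int = 0
    n_glyc: int = 0
    n_glyc_on_sequon: int = 0
    n_glyc_atypical: int = 0
    n_cys: int = 0
    n_sequon: int = 0
    cys_utilization: Optional[float] = None
    sequon_occupancy: Optional[float] = None
    q_ss: QuantileVector = ZERO_Q
    q_glyc: QuantileVector = ZERO_Q
    q_glyc_on_sequon: QuantileVector = ZERO_Q
    q_tm: QuantileVector = ZERO_Q
    q_cys: QuantileVector = ZERO_Q
    q_sequon: QuantileVector = ZERO_Q

    def quantile_vector(self, kind: FeatureKind) -> QuantileVector:
        return {
            FeatureKind.SS: self.q_ss,
            FeatureKind.NGLYC: self.q_glyc,
            FeatureKind.TM: self.q_tm,
            FeatureKind.CYS: self.q_cys,
            FeatureKind.SEQUON: self.q_sequon,
        }[kind]

    def count(self, kind: FeatureKind) -> int:
        return {
            FeatureKind.SS: self.n_ss,
            FeatureKind.NGLYC: self.n_glyc,
            FeatureKind.TM: self.n_tm,
            FeatureKind.CYS: self.n_cys,
            FeatureKind.SEQUON: self.n_sequon,
        }[kind]


@dataclass(frozen=True)
class ConflictRecord:
    """One feature site judged against the predicted topology.

    ``is_conflict`` is true when any of the feature's residues sits in a
    cytosolic (INSIDE) or membrane-embedded region — incompatible with the
    extracellular/ER-lumenal compartmentalisation of disulfide bonds and
    N-glycans.
    """

    accession: str
    feature_kind: FeatureKind
    positions: tuple[int, ...]
    labels: tuple[SegmentLabel, ...]
    is_conflict: bool


def mean_quantile(vector: Sequence[float]) -> float:
    """Weighted mean quantile index (1-4) of a feature's sites; 0 if absent."""
    total = float(sum(vector))
    if total == 0 or math.isnan(total):
        return 0.0
    return sum((i + 1) * v for i, v in enumerate(vector)) / total
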