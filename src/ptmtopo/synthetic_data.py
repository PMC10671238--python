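"""Synthetic proteome generator with full ground truth.

Builds proteins segment-wise: membrane helices from a hydrophobic residue
pool, loops from a background pool that deliberately contains neither C
nor N, so that every cysteine and every sequon in the emitted sequences is
planted and therefore known exactly. Disulfide bonds, N-glycosites, free
cysteines and free sequons are placed on OUTSIDE-labelled residues except
for deliberately injected conflicts, which are forced onto INSIDE (or
membrane) residues. The same proteome is emitted in every format the
pipeline reads (FASTA, Swiss-Prot-style flat file, DeepTMHMM 3-line and
GFF3-like, TMHMM2 long) together with a ground-truth JSON, and the whole
run is byte-deterministic for a fixed config and seed.

Defaults emulate the human-proteome study conditions: lognormal lengths
with proteome-scale mean (~550 aa), ~25% membrane proteins, a TM-count
distribution with spikes at 1 and 7 (single-pass proteins and GPCRs),
cysteine utilization ~0.70 and sequon occupancy ~0.85, and a type-I
orientation bias that makes PTMs N-terminal-heavy and membrane segments
C-terminal-heavy.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import annotation_io
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

GROUND_TRUTH_SCHEMA = "gt-v1"

# loop/background pool excludes C and N so features are exactly the planted ones
_BACKGROUND_POOL = list("ADEFGHIKLMPQRSTVWY")
_BACKGROUND_FREQ = np.array(
    [8.3, 5.5, 6.8, 3.9, 7.1, 2.3, 6.0, 9.7, 2.4, 4.7, 6.3, 3.9, 5.7, 6.6, 5.4, 6.9, 1.1, 2.9]
)
_BACKGROUND_FREQ = _BACKGROUND_FREQ / _BACKGROUND_FREQ.sum()
_TM_POOL = list("AFGILMVW")
_SEQUON_X_POOL = list("ADEGHIKLMQRSTV")  # sequon middle residue: not P/C/N

_GLYC_NOTE = "N-linked (GlcNAc...) asparagine"

_DEFAULT_TM_COUNT_DIST = {
    1: 0.35,
    2: 0.06,
    3: 0.05,
    4: 0.05,
    5: 0.04,
    6: 0.04,
    7: 0.18,
    8: 0.04,
    9: 0.03,
    10: 0.03,
    11: 0.03,
    12: 0.04,
    13: 0.03,
    14: 0.03,
}


class InfeasibleConfigError(ValueError):
    """Raised before any file is written when a config cannot be realised."""


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic proteome; defaults are the study conditions."""

    n_proteins: int = 1000
    seed: int = 0
    length_median: float = 400.0
    length_sigma: float = 0.8
    min_length: int = 50
    fraction_tm: float = 0.25
    tm_count_dist: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_TM_COUNT_DIST)
    )
    tm_length: int = 21
    min_loop: int = 5
    p_signal: float = 0.30
    signal_length: int = 20
    cys_density: float = 2.5  # per 100 loop residues
    sequon_density: float = 1.2  # per 100 loop residues
    p_cys_utilization: float = 0.70
    p_sequon_occupancy: float = 0.85
    interchain_rate: float = 0.03
    orientation_bias: float = 0.75  # P(N-terminus faces outside) sans signal
    crossing_bonds: bool = False
    conflict_rate_ss: float = 0.0
    conflict_rate_nglyc: float = 0.0
    conflict_rate_free_cys: float = 0.0
    conflict_rate_free_sequon: float = 0.0
    tmhmm2_flip_rate: float = 0.0  # emulated predictor-B orientation flips

    def validate(self) -> None:
        probs = [
            self.fraction_tm,
            self.p_signal,
            self.p_cys_utilization,
            self.p_sequon_occupancy,
            self.interchain_rate,
            self.orientation_bias,
            self.conflict_rate_ss,
            self.conflict_rate_nglyc,
            self.conflict_rate_free_cys,
            self.conflict_rate_free_sequon,
            self.tmhmm2_flip_rate,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise InfeasibleConfigError("all probabilities must lie in [0, 1]")
        if self.cys_density < 0 or self.sequon_density < 0:
            raise InfeasibleConfigError("densities must be >= 0")
        if self.n_proteins < 1:
            raise InfeasibleConfigError("n_proteins must be >= 1")
        # each sequon consumes 3 residues, each cysteine 1; demand beyond half
        # the loop budget cannot be placed reliably
        demand = (3 * self.sequon_density + self.cys_density) / 100.0
        if demand > 0.5:
            raise InfeasibleConfigError(
                f"feature demand {demand:.2f} residues/residue exceeds loop capacity"
            )
        total = sum(self.tm_count_dist.values())
        if abs(total - 1.0) > 1e-9 or any(
            m < 1 or p < 0 for m, p in self.tm_count_dist.items()
        ):
            raise InfeasibleConfigError("tm_count_dist must be a distribution over m >= 1")


@dataclass
class SyntheticProteome:
    """In-memory result of one generator run."""

    config: SyntheticConfig
    records: list[ProteinRecord]
    annotations: dict[str, ProteinAnnotations]
    topologies: dict[str, ProteinTopology]
    tmhmm2_topologies: dict[str, ProteinTopology]
    ground_truth: dict

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit every format into ``out_dir``; returns the file map."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "proteome.fasta",
            "flatfile": out / "proteome.dat",
            "deeptmhmm_3line": out / "deeptmhmm.3line",
            "deeptmhmm_gff3": out / "deeptmhmm.gff3",
            "tmhmm2": out / "tmhmm2.long",
            "ground_truth": out / "ground_truth.json",
        }
        annotation_io.write_fasta(self.records, paths["fasta"])
        annotation_io.write_uniprot_flatfile(
            {r.accession: (r, self.annotations[r.accession]) for r in self.records},
            paths["flatfile"],
        )
        sequences = {r.accession: r.sequence for r in self.records}
        topos = [self.topologies[r.accession] for r in self.records]
        annotation_io.write_deeptmhmm_3line(topos, paths["deeptmhmm_3line"], sequences)
        annotation_io.write_deeptmhmm_gff3(topos, paths["deeptmhmm_gff3"])
        annotation_io.write_tmhmm2_long(
            [self.tmhmm2_topologies[r.accession] for r in self.records], paths["tmhmm2"]
        )
        paths["ground_truth"].write_text(
            json.dumps(self.ground_truth, indent=1, sort_keys=True) + "\n"
        )
        return paths


def _sample_counts(rng: np.random.Generator, mean: float) -> int:
    return int(rng.poisson(mean)) if mean > 0 else 0


def _partition_loops(
    rng: np.random.Generator, budget: int, n_loops: int, min_loop: int, first_frac: float
) -> list[int]:
    """Split a loop budget into n_loops parts, first loop taking first_frac."""
    sizes = [min_loop] * n_loops
    remainder = budget - min_loop * n_loops
    first_extra = int(round(first_frac * remainder))
    sizes[0] += first_extra
    remainder -= first_extra
    if remainder > 0 and n_loops > 1:
        shares = rng.multinomial(remainder, np.ones(n_loops - 1) / (n_loops - 1))
        for i, s in enumerate(shares, start=1):
            sizes[i] += int(s)
    elif remainder > 0:
        sizes[0] += remainder
    return sizes


def _build_topology(
    rng: np.random.Generator, cfg: SyntheticConfig, length: int
) -> tuple[np.ndarray, PredictedClass]:
    """Per-residue label array (as SegmentLabel values) and protein class.

    Draw order is fixed: signal, TM membership, TM count, orientation,
    loop partition — so adding downstream features never shifts these.
    """
    has_signal = bool(rng.random() < cfg.p_signal) and length >= 3 * cfg.signal_length
    is_tm = bool(rng.random() < cfg.fraction_tm)
    m = 0
    if is_tm:
        ms = np.array(sorted(cfg.tm_count_dist))
        ps = np.array([cfg.tm_count_dist[int(k)] for k in ms])
        m = int(rng.choice(ms, p=ps))
    first_outside = True if has_signal else bool(rng.random() < cfg.orientation_bias)
    first_frac = float(rng.uniform(0.35, 0.65))

    signal_len = cfg.signal_length if has_signal else 0
    avail = length - signal_len
    if m > 0:
        m_max = (avail - cfg.min_loop) // (cfg.tm_length + cfg.min_loop)
        m = min(m, int(m_max))
    labels = np.empty(length, dtype=object)
    pos = 0
    if signal_len:
        labels[:signal_len] = SegmentLabel.SIGNAL
        pos = signal_len
    if m < 1:
        # globular: secreted proteins (signal) are lumenal/extracellular,
        # the rest cytosolic
        labels[pos:] = SegmentLabel.OUTSIDE if has_signal else SegmentLabel.INSIDE
        cls = PredictedClass.SP_GLOB if has_signal else PredictedClass.GLOB
        return labels, cls
    budget = avail - m * cfg.tm_length
    loops = _partition_loops(rng, budget, m + 1, cfg.min_loop, first_frac)
    side = SegmentLabel.OUTSIDE if first_outside else SegmentLabel.INSIDE
    for i in range(m):
        labels[pos : pos + loops[i]] = side
        pos += loops[i]
        labels[pos : pos + cfg.tm_length] = SegmentLabel.TM_HELIX
        pos += cfg.tm_length
        side = (
            SegmentLabel.INSIDE if side is SegmentLabel.OUTSIDE else SegmentLabel.OUTSIDE
        )
    labels[pos:] = side
    cls = PredictedClass.SP_TM if has_signal else PredictedClass.TM
    return labels, cls


def _labels_to_topology(
    accession: str, labels: np.ndarray, cls: PredictedClass
) -> ProteinTopology:
    segments = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] is not labels[start]:
            segments.append(TopologySegment(labels[start], start + 1, i))
            start = i
    return ProteinTopology(accession=accession, segments=tuple(segments), predicted_class=cls)


def _pick_triplet(
    rng: np.random.Generator, label_ok: np.ndarray, free: np.ndarray
) -> Optional[int]:
    """Random start index (0-based) of a free 3-mer within one compartment."""
    ok = label_ok & free
    cand = ok[:-2] & ok[1:-1] & ok[2:]
    idx = np.flatnonzero(cand)
    if idx.size == 0:
        return None
    return int(rng.choice(idx))


def _pick_single(
    rng: np.random.Generator, label_ok: np.ndarray, free: np.ndarray
) -> Optional[int]:
    idx = np.flatnonzero(label_ok & free)
    if idx.size == 0:
        return None
    return int(rng.choice(idx))


def generate_proteome(config: Optional[SyntheticConfig] = None) -> SyntheticProteome:
    """Generate a proteome with exact ground truth (see module docstring).

    Raises :class:`InfeasibleConfigError` before building anything when
    the config cannot be realised.
    """
    cfg = config or SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    records: list[ProteinRecord] = []
    annotations: dict[str, ProteinAnnotations] = {}
    topologies: dict[str, ProteinTopology] = {}
    tmhmm2_topologies: dict[str, ProteinTopology] = {}
    gt_proteins: dict[str, dict] = {}

    width = len(str(cfg.n_proteins))
    for idx in range(cfg.n_proteins):
        accession = f"SYN{idx + 1:0{width}d}"
        length = max(
            cfg.min_length,
            int(round(rng.lognormal(np.log(cfg.length_median), cfg.length_sigma))),
        )
        labels, cls = _build_topology(rng, cfg, length)
        outside = np.array([lab is SegmentLabel.OUTSIDE for lab in labels])
        inside = np.array([lab is SegmentLabel.INSIDE for lab in labels])
        membrane = np.array(
            [lab in (SegmentLabel.TM_HELIX, SegmentLabel.BETA_STRAND) for lab in labels]
        )
        free = np.ones(length, dtype=bool)
        n_outside = int(outside.sum())

        is_mp = bool(membrane.any())

        # --- plan sequons -------------------------------------------------
        n_seq = _sample_counts(rng, cfg.sequon_density * n_outside / 100.0)
        seq_occupied = rng.random(n_seq) < cfg.p_sequon_occupancy
        seq_conflict_wanted = np.where(
            seq_occupied,
            rng.random(n_seq) < cfg.conflict_rate_nglyc,
            rng.random(n_seq) < cfg.conflict_rate_free_sequon,
        )
        sequon_entries: list[dict] = []
        for j in range(n_seq):
            want_conflict = bool(seq_conflict_wanted[j]) and is_mp
            target = inside if want_conflict else outside
            start0 = _pick_triplet(rng, target, free)
            actually_conflict = want_conflict
            if start0 is None and want_conflict:
                start0 = _pick_triplet(rng, membrane, free)
                if start0 is None:
                    start0 = _pick_triplet(rng, outside, free)
                    actually_conflict = False
            elif start0 is None:
                continue  # no room left: drop this sequon
            if start0 is None:
                continue
            free[start0 : start0 + 3] = False
            third = "S" if rng.random() < 0.5 else "T"
            x = _SEQUON_X_POOL[int(rng.integers(len(_SEQUON_X_POOL)))]
            sequon_entries.append(
                {
                    "position": start0 + 1,
                    "triplet": "N" + x + third,
                    "occupied": bool(seq_occupied[j]),
                    "conflict": actually_conflict,
                }
            )
        sequon_entries.sort(key=lambda e: e["position"])

        # --- plan cysteines ----------------------------------------------
        n_cys = _sample_counts(rng, cfg.cys_density * n_outside / 100.0)
        engaged_flags = rng.random(n_cys) < cfg.p_cys_utilization
        engaged_idx = np.flatnonzero(engaged_flags)
        # intrachain bonds need an even engaged count; an odd leftover
        # engaged cysteine becomes an interchain bond (partner in another
        # chain), keeping the realised utilization unbiased at p
        odd_interchain = engaged_idx.size % 2 == 1
        n_bonds = engaged_idx.size // 2
        bond_conflict = rng.random(n_bonds) < cfg.conflict_rate_ss
        free_cys_conflict = rng.random(n_cys) < cfg.conflict_rate_free_cys

        # positions for bond ends: clean bonds need two outside residues,
        # a conflicted bond one outside + one inside/membrane residue
        clean_positions: list[int] = []
        conflicted_bonds: list[tuple[int, int]] = []  # (outside_pos, inside_pos)
        dropped_bonds = 0
        for b in range(n_bonds):
            if bond_conflict[b] and is_mp:
                p_out = _pick_single(rng, outside, free)
                if p_out is not None:
                    free[p_out] = False
                p_in = _pick_single(rng, inside, free)
                if p_in is None:
                    p_in = _pick_single(rng, membrane, free)
                if p_out is None or p_in is None:
                    if p_out is not None:  # give the spare residue back
                        free[p_out] = True
                    dropped_bonds += 1
                    continue
                free[p_in] = False
                conflicted_bonds.append((p_out + 1, p_in + 1))
            else:
                p1 = _pick_single(rng, outside, free)
                if p1 is not None:
                    free[p1] = False
                p2 = _pick_single(rng, outside, free)
                if p1 is None or p2 is None:
                    if p1 is not None:
                        free[p1] = True
                    dropped_bonds += 1
                    continue
                free[p2] = False
                clean_positions.extend([p1 + 1, p2 + 1])

        free_cys_positions: list[tuple[int, bool]] = []
        for j in np.flatnonzero(~engaged_flags):
            want_conflict = bool(free_cys_conflict[j]) and is_mp
            target = inside if want_conflict else outside
            p = _pick_single(rng, target, free)
            actually_conflict = want_conflict
            if p is None and want_conflict:
                p = _pick_single(rng, membrane, free)
                if p is None:
                    p = _pick_single(rng, outside, free)
                    actually_conflict = False
            if p is None:
                continue
            free[p] = False
            free_cys_positions.append((p + 1, actually_conflict))

        # non-crossing pairing of clean bonds: sort ends, pair adjacent;
        # crossing mode pairs a random perfect matching instead
        clean_positions.sort()
        bonds: list[tuple[int, int]] = []
        if cfg.crossing_bonds and len(clean_positions) >= 4:
            perm = rng.permutation(len(clean_positions))
            for k in range(0, len(perm) - 1, 2):
                a, b = clean_positions[perm[k]], clean_positions[perm[k + 1]]
                bonds.append((min(a, b), max(a, b)))
        else:
            for k in range(0, len(clean_positions) - 1, 2):
                bonds.append((clean_positions[k], clean_positions[k + 1]))
        conflicted_norm = [(min(a, b), max(a, b)) for a, b in conflicted_bonds]
        all_bonds = sorted(bonds + conflicted_norm)
        conflict_bond_set = set(conflicted_norm)

        # interchain bonds: the odd leftover engaged cysteine plus, at the
        # configured rate, one extra engaged cysteine
        interchain_positions: list[int] = []
        n_interchain_wanted = int(odd_interchain) + int(
            rng.random() < cfg.interchain_rate
        )
        for _ in range(n_interchain_wanted):
            p = _pick_single(rng, outside, free)
            if p is not None:
                free[p] = False
                interchain_positions.append(p + 1)
        interchain_positions.sort()

        # --- materialize the sequence ------------------------------------
        seq = np.empty(length, dtype="U1")
        for mask, pool, freq in (
            (membrane, _TM_POOL, None),
            (~membrane, _BACKGROUND_POOL, _BACKGROUND_FREQ),
        ):
            k = int(mask.sum())
            if k:
                seq[mask] = rng.choice(pool, size=k, p=freq)
        for entry in sequon_entries:
            i = entry["position"] - 1
            seq[i : i + 3] = list(entry["triplet"])
        cys_positions_all = sorted(
            [p for pair in all_bonds for p in pair]
            + [p for p, _ in free_cys_positions]
            + interchain_positions
        )
        for p in cys_positions_all:
            seq[p - 1] = "C"
        sequence = "".join(seq)

        record = ProteinRecord(
            accession=accession, sequence=sequence, entry_name=f"{accession}_SYNTH"
        )
        disulfides = [
            DisulfideAnnotation(a, b, interchain=False) for a, b in all_bonds
        ]
        disulfides.extend(
            DisulfideAnnotation(p, None, interchain=True) for p in interchain_positions
        )
        glycosites = sorted(
            e["position"] for e in sequon_entries if e["occupied"]
        )
        annots = ProteinAnnotations(
            disulfides=tuple(disulfides),
            glycosites=tuple(
                GlycosylationAnnotation(p, _GLYC_NOTE) for p in glycosites
            ),
            declared_length=length,
        )
        topology = _labels_to_topology(accession, labels, cls)

        # TMHMM2-style view of the same protein: no signal vocabulary, and
        # optionally a flipped orientation to emulate predictor disagreement
        flip = bool(rng.random() < cfg.tmhmm2_flip_rate) and is_mp
        labels2 = labels.copy()
        labels2[labels2 == SegmentLabel.SIGNAL] = (
            labels[cfg.signal_length] if cls in (PredictedClass.SP_TM,) else SegmentLabel.OUTSIDE
        )
        if flip:
            swap = {
                SegmentLabel.INSIDE: SegmentLabel.OUTSIDE,
                SegmentLabel.OUTSIDE: SegmentLabel.INSIDE,
            }
            labels2 = np.array([swap.get(lab, lab) for lab in labels2], dtype=object)
        cls2 = PredictedClass.TM if is_mp else PredictedClass.GLOB
        tmhmm2_topologies[accession] = _labels_to_topology(accession, labels2, cls2)

        records.append(record)
        annotations[accession] = annots
        topologies[accession] = topology

        n_sequon = len(sequon_entries)
        n_glyc = len(glycosites)
        n_ss = len(all_bonds) + len(interchain_positions)
        n_ss_cys = 2 * len(all_bonds) + len(interchain_positions)
        n_cys_actual = len(cys_positions_all)
        conflicts = {
            "SS": sorted(list(pair) for pair in conflict_bond_set),
            "NGLYC": sorted(
                e["position"]
                for e in sequon_entries
                if e["occupied"] and e["conflict"]
            ),
            "FREE_CYS": sorted(p for p, c in free_cys_positions if c),
            "FREE_SEQUON": sorted(
                e["position"]
                for e in sequon_entries
                if not e["occupied"] and e["conflict"]
            ),
        }
        gt_proteins[accession] = {
            "length": length,
            "predicted_class": cls.value,
            "tm_count": topology.tm_count(),
            "flipped_in_tmhmm2": flip,
            "cys_positions": cys_positions_all,
            "sequon_positions": [e["position"] for e in sequon_entries],
            "bonds": [list(b) for b in all_bonds],
            "interchain_positions": interchain_positions,
            "glycosites": glycosites,
            "free_cys": sorted(p for p, _ in free_cys_positions),
            "free_sequons": sorted(
                e["position"] for e in sequon_entries if not e["occupied"]
            ),
            "conflicts": conflicts,
            "n_tm": topology.tm_count(),
            "n_ss": n_ss,
            "n_ss_cys": n_ss_cys,
            "n_glyc": n_glyc,
            "n_cys": n_cys_actual,
            "n_sequon": n_sequon,
            "cys_utilization": (n_ss_cys / n_cys_actual) if n_cys_actual else None,
            "sequon_occupancy": (n_glyc / n_sequon) if n_sequon else None,
        }

    ground_truth = {
        "schema_version": GROUND_TRUTH_SCHEMA,
        "config": {k: (dict(v) if isinstance(v, dict) else v) for k, v in asdict(cfg).items()},
        "proteins": gt_proteins,
    }
    return SyntheticProteome(
        config=cfg,
        records=records,
        annotations=annotations,
        topologies=topologies,
        tmhmm2_topologies=tmhmm2_topologies,
        ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# Planted archetypes for clustering tests
# ---------------------------------------------------------------------------

#: Archetype means over the clustering matrix columns
#: (n_ss, n_glyc, n_tm, n_cys, n_sequon, q_mean_ss, q_mean_glyc, q_mean_tm).
ARCHETYPE_MEANS = {
    "TM_RICH": (1, 1, 7, 3, 2, 1.5, 1.5, 3.0),
    "GLYC_RICH": (2, 12, 0, 6, 14, 2.0, 2.0, 0.0),
    "SS_RICH": (12, 2, 0, 26, 3, 2.0, 2.0, 0.0),
}


def plant_archetypes(
    n_rows: int = 300,
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    jitter: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Labelled clustering-matrix rows drawn from three planted archetypes.

    Count columns get Poisson jitter around the archetype mean (scaled by
    ``jitter``; 0 gives the exact means), quantile-mean columns Gaussian
    jitter clipped to [1, 4] (0 stays 0). Returns (matrix, labels) with
    labels in {0, 1, 2} ordered as ARCHETYPE_MEANS.
    """
    from .cluster_analysis import MATRIX_COLUMNS

    rng = np.random.default_rng(seed)
    names = list(ARCHETYPE_MEANS)
    labels = rng.choice(len(names), size=n_rows, p=np.asarray(weights) / sum(weights))
    rows = []
    for lab in labels:
        mean = ARCHETYPE_MEANS[names[lab]]
        row = []
        for j, mu in enumerate(mean):
            if j < 5:  # count columns
                if jitter > 0:
                    val = float(rng.poisson(mu)) * jitter + mu * (1 - jitter)
                else:
                    val = float(mu)
                if j in (0, 1):  # matrix invariant: n_ss, n_glyc >= 1
                    val = max(1.0, val)
            else:  # quantile-mean columns
                if mu == 0 or jitter == 0:
                    val = float(mu)
                else:
                    val = float(np.clip(mu + rng.normal(0, 0.3 * jitter), 1.0, 4.0))
            row.append(val)
        rows.append(row)
    matrix = pd.DataFrame(
        rows,
        columns=MATRIX_COLUMNS,
        index=[f"ARCH{i + 1:04d}" for i in range(n_rows)],
    )
    matrix.index.name = "accession"
    return matrix, labels
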