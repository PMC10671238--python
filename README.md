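# ptmtopo

Proteome-wide integration of three structural features of membrane and
secreted proteins: **transmembrane segments (TMs)**, **disulfide bonds
(SSs)** and **N-linked glycosylation (N-GLYCO)**.

Disulfide bonds and N-glycans are both installed in the endoplasmic
reticulum and end up on the extracellular/lumenal side of the membrane;
transmembrane segments are inserted by the translocon. Integrating the
three features over a whole proteome exposes relationships that none of
them shows alone — how SS and N-GLYCO occurrence scales with protein
length while TM count does not, how TM-rich proteins are PTM-poor, where
along the chain (N- vs C-terminal) each feature sits, and where an
annotated PTM *contradicts* the predicted membrane topology (a cytosolic
or membrane-embedded disulfide cysteine or glycosylated Asn is a
"conflict" that flags either a mispredicted topology or a dynamic site).

The package is aimed at structural bioinformaticians and proteomics
groups who have a FASTA proteome, UniProtKB/Swiss-Prot annotations and
DeepTMHMM (or TMHMM 2.0) predictions, and want the full analysis stack
behind one reproducible command.

## What it computes

Per protein (``features.tsv``), with all positions 1-based:

* sequons — every N-X-S/T with X ≠ P (overlaps included), cysteines;
* counts: n_tm, n_ss (bonds, interchain included), n_ss_cys
  (disulfide-engaged cysteines, i.e. half-cystines), n_glyc (annotated
  N-glycosites; atypical non-sequon sites counted and also reported
  separately), n_cys, n_sequon;
* rates: cysteine utilization = n_ss_cys / n_cys, sequon occupancy =
  (glycosites on sequons) / n_sequon — undefined (``NA``), not 0, when
  the denominator is empty;
* length-quantile vectors: each protein is cut into four equal N→C
  slices (Q1…Q4, quantile of position *p* in a length-*L* chain is
  ``min(4, ⌊4(p−1)/L⌋+1)``), and every feature's sites are binned into
  them (SS mass in half-cystines, each TM at its segment midpoint).

Per proteome: length histograms with sliding-window peak intervals
(width 101, step 1), multiplicity profiles (1…30 singly, then width-10
bins), mean-count correlation curves, three-set Venn partitions over
count predicates (e.g. exactly 1, 1–3, >10 of each feature), quantile
profiles, UPGMA clustering of the SS/N-GLYCO proteome (proteins with ≥1
bond and ≥1 glycosite) with Pearson-correlation distance d = 1 − r and
k = 3, and conflict detection per predicted membrane protein with
per-predictor comparison. A versioned per-protein JSON document
(``viz-v1``) feeds an interactive protein renderer.

A synthetic-proteome generator emits the same proteome in every format
the pipeline reads (FASTA, Swiss-Prot flat file, DeepTMHMM 3-line and
GFF3-like, TMHMM2 long) plus an exact ground-truth JSON, so the entire
stack is testable offline.

## Worked example

Simulate a 500-protein proteome (5 % of feature sites deliberately
mislocated) and run the full pipeline:

```sh
ptmtopo simulate --out-dir demo/sim --n 500 --seed 7 --conflict-rate 0.05
ptmtopo run-all --fasta demo/sim/proteome.fasta \
                --flatfile demo/sim/proteome.dat \
                --topology demo/sim/deeptmhmm.3line \
                --out-dir demo/out
```

which logs, among other stages:

```
INFO ptmtopo.report: inputs: 500 proteins, 500 annotated entries, 500 topologies
INFO ptmtopo.report: subset tm: n=131 mean=525.81 peak=(321, 421)
INFO ptmtopo.report: subset non_tm: n=369 mean=569.92 peak=(211, 311)
INFO ptmtopo.report: conflicts: 22/131 predicted MPs (16.79%) with observed-PTM conflicts
```

Read: 131 of 500 proteins carry ≥1 predicted membrane segment; their
mean length (525.8 aa) is close to the soluble set (569.9 aa) while the
peak of the length distribution sits in a different 101-residue window
(321–421 vs 211–311) — the length *distribution* separates the
proteomes even where the means do not. With a 5 % injection rate, 22 of
the 131 predicted membrane proteins carry at least one annotated
disulfide or glycosite on the wrong side of the membrane.

The single-count Venn partition of the SS/N-GLYCO proteome:

```sh
ptmtopo venn --features demo/out/features.tsv --lo 1 --hi 1
```

```
     region  size  percentage
         SS    12   16.901408
      NGLYC    10   14.084507
   NGLYC&SS    16   22.535211
         TM    17   23.943662
      SS&TM     5    7.042254
   NGLYC&TM     8   11.267606
NGLYC&SS&TM     3    4.225352
```

Only 3 proteins (4.2 % of the 71 in-range entries) carry exactly one of
each feature — proteins rarely combine all three at low copy number.

## Layout

```
src/ptmtopo/
  annotation_io.py    FASTA / Swiss-Prot FT / DeepTMHMM / TMHMM2 readers+writers
  sequence_features.py  sequons, cysteines, quantiles, FeatureRow table
  proteome_stats.py   histograms, multiplicity, correlation, Venn, quantile profiles
  cluster_analysis.py Pearson-distance UPGMA clustering of the SS/N-GLYCO proteome
  conflict_analysis.py  compartment-rule conflicts vs predicted topology
  synthetic_data.py   ground-truthed synthetic proteome generator
  report.py           orchestration + viz-v1 JSON export
  cli.py              typer CLI (`ptmtopo`)
```

See ``docs/methods.md`` for the modelling decisions and their rationale.
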