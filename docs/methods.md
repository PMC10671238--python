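# Methods

This note records how the pipeline defines its quantities, what the
synthetic generator does and does not emulate, and the choices made
where the underlying conventions were genuinely open.

## Coordinates and formats

All residue positions are 1-based inclusive, the shared convention of
UniProt feature tables and DeepTMHMM output. Swiss-Prot flat files are
parsed with Biopython's `Bio.SwissProt`; the file is split on record
terminators first so that one malformed entry is skipped with a warning
instead of aborting the whole file. Uncertain UniProt positions (`?`,
`<`, `>`) are **dropped, never guessed** — conservative for every
downstream count — and each drop is logged. `FT CARBOHYD` records count
as glycosites only when their note says "N-linked"; O-linked and
C-linked records are ignored throughout. A `FT DISULFID a..b` span is an
intrachain bond; a single-position record, or one whose note says
"Interchain", is an interchain bond contributing one bond to `n_ss` and
one engaged cysteine per listed residue. Only the canonical sequence per
accession is used; isoforms are out of scope.

The DeepTMHMM 3-line and GFF3-like dialects are parsed by hand (no
installed library reads these tool-specific 4-column formats) into one
topology type: an ordered, gap-free segmentation over {SIGNAL, INSIDE,
OUTSIDE, TM_HELIX, BETA_STRAND, PERIPLASM}, validated to cover
1..length exactly. The two readers are tested to produce identical
structures on matched files. PERIPLASM is accepted for format
completeness, never produced for eukaryotic input, and treated as
OUTSIDE-equivalent wherever compartments matter.

## Feature definitions

* **Sequon**: N-X-S/T with X ≠ P; overlapping sequons are all counted
  and no constraint is applied at the i+3 position. Annotated
  glycosites whose Asn does not start a sequon ("atypical") stay in
  `n_glyc` but are excluded from the occupancy numerator and reported in
  their own column, so either convention can be recovered.
* **Rates**: cysteine utilization = engaged cysteines / cysteines;
  sequon occupancy = on-sequon glycosites / sequons. A rate with an
  empty denominator is undefined (`NA`), never 0 — a protein without
  sequons carries no information about occupancy.
* **Length quantiles**: quantile(p, L) = min(4, ⌊4(p−1)/L⌋+1). The
  N-terminus always falls in Q1 and, for L ≥ 4, the C-terminus in Q4;
  chains shorter than four residues are degenerate by construction.
  Remainder residues are absorbed by alternating quantiles under this
  floor rule; any consistent convention would do, this one is fixed and
  tested against an independent equal-parts enumeration.
* **Quantile units**: disulfide mass is counted in **half-cystines**
  (each engaged cysteine at its own position). A two-ended bond has no
  single natural location — its ends can sit in different domains — so
  placing each end where it sits avoids an arbitrary midpoint choice.
  Both the bond count and the half-cystine count are exposed so either
  can be plotted. A membrane segment is assigned the quantile of its
  midpoint ⌊(start+end)/2⌋; a ~21-residue helix rarely straddles a
  quantile boundary at typical protein lengths.

## Distributional statistics

Length histograms use fixed-width bins (default 100 aa) anchored at the
minimum length. Reported *peak intervals* are computed separately as the
earliest inclusive window of width `bin_width + 1` (default 101) that
maximises membership, sliding in steps of 1 — peak intervals of
published length distributions have data-dependent offsets that fixed
binning cannot reproduce, a sliding-window mode can. Multiplicity
profiles keep multiplicities 1–30 singly and pool larger ones into
width-10 bins; the pooled utilization of a bin is Σused/Σavailable, not
a mean of per-protein ratios, so that proteins with many sites weigh
accordingly. Outlier exclusion (e.g. dropping an extreme mucin from
mean-length curves) is an explicit accession list, empty by default.
Venn percentages are relative to the union of the three in-range sets
("total unique entries").

## Clustering

The SS/N-GLYCO proteome (≥1 bond and ≥1 glycosite) is clustered on an
8-column matrix: the five counts (SS, N-glyc, TM, Cys, sequon) plus one
mean length-quantile column per feature in {SS, N-GLYCO, TM} — the
weighted mean quantile index (1–4) of that feature's sites, 0 when the
feature is absent. The exact composition of the quantile columns is not
recoverable from common practice; the per-feature mean matches a 1–4
colour scale and is pluggable. Rows are compared with Pearson
correlation distance d = 1 − r across columns (no standardisation:
row-wise Pearson is already location/scale-invariant) and agglomerated
with unweighted average linkage (UPGMA) via
`scipy.cluster.hierarchy.linkage`; rows with zero variance get distance
1 to all others by convention, logged. Constant-free real matrices give
ties with measure zero, so scipy's deterministic tie handling is
sufficient; merge heights are verified against a naive O(n³)
agglomerator in the tests. The tree is cut by undoing the last k−1
merges (`scipy.cluster.hierarchy.cut_tree`), k = 3 by default. On
naturally generated (non-archetype) data UPGMA on correlation distance
can produce very unbalanced clusters — one near-singleton is normal and
is simply reported via cluster sizes, not treated as an outlier.

## Conflict rules

Conflicts are judged only for predicted membrane proteins (≥1 membrane
segment). A feature residue conflicts when its topology label is INSIDE
(cytosolic) or membrane-embedded (TM_HELIX/BETA_STRAND); the
membrane-embedded case can be switched off
(`membrane_is_conflict=False`) for sensitivity analysis, restricting
conflicts to INSIDE. SIGNAL residues never conflict: the signal peptide
is lumen-side and cleaved. A disulfide conflicts if **either** cysteine
is misplaced; an interchain bond with one known residue is judged at
that residue. Free cysteines (not in any annotated bond) and free
sequons (Asn without a glycosite) are judged singly, so per protein
free + engaged cysteines always partition all cysteines. Headline
conflict counts include only the *observed* PTM kinds (SS, N-GLYCO);
free-cysteine and free-sequon conflicts are reported separately — the
four kinds answer different questions (wrong annotation/topology vs
latent modification potential).

## Synthetic proteome generator

The generator is the package's test substrate and defines its study
conditions. Defaults, chosen once to emulate a human-proteome-scale
analysis: lognormal lengths (median 400 aa, σ = 0.8 → mean ≈ 551 aa,
minimum 50); 25 % membrane proteins; a categorical TM-count
distribution with spikes at 1 (0.35, single-pass proteins) and 7 (0.18,
the GPCR class); 21-residue helices; 30 % signal peptides; cysteine and
sequon densities of 2.5 and 1.2 per 100 loop residues (cysteine ≈ its
background amino-acid frequency); cysteine utilization 0.70 and sequon
occupancy 0.85 (both in the empirically observed >50 % / ~85 % regime);
orientation bias 0.75 toward an extracellular N-terminus (type-I
dominance, which makes PTMs N-terminal-heavy and membrane segments
C-terminal-heavy in aggregate).

Sequences are built segment-wise: membrane segments from a hydrophobic
pool, loops from a background pool that **contains neither C nor N**, so
every cysteine and sequon in the emitted sequence is planted and the
ground truth is exact rather than statistical. Engaged cysteines are
drawn per cysteine with probability p; an odd leftover becomes an
interchain bond (partner in another chain), which keeps the realised
pooled utilization unbiased at p — demoting the leftover instead would
systematically depress utilization in low-cysteine proteins. Intrachain
bonds pair sorted engaged positions adjacently (non-crossing, the
common case in real structures); a crossing "knot" mode pairs a random
perfect matching instead. All feature sites are placed on
OUTSIDE-labelled residues except injected conflicts, which are forced
onto INSIDE (or membrane) residues at per-kind rates; the emitted
ground truth records exactly which sites were mislocated, so conflict
detection can be scored with precision and recall of 1.0 as the target.
A single seeded random stream with a fixed, versioned draw order makes
every run byte-identical for the same config and seed.

What the generator does **not** emulate: realistic amino-acid
composition beyond coarse frequencies, cytosolic free cysteines (real
cytosols are cysteine-rich; here features are confined to the lumenal
side so injected conflicts are the only violations), isoforms, evidence
codes, beta-barrels, signal-anchor proteins, and correlated
evolution of features within families. Passing tests on this substrate
therefore demonstrate correctness of counting, parsing, rate and
conflict logic — not biological validity of any trend on real data.

The archetype generator for clustering tests draws rows directly in
matrix space from three planted profiles (TM-rich/PTM-poor,
glycan-dominant, disulfide-dominant) with Poisson jitter on counts;
recovery is scored as best-permutation label agreement.

## Problem sizes and numerics

Test and acceptance runs use 150–2,000-protein proteomes, 10,000 length
draws for the length-model check, 1,000 random sequences for the sequon
oracle, 50-point instances for the UPGMA oracle and 300-row archetype
matrices — sizes at which binomial/multinomial error bounds in the
tests are tight while the whole suite stays in the tens of seconds.
Pearson distances are clipped to [0, 2] against floating-point
overshoot. Rate tolerances in tests are derived from binomial standard
errors at the stated n, not tuned constants.

## Known limitations

* UniProt-release sensitivity: absolute proteome-level counts from real
  data (proteome sizes, Venn region sizes, conflict totals) drift with
  annotation releases; only a pinned release reproduces them exactly.
* The TMHMM2 emulation maps signal peptides to OUTSIDE (TMHMM 2.0 has
  no signal vocabulary) and emulates predictor disagreement only as
  whole-protein orientation flips.
* The visualizer JSON schema (`viz-v1`) is this package's own contract;
  renderers need only its stability, which is versioned.
* GO-term/functional enrichment of protein classes is out of scope
  (external services).
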