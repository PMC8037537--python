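# Methods

## Scope and model

The package models post-transcriptional regulation in an annotated
transcriptome as a three-layer ceRNA system: miRNAs bind miRNA response
elements (MREs) in mRNA 3'UTRs; pseudogenes, being high-identity transcribed
copies of parent genes, carry the same MREs and sequester miRNAs; pathway
membership connects regulated genes into networks.  Every stage is exercised
on synthetic data with planted ground truth, so all recovery claims are
exact; packaged transcriptions of published reference tables provide the
real-data fixtures.

Sequences are handled internally as RNA (ACGU, uppercase); DNA input is
mapped T→U on read.  All coordinates are 1-based, fully closed intervals.

## Synthetic-data generator

The generator emulates the input classes the analysis expects, not raw NGS
reads (no FASTQ, no expression, no isoforms):

* **mRNAs** — a random coding region (default 150–450 nt) followed by a 3'UTR
  (default 100–300 nt; 150–300 when all seven cis-elements are planted, so
  ~100 nt of planted blocks always fit).  Background sequence is i.i.d.
  uniform over ACGU unless a composition vector is configured — real UTRs are
  AU-biased and autocorrelated, so false-positive rates measured here do not
  transfer to real data; recovery (sensitivity) claims do.
* **planted MREs** — a perfect reverse complement of the planting miRNA's
  7-nt seed, preceded 5'-ward by a tail-complement block at 70% identity
  (exact mismatch counts, not Bernoulli draws, so the planted dissimilarity
  is deterministic: e.g. 4/14 ≈ 0.286 for a 22-nt mature).  The 5'-ward
  placement makes the mature:site duplex a single antiparallel co-linear
  helix, which is what the energy model scores.  Sites are planted
  round-robin over a shuffled miRNA order so coverage is balanced.  Each UTR
  is redrawn (blocks included) until an exhaustive rescan confirms every
  planted feature is recoverable exactly at its recorded coordinates — no
  accidental duplicate seed-complements, no earlier overlapping motif match.
* **miRNA precursors** — mature + loop (default 15 nt) + a
  reverse-complement arm with up to 3 mismatches; total length is required to
  fall in the 59–77 nt precursor band.
* **pseudogenes** — substitution-only mutated copies of randomly chosen
  parent mRNAs with identity drawn from 94–100%; the realized identity is
  exactly round(len·target)/len and is recorded in the truth table.

## Target prediction

1. **Seed clustering.**  Seeds (mature positions 2–8) are one-hot encoded
   (28 dimensions); a batch self-organizing map clusters them.  Defaults:
   square grid of side ⌈√(5√n)⌉, 100 epochs, Gaussian neighborhood with
   radius max(rows, cols)/2 decaying linearly (floor 0.5), learning rate
   0.5→0.01 linear.  Batch updates make training independent of input order;
   BMU ties break to the lowest row-major index.  Everything is deterministic
   given the RNG seed.
2. **Projection.**  Each 7-nt window of the searchable region (3'UTR for
   mRNAs — the MRE frame of reference — and the whole sequence for
   pseudogenes, which lack UTR annotation) is reverse-complemented, encoded
   and assigned a BMU; a window is a candidate for every seed sharing that
   BMU.  Cluster compatibility is shared BMU (the strictest reading); an
   exact seed complement always encodes identically to its seed, so the
   candidate stage provably never misses a perfect site.
3. **Tail dissimilarity.**  The tail (mature positions 9..end) is aligned,
   unit costs and at most `max_bulge` (default 4) gaps, against the reverse
   complement of the extension — the |tail|+max_bulge nt 5' of the site.
   d = cost/|tail|, clipped to [0,1]; candidates with d > τ (default 0.3)
   are dropped.  τ = 0.3 admits the planted 70%-complementary tails with a
   small margin while rejecting random tails (expected d ≈ 0.75).
4. **Free energy.**  ΔG = initiation (+4.09 kcal/mol) + nearest-neighbor
   stack energies over the best co-linear antiparallel pairing (Watson–Crick
   and GU wobble) + bulge penalties (+3.0 per event, +0.5 per unpaired nt
   beyond the first), minimized by an O(nm) dynamic program over the site
   plus extension context (one extra 3' nt covers mature position 1).  The
   stack table ships as an editable TSV of Turner-style 37 °C values with the
   weakly destabilizing wobble–wobble steps clamped to small negative values
   so every stack is ≤ 0; the table is completed by strand-flip symmetry at
   load.  Interactions with ΔG < −12 kcal/mol are retained, duplicates
   (same miRNA, same target) collapse to the lowest-ΔG site, and output is
   sorted by ΔG.

With these defaults the reference synthetic condition (20 miRNAs, 100 mRNAs,
one site per UTR) yields planted-site sensitivity of roughly 0.9–1.0 and
precision near 0.9 (the residual misses are AU-rich seeds whose duplexes are
genuinely weaker than −12 kcal/mol — a property of the energy model, not a
bookkeeping artifact).

## Alignment and E-values

Local alignment is Smith–Waterman (match +2, mismatch −3, linear gap −5) with
a deterministic tie-break (lowest subject start, then lowest query start).
E-values use the Karlin–Altschul form E = K·m·n·e^(−λS) with ungapped
nucleotide defaults λ = 0.625, K = 0.41 for this scoring; a Monte-Carlo test
confirms empirical exceedance probabilities track 1−e^(−E) within a factor of
3 for E ∈ [0.01, 10].  Precursor annotation accepts the best catalogue hit at
E < 10⁻⁵ (search space = total catalogue length) and additionally reports the
score-based gate E < 0.05 ∧ S > 100 as a labelled column; with +2 match
scoring a 22-nt mature caps S at 44, so that gate is informative only for
longer queries.

## Census and identity

Percent identity is computed from a global Needleman–Wunsch alignment
(match +1, mismatch −1, gap −2) as identities over all alignment columns,
gap columns included — the Blast-style "identities/alignment length"
convention, chosen to match how pseudogene/parent identities are usually
printed.  Local-alignment identities can differ slightly; the packaged
pseudogene table ships its published values verbatim rather than recomputing
them.

## Enrichment

One-sided (enrichment-only) testing throughout: p_fisher is the
hypergeometric upper tail P(X ≥ k); the EASE score recomputes the tail with
one study hit removed (defined as 1 for k ≤ 1), hence always dominates
p_fisher; Benjamini–Hochberg step-up q-values are computed across all emitted
terms (statsmodels' fdr_bh, cross-checked against an independent step-up
implementation).  Gates: p < 0.05 and q < 0.05 and EASE ≤ 0.1.  Under a
uniform null the realized type-I rate is well below 0.05 because the
hypergeometric is discrete at these term sizes.

## 3'UTR elements

Element classes are defined by an editable IUPAC pattern table; consensus
choices (ARE = AUUUA, CPE = UUUUWAU, MBE = RUAGU, GU-rich = UGUUUGUUUGU,
MOS-PRE and UNR heuristic cores) are documented in the table header.  GAIT is
structural, so its hit requires a flanking stem of ≥ 5 complementary base
pairs (GU allowed) within 30 nt of the loop match — a deliberate heuristic
stand-in for secondary-structure prediction.  Scans report all
non-overlapping leftmost matches per element; generator plantings use the
same table, so recovery tests are decoupled from the consensus choice and do
not validate the patterns against real element databases.

## Network

The ceRNA graph is a typed directed graph: targets (miRNA→gene, only genes in
≥ 1 supplied pathway), sequesters (miRNA→pseudogene, only for miRNAs that
target ≥ 1 pathway gene), member_of (gene→pathway).  A couple is a sequesters
edge whose miRNA also has ≥ 1 targets edge.  Exports (edge-list TSV and
GraphML) write a canonically sorted copy, making export→import→export
byte-stable.  Pathway-internal protein–protein edges are out of scope: only
the RNA layer and pathway membership are modeled.

## Problem sizes and determinism

Default test and acceptance problem sizes — 100 mRNAs × 20 miRNAs for
prediction, 100 UTRs × 7 elements for scanning, 1000 replicates × 25 terms
for the null calibration, 10,000 random 70-mer pairs for the E-value check —
were chosen so the whole suite completes in well under a minute while keeping
Monte-Carlo errors small.  All randomness flows through explicit
`numpy.random.default_rng` seeds; pipeline runs record config, seeds, record
counts and sha256 digests in a manifest, and repeated fixed-seed runs are
byte-identical.

## Known limitations

* Uniform background sequence understates real-UTR false-positive rates.
* The energy model is a single-duplex nearest-neighbor approximation: no
  partition function, no target-site accessibility, no conservation.
* GAIT detection is a stem heuristic, not structure prediction.
* The fixture interaction table carries no energies or coordinates, so
  network fixtures exercise topology only.
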