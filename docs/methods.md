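# Methods

`endkit` identifies discrete RNA 5′-end features — capped transcription
start sites and noncapped processed 5′ ends — from paired 5′-end (5P) and
gene-body (BODY) sequencing libraries, and detects small-RNA-guided cleavage
sites on transcripts with an empirical-null statistic. This note documents
the models, the parameters that matter, the numerical choices, and what the
synthetic-data tests do and do not demonstrate.

## Signal model

A 5P library (template-switching 5′ capture) marks the 5′
terminus of each captured cDNA; a BODY library (non-stranded Smart-seq2 from
the same sample) samples fragments across the whole transcript. Both are
reduced to per-position weighted 5′-end count tracks (`EndSignalTrack`),
0-based half-open coordinates, one sparse map per chromosome and strand.
BODY signal is stored strandless and contributes to both strands wherever a
stranded consumer needs it.

### Read reduction (endmap)

* The 5′-most aligned base in read orientation defines the position
  (alignment end for reverse-strand alignments). Soft-clipped 5′
  nucleotides are retained in cDNA sense as upstream untemplated nucleotides
  (uuN); an untemplated G immediately adjacent to the genome match (uuG) is
  the signature of reverse transcription across the m7G cap. Only that one
  adjacent base decides the uuG call; extra clipped bases further upstream
  are treated as template-switch-oligo remnants and ignored.
* **Complexity filter.** Reads with per-nucleotide substring-growth
  complexity below 0.15 are removed. We score a read as
  `sum_i log4(d_i) / n`, where `d_i` is the number of distinct substrings
  ending at position `i` that have not occurred ending earlier
  (a longest-previous-factor computation). Homopolymers score exactly 0;
  uniform random 50-mers score ≈ 2 and are essentially never removed
  (≥ 99% kept over thousands of draws). Bit-exact parity with other
  implementations of the underlying complexity measure is not claimed; the
  documented contract is what the tests pin down.
* **Multiplicity.** The number of best-score alignments present in the file
  for a read name (matching an upstream aligner reporting all best-score
  hits as primary), with an optional tag override (e.g. `NH`).
* **Rich-get-richer rescue.** Unique reads seed a coverage map. Multimapped
  reads are processed in multiplicity bins 2..100; within a bin reads are
  sorted from lowest genomic position to highest (chromosome order, minimum
  candidate position, then read id so repeated runs are bit-identical). A
  read with any covered candidate location is assigned proportionally,
  `P_i = C_i / Σ_j C_j`, updating coverage immediately; the bin is re-swept
  until a pass assigns nothing, and remaining reads get `P_i = 1/n`.
  Termination is guaranteed because assignment is monotone. Reads mapping
  to more than 100 loci are discarded. The implementation is checked
  against an independent literal replay of this loop on hundreds of random
  instances to 1e-9.
* **k-mer bias model (optional, off by default).** Observed k-mer
  frequencies at exonic read 5′ ends — with per-position depth clipped to 1,
  since RNA coverage is not expected to be uniform — are compared with the
  background frequency over all exonic positions; a read's weight is
  background/observed for its context. Defaults: k = 6 spanning offsets
  −3..+2 around the 5′ end, weights clipped to [0.1, 10] to prevent
  unbounded reweighting. The clip bounds, k, and window are package
  choices; the statistical pipeline is testable with the correction off.

### Feature calling (endgraph)

Positions whose upstream genomic 4-mer (cDNA sense) matches the last four
bases of the template-switching oligo with ≤ 1 mismatch are masked first:
such 5′ ends are explainable by strand invasion rather than biology.

The 5P and BODY tracks are placed on a common scale with

    S = (2 · F · 10^6 / Σ_i TPM_i · L_i) · (R_B / R_E)

where `F` is the mean BODY fragment length (nt), `TPM_i` and `L_i` are the
abundance and spliced length of transcript *i*, and `R_B`, `R_E` are total
mapped BODY and 5P reads. `S` estimates the expected ratio of
5′-end-containing to body fragments under the assumption that all RNA is
full length. TPM is estimated internally from BODY exonic coverage (reads
per exonic base, normalized to one million); `F` comes from configuration
(default 500 nt, the tagmentation regime) since insert sizes are not always
available.

A Laplace kernel of bandwidth `b` = 15 nt is evaluated over the signed
weights `S·ER − BR` at every integer position. The kernel is truncated at
4b = 60 nt, where the tail is below e⁻⁴ of the peak: the untruncated
Laplace has infinite support, which would make "continuous positive
density" ill-defined. Density is computed by direct discrete convolution
over a dense window spanning all data points plus the truncation radius; it
is exactly zero elsewhere by construction, and matches a brute-force
kernel-sum oracle to 1e-9. Maximal runs of strictly positive density become
features (no minimum width). BODY mass subtracts from both strands because
the body library is non-stranded.

### Replicate merging and cap classification (endclass)

Merging is positional: a genomic position is retained when covered by
features from ≥ 2 distinct replicates on the same strand, and maximal
retained runs become merged features. (Whole-feature any-overlap clustering
is the alternative reading; positional support is the least ambiguous and
the one implemented.) Counts are re-aggregated over merged intervals from
the pooled, pre-masking tracks of all replicates.

A merged feature is **capped** when the pooled uuG fraction is ≥ 0.10 — the
boundary is inclusive, and the fraction is the ratio of sums across
replicates, never the mean of per-replicate ratios. Features without reads
are `unclassified`.

### Transcript projection and cap masking (endmask)

Each gene is represented by its dominant isoform — the isoform with the
most BODY read mass in its exons (BODY, not 5P, because body coverage
measures abundance while 5P concentrates at termini); ties break to the
longer isoform, then lexicographic id. 5P signal inside replicable capped
features is discarded (those are start sites, not cleavage products), the
remainder is projected to spliced offsets from the isoform's 5′ start, and
intronic/intergenic signal is dropped. Only sense-strand signal is kept.
Mass bookkeeping (projected + masked + off-transcript = input) holds to
1e-9. The per-gene cleaved proportion is `cleaved / (cleaved + capped)`,
undefined when both are zero.

## Cleavage-site statistic (endcut)

Plant miRNAs/tasiRNAs cleave their targets between the target bases paired
to sRNA positions 10 and 11, so the 5′ end of the 3′ fragment sits opposite
sRNA position 10; that position is the predicted cleavage coordinate.

**Site enumeration.** Each transcript is scanned for antisense duplexes
allowing Watson–Crick pairs, G:U wobbles, mismatches, and a single
one-nucleotide bulge on either strand, scored with the position-weighted
penalty scheme of Allen et al.: mismatch 1.0, G:U 0.5, bulge 1.0, doubled
at sRNA positions 2–13. For each duplex start the best-scoring alignment
shape is kept, then the best alignment per cleavage position; sites with
score ≤ 10 (configurable) are candidates. This windowed alignment replaces
the thermodynamic predictor used historically: the downstream statistic
consumes only Allen scores and coordinates. The scan kernel is compiled
with numba and is verified against an exhaustive per-offset enumeration.

**Local enrichment.** `FC = (reads at site + 1) / (max reads in the
flanking ±20 or ±50 nt + 1)`, computed on the cap-masked transcript track;
positions within 1 nt of the site are excluded from the flank so sRNA
isoforms with slightly offset sites are not penalized; windows clip at
transcript bounds. Both windows are reported; the 50-nt window gates
significance by default (the choice between windows is not fixed by the
method's definition; both numbers are emitted so either gate can be
applied).

**Empirical null.** Each sRNA is shuffled 1000 times
(composition-preserving, seeded); every shuffle is processed identically —
same scan, same track, same fold changes. The pooled null fold changes and
Allen scores give one-sided add-one-corrected p-values:

    p_fc = (1 + #{null FC ≥ observed}) / (1 + N)
    p_as = (1 + #{null score ≤ observed}) / (1 + N)

The add-one correction keeps p > 0 (Fisher's method needs finite logs) and
makes the p-values conservative. The two are combined with Fisher's method
(χ², 4 df) and adjusted by Benjamini–Hochberg across **all** sites tested
in the library (all sRNAs pooled — no per-sRNA grouping). A site is
significant when adjusted p < 0.05, FC > 1.0, and it is supported by at
least one read per ten million transcriptome-mapping reads (RPTM ≥ 1).

Because the observed sRNA genuinely complements its targets while shuffles
do not, `p_as` is small at any well-paired site even without signal; the
FC > 1 and RPTM gates are what prevent signal-free sites from being called.
All statistics are invariant to transcript order and shuffle order.

## Synthetic data (simulate)

The generator emulates the paired-library data model with known truth:

* capped 5P reads pile at each gene's TSS with Gaussian jitter (sd 2 nt)
  and uuG at rate 0.15, the rate seen in real template-switching libraries;
* noncapped degradation 5′ ends are spread along transcripts with linearly
  increasing density toward the 3′ end (`offset = L·√U`), uuG rate 0.02;
* planted cleavage products start exactly at the duplex position-10/11
  scissile bond of a target motif embedded in the transcript sequence
  (optionally corrupted with core mutations to degrade its Allen score);
* BODY fragments tile transcripts uniformly, non-stranded;
* `xrn1_mode` emulates in-vitro 5′→3′ exonuclease treatment by removing
  90% (configurable) of noncapped-label reads from an independent random
  stream, so the surviving capped reads are identical read-for-read to the
  untreated library at the same seed.

Default study conditions: 200 genes on 2 chromosomes, 1–2 kb genes (25%
two-exon), log-normal expression, 200 k 5P + 200 k BODY reads per
replicate, 3 replicates, read length 50 nt. The cleavage-statistic studies
use 20 random 21-nt sRNAs × 1000 shuffles against 20 genes of ~1 kb, with
four embedded target motifs per sRNA at fixed non-overlapping slots
(offsets 150/320/490/660) so no motif sits inside another's flanking
window; the null design corrupts motifs with 1–3 core mutations and plants
no cleavage reads, the power design embeds perfect complements receiving 5%
of the gene's 5P reads.

What the simulation does **not** model: sequencing errors, PCR duplicates,
junction-spanning reads (reads truncate at exon boundaries), realistic
promoter architecture, isoform diversity (one transcript per gene in
generated annotations), and genomic repeats (multimapping is exercised by
dedicated fixtures instead). Passing the closed-loop tests therefore shows
the pipeline recovers what it models, not that real-library artifact rates
are reproduced.

## Numerical choices and degenerate inputs

* All coordinates 0-based half-open; minus-strand transcript offsets run
  5′→3′ along the RNA.
* KDE grid = integer genomic positions; truncation radius ≥ 4 bandwidths
  enforced by validation.
* Rescue ties broken by (chromosome order, minimum candidate position,
  read id); repeated runs are bit-identical.
* Dominant-isoform ties: longer isoform, then lexicographic id.
* Empty tracks, empty features, zero-read features, and empty call tables
  all return well-defined empty results; zero denominators (scaling factor,
  RPTM, empirical null) raise errors rather than silently producing NaN.
* bedGraph values are written with shortest round-trip float formatting, so
  write→read is exact; runs of equal values are merged.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; per-sRNA shuffle seeds are derived
  deterministically from the master seed.

## Problem sizes used in tests

Oracle equivalence runs 200 random rescue instances (≤ 20 reads, ≤ 5 loci)
and 50 random 10-kb KDE tracks; the closed-loop study uses the default
200-gene, 3-replicate, 200 k + 200 k-read conditions; the cleavage-site
calibration uses three independent null simulations (seeds 1–3) and one
power simulation at the conditions above. These sizes keep the full suite
in the minutes range on a single CPU while leaving every stage's statistics
well above the thresholds they are tested against.
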