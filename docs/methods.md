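# Methods

## The pipeline model

The package treats srRNA discovery as a two-pass selection problem. Reads
are first quality-trimmed and aligned end-to-end against the rDNA repeat
unit; only reads with an rDNA alignment are retained (this *defines* the
srRNA class operationally), deduplicated, and aligned against a genome that
does not contain the rDNA array itself. Wherever such reads land, a diverged
fragment of the rDNA unit must exist; the genes overlapping those landing
sites are the srRNA target genes. Validation rests on two constructed nulls:
a *permutation null* (shuffling each read internally destroys contiguous
homology while conserving composition, so the whole mapping signal should
collapse) and *Monte-Carlo calibration* of the Mann–Whitney U-test used for
expression comparisons (its empirical type-I error on expression-shaped data
should match the nominal α).

## Read trimming

`trim_read` applies LEADING → TRAILING → SLIDINGWINDOW → MINLEN with
defaults 18 / 18 / (4, 22) / 20. The sliding window scans 5'→3' over full
4-base windows; at the first window whose mean quality falls below 22 the
read is cut at the window start, and trailing bases below 22 are then
stripped so the kept part ends on a confident base. This back-trim matches
the de-facto behaviour of the standard trimmer these option strings come
from, and it is what makes trimming idempotent: without it a cut read could
end on a base below the TRAILING threshold and a second pass would shorten
it again. A read shorter than one window is kept only if its mean quality
reaches the window threshold. Deduplication strips bases below Q18 from both
ends and collapses byte-identical sequences, keeping the first occurrence as
representative; the copy counts are carried through the genome pass so the
mapping table still counts every original read.

## Alignment

The aligner is deliberately simple and fully auditable: gapless, end-to-end,
strand-aware, with a configurable mismatch cap. Candidate placements come
from exact 12-mer seeds taken at *every* read offset on both strands; each
candidate is verified by Hamming distance, N mismatching everything. Ties
are broken deterministically (fewest mismatches, then lowest target name and
start, + before −) and the number of equally-best loci is reported as
`multiplicity`. With all offsets seeded, a placement with m mismatches is
guaranteed to be found when the read length L satisfies L ≥ (m+1)·k − m
(k = 12: L ≥ 23 for one mismatch, L ≥ 34 for two). Shorter reads carrying
that many errors can in principle be missed when the errors split every
clean window; this is the aligner's one documented deviation from an
exhaustive scan, and the oracle-equivalence test is therefore run inside the
guaranteed regime. Defaults use a cap of 2 mismatches for the rDNA pass and
1 for the genome pass — the rDNA pass is the sensitive, class-defining step,
while the stricter genome pass mirrors the protocol's use of a more
sensitive preset for rDNA than for the genome and keeps spurious genome hits
of the shortest reads negligible.

## Mapping table and target genes

One record is emitted per distinct (chrom, start, end, strand, aligned
sequence); `read_count` sums the underlying original reads (via dedup copy
counts), `unique_count` counts distinct pre-trim sequences collapsing onto
the record, and `mean_depth` equals `read_count` — for identical end-to-end
placements the per-base depth of the record is exactly its read count, and
this interpretation of the per-mapping "coverage" column is recorded here as
a package choice. Regions are maximal runs of overlapping or bookended
(gap = 0) mappings, strand-agnostic. Gene assignment is ≥1 bp interval
overlap, also strand-agnostic: a sense srRNA legitimately targets a fragment
embedded antisense in an intron. The 13 rDNA-family gene identifiers are
removed from target lists before expression analysis by exact name match.

## Metaprofiles and chromatin states

Signal metaprofiles average a step-function track in 10-bp bins across
±1.5 kb windows (300 bins) centred on mapping midpoints (floor of the
interval midpoint). Signal within a bin is length-weighted by step overlap;
windows clipped at chromosome ends contribute only their covered length to
the per-bin denominators. Z-scoring is over the 300 bins; a zero-variance
profile z-scores to all zeros rather than raising, since constant tracks are
legitimate inputs. The profile is linear in the track before z-scoring and
invariant to positive affine track transforms after it.

Chromatin-state composition counts base pairs of (merged) target intervals
per state against the whole-genome state base-pair fractions; untiled bases
fall into an explicit `Unannotated` bucket, so both fraction columns sum
to 1. Base-pair weighting (rather than per-mapping weighting) is the
package's reading of the state-composition comparison. Significance per
state uses a Welch (unequal-variances) two-sample t-test whose replicates
are per-chromosome fractions — the only replication unit available without
biological replicates; this is an interpretation, recorded as such. Both
groups use the chromosomes that carry targets, and the degenerate case
(zero variance in both groups, equal means) returns t = 0, p = 1. No
multiplicity correction is applied to the per-state p-values.

## TSS classification

Within each gene, TSSs with CAGE expression strictly below 1% of the gene's
strongest TSS are filtered. Among survivors, a pair is bidirectional iff the
two TSSs are on opposite strands, less than 1000 bp apart, and divergently
oriented — the minus-strand TSS at or upstream of the plus-strand TSS, so
the transcripts run apart. "Transcription must not intersect" is implemented
as exactly this divergence requirement: a convergent or tandem pair within
1 kb would place one TSS inside the other's transcript. All other survivors
are unidirectional; the three classes partition the table.

## Resampling statistics

* **Within-read shuffling** is Durstenfeld's Fisher–Yates over (base,
  quality) pairs, conserving the multiset exactly and the read id; every
  permutation trial then reruns trimming, rDNA selection, deduplication and
  genome mapping with the same configuration as the observed run, and
  reports mapped reads/regions, region intersections with the observed run,
  interval Jaccard, overlapping target genes with a hypergeometric p-value,
  and a rank-correlation z/p between binned observed and permuted coverage.
* The **correlation test** between observed and permuted mappings is
  Spearman rank correlation on genome-wide binned coverage (10-kb bins by
  default) with a Fisher-transform z; constant coverage vectors return
  (0, 1). This preserves the contract of the external correlation tool used
  in the original protocol — a z and p near the null under permutation —
  without reproducing that tool's unspecified internals.
* **Hypergeometric overlap**: `P(X > q)` via the scipy survival function
  (log-space stable); an exact combinatorial enumeration backs it in tests
  for universes ≤ 30.
* **Mann–Whitney U** uses midranks; p-values come from exact enumeration of
  all labelings for tie-free samples with n1+n2 ≤ 12, otherwise from the
  normal approximation with tie-corrected variance and a 0.5 continuity
  correction. Zero variance (all values tied) returns p = 1.
* **Calibrations**: the equal-subsets design shuffles the expression vector
  each repetition and takes the first two disjoint 1,575-value blocks — the
  disjointness the protocol implies is enforced by construction; the
  full-vs-subset design tests a drawn subset against the entire vector
  including it (the induced dependence makes the test slightly
  conservative, visible as rejection fractions just under α). "FDR" in this
  context is the empirical type-I error rate — the fraction of rejections
  under a true null. The subset-vs-random comparison reports the maximum
  p over repetitions and the rejection fraction at the chosen α. The
  averaged random subset (sorted subsets accumulated element-wise over
  trials) is a display dataset only.

## The synthetic study

Defaults are a 1/10-scale system chosen once: a 4,300-bp rDNA unit with the
human unit's segment proportions (the IGS absorbing rounding); three 250-kb
chromosomes carrying 56 non-overlapping genes with exon/intron structure, a
quarter of them placed as head-to-head divergent pairs (gap 100–800 bp) so
genuine bidirectional promoters exist; 50,000 reads sampled from 12 rDNA
hotspots (ten in the transcribed portion — the strongest at the 5' region of
28S, a prominent 5.8S peak, two 18S peaks — plus two small IGS hotspots),
with lengths from a discretized two-component truncated-normal mixture on
[19, 50] whose narrow component produces the twin peaks at 25/26 nt and
whose broad component location is solved by bisection so the mixture mean is
exactly 29 nt; strand is sense with probability 0.995. Qualities sit on a
Q38–40 plateau with occasional (10%) low-quality 1–3-base read ends so
trimming is actually exercised. Planted fragments copy hotspot source
intervals (hotspot ± 55 bp, covering any read start inside the hotspot) into
introns and intergenic slots at 96.32% identity — substitutions only, no
indels, matching the gapless aligner downstream — reverse-complemented with
probability 0.3. Decoy fragments come from rDNA intervals kept ≥ 115 bp
clear of every hotspot, so no simulated read can even partially overlap
their source: they are homology without signal, and recovering their host
genes would be a precision failure. Expression tables are zero-inflated
log-normal (40% exact zeros, log-normal(μ=1, σ=2) otherwise) — heavy-tailed
and far from normal, which is the entire reason the U-test needs
calibrating. State segmentations tile chromosomes with ~exponential segment
lengths under a quiescent-heavy 15-state weight vector; signal tracks are
50-bp step functions with unit-mean gamma noise plus an additive uplift
inside enriched regions (so zero enrichment is exactly flat in expectation).

What the generator does **not** emulate: hairpin secondary structure or
Microprocessor cleavage biochemistry, raw RNA-seq or chromosome-conformation
reads, sequencing indels or adapter contamination, repeat families other
than the planted rDNA fragments, and any realistic generative process for
antisense IGS srRNAs (IGS hotspots are exposed but their realism is
unconstrained). Passing tests therefore demonstrate the correctness and
calibration of the *computational* pipeline under its stated model, not the
biological completeness of that model on real libraries.

## Numerical and scale choices

Interval arithmetic is 0-based half-open everywhere inside the package;
GFF3 is converted at the I/O boundary. All generators and resampling
routines take an explicit seed or numpy Generator; the orchestrator derives
per-stage seeds from the master seed through a fixed SeedSequence spawn, so
identical (config, seed) gives bit-identical scientific outputs while stages
remain independently re-runnable. The acceptance script runs the U-test
calibrations at the protocol scale (60,522 values, 1,575-value subsets,
10,000 repetitions, α = 0.05); 10,000 repetitions puts the three-sigma
Monte-Carlo band at ±0.0065 around the measured rejection fraction, which is
tight enough to detect a miscalibrated tie or continuity correction while
completing in minutes on one CPU. End-to-end tests run the default study
(50,000 reads) once and reuse it; permutation-collapse checks run ten trials
on it, mirroring the protocol's trial count.

## Known limitations

* The aligner's sensitivity guarantee does not cover the shortest reads
  carrying the maximum mismatch count (see above); presets of production
  aligners are approximated by per-pass mismatch caps, not reproduced.
* Welch-test replicates are per-chromosome fractions; with few chromosomes
  the test is low-powered and its p-values should be read qualitatively.
* `unique_count` distinguishes pre-trim sequence variants only when raw
  sequences are supplied; after exact deduplication most records carry
  unique_count = 1 by construction.
* The permutation trial reruns the pipeline with the same thresholds as the
  observed run but draws fresh shuffles per trial; trials are not variance-
  reduced and ten trials give only an order-of-magnitude picture, which is
  all the collapse claim needs.
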