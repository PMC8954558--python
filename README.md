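# srrna-scout

Discovery and statistical validation of **small rDNA-derived RNAs (srRNAs)**
and their genomic targets.

srRNAs are 19–50 nt small RNAs whose sequences match the ribosomal DNA repeat
unit (5'ETS–18S–ITS1–5.8S–ITS2–28S–3'ETS followed by the intergenic spacer).
Diverged, rearranged fragments of the rDNA unit are scattered through the
genome — mostly inside introns and intergenic space — and srRNAs mark the
genes hosting such fragments ("srRNA target genes"). This package implements
the full computational pipeline for finding and validating those targets,
exercisable end-to-end on synthetic data with planted ground truth:

* **read QC** — quality trimming (LEADING:18 / TRAILING:18 /
  SLIDINGWINDOW:4:22 / MINLEN:20) and exact deduplication after low-quality
  end-stripping;
* **two-pass alignment** — a gapless, mismatch-tolerant, strand-aware
  seed-and-check aligner; reads are selected by alignment to the rDNA unit
  and only those reads proceed to the genome pass;
* **target construction** — a mapping table (one record per distinct locus /
  strand / sequence), interval-merged regions, and strand-agnostic
  intersection with the gene annotation;
* **epigenomic context** — z-scored signal metaprofiles in 10-bp bins ±1.5 kb
  around mapping midpoints, 15-state chromatin-state composition of targets
  vs genome with per-chromosome Welch t-tests, and TSS classification into
  bidirectional (divergent, <1 kb, opposite strands) and unidirectional
  promoters after a 1% minor-TSS filter;
* **validation statistics** — a permutation null built by Fisher–Yates
  shuffling each read's (base, quality) pairs and rerunning the whole
  pipeline; interval Jaccard; hypergeometric gene-set overlap
  (`P(X > q)` for `X ~ Hypergeom(N, m, k)`, the R `phyper(..., lower.tail =
  FALSE)`); and a Mann–Whitney U-test (midranks, tie-corrected normal
  approximation with continuity correction, exact enumeration for small
  tie-free samples) with Monte-Carlo calibration of its type-I error on
  zero-inflated expression data;
* **synthetic data** — generators for every input: an rDNA unit with a
  realistic segment layout, a genome with planted diverged (~96% identity,
  optionally inverted) rDNA fragments, hotspot-sampled reads (mean 29 nt,
  twin peaks at 25/26 nt, 99.5% sense), zero-inflated log-normal expression,
  chromatin-state segmentations, step-function signal tracks, and CAGE-style
  TSS tables — all pure functions of (config, seed), with truth records.

## Worked example

```python
from srrna_scout.config import validate_config
from srrna_scout.orchestrate import run_all

cfg = validate_config(None)          # protocol defaults
cfg.outdir = "demo_run"
cfg.seed = 1
manifest = run_all(cfg)
print(manifest.counts["qc"])
print(manifest.counts["genome_pass"])
print(manifest.counts["targets"])
print(manifest.counts["validation"]["permuted_mapped_reads"])
```

On the default synthetic study (50,000 reads, three 250-kb chromosomes,
56 genes, fragments planted at 96.32% identity) this prints:

```
{'input': 50000, 'kept': 49250, 'rejected': 750}
{'unique_reads': 18474, 'aligned_unique_reads': 17468, 'mapped_reads': 47724, 'mapping_records': 17468}
{'regions': 50, 'target_genes': 21, 'contacting_overlap': 7, 'target_only': 14, 'contacting_only': 20}
[0, 0, 0, 0, 0, 0, 0, 0, 0, 0]
```

Reading it: 49,250 of 50,000 reads survive trimming; 47,724 of them map to
planted rDNA fragments in the genome across 17,468 distinct mapping records
in 50 merged regions, recovering 21 target genes — exactly the genes whose
introns host a fragment copied from a read hotspot (this run recovers the
planted truth in full). The last line is the permutation null: after
within-read shuffling, *zero* reads map in all ten trials, against 47,724
observed — the mapping signal collapses completely when contiguous homology
is destroyed, so it cannot be a base-composition artifact.

The same stages are available as a CLI:

```bash
srrna-scout simulate --outdir sim --seed 1
srrna-scout qc --in sim/reads.fastq --out trimmed.fastq --dedup unique.fastq
srrna-scout align --ref sim/rdna.fa --reads trimmed.fastq --max-mm 2 --out aln.tsv
srrna-scout run --outdir demo_run --seed 1
srrna-scout calibrate --mode equal --reps 10000 --seed 1
```

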