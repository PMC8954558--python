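"""The two-pass srRNA selection pipeline.

Reads are first aligned to the rDNA unit; only rDNA-matching reads proceed to
the genome pass.  Genome alignments are grouped into a mapping table (one
record per distinct locus/strand/sequence), merged into regions, and
intersected with the gene annotation to yield srRNA target genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree

from srrna_scout.align import Alignment, ReferenceIndex, align_read
from srrna_scout.core import GeneInterval, RdnaReference, SmallRead

# The 13 gene identifiers of the rDNA gene family excluded from the
# expression analysis of target genes.
RDNA_FAMILY_GENES = (
    "RNA5-8SN1", "RNA5-8SN3", "RNA5-8SN2",
    "FP671120.4", "FP671120.2",
    "FP236383.3", "FP236383.1", "FP236383.2",
    "RNA5-8SP6", "FP671120.1", "RF00002", "RNA5-8SP2", "AC010970.1",
)


@dataclass(frozen=True)
class MappingRecord:
    """One srRNA target locus: a distinct (chrom, span, strand, sequence)."""

    chrom: str
    start: int
    end: int
    strand: str
    read_count: int
    unique_count: int
    mean_depth: float
    sequence: str

    def __post_init__(self) -> None:
        if not self.read_count >= self.unique_count >= 1:
            raise ValueError("read_count >= unique_count >= 1 required")
        if self.end <= self.start:
            raise ValueError("end must exceed start")


@dataclass
class CoverageProfile:
    """Per-position read depth over a reference, split by strand."""

    target_len: int
    sense_depth: np.ndarray
    antisense_depth: np.ndarray


@dataclass
class TargetGene:
    gene: GeneInterval
    mappings: list[MappingRecord]
    n_srRNAs: int


def select_rdna_reads(
    trimmed_reads: list[SmallRead],
    rdna_index: ReferenceIndex,
    max_mismatch: int = 2,
) -> tuple[list[SmallRead], list[Alignment]]:
    """Keep exactly the reads that align to the rDNA unit.

    Returns the selected reads (in input order, in their trimmed form as
    aligned) and their rDNA alignments, index-parallel.
    """
    selected, alignments = [], []
    for read in trimmed_reads:
        aln = align_read(read, rdna_index, max_mismatch)
        if aln is not None:
            selected.append(read)
            alignments.append(aln)
    return selected, alignments


def rdna_coverage_profile(
    alignments: list[Alignment], rdna: RdnaReference
) -> CoverageProfile:
    """Per-base alignment depth along the rDNA unit, by strand.

    The conservation invariant holds exactly: the sum of each depth vector
    equals the summed lengths of the alignments on that strand.
    """
    n = len(rdna)
    sense = np.zeros(n + 1, dtype=np.int64)
    anti = np.zeros(n + 1, dtype=np.int64)
    for aln in alignments:
        if aln.start < 0 or aln.end > n:
            raise ValueError(
                f"alignment [{aln.start}, {aln.end}) outside the {n}-bp reference"
            )
        vec = sense if aln.strand == "+" else anti
        vec[aln.start] += 1
        vec[aln.end] -= 1
    return CoverageProfile(
        target_len=n,
        sense_depth=np.cumsum(sense[:-1]),
        antisense_depth=np.cumsum(anti[:-1]),
    )


def strand_fraction(alignments: list[Alignment]) -> float:
    """Fraction of alignments on the sense (+) strand."""
    if not alignments:
        raise ValueError("strand_fraction of an empty alignment set is undefined")
    return sum(1 for a in alignments if a.strand == "+") / len(alignments)


def build_mapping_table(
    genome_alignments: list[Alignment],
    raw_sequences: dict[str, str] | None = None,
    copy_counts: dict[str, int] | None = None,
) -> list[MappingRecord]:
    """Group genome alignments into one record per distinct placement.

    The grouping key is (chrom, start, end, strand, aligned sequence).
    ``read_count`` counts all underlying reads (each alignment contributes
    its copy count, default 1 — pass ``copy_counts`` when aligning the
    deduplicated dataset).  ``unique_count`` counts distinct pre-trimming
    sequences collapsing onto the record, looked up in ``raw_sequences``
    (read_id -> original sequence); without it each alignment counts as one
    distinct sequence.  ``mean_depth`` is the depth of the identical
    placements, i.e. read_count.
    """
    groups: dict[tuple, list[Alignment]] = {}
    for aln in genome_alignments:
        key = (aln.target_name, aln.start, aln.end, aln.strand, aln.sequence.upper())
        groups.setdefault(key, []).append(aln)
    records = []
    for (chrom, start, end, strand, seq), alns in sorted(groups.items()):
        read_count = sum(
            (copy_counts or {}).get(a.read_id, 1) for a in alns
        )
        if raw_sequences is not None:
            unique_count = len({raw_sequences.get(a.read_id, a.sequence) for a in alns})
        else:
            unique_count = len(alns)
        records.append(
            MappingRecord(
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                read_count=read_count,
                unique_count=unique_count,
                mean_depth=float(read_count),
                sequence=seq,
            )
        )
    return records


def merge_regions(
    records: list[MappingRecord] | list[tuple[str, int, int]], gap: int = 0
) -> list[tuple[str, int, int]]:
    """Merge overlapping or near-bookended mappings into regions.

    Strand-agnostic: intervals at most ``gap`` bp apart fuse (gap=0 merges
    bookended intervals).  Accepts MappingRecords or (chrom, start, end).
    """
    ivs = sorted(
        (r.chrom, r.start, r.end) if isinstance(r, MappingRecord) else tuple(r)
        for r in records
    )
    merged: list[list] = []
    for chrom, s, e in ivs:
        if merged and merged[-1][0] == chrom and s - merged[-1][2] <= gap:
            merged[-1][2] = max(merged[-1][2], e)
        else:
            merged.append([chrom, s, e])
    return [(c, s, e) for c, s, e in merged]


def assign_target_genes(
    records: list[MappingRecord], genes: list[GeneInterval]
) -> list[TargetGene]:
    """Assign each mapping to every gene it overlaps by >= 1 bp.

    Strand is ignored — an srRNA can target a fragment embedded antisense in
    an intron.  Genes with at least one overlapping record become targets.
    """
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        trees.setdefault(gene.chrom, IntervalTree()).addi(gene.start, gene.end, gene)
    hits: dict[str, list[MappingRecord]] = {}
    gene_by_id: dict[str, GeneInterval] = {}
    for rec in records:
        tree = trees.get(rec.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(rec.start, rec.end):
            gene = iv.data
            gene_by_id[gene.gene_id] = gene
            hits.setdefault(gene.gene_id, []).append(rec)
    targets = []
    for gene_id in sorted(hits):
        mappings = hits[gene_id]
        targets.append(
            TargetGene(
                gene=gene_by_id[gene_id],
                mappings=mappings,
                n_srRNAs=sum(m.read_count for m in mappings),
            )
        )
    return targets


def overlap_gene_lists(
    list_a: list[str], list_b: list[str]
) -> tuple[set[str], set[str], set[str]]:
    """Set algebra on gene-id lists: (intersection, a_only, b_only)."""
    a, b = set(list_a), set(list_b)
    return a & b, a - b, b - a


def exclude_rdna_family(gene_list: list[str]) -> list[str]:
    """Drop the 13 rDNA-family gene identifiers (exact name match)."""
    family = set(RDNA_FAMILY_GENES)
    return [g for g in gene_list if g not in family]
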