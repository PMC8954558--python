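"""Gapless, mismatch-tolerant, strand-aware end-to-end short-read alignment.

A seed-and-check scheme: every overlapping k-mer of the read (and of its
reverse complement) is looked up in an exact k-mer table of the reference;
each seed hit proposes a candidate end-to-end placement, whose Hamming
distance is then computed.  Checking *all* read k-mers before declaring a
read unaligned guarantees full sensitivity for up to ``floor((L - k)/k)``
mismatches (so two mismatches whenever the read length L >= 3k - 2); for the
shortest srRNA-length reads carrying two errors sensitivity is high but not
guaranteed — a documented limitation of the seed scheme.

N bases mismatch everything, including other Ns.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from srrna_scout.core import SmallRead, reverse_complement


@dataclass(frozen=True)
class Alignment:
    """An end-to-end gapless placement of a read on a reference target."""

    read_id: str
    target_name: str
    start: int
    end: int
    strand: str  # "+" | "-"
    mismatches: int
    multiplicity: int  # number of equally-best loci
    sequence: str  # the read sequence as given (not reference-oriented)


@dataclass
class ReferenceIndex:
    sequences: dict[str, str]
    k: int
    seeds: dict[str, list[tuple[str, int]]]


def build_index(sequences: dict[str, str], k: int = 12) -> ReferenceIndex:
    """Exact k-mer position table over the given reference sequences."""
    if not sequences:
        raise ValueError("reference must contain at least one sequence")
    if k < 8:
        raise ValueError("seed length k must be >= 8")
    shortest = min(len(s) for s in sequences.values())
    if k > shortest:
        raise ValueError(f"k={k} exceeds the shortest reference sequence ({shortest} bp)")
    seeds: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for name, seq in sequences.items():
        seq = seq.upper()
        for pos in range(len(seq) - k + 1):
            kmer = seq[pos : pos + k]
            if "N" not in kmer:
                seeds[kmer].append((name, pos))
    return ReferenceIndex(
        sequences={n: s.upper() for n, s in sequences.items()}, k=k, seeds=dict(seeds)
    )


def lookup_kmer(index: ReferenceIndex, kmer: str) -> list[tuple[str, int]]:
    """All (target, position) occurrences of an exact k-mer."""
    if len(kmer) != index.k:
        raise ValueError(f"query length {len(kmer)} != k={index.k}")
    return list(index.seeds.get(kmer.upper(), ()))


def _hamming(a: str, b: str, cap: int) -> int:
    """Mismatches between equal-length strings; N never matches. Early exit past cap."""
    if a == b and "N" not in a:
        return 0
    mm = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            mm += 1
            if mm > cap:
                return mm
    return mm


def _candidates(seq: str, index: ReferenceIndex) -> set[tuple[str, int]]:
    k = index.k
    length = len(seq)
    seeds = index.seeds
    out: set[tuple[str, int]] = set()
    for offset in range(length - k + 1):
        hits = seeds.get(seq[offset : offset + k])
        if not hits:
            continue
        for name, pos in hits:
            start = pos - offset
            if start >= 0 and start + length <= len(index.sequences[name]):
                out.add((name, start))
    return out


def align_read(
    read: SmallRead, index: ReferenceIndex, max_mismatch: int = 2
) -> Alignment | None:
    """Best end-to-end gapless alignment of a read, or None if unaligned.

    Candidate loci come from seed hits of all read k-mers on both strands;
    the alignment with the fewest mismatches (<= ``max_mismatch``) is
    returned, with ties counted in ``multiplicity`` and broken towards the
    lowest (target, start), "+" strand before "-".
    """
    length = len(read)
    if length < index.k:
        return None
    seq = read.sequence.upper()
    hits: list[tuple[int, str, int, int]] = []
    for strand_rank, query in enumerate((seq, reverse_complement(seq))):
        for name, start in _candidates(query, index):
            mm = _hamming(query, index.sequences[name][start : start + length], max_mismatch)
            if mm <= max_mismatch:
                hits.append((mm, name, start, strand_rank))
    if not hits:
        return None
    hits.sort()
    mm, name, start, strand_rank = hits[0]
    multiplicity = sum(1 for h in hits if h[0] == mm)
    return Alignment(
        read_id=read.read_id,
        target_name=name,
        start=start,
        end=start + length,
        strand="+" if strand_rank == 0 else "-",
        mismatches=mm,
        multiplicity=multiplicity,
        sequence=read.sequence,
    )


def align_dataset(
    reads: list[SmallRead],
    index: ReferenceIndex,
    max_mismatch: int = 2,
    keep_unaligned: bool = False,
) -> tuple[list[Alignment | None], dict[str, int]]:
    """Align every read; return alignments sorted by (target, start) and stats.

    With ``keep_unaligned`` the output keeps input order and holds None for
    unaligned reads (useful for read-level bookkeeping); otherwise unaligned
    reads are dropped and the output is coordinate-sorted.
    """
    alignments = [align_read(r, index, max_mismatch) for r in reads]
    n_aligned = sum(1 for a in alignments if a is not None)
    stats = {"input": len(reads), "aligned": n_aligned, "unaligned": len(reads) - n_aligned}
    if keep_unaligned:
        return alignments, stats
    aligned = [a for a in alignments if a is not None]
    aligned.sort(key=lambda a: (a.target_name, a.start, a.end, a.strand, a.read_id))
    return aligned, stats


def alignments_to_sam(alignments: list[Alignment], index: ReferenceIndex) -> str:
    """Render alignments as minimal SAM text (gapless CIGAR, NM tag)."""
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for name in sorted(index.sequences):
        lines.append(f"@SQ\tSN:{name}\tLN:{len(index.sequences[name])}")
    for aln in sorted(alignments, key=lambda a: (a.target_name, a.start)):
        flag = 16 if aln.strand == "-" else 0
        seq = aln.sequence if aln.strand == "+" else reverse_complement(aln.sequence)
        lines.append(
            "\t".join(
                [
                    aln.read_id,
                    str(flag),
                    aln.target_name,
                    str(aln.start + 1),
                    "255",
                    f"{aln.end - aln.start}M",
                    "*",
                    "0",
                    "0",
                    seq,
                    "*",
                    f"NM:i:{aln.mismatches}",
                ]
            )
        )
    return "\n".join(lines) + "\n"
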