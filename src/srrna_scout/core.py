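"""Shared domain types.

Coordinates are 0-based half-open throughout the package; GFF3 (1-based,
inclusive) is converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# Canonical segment order of a ribosomal DNA repeat unit: the transcribed
# portion (pre-rRNA: external/internal transcribed spacers and the 18S, 5.8S
# and 28S genes) followed by the intergenic spacer.
RDNA_SEGMENT_ORDER = ("5'ETS", "18S", "ITS1", "5.8S", "ITS2", "28S", "3'ETS", "IGS")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SmallRead:
    """A small-RNA read: sequence plus per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.sequence)} bases but "
                f"{len(self.qualities)} quality values"
            )
        if self.qualities and not all(0 <= q <= 60 for q in self.qualities):
            raise ValueError(f"read {self.read_id!r}: Phred qualities must lie in [0, 60]")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class UniqueRead:
    """A deduplicated read: one representative and its copy number."""

    representative: SmallRead
    copy_count: int

    def __post_init__(self) -> None:
        if self.copy_count < 1:
            raise ValueError("copy_count must be >= 1")


@dataclass
class RdnaReference:
    """An rDNA repeat unit with its named segment layout.

    ``segments`` tile ``[0, len(sequence))`` without gaps or overlap, in the
    canonical order; ``transcribed_end`` is where the transcribed portion
    ends and the IGS begins.
    """

    name: str
    sequence: str
    segments: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        pos = 0
        for label, start, end in self.segments:
            if start != pos or end <= start:
                raise ValueError(
                    f"segments must tile [0, {len(self.sequence)}) contiguously; "
                    f"segment {label!r} spans [{start}, {end}) after position {pos}"
                )
            pos = end
        if pos != len(self.sequence):
            raise ValueError(
                f"segments cover [0, {pos}) but the sequence has length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def transcribed_end(self) -> int:
        for label, start, _end in self.segments:
            if label == "IGS":
                return start
        return len(self.sequence)

    def segment(self, label: str) -> tuple[int, int]:
        for seg_label, start, end in self.segments:
            if seg_label == label:
                return start, end
        raise KeyError(label)

    def segment_of(self, position: int) -> str:
        for label, start, end in self.segments:
            if start <= position < end:
                return label
        raise ValueError(f"position {position} outside [0, {len(self.sequence)})")


@dataclass(frozen=True)
class Hotspot:
    """An rDNA interval from which srRNA reads are sampled.

    ``sense_fraction`` overrides the generator-wide sense fraction when set.
    """

    start: int
    end: int
    weight: float
    sense_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("hotspot end must exceed start")
        if self.weight < 0:
            raise ValueError("hotspot weight must be >= 0")


@dataclass(frozen=True)
class ReadOrigin:
    """Ground-truth provenance of one simulated read."""

    read_id: str
    hotspot_index: int
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class PlantedFragment:
    """Ground-truth record of a diverged rDNA fragment planted in the genome."""

    chrom: str
    start: int
    end: int
    source_segment_label: str
    source_start: int
    source_end: int
    orientation: str  # "sense" | "antisense"
    identity_fraction: float
    host_gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.end - self.start != self.source_end - self.source_start:
            raise ValueError("planted fragment length must equal source length")
        if not 0 < self.identity_fraction <= 1:
            raise ValueError("identity_fraction must lie in (0, 1]")
        if self.orientation not in ("sense", "antisense"):
            raise ValueError("orientation must be 'sense' or 'antisense'")


@dataclass
class SyntheticTruth:
    """Everything needed to score a pipeline run against the generator."""

    planted_fragments: list[PlantedFragment]
    hotspot_regions: list[tuple[int, int]]
    true_target_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        expected = {
            f.host_gene_id
            for f in self.planted_fragments
            if f.host_gene_id is not None
            and any(f.source_start < e and s < f.source_end for s, e in self.hotspot_regions)
        }
        if not self.true_target_genes:
            self.true_target_genes = expected
        elif self.true_target_genes != expected:
            raise ValueError("true_target_genes inconsistent with fragments and hotspots")


@dataclass(frozen=True)
class GeneInterval:
    """A gene locus (0-based half-open)."""

    gene_id: str
    name: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end must exceed start")

    @property
    def tss(self) -> int:
        """Transcription start position (strand-aware, 0-based)."""
        return self.start if self.strand == "+" else self.end - 1
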