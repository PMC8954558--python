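"""Synthetic inputs with the statistical structure of the real study, scaled down.

Every generator is a pure function of (config, seed) and returns ground-truth
records sufficient to recompute the summaries it claims.  The default study
is a 1/10-scale system: a 4.3-kb rDNA unit, a 0.75-Mb three-chromosome
genome hosting diverged (~96% identity, optionally inverted) rDNA fragments
inside introns and intergenic space, and 50,000 srRNA-like reads (19–50 nt,
mean 29 nt, twin length peaks near 25/26 nt, 99.5% sense) sampled from
hotspot intervals of the rDNA unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from srrna_scout.core import (
    RDNA_SEGMENT_ORDER,
    GeneInterval,
    Hotspot,
    PlantedFragment,
    RdnaReference,
    ReadOrigin,
    SmallRead,
    SyntheticTruth,
    reverse_complement,
)
from srrna_scout.epigenomics import SignalTrack, StateSegmentation

_BASES = np.array(list("ACGT"))

# Segment fractions of the rDNA unit, matching the proportions of the human
# repeat (3.7-kb 5'ETS, 1.9-kb 18S, ... 29.6-kb IGS out of 43 kb); the IGS
# absorbs rounding so the fractions sum to exactly 1.
_TRANSCRIBED_FRACTIONS = {
    "5'ETS": 0.0850,
    "18S": 0.0435,
    "ITS1": 0.0255,
    "5.8S": 0.0037,
    "ITS2": 0.0271,
    "28S": 0.1179,
    "3'ETS": 0.0084,
}
DEFAULT_SEGMENT_FRACTIONS = dict(_TRANSCRIBED_FRACTIONS)
DEFAULT_SEGMENT_FRACTIONS["IGS"] = 1.0 - sum(_TRANSCRIBED_FRACTIONS.values())

# Roadmap-style 15-state chromatin model labels.
STATE_LABELS_15 = (
    "1_TssA", "2_TssAFlnk", "3_TxFlnk", "4_Tx", "5_TxWk",
    "6_EnhG", "7_Enh", "8_ZNF/Rpts", "9_Het", "10_TssBiv",
    "11_BivFlnk", "12_EnhBiv", "13_ReprPC", "14_ReprPCWk", "15_Quies",
)
DEFAULT_STATE_WEIGHTS = (
    0.01, 0.01, 0.005, 0.05, 0.12, 0.01, 0.02, 0.01, 0.05,
    0.005, 0.005, 0.005, 0.02, 0.06, 0.62,
)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


# ---------------------------------------------------------------------------
# rDNA reference
# ---------------------------------------------------------------------------


def make_rdna_reference(
    total_len: int = 4300,
    segment_fractions: dict[str, float] | None = None,
    seed: int = 0,
) -> RdnaReference:
    """A random rDNA unit whose segments tile [0, total_len) exactly."""
    if total_len < 1000:
        raise ValueError("total_len must be >= 1000")
    fractions = segment_fractions or DEFAULT_SEGMENT_FRACTIONS
    if set(fractions) != set(RDNA_SEGMENT_ORDER):
        raise ValueError(f"segment_fractions must cover exactly {RDNA_SEGMENT_ORDER}")
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("segment fractions must sum to 1")
    cum = np.cumsum([fractions[lab] for lab in RDNA_SEGMENT_ORDER])
    bounds = [0] + [int(round(c * total_len)) for c in cum]
    bounds[-1] = total_len
    segments = [
        (lab, bounds[i], bounds[i + 1]) for i, lab in enumerate(RDNA_SEGMENT_ORDER)
    ]
    rng = np.random.default_rng(seed)
    return RdnaReference(
        name="rDNA_synthetic", sequence=_random_sequence(rng, total_len), segments=segments
    )


# ---------------------------------------------------------------------------
# genome + gene annotation
# ---------------------------------------------------------------------------


@dataclass
class GenomeAnnotation:
    """Genes plus exon structure (introns are the gaps between exons)."""

    genes: list[GeneInterval]
    exons: dict[str, list[tuple[int, int]]]

    def introns(self) -> list[tuple[str, int, int, str]]:
        """(chrom, start, end, gene_id) for every intron."""
        out = []
        by_id = {g.gene_id: g for g in self.genes}
        for gene_id, exons in self.exons.items():
            chrom = by_id[gene_id].chrom
            for (s1, e1), (s2, e2) in zip(exons[:-1], exons[1:]):
                out.append((chrom, e1, s2, gene_id))
        return out

    def intergenic(self, chrom_lengths: dict[str, int], margin: int = 200):
        """(chrom, start, end, None) gaps between genes, trimmed by margin."""
        out = []
        for chrom, length in chrom_lengths.items():
            spans = sorted(
                (g.start, g.end) for g in self.genes if g.chrom == chrom
            )
            cursor = 0
            for s, e in spans + [(length, length)]:
                if s - cursor > 2 * margin:
                    out.append((chrom, cursor + margin, s - margin, None))
                cursor = max(cursor, e)
        return out


def make_genome(chrom_lengths: dict[str, int], seed: int = 0) -> dict[str, str]:
    """Uniform-random chromosome sequences."""
    rng = np.random.default_rng(seed)
    return {chrom: _random_sequence(rng, n) for chrom, n in chrom_lengths.items()}


def make_gene_annotation(
    chrom_lengths: dict[str, int],
    n_genes: int = 56,
    gene_length_range: tuple[int, int] = (4000, 9000),
    n_exons_range: tuple[int, int] = (2, 5),
    divergent_pair_fraction: float = 0.25,
    min_gap: int = 500,
    seed: int = 0,
) -> GenomeAnnotation:
    """Non-overlapping genes with exon/intron structure.

    A fraction of genes are placed as head-to-head divergent pairs (a minus-
    strand gene followed, after a 100–800 bp gap, by a plus-strand gene) so
    the TSS table contains genuine bidirectional promoters.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_lengths)
    genes: list[GeneInterval] = []
    exons: dict[str, list[tuple[int, int]]] = {}
    cursors = {c: min_gap for c in chroms}
    n_pairs = int(divergent_pair_fraction * n_genes / 2)

    def _add_gene(idx: int, chrom: str, start: int, strand: str) -> GeneInterval:
        length = int(rng.integers(gene_length_range[0], gene_length_range[1] + 1))
        gene_id = f"SYNG{idx:04d}"
        if start + length > chrom_lengths[chrom] - min_gap:
            raise ValueError("genome too small to place the requested genes")
        gene = GeneInterval(gene_id, f"G{idx}", chrom, start, start + length, strand)
        n_ex = int(rng.integers(n_exons_range[0], n_exons_range[1] + 1))
        exon_lens = rng.integers(150, 401, size=n_ex)
        intron_total = length - int(exon_lens.sum())
        if n_ex > 1:
            w = rng.random(n_ex - 1)
            intron_lens = 400 + ((intron_total - 400 * (n_ex - 1)) * w / w.sum()).astype(int)
            intron_lens[-1] += intron_total - 400 * (n_ex - 1) - int(
                (intron_lens - 400).sum()
            )
        else:
            intron_lens = np.array([], dtype=int)
            exon_lens = np.array([length])
        pos, ex = start, []
        for i in range(n_ex):
            ex.append((pos, pos + int(exon_lens[i])))
            pos += int(exon_lens[i])
            if i < n_ex - 1:
                pos += int(intron_lens[i])
        ex[-1] = (ex[-1][0], start + length)
        genes.append(gene)
        exons[gene_id] = ex
        return gene

    idx = 0
    while idx < n_genes:
        chrom = chroms[idx % len(chroms)]
        start = cursors[chrom] + int(rng.integers(0, min_gap))
        if idx < 2 * n_pairs:
            a = _add_gene(idx, chrom, start, "-")
            gap = int(rng.integers(100, 801))
            b = _add_gene(idx + 1, chrom, a.end + gap, "+")
            cursors[chrom] = b.end + min_gap
            idx += 2
        else:
            g = _add_gene(idx, chrom, start, "+" if rng.random() < 0.5 else "-")
            cursors[chrom] = g.end + min_gap
            idx += 1
    return GenomeAnnotation(genes=genes, exons=exons)


# ---------------------------------------------------------------------------
# planting diverged rDNA fragments
# ---------------------------------------------------------------------------


def _mutate(rng: np.random.Generator, seq: str, identity: float) -> str:
    """Per-base substitution with probability 1 - identity (no indels)."""
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < (1.0 - identity)
    if hit.any():
        shifts = rng.integers(1, 4, size=int(hit.sum()))
        codes = np.searchsorted(_BASES, arr[hit])
        arr[hit] = _BASES[(codes + shifts) % 4]
    return "".join(arr)


def plant_fragments(
    genome: dict[str, str],
    annotation: GenomeAnnotation,
    rdna: RdnaReference,
    n_fragments: int = 8,
    identity: float = 0.9632,
    antisense_prob: float = 0.3,
    seed: int = 0,
    where: tuple[str, ...] = ("intron", "intergenic"),
    source_intervals: list[tuple[int, int]] | None = None,
    length_range: tuple[int, int] = (250, 600),
) -> tuple[dict[str, str], list[PlantedFragment]]:
    """Overwrite genome loci with diverged copies of rDNA subsequences.

    Each fragment copies an rDNA source interval (given explicitly, or drawn
    at random with a length in ``length_range``), substitutes bases with
    probability ``1 - identity``, reverse-complements with probability
    ``antisense_prob``, and replaces the sequence of an intron or intergenic
    slot.  Fragments never overlap each other.  Returns the modified genome
    and the truth records.
    """
    if not 0.5 < identity <= 1.0:
        raise ValueError("identity must lie in (0.5, 1]")
    rng = np.random.default_rng(seed)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    slots: list[tuple[str, int, int, str | None]] = []
    if "intron" in where:
        slots += annotation.introns()
    if "intergenic" in where:
        slots += annotation.intergenic(chrom_lengths)
    slots = [s for s in slots if s[2] - s[1] >= 100]
    order = rng.permutation(len(slots))
    slots = [slots[i] for i in order]

    genome = dict(genome)
    fragments: list[PlantedFragment] = []
    for i in range(n_fragments):
        if source_intervals is not None:
            src_s, src_e = source_intervals[i % len(source_intervals)]
        else:
            frag_len = int(rng.integers(length_range[0], length_range[1] + 1))
            src_s = int(rng.integers(0, len(rdna) - frag_len))
            src_e = src_s + frag_len
        frag_len = src_e - src_s
        slot_idx = next(
            (j for j, (_, s, e, _) in enumerate(slots) if e - s >= frag_len), None
        )
        if slot_idx is None:
            raise ValueError(
                f"genome too small: no free intron/intergenic slot for fragment {i} "
                f"({frag_len} bp)"
            )
        chrom, s, e, host = slots.pop(slot_idx)
        offset = int(rng.integers(s, e - frag_len + 1))
        # return the unused slot remainders to the pool
        for rs, re_ in ((s, offset), (offset + frag_len, e)):
            if re_ - rs >= 100:
                slots.append((chrom, rs, re_, host))
        mutated = _mutate(rng, rdna.sequence[src_s:src_e], identity)
        orientation = "antisense" if rng.random() < antisense_prob else "sense"
        planted = reverse_complement(mutated) if orientation == "antisense" else mutated
        g = genome[chrom]
        genome[chrom] = g[:offset] + planted + g[offset + frag_len :]
        fragments.append(
            PlantedFragment(
                chrom=chrom,
                start=offset,
                end=offset + frag_len,
                source_segment_label=rdna.segment_of((src_s + src_e) // 2),
                source_start=src_s,
                source_end=src_e,
                orientation=orientation,
                identity_fraction=identity,
                host_gene_id=host,
            )
        )
    return genome, fragments


# ---------------------------------------------------------------------------
# srRNA reads
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QualityModel:
    """High-quality plateau with occasional low-quality read ends,
    so that quality trimming is actually exercised."""

    plateau: tuple[int, int] = (38, 40)
    tail_prob: float = 0.1
    tail_len: tuple[int, int] = (1, 3)
    tail_q: tuple[int, int] = (2, 17)


def _length_pmf(
    length_range: tuple[int, int],
    mean_len: float,
    peak_mu: float = 25.5,
    peak_sigma: float = 1.2,
    peak_weight: float = 0.35,
    broad_sigma: float = 6.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Discrete read-length distribution on ``length_range``.

    A two-component mixture: a narrow component producing the twin peaks at
    25/26 nt and a broad component whose location is solved (bisection) so
    the discretized, truncated mixture has exactly the requested mean.
    """
    lo, hi = length_range
    lengths = np.arange(lo, hi + 1)
    if not lo < mean_len < hi:
        raise ValueError("mean_len must lie strictly inside length_range")
    peak = np.exp(-0.5 * ((lengths - peak_mu) / peak_sigma) ** 2)
    peak /= peak.sum()

    def pmf(mu_b: float) -> np.ndarray:
        broad = np.exp(-0.5 * ((lengths - mu_b) / broad_sigma) ** 2)
        broad /= broad.sum()
        return peak_weight * peak + (1 - peak_weight) * broad

    a, b = float(lo) - 20, float(hi) + 20
    for _ in range(200):
        mid = (a + b) / 2
        if (pmf(mid) * lengths).sum() < mean_len:
            a = mid
        else:
            b = mid
    return lengths, pmf((a + b) / 2)


def simulate_srrna_reads(
    rdna: RdnaReference,
    hotspots: list[Hotspot],
    n_reads: int = 50_000,
    length_range: tuple[int, int] = (19, 50),
    mean_len: float = 29.0,
    sense_fraction: float = 0.995,
    quality_model: QualityModel | None = None,
    seed: int = 0,
) -> tuple[list[SmallRead], list[ReadOrigin]]:
    """Sample srRNA-like reads from weighted rDNA hotspots.

    Read lengths follow the twin-peaked mixture of :func:`_length_pmf`; the
    strand is sense with probability ``sense_fraction`` (antisense reads are
    reverse complements of the sampled interval); qualities follow the
    quality model.  Returns reads plus per-read ground-truth origins.
    """
    if not hotspots:
        raise ValueError("at least one hotspot is required")
    for h in hotspots:
        if not 0 <= h.start < h.end <= len(rdna):
            raise ValueError(f"hotspot [{h.start}, {h.end}) outside the rDNA unit")
    qm = quality_model or QualityModel()
    rng = np.random.default_rng(seed)
    weights = np.array([h.weight for h in hotspots], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("hotspot weights must sum to a positive value")
    weights /= weights.sum()
    lengths, pmf = _length_pmf(length_range, mean_len)

    hot_idx = rng.choice(len(hotspots), size=n_reads, p=weights)
    read_lens = rng.choice(lengths, size=n_reads, p=pmf)
    u_strand = rng.random(n_reads)
    reads: list[SmallRead] = []
    origins: list[ReadOrigin] = []
    for i in range(n_reads):
        h = hotspots[hot_idx[i]]
        length = int(read_lens[i])
        start = int(rng.integers(h.start, h.end))
        start = min(start, len(rdna) - length)
        sf = h.sense_fraction if h.sense_fraction is not None else sense_fraction
        strand = "+" if u_strand[i] < sf else "-"
        seq = rdna.sequence[start : start + length]
        if strand == "-":
            seq = reverse_complement(seq)
        quals = rng.integers(qm.plateau[0], qm.plateau[1] + 1, size=length)
        for side in (0, 1):
            if rng.random() < qm.tail_prob:
                tl = int(rng.integers(qm.tail_len[0], qm.tail_len[1] + 1))
                tq = rng.integers(qm.tail_q[0], qm.tail_q[1] + 1, size=tl)
                if side == 0:
                    quals[:tl] = tq
                else:
                    quals[length - tl :] = tq
        read_id = f"sr{i:07d}"
        reads.append(SmallRead(read_id, seq, tuple(int(q) for q in quals)))
        origins.append(ReadOrigin(read_id, int(hot_idx[i]), start, start + length, strand))
    return reads, origins


# ---------------------------------------------------------------------------
# expression, states, tracks, TSS
# ---------------------------------------------------------------------------


def simulate_expression_table(
    n_genes: int,
    zero_fraction: float = 0.4,
    lognormal_params: tuple[float, float] = (1.0, 2.0),
    seed: int = 0,
    gene_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Zero-inflated log-normal TPM table (columns: gene_id, tpm).

    A ``zero_fraction`` of genes are exact zeros (undetected transcripts);
    the rest are log-normal, mimicking the heavy-tailed, non-normal shape of
    real expression data.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    if not 0 <= zero_fraction < 1:
        raise ValueError("zero_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    mu, sigma = lognormal_params
    tpm = rng.lognormal(mu, sigma, size=n_genes)
    tpm[rng.random(n_genes) < zero_fraction] = 0.0
    ids = gene_ids if gene_ids is not None else [f"G{i:06d}" for i in range(n_genes)]
    if len(ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    return pd.DataFrame({"gene_id": ids, "tpm": tpm})


def simulate_state_segmentation(
    chrom_lengths: dict[str, int],
    n_states: int = 15,
    mean_segment_len: int = 2000,
    state_weights: tuple[float, ...] | None = None,
    seed: int = 0,
    labels: tuple[str, ...] | None = None,
) -> StateSegmentation:
    """Tile each chromosome with labeled segments of ~exponential length."""
    weights = np.asarray(
        state_weights if state_weights is not None else DEFAULT_STATE_WEIGHTS[:n_states],
        dtype=float,
    )
    if len(weights) != n_states:
        raise ValueError("state_weights length must equal n_states")
    weights = weights / weights.sum()
    labs = labels or (
        STATE_LABELS_15 if n_states == 15 else tuple(f"S{i + 1}" for i in range(n_states))
    )
    rng = np.random.default_rng(seed)
    rows = []
    for chrom in sorted(chrom_lengths):
        pos, length = 0, chrom_lengths[chrom]
        while pos < length:
            seg = max(200, int(rng.exponential(mean_segment_len)))
            end = min(pos + seg, length)
            rows.append((chrom, pos, end, labs[int(rng.choice(n_states, p=weights))]))
            pos = end
    return StateSegmentation(pd.DataFrame(rows, columns=["chrom", "start", "end", "state"]))


@dataclass(frozen=True)
class NoiseModel:
    step: int = 50
    gamma_shape: float = 4.0  # baseline ~ Gamma(shape, 1/shape): mean 1


def simulate_signal_track(
    chrom_lengths: dict[str, int],
    enriched_regions: list[tuple[str, int, int]],
    enrichment: float = 10.0,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> SignalTrack:
    """Step-function track: unit-mean noise, plus ``enrichment`` inside regions.

    The uplift is additive on a baseline of mean 1, so ``enrichment=0`` gives
    a flat-mean track and the inside/outside mean ratio is 1 + enrichment.
    Overlapping enriched regions are merged (with a warning).
    """
    import warnings

    if enrichment < 0:
        raise ValueError("enrichment must be >= 0")
    nm = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
    for chrom, s, e in enriched_regions:
        by_chrom[chrom].append((s, e))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in by_chrom.items():
        m = _merge_intervals(ivs)
        if len(m) < len(ivs):
            warnings.warn(f"{chrom}: overlapping enriched regions merged", stacklevel=2)
        merged[chrom] = m
    steps: dict[str, list[tuple[int, int, float]]] = {}
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        edges = np.arange(0, length + nm.step, nm.step)
        edges[-1] = length
        starts, ends = edges[:-1], edges[1:]
        values = rng.gamma(nm.gamma_shape, 1.0 / nm.gamma_shape, size=len(starts))
        mids = (starts + ends) // 2
        for s, e in merged[chrom]:
            values[(mids >= s) & (mids < e)] += enrichment
        steps[chrom] = [
            (int(a), int(b), float(v)) for a, b, v in zip(starts, ends, values) if b > a
        ]
    return SignalTrack.from_steps(steps)


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def simulate_tss_table(
    annotation: GenomeAnnotation,
    minor_tss_prob: float = 0.35,
    seed: int = 0,
) -> pd.DataFrame:
    """CAGE-style TSS table: a major TSS per gene, occasional minor TSSs.

    Minor TSSs carry 0.1–5% of the major TSS expression, so a portion falls
    below the 1% filtering threshold used downstream.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gene in annotation.genes:
        major = float(rng.lognormal(2.0, 1.0))
        rows.append((gene.gene_id, gene.chrom, gene.tss, gene.strand, major))
        if rng.random() < minor_tss_prob:
            shift = int(rng.integers(200, 2501))
            pos = gene.tss + shift if gene.strand == "+" else gene.tss - shift
            if 0 <= pos:
                rows.append(
                    (
                        gene.gene_id,
                        gene.chrom,
                        pos,
                        gene.strand,
                        major * float(rng.uniform(0.001, 0.05)),
                    )
                )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "pos", "strand", "cage_expression"])


# ---------------------------------------------------------------------------
# the full study
# ---------------------------------------------------------------------------


def default_hotspots(rdna: RdnaReference, width: int = 120) -> list[Hotspot]:
    """Twelve read-source hotspots emulating the observed rDNA peaks: ten in
    the transcribed portion (the strongest at the 5' region of 28S, a
    prominent 5.8S peak, two 18S peaks) and two small IGS hotspots."""

    def centered(seg: str, frac: float, weight: float) -> Hotspot:
        s, e = rdna.segment(seg)
        mid = s + int(frac * (e - s))
        lo = max(0, mid - width // 2)
        return Hotspot(lo, min(len(rdna), lo + width), weight)

    return [
        centered("5'ETS", 0.5, 0.04),
        centered("18S", 0.33, 0.08),
        centered("18S", 0.67, 0.05),
        centered("ITS1", 0.5, 0.03),
        centered("5.8S", 0.5, 0.12),
        centered("ITS2", 0.5, 0.03),
        centered("28S", 0.10, 0.30),
        centered("28S", 0.35, 0.12),
        centered("28S", 0.60, 0.10),
        centered("28S", 0.85, 0.08),
        centered("IGS", 0.20, 0.025),
        centered("IGS", 0.60, 0.025),
    ]


@dataclass
class StudyConfig:
    """Scale and effect-size parameters of the synthetic study (1/10 scale)."""

    rdna_total_len: int = 4300
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 250_000, "chr2": 250_000, "chr3": 250_000}
    )
    n_genes: int = 56
    divergent_pair_fraction: float = 0.25
    n_reads: int = 50_000
    length_range: tuple[int, int] = (19, 50)
    mean_len: float = 29.0
    sense_fraction: float = 0.995
    identity: float = 0.9632
    antisense_prob: float = 0.3
    hotspot_width: int = 120
    n_intronic_per_transcribed_hotspot: int = 24  # round-robin over 10 hotspots
    n_intergenic_fragments: int = 3
    n_decoy_fragments: int = 8
    expression_zero_fraction: float = 0.4
    signal_enrichment: float = 10.0
    n_contacting_extra: int = 20


@dataclass
class SyntheticStudy:
    """All pipeline inputs for one synthetic run, plus the ground truth."""

    config: StudyConfig
    rdna: RdnaReference
    hotspots: list[Hotspot]
    genome: dict[str, str]
    annotation: GenomeAnnotation
    reads: list[SmallRead]
    origins: list[ReadOrigin]
    expression: pd.DataFrame
    states: StateSegmentation
    tracks: dict[str, SignalTrack]
    tss: pd.DataFrame
    contacting_genes: list[str]
    truth: SyntheticTruth

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def _decoy_sources(
    rng: np.random.Generator,
    rdna: RdnaReference,
    hotspots: list[Hotspot],
    n: int,
    frag_len: int = 150,
    margin: int = 115,
) -> list[tuple[int, int]]:
    """Source intervals kept clear of every hotspot, so no read reaches them.

    The margin exceeds the maximum read length, so no simulated read can even
    partially overlap a decoy source.  Candidates tile the hotspot-free space
    deterministically; a random subset of them is returned.
    """
    keepout = _merge_intervals(
        [(max(0, h.start - margin), min(len(rdna), h.end + margin)) for h in hotspots]
    )
    free: list[tuple[int, int]] = []
    cursor = 0
    for ks, ke in keepout + [(len(rdna), len(rdna))]:
        if ks - cursor >= frag_len:
            free.append((cursor, ks))
        cursor = max(cursor, ke)
    candidates: list[tuple[int, int]] = []
    for s, e in free:
        pos = s
        while pos + frag_len <= e:
            candidates.append((pos, pos + frag_len))
            pos += frag_len + 50
    if len(candidates) < n:
        raise ValueError(
            f"only {len(candidates)} hotspot-free decoy slots available, {n} requested"
        )
    picked = rng.choice(len(candidates), size=n, replace=False)
    return [candidates[i] for i in sorted(picked)]


def simulate_study(config: StudyConfig | None = None, seed: int = 0) -> SyntheticStudy:
    """Generate every input of the srRNA pipeline plus ground truth.

    Fragments copied from read-hotspot source intervals are planted inside
    introns (their host genes form ``truth.true_target_genes``) and in
    intergenic space; decoy fragments come from rDNA regions no read can
    reach.  Default fragment identity is 96.32%.
    """
    cfg = config or StudyConfig()
    master = np.random.default_rng(seed)
    sub = master.integers(0, 2**31 - 1, size=12)

    rdna = make_rdna_reference(cfg.rdna_total_len, seed=int(sub[0]))
    hotspots = default_hotspots(rdna, width=cfg.hotspot_width)
    transcribed, igs = hotspots[:10], hotspots[10:]  # default_hotspots layout

    genome = make_genome(cfg.chrom_lengths, seed=int(sub[1]))
    annotation = make_gene_annotation(
        cfg.chrom_lengths,
        n_genes=cfg.n_genes,
        divergent_pair_fraction=cfg.divergent_pair_fraction,
        seed=int(sub[2]),
    )

    def source_of(h: Hotspot, margin: int = 55) -> tuple[int, int]:
        return max(0, h.start - margin), min(len(rdna), h.end + margin)

    n_tr = cfg.n_intronic_per_transcribed_hotspot
    intron_sources = [source_of(transcribed[i % len(transcribed)]) for i in range(n_tr)]
    intron_sources += [source_of(h) for h in igs]
    genome, frags_intron = plant_fragments(
        genome, annotation, rdna,
        n_fragments=len(intron_sources),
        identity=cfg.identity,
        antisense_prob=cfg.antisense_prob,
        seed=int(sub[3]),
        where=("intron",),
        source_intervals=intron_sources,
    )
    inter_sources = [source_of(transcribed[i]) for i in range(cfg.n_intergenic_fragments)]
    genome, frags_inter = plant_fragments(
        genome, annotation, rdna,
        n_fragments=len(inter_sources),
        identity=cfg.identity,
        antisense_prob=cfg.antisense_prob,
        seed=int(sub[4]),
        where=("intergenic",),
        source_intervals=inter_sources,
    )
    rng_decoy = np.random.default_rng(int(sub[5]))
    decoy_sources = _decoy_sources(rng_decoy, rdna, hotspots, cfg.n_decoy_fragments)
    genome, frags_decoy = plant_fragments(
        genome, annotation, rdna,
        n_fragments=len(decoy_sources),
        identity=cfg.identity,
        antisense_prob=cfg.antisense_prob,
        seed=int(sub[6]),
        where=("intron", "intergenic"),
        source_intervals=decoy_sources,
    )
    fragments = frags_intron + frags_inter + frags_decoy

    reads, origins = simulate_srrna_reads(
        rdna, hotspots,
        n_reads=cfg.n_reads,
        length_range=cfg.length_range,
        mean_len=cfg.mean_len,
        sense_fraction=cfg.sense_fraction,
        seed=int(sub[7]),
    )

    gene_ids = [g.gene_id for g in annotation.genes]
    expression = simulate_expression_table(
        len(gene_ids),
        zero_fraction=cfg.expression_zero_fraction,
        seed=int(sub[8]),
        gene_ids=gene_ids,
    )
    states = simulate_state_segmentation(cfg.chrom_lengths, seed=int(sub[9]))
    frag_regions = [(f.chrom, f.start, f.end) for f in fragments]
    tracks = {
        "activating_mark": simulate_signal_track(
            cfg.chrom_lengths, frag_regions, enrichment=cfg.signal_enrichment,
            seed=int(sub[10]),
        ),
        "control": simulate_signal_track(
            cfg.chrom_lengths, [], enrichment=0.0, seed=int(sub[10]) // 2 + 1
        ),
    }
    tss = simulate_tss_table(annotation, seed=int(sub[11]))

    truth = SyntheticTruth(
        planted_fragments=fragments,
        hotspot_regions=[(h.start, h.end) for h in hotspots],
    )
    rng_contact = np.random.default_rng(int(sub[5]) + 1)
    true_sorted = sorted(truth.true_target_genes)
    n_true_contact = max(1, len(true_sorted) // 3)
    others = [g for g in gene_ids if g not in truth.true_target_genes]
    contacting = list(
        rng_contact.choice(true_sorted, size=min(n_true_contact, len(true_sorted)), replace=False)
    ) + list(
        rng_contact.choice(
            others, size=min(cfg.n_contacting_extra, len(others)), replace=False
        )
    )

    return SyntheticStudy(
        config=cfg,
        rdna=rdna,
        hotspots=hotspots,
        genome=genome,
        annotation=annotation,
        reads=reads,
        origins=origins,
        expression=expression,
        states=states,
        tracks=tracks,
        tss=tss,
        contacting_genes=sorted(contacting),
        truth=truth,
    )
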