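"""File-format boundary: FASTQ/FASTA via Biopython, tabular formats via pandas.

Internal coordinates are 0-based half-open; GFF3 is written/read as 1-based
inclusive, BED and bedGraph as native half-open.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from srrna_scout.core import GeneInterval, PlantedFragment, SmallRead, SyntheticTruth
from srrna_scout.epigenomics import SignalTrack, StateSegmentation


# --- FASTQ / FASTA ---------------------------------------------------------


def read_fastq(path) -> list[SmallRead]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            SmallRead(rec.id, str(rec.seq), tuple(rec.letter_annotations["phred_quality"]))
        )
    return reads


def write_fastq(reads: list[SmallRead], path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()],
        str(path),
        "fasta",
    )


# --- GFF3 (1-based inclusive at the boundary) ------------------------------


def write_gff3_genes(annotation, path) -> None:
    """Write genes (+ exons when available) as GFF3."""
    lines = ["##gff-version 3"]
    exons = getattr(annotation, "exons", {})
    genes = getattr(annotation, "genes", annotation)
    for g in genes:
        attrs = f"ID={g.gene_id};Name={g.name}"
        lines.append(
            f"{g.chrom}\tsrrna_scout\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}"
        )
        for i, (es, ee) in enumerate(exons.get(g.gene_id, [])):
            lines.append(
                f"{g.chrom}\tsrrna_scout\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.e{i};Parent={g.gene_id}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3_genes(path) -> list[GeneInterval]:
    genes = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, _src, ftype, start, end, _score, strand, _phase, attrs = line.split("\t")
        if ftype != "gene":
            continue
        fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        genes.append(
            GeneInterval(
                gene_id=fields.get("ID", ""),
                name=fields.get("Name", fields.get("ID", "")),
                chrom=chrom,
                start=int(start) - 1,
                end=int(end),
                strand=strand,
            )
        )
    return genes


# --- BED / bedGraph --------------------------------------------------------


def write_bed(intervals, path, names=None) -> None:
    """Write (chrom, start, end[, name]) rows as BED (half-open)."""
    rows = []
    for i, iv in enumerate(intervals):
        chrom, start, end = iv[0], iv[1], iv[2]
        name = iv[3] if len(iv) > 3 else (names[i] if names else ".")
        rows.append(f"{chrom}\t{start}\t{end}\t{name}")
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name"], usecols=[0, 1, 2, 3],
    )
    return df


def write_state_bed(states: StateSegmentation, path) -> None:
    states.intervals.to_csv(path, sep="\t", header=False, index=False)


def read_state_bed(path) -> StateSegmentation:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "state"]
    )
    return StateSegmentation(df)


def write_bedgraph(track: SignalTrack, path) -> None:
    track.to_frame().to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> SignalTrack:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="t",
        names=["chrom", "start", "end", "value"],
    )
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for row in df.itertuples(index=False):
        by_chrom.setdefault(row.chrom, []).append((row.start, row.end, row.value))
    return SignalTrack.from_steps(by_chrom)


# --- mapping tables, truth, study ------------------------------------------


def mapping_table_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.chrom, r.start, r.end, r.strand, r.read_count, r.unique_count,
             r.mean_depth, r.sequence)
            for r in records
        ],
        columns=["chrom", "start", "end", "strand", "read_count", "unique_count",
                 "mean_depth", "sequence"],
    )


def write_truth(truth: SyntheticTruth, path) -> None:
    payload = {
        "planted_fragments": [asdict(f) for f in truth.planted_fragments],
        "hotspot_regions": [list(h) for h in truth.hotspot_regions],
        "true_target_genes": sorted(truth.true_target_genes),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    return SyntheticTruth(
        planted_fragments=[PlantedFragment(**f) for f in payload["planted_fragments"]],
        hotspot_regions=[tuple(h) for h in payload["hotspot_regions"]],
        true_target_genes=set(payload["true_target_genes"]),
    )


def write_study(study, outdir) -> dict[str, str]:
    """Serialize a SyntheticStudy to plain-text files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reads": outdir / "reads.fastq",
        "rdna": outdir / "rdna.fa",
        "genome": outdir / "genome.fa",
        "genes": outdir / "genes.gff3",
        "fragments": outdir / "planted_fragments.bed",
        "states": outdir / "states.bed",
        "expression": outdir / "expression.tsv",
        "tss": outdir / "tss.tsv",
        "contacting": outdir / "contacting_genes.txt",
        "truth": outdir / "truth.json",
    }
    write_fastq(study.reads, paths["reads"])
    write_fasta({study.rdna.name: study.rdna.sequence}, paths["rdna"])
    write_fasta(study.genome, paths["genome"])
    write_gff3_genes(study.annotation, paths["genes"])
    write_bed(
        [
            (f.chrom, f.start, f.end, f"{f.source_segment_label}:{f.orientation}")
            for f in study.truth.planted_fragments
        ],
        paths["fragments"],
    )
    write_state_bed(study.states, paths["states"])
    study.expression.to_csv(paths["expression"], sep="\t", index=False)
    study.tss.to_csv(paths["tss"], sep="\t", index=False)
    Path(paths["contacting"]).write_text("\n".join(study.contacting_genes) + "\n")
    write_truth(study.truth, paths["truth"])
    for name, track in study.tracks.items():
        p = outdir / f"track_{name}.bedgraph"
        write_bedgraph(track, p)
        paths[f"track_{name}"] = p
    return {k: str(v) for k, v in paths.items()}
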