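"""End-to-end execution: simulate -> qc -> rDNA pass -> genome pass ->
targets -> epigenomics -> validation, with a machine-readable run manifest.

A master seed spawns one named seed per stochastic stage (fixed derivation
via numpy SeedSequence), so stages are independently re-runnable yet the full
run is bit-deterministic for a given (config, seed).
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from srrna_scout import __version__
from srrna_scout import io as sio
from srrna_scout.align import build_index
from srrna_scout.config import RunConfig
from srrna_scout.epigenomics import (
    anchor_midpoints,
    metaprofile,
    classify_tss,
    state_composition,
    state_welch_test,
    tss_metaprofile,
)
from srrna_scout.pipeline import (
    assign_target_genes,
    build_mapping_table,
    exclude_rdna_family,
    merge_regions,
    overlap_gene_lists,
    rdna_coverage_profile,
    select_rdna_reads,
    strand_fraction,
)
from srrna_scout.qc import deduplicate, trim_dataset
from srrna_scout.stats import (
    mc_type1_equal_subsets,
    mc_type1_full_vs_subset,
    permutation_trial,
)
from srrna_scout.synthetic import simulate_study

_STAGE_NAMES = ("simulate", "permutation", "calibration")


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Fixed derivation of per-stage seeds from the master seed."""
    children = np.random.SeedSequence(master_seed).spawn(len(_STAGE_NAMES))
    return {
        name: int(c.generate_state(1)[0] % (2**31 - 1))
        for name, c in zip(_STAGE_NAMES, children)
    }


@dataclass
class RunManifest:
    config: dict
    seeds: dict[str, int]
    version: str = __version__
    counts: dict = field(default_factory=dict)
    wall_times: dict = field(default_factory=dict)
    stages_completed: list = field(default_factory=list)
    stages_skipped: list = field(default_factory=list)
    failed_stage: str | None = None
    error: str | None = None


def run_all(cfg: RunConfig) -> RunManifest:
    """Execute every stage in fixed order; the manifest is written to
    ``<outdir>/manifest.json`` even when a stage fails (partially filled)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results = outdir / "results"
    results.mkdir(exist_ok=True)
    seeds = stage_seeds(cfg.seed)
    manifest = RunManifest(config=asdict(cfg), seeds=seeds)
    state: dict = {}

    stages = [
        ("simulate", _stage_simulate),
        ("qc", _stage_qc),
        ("rdna_pass", _stage_rdna),
        ("genome_pass", _stage_genome),
        ("targets", _stage_targets),
        ("epigenomics", _stage_epigenomics),
        ("validation", _stage_validation),
    ]
    try:
        for name, fn in stages:
            t0 = time.perf_counter()
            skipped = fn(cfg, seeds, state, outdir, manifest)
            manifest.wall_times[name] = round(time.perf_counter() - t0, 3)
            (manifest.stages_skipped if skipped else manifest.stages_completed).append(name)
    except Exception as exc:
        manifest.failed_stage = name
        manifest.error = str(exc)
        _write_manifest(manifest, outdir)
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: RunManifest, outdir: Path) -> None:
    (outdir / "manifest.json").write_text(json.dumps(asdict(manifest), indent=1, default=str))


def _stage_simulate(cfg, seeds, state, outdir, manifest) -> bool:
    study = simulate_study(cfg.simulate, seed=seeds["simulate"])
    state["study"] = study
    sio.write_study(study, outdir / "inputs")
    manifest.counts["simulate"] = {
        "reads": len(study.reads),
        "genes": len(study.annotation.genes),
        "planted_fragments": len(study.truth.planted_fragments),
        "true_target_genes": len(study.truth.true_target_genes),
    }
    return False


def _stage_qc(cfg, seeds, state, outdir, manifest) -> bool:
    study = state["study"]
    trimmed, counts = trim_dataset(study.reads, **asdict(cfg.trim))
    state["trimmed"] = trimmed
    manifest.counts["qc"] = counts
    return False


def _stage_rdna(cfg, seeds, state, outdir, manifest) -> bool:
    study = state["study"]
    rdna_index = build_index({study.rdna.name: study.rdna.sequence}, k=cfg.align.k)
    state["rdna_index"] = rdna_index
    selected, alignments = select_rdna_reads(
        state["trimmed"], rdna_index, cfg.align.rdna_max_mismatch
    )
    state["selected"], state["rdna_alignments"] = selected, alignments
    profile = rdna_coverage_profile(alignments, study.rdna)
    pd.DataFrame(
        {
            "pos": np.arange(profile.target_len),
            "sense": profile.sense_depth,
            "antisense": profile.antisense_depth,
        }
    ).to_csv(outdir / "results" / "rdna_coverage.tsv", sep="\t", index=False)
    manifest.counts["rdna_pass"] = {
        "selected": len(selected),
        "sense_fraction": round(strand_fraction(alignments), 5) if alignments else None,
    }
    return False


def _stage_genome(cfg, seeds, state, outdir, manifest) -> bool:
    from srrna_scout.align import align_read

    study = state["study"]
    genome_index = build_index(study.genome, k=cfg.align.k)
    state["genome_index"] = genome_index
    unique = deduplicate(state["selected"])
    copy_counts = {u.representative.read_id: u.copy_count for u in unique}
    raw_by_id = {r.read_id: r.sequence for r in study.reads}
    aligned = []
    for u in unique:
        aln = align_read(u.representative, genome_index, cfg.align.genome_max_mismatch)
        if aln is not None:
            aligned.append(aln)
    records = build_mapping_table(aligned, raw_sequences=raw_by_id, copy_counts=copy_counts)
    state["records"] = records
    sio.mapping_table_frame(records).to_csv(
        outdir / "results" / "mapping_table.tsv", sep="\t", index=False
    )
    manifest.counts["genome_pass"] = {
        "unique_reads": len(unique),
        "aligned_unique_reads": len(aligned),
        "mapped_reads": sum(r.read_count for r in records),
        "mapping_records": len(records),
    }
    return False


def _stage_targets(cfg, seeds, state, outdir, manifest) -> bool:
    study = state["study"]
    records = state["records"]
    regions = merge_regions(records)
    sio.write_bed(regions, outdir / "results" / "regions.bed")
    targets = assign_target_genes(records, study.annotation.genes)
    state["targets"] = targets
    target_ids = exclude_rdna_family([t.gene.gene_id for t in targets])
    state["target_ids"] = target_ids
    inter, a_only, b_only = overlap_gene_lists(target_ids, study.contacting_genes)
    pd.DataFrame(
        [
            (t.gene.gene_id, t.gene.name, len(t.mappings), t.n_srRNAs)
            for t in targets
        ],
        columns=["gene_id", "name", "n_mappings", "n_srRNAs"],
    ).to_csv(outdir / "results" / "target_genes.tsv", sep="\t", index=False)
    manifest.counts["targets"] = {
        "regions": len(regions),
        "target_genes": len(target_ids),
        "contacting_overlap": len(inter),
        "target_only": len(a_only),
        "contacting_only": len(b_only),
    }
    return False


def _stage_epigenomics(cfg, seeds, state, outdir, manifest) -> bool:
    study = state["study"]
    records = state["records"]
    anchors = anchor_midpoints(records)
    n_profiles = 0
    if anchors:
        for name, track in study.tracks.items():
            prof = metaprofile(
                track, anchors, flank=cfg.profile.flank, bin_size=cfg.profile.bin_size,
                chrom_lengths=study.chrom_lengths,
            )
            prof.to_frame().to_csv(
                outdir / "results" / f"profile_{name}.tsv", sep="\t", index=False
            )
            n_profiles += 1
    target_ivs = [(r.chrom, r.start, r.end) for r in records]
    comp = state_composition(target_ivs, study.states, study.chrom_lengths)
    welch = state_welch_test(target_ivs, study.states, study.chrom_lengths)
    comp.join(welch).to_csv(outdir / "results" / "state_composition.tsv", sep="\t")
    classified = classify_tss(
        study.tss, minor_fraction=cfg.tss.minor_fraction,
        bidir_max_dist=cfg.tss.bidir_max_dist,
    )
    classified.to_csv(outdir / "results" / "tss_classes.tsv", sep="\t", index=False)
    tss_profiles = tss_metaprofile(
        records, classified, study.chrom_lengths,
        flank=cfg.profile.flank, bin_size=cfg.profile.bin_size,
    )
    for cls, prof in tss_profiles.items():
        prof.to_frame().to_csv(
            outdir / "results" / f"tss_profile_{cls}.tsv", sep="\t", index=False
        )
    manifest.counts["epigenomics"] = {
        "profiles": n_profiles,
        "states": len(comp),
        "tss_bidirectional": int((classified["tss_class"] == "bidirectional").sum()),
        "tss_unidirectional": int((classified["tss_class"] == "unidirectional").sum()),
        "tss_filtered_minor": int((classified["tss_class"] == "filtered_minor").sum()),
    }
    return False


def _stage_validation(cfg, seeds, state, outdir, manifest) -> bool:
    study = state["study"]
    v = cfg.validation
    if v.permutation_trials == 0 and v.mc_reps == 0:
        manifest.counts["validation"] = {"skipped": True}
        return True
    rng = np.random.default_rng(seeds["permutation"])
    rows = []
    for trial in range(v.permutation_trials):
        res = permutation_trial(
            study.reads,
            state["rdna_index"],
            state["genome_index"],
            study.annotation.genes,
            state["records"],
            rng,
            trial_id=trial,
            rdna_max_mismatch=cfg.align.rdna_max_mismatch,
            genome_max_mismatch=cfg.align.genome_max_mismatch,
            trim_params=asdict(cfg.trim),
            chrom_lengths=study.chrom_lengths,
        )
        rows.append(asdict(res))
    if rows:
        pd.DataFrame(rows).to_csv(
            outdir / "results" / "permutation_trials.tsv", sep="\t", index=False
        )
    calib = {}
    if v.mc_reps > 0:
        values = study.expression["tpm"].to_numpy()
        crng = np.random.default_rng(seeds["calibration"])
        calib["equal_subsets"] = asdict(
            mc_type1_equal_subsets(
                values, subset_size=v.mc_subset_size, n_reps=v.mc_reps,
                alpha=v.alpha, rng=crng,
            )
        )
        calib["full_vs_subset"] = asdict(
            mc_type1_full_vs_subset(
                values, subset_size=v.mc_subset_size, n_reps=v.mc_reps,
                alpha=v.alpha, rng=crng,
            )
        )
        (outdir / "results" / "calibration.json").write_text(json.dumps(calib, indent=1))
    observed_mapped = manifest.counts["genome_pass"]["mapped_reads"]
    manifest.counts["validation"] = {
        "permutation_trials": v.permutation_trials,
        "observed_mapped_reads": observed_mapped,
        "permuted_mapped_reads": [r["n_mapped_reads"] for r in rows],
        "calibration": calib,
    }
    return False
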