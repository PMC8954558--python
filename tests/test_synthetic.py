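"""Generator contracts: determinism, invariants, and the statistical
structure the synthetic data claims to have."""

from __future__ import annotations

import numpy as np
import pytest

from srrna_scout.core import Hotspot, reverse_complement
from srrna_scout.synthetic import (
    DEFAULT_SEGMENT_FRACTIONS,
    StudyConfig,
    make_gene_annotation,
    make_genome,
    make_rdna_reference,
    plant_fragments,
    simulate_expression_table,
    simulate_signal_track,
    simulate_srrna_reads,
    simulate_state_segmentation,
    simulate_study,
    simulate_tss_table,
)

from _oracles import revcomp


class TestRdnaReference:
    def test_segments_tile_unit_exactly(self):
        rdna = make_rdna_reference(4300, seed=0)
        pos = 0
        for _label, start, end in rdna.segments:
            assert start == pos
            pos = end
        assert pos == len(rdna) == 4300

    def test_same_seed_identical_sequence(self):
        a = make_rdna_reference(4300, seed=7)
        b = make_rdna_reference(4300, seed=7)
        assert a.sequence == b.sequence and a.segments == b.segments

    def test_28s_is_longest_transcribed_segment(self):
        # derived from the configured segment fractions
        transcribed = {
            k: v for k, v in DEFAULT_SEGMENT_FRACTIONS.items() if k != "IGS"
        }
        assert max(transcribed, key=transcribed.get) == "28S"
        rdna = make_rdna_reference(4300, seed=0)
        seg_lens = {lab: e - s for lab, s, e in rdna.segments if lab != "IGS"}
        assert max(seg_lens, key=seg_lens.get) == "28S"

    def test_bad_fractions_rejected(self):
        fractions = dict(DEFAULT_SEGMENT_FRACTIONS)
        fractions["IGS"] += 0.01
        with pytest.raises(ValueError):
            make_rdna_reference(4300, segment_fractions=fractions, seed=0)
        with pytest.raises(ValueError):
            make_rdna_reference(500, seed=0)


class TestPlantFragments:
    @pytest.fixture()
    def setup(self):
        rdna = make_rdna_reference(4300, seed=1)
        chrom_lengths = {"chrA": 120_000, "chrB": 120_000}
        genome = make_genome(chrom_lengths, seed=2)
        annotation = make_gene_annotation(chrom_lengths, n_genes=12, seed=3)
        return rdna, genome, annotation

    def test_identity_one_sense_fragment_is_exact_copy(self, setup):
        rdna, genome, annotation = setup
        new_genome, frags = plant_fragments(
            genome, annotation, rdna, n_fragments=3, identity=1.0,
            antisense_prob=0.0, seed=4,
        )
        for f in frags:
            planted = new_genome[f.chrom][f.start : f.end]
            assert planted == rdna.sequence[f.source_start : f.source_end]
            assert f.orientation == "sense"

    def test_divergence_matches_configured_identity(self, setup):
        # 96.32% identity -> mismatch fraction 0.0368 within 3 binomial SDs
        rdna, genome, annotation = setup
        new_genome, frags = plant_fragments(
            genome, annotation, rdna, n_fragments=4, identity=0.9632,
            antisense_prob=0.0, seed=5, length_range=(400, 600),
        )
        total_bp = sum(f.end - f.start for f in frags)
        assert total_bp >= 1000
        mismatches = 0
        for f in frags:
            planted = new_genome[f.chrom][f.start : f.end]
            source = rdna.sequence[f.source_start : f.source_end]
            mismatches += sum(a != b for a, b in zip(planted, source))
        p = 0.0368
        sd = (p * (1 - p) / total_bp) ** 0.5
        assert abs(mismatches / total_bp - p) < 3 * sd

    def test_antisense_fragment_matches_source_after_revcomp(self, setup):
        rdna, genome, annotation = setup
        identity = 0.96
        new_genome, frags = plant_fragments(
            genome, annotation, rdna, n_fragments=3, identity=identity,
            antisense_prob=1.0, seed=6, length_range=(400, 600),
        )
        for f in frags:
            assert f.orientation == "antisense"
            planted_rc = revcomp(new_genome[f.chrom][f.start : f.end])
            source = rdna.sequence[f.source_start : f.source_end]
            observed = np.mean([a == b for a, b in zip(planted_rc, source)])
            sd = (identity * (1 - identity) / (f.end - f.start)) ** 0.5
            assert observed > identity - 4 * sd

    def test_identity_out_of_range_rejected(self, setup):
        rdna, genome, annotation = setup
        with pytest.raises(ValueError):
            plant_fragments(genome, annotation, rdna, n_fragments=1, identity=0.4, seed=0)

    def test_too_many_fragments_raises(self):
        rdna = make_rdna_reference(4300, seed=1)
        chrom_lengths = {"chrA": 4000}
        genome = make_genome(chrom_lengths, seed=2)
        annotation = make_gene_annotation(chrom_lengths, n_genes=0, seed=3)
        with pytest.raises(ValueError, match="too small"):
            plant_fragments(
                genome, annotation, rdna, n_fragments=50, identity=0.96, seed=4,
                length_range=(500, 600),
            )


class TestSimulateReads:
    @pytest.fixture()
    def rdna(self):
        return make_rdna_reference(4300, seed=1)

    def test_lengths_within_range_and_mean(self, rdna):
        hotspots = [Hotspot(100, 300, 1.0), Hotspot(800, 1000, 2.0)]
        reads, _ = simulate_srrna_reads(rdna, hotspots, n_reads=10_000, seed=2)
        lengths = [len(r) for r in reads]
        assert min(lengths) >= 19 and max(lengths) <= 50
        assert abs(np.mean(lengths) - 29.0) < 0.5

    def test_sense_fraction_one_gives_no_antisense(self, rdna):
        reads, origins = simulate_srrna_reads(
            rdna, [Hotspot(100, 300, 1.0)], n_reads=500, sense_fraction=1.0, seed=3
        )
        assert all(o.strand == "+" for o in origins)
        for r, o in zip(reads[:50], origins[:50]):
            assert r.sequence == rdna.sequence[o.start : o.end]

    def test_antisense_reads_are_reverse_complements(self, rdna):
        reads, origins = simulate_srrna_reads(
            rdna, [Hotspot(100, 300, 1.0)], n_reads=200, sense_fraction=0.0, seed=4
        )
        assert all(o.strand == "-" for o in origins)
        for r, o in zip(reads[:20], origins[:20]):
            assert r.sequence == reverse_complement(rdna.sequence[o.start : o.end])

    def test_weight_concentration_confines_origins(self, rdna):
        hotspots = [Hotspot(100, 220, 1000.0), Hotspot(2000, 2120, 0.001)]
        _, origins = simulate_srrna_reads(rdna, hotspots, n_reads=2000, seed=5)
        inside = sum(1 for o in origins if 100 <= o.start < 220)
        assert inside / len(origins) >= 0.99

    def test_empty_hotspots_rejected(self, rdna):
        with pytest.raises(ValueError):
            simulate_srrna_reads(rdna, [], n_reads=10, seed=0)

    def test_default_study_sense_fraction_calibrated(self, default_study):
        origins = default_study.origins
        sense = sum(1 for o in origins if o.strand == "+") / len(origins)
        sd = (0.995 * 0.005 / len(origins)) ** 0.5
        assert abs(sense - 0.995) <= 2 * sd


class TestExpressionTable:
    def test_zero_fraction_zero_means_all_positive(self):
        df = simulate_expression_table(500, zero_fraction=0.0, seed=1)
        assert (df["tpm"] > 0).all()

    def test_zero_inflation_matches_configuration(self):
        df = simulate_expression_table(60_522, zero_fraction=0.4, seed=2)
        frac = (df["tpm"] == 0).mean()
        assert abs(frac - 0.4) < 3 * (0.4 * 0.6 / 60_522) ** 0.5

    def test_same_seed_identical(self):
        a = simulate_expression_table(1000, seed=3)["tpm"].to_numpy()
        b = simulate_expression_table(1000, seed=3)["tpm"].to_numpy()
        assert np.array_equal(a, b)

    def test_invalid_zero_fraction(self):
        with pytest.raises(ValueError):
            simulate_expression_table(100, zero_fraction=1.0, seed=0)
        with pytest.raises(ValueError):
            simulate_expression_table(1, seed=0)


class TestStateSegmentation:
    def test_segments_tile_chromosomes(self):
        lengths = {"chr1": 50_000, "chr2": 30_000}
        seg = simulate_state_segmentation(lengths, seed=1)
        for chrom, length in lengths.items():
            grp = seg.intervals[seg.intervals["chrom"] == chrom]
            assert grp["start"].iloc[0] == 0
            assert grp["end"].iloc[-1] == length
            assert (grp["start"].values[1:] == grp["end"].values[:-1]).all()

    def test_single_state_genome(self):
        weights = tuple([1.0] + [0.0] * 14)
        seg = simulate_state_segmentation({"chr1": 20_000}, state_weights=weights, seed=2)
        assert set(seg.intervals["state"]) == {"1_TssA"}

    def test_bp_fractions_follow_weights(self):
        weights = (0.5, 0.3, 0.2)
        seg = simulate_state_segmentation(
            {"chr1": 2_000_000}, n_states=3, state_weights=weights, seed=3,
            mean_segment_len=1000,
        )
        df = seg.intervals.assign(bp=lambda d: d["end"] - d["start"])
        fracs = df.groupby("state")["bp"].sum() / df["bp"].sum()
        n_segs = len(df)
        for w, lab in zip(weights, ("S1", "S2", "S3")):
            sd = (w * (1 - w) / n_segs) ** 0.5
            assert abs(fracs[lab] - w) < 3 * sd


class TestSignalTrack:
    def test_zero_enrichment_flat_mean(self):
        track = simulate_signal_track(
            {"chr1": 100_000}, [("chr1", 10_000, 20_000)], enrichment=0.0, seed=1
        )
        starts, ends, values = track.steps["chr1"]
        mids = (starts + ends) // 2
        inside = values[(mids >= 10_000) & (mids < 20_000)]
        outside = values[(mids < 10_000) | (mids >= 20_000)]
        assert abs(inside.mean() - outside.mean()) < 0.15

    def test_enrichment_ratio(self):
        e = 10.0
        track = simulate_signal_track(
            {"chr1": 200_000}, [("chr1", 50_000, 100_000)], enrichment=e, seed=2
        )
        starts, ends, values = track.steps["chr1"]
        mids = (starts + ends) // 2
        inside = values[(mids >= 50_000) & (mids < 100_000)].mean()
        outside = values[(mids < 50_000) | (mids >= 100_000)].mean()
        assert abs(inside / outside - (1 + e)) / (1 + e) < 0.2

    def test_steps_sorted_nonoverlapping(self):
        track = simulate_signal_track({"chr1": 10_000}, [], enrichment=0.0, seed=3)
        starts, ends, _ = track.steps["chr1"]
        assert (ends > starts).all()
        assert (starts[1:] >= ends[:-1]).all()

    def test_overlapping_regions_merged_with_warning(self):
        with pytest.warns(UserWarning, match="merged"):
            simulate_signal_track(
                {"chr1": 10_000},
                [("chr1", 100, 500), ("chr1", 300, 800)],
                enrichment=2.0,
                seed=4,
            )


class TestStudyAssembly:
    def test_truth_consistency(self, default_study):
        s = default_study
        hosts = {
            f.host_gene_id
            for f in s.truth.planted_fragments
            if f.host_gene_id
            and any(f.source_start < e and st < f.source_end
                    for st, e in s.truth.hotspot_regions)
        }
        assert hosts == s.truth.true_target_genes
        assert len(s.truth.true_target_genes) >= 15

    def test_decoy_fragments_unreachable_by_reads(self, default_study):
        s = default_study
        decoys = [
            f
            for f in s.truth.planted_fragments
            if not any(
                f.source_start < e and st < f.source_end
                for st, e in s.truth.hotspot_regions
            )
        ]
        assert decoys, "study must contain decoy fragments"
        for o in s.origins:
            for f in decoys:
                assert not (o.start < f.source_end and f.source_start < o.end)

    def test_same_seed_reproduces_reads(self):
        cfg = StudyConfig(n_reads=300)
        a = simulate_study(cfg, seed=5)
        b = simulate_study(cfg, seed=5)
        assert [r.sequence for r in a.reads] == [r.sequence for r in b.reads]
        assert a.genome == b.genome

    def test_tss_table_contains_minor_tss(self):
        ann = make_gene_annotation({"chr1": 200_000}, n_genes=15, seed=1)
        tss = simulate_tss_table(ann, minor_tss_prob=1.0, seed=2)
        per_gene = tss.groupby("gene_id").size()
        assert (per_gene >= 2).any()


def test_fastq_roundtrip_bit_exact(tmp_path, default_study):
    from srrna_scout import io as sio

    reads = default_study.reads[:500]
    path = tmp_path / "reads.fastq"
    sio.write_fastq(reads, path)
    back = sio.read_fastq(path)
    assert back == reads
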