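"""Metaprofiles, chromatin-state composition and TSS classification."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from srrna_scout.epigenomics import (
    SignalTrack,
    StateSegmentation,
    anchor_midpoints,
    classify_tss,
    coverage_track,
    metaprofile,
    state_composition,
    state_welch_test,
    tss_metaprofile,
)
from srrna_scout.pipeline import MappingRecord

from _oracles import per_bp_state_fractions, welch_formula


def flat_track(chrom="chr1", length=100_000, value=3.0):
    return SignalTrack.from_steps({chrom: [(0, length, value)]})


class TestMetaProfile:
    def test_constant_track_zscores_to_zeros(self):
        prof = metaprofile(flat_track(), [("chr1", 50_000)], zscore=True)
        assert prof.n_bins == 300  # 2 * 1500 / 10
        assert np.allclose(prof.values, 0.0)

    def test_unit_step_resampled_into_bins(self):
        # track jumps from 0 to 1 exactly at the anchor midpoint
        track = SignalTrack.from_steps({"chr1": [(0, 5000, 0.0), (5000, 10_000, 1.0)]})
        prof = metaprofile(track, [("chr1", 5000)], zscore=False)
        assert np.allclose(prof.values[:150], 0.0)
        assert np.allclose(prof.values[150:], 1.0)

    def test_partial_bin_overlap_is_length_weighted(self):
        track = SignalTrack.from_steps({"chr1": [(0, 4995, 0.0), (4995, 10_000, 2.0)]})
        prof = metaprofile(track, [("chr1", 5000)], zscore=False)
        # the bin [4990, 5000) holds 5 bp at 0 and 5 bp at 2 -> mean 1
        assert prof.values[149] == pytest.approx(1.0)

    def test_window_clipping_adjusts_denominators(self):
        track = flat_track(length=2000, value=4.0)
        prof = metaprofile(
            track, [("chr1", 100)], zscore=False, chrom_lengths={"chr1": 2000}
        )
        # the window starts 1400 bp before the chromosome; covered bins still
        # average to the track value instead of being diluted
        assert np.allclose(prof.values[140:], 4.0)
        assert np.allclose(prof.values[:140], 0.0)

    def test_zscore_mean_zero_sd_one(self):
        track = SignalTrack.from_steps(
            {"chr1": [(i * 100, (i + 1) * 100, float(i % 7)) for i in range(1000)]}
        )
        prof = metaprofile(track, [("chr1", 20_000), ("chr1", 60_000)], zscore=True)
        assert prof.values.mean() == pytest.approx(0.0, abs=1e-12)
        assert prof.values.std() == pytest.approx(1.0)

    def test_linearity_and_affine_invariance(self):
        steps = {"chr1": [(i * 50, (i + 1) * 50, float((i * 13) % 11)) for i in range(2000)]}
        track = SignalTrack.from_steps(steps)
        anchors = [("chr1", 30_000), ("chr1", 50_000), ("chr1", 70_000)]
        raw = metaprofile(track, anchors, zscore=False).values
        raw_scaled = metaprofile(track.scaled(3.5), anchors, zscore=False).values
        assert np.allclose(raw_scaled, 3.5 * raw)
        z = metaprofile(track, anchors, zscore=True).values
        z_affine = metaprofile(track.scaled(2.0).shifted(7.0), anchors, zscore=True).values
        assert np.allclose(z, z_affine)

    def test_no_anchors_rejected(self):
        with pytest.raises(ValueError):
            metaprofile(flat_track(), [])

    def test_midpoint_formula(self):
        recs = [
            MappingRecord("c", 100, 130, "+", 1, 1, 1.0, "A" * 30),
            MappingRecord("c", 0, 1, "+", 1, 1, 1.0, "A"),
            MappingRecord("c", 7, 10, "+", 1, 1, 1.0, "AAA"),
        ]
        assert anchor_midpoints(recs) == [("c", 115), ("c", 0), ("c", 8)]


class TestStateComposition:
    def test_targets_inside_one_state(self):
        seg = StateSegmentation(
            pd.DataFrame(
                [("c", 0, 500, "A"), ("c", 500, 1000, "B")],
                columns=["chrom", "start", "end", "state"],
            )
        )
        comp = state_composition([("c", 100, 200)], seg, {"c": 1000})
        assert comp.loc["A", "target_fraction"] == 1.0
        assert comp.loc["B", "target_fraction"] == 0.0
        assert comp["target_fraction"].sum() == pytest.approx(1.0)
        assert comp["genome_fraction"].sum() == pytest.approx(1.0)

    def test_single_state_genome(self):
        seg = StateSegmentation(
            pd.DataFrame([("c", 0, 1000, "Q")], columns=["chrom", "start", "end", "state"])
        )
        comp = state_composition([("c", 10, 900)], seg, {"c": 1000})
        assert comp.loc["Q", "target_fraction"] == 1.0
        assert comp.loc["Q", "genome_fraction"] == 1.0

    def test_unannotated_bucket(self):
        seg = StateSegmentation(
            pd.DataFrame([("c", 0, 600, "A")], columns=["chrom", "start", "end", "state"])
        )
        comp = state_composition([("c", 500, 700)], seg, {"c": 1000})
        assert comp.loc["A", "target_fraction"] == pytest.approx(0.5)
        assert comp.loc["Unannotated", "target_fraction"] == pytest.approx(0.5)
        assert comp.loc["Unannotated", "genome_fraction"] == pytest.approx(0.4)

    def test_matches_per_bp_oracle(self, rng):
        chrom_lengths = {"c1": 5000, "c2": 4000}
        rows = []
        for chrom, length in chrom_lengths.items():
            pos = 0
            while pos < length:
                seg_len = int(rng.integers(100, 600))
                end = min(pos + seg_len, length)
                rows.append((chrom, pos, end, f"S{int(rng.integers(1, 5))}"))
                pos = end
        seg = StateSegmentation(pd.DataFrame(rows, columns=["chrom", "start", "end", "state"]))
        targets = []
        for _ in range(40):
            chrom = "c1" if rng.random() < 0.5 else "c2"
            start = int(rng.integers(0, chrom_lengths[chrom] - 60))
            targets.append((chrom, start, start + int(rng.integers(10, 60))))
        comp = state_composition(targets, seg, chrom_lengths)
        # merge targets for the oracle exactly as the implementation documents
        t_oracle, g_oracle = per_bp_state_fractions(targets, rows, chrom_lengths)
        for state, frac in t_oracle.items():
            assert comp.loc[state, "target_fraction"] == pytest.approx(frac)
        for state, frac in g_oracle.items():
            assert comp.loc[state, "genome_fraction"] == pytest.approx(frac)


class TestWelch:
    def test_identical_fractions_give_t0_p1(self):
        seg = StateSegmentation(
            pd.DataFrame(
                [(c, 0, 1000, "A") for c in ("c1", "c2", "c3")],
                columns=["chrom", "start", "end", "state"],
            )
        )
        targets = [(c, 100, 200) for c in ("c1", "c2", "c3")]
        res = state_welch_test(targets, seg, {c: 1000 for c in ("c1", "c2", "c3")})
        assert res.loc["A", "t"] == 0.0 and res.loc["A", "p"] == 1.0

    def test_matches_closed_form(self):
        a = np.array([0.1, 0.2, 0.3])
        b = np.array([0.4, 0.5, 0.6])
        t_ref, df_ref = welch_formula(a, b)
        t, p = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(t_ref)
        assert p == pytest.approx(2 * sps.t.sf(abs(t_ref), df_ref))

    def test_single_chromosome_rejected(self):
        seg = StateSegmentation(
            pd.DataFrame([("c1", 0, 1000, "A")], columns=["chrom", "start", "end", "state"])
        )
        with pytest.raises(ValueError):
            state_welch_test([("c1", 0, 10)], seg, {"c1": 1000})

    def test_study_scale_run(self, default_run, default_study):
        targets = [(r.chrom, r.start, r.end) for r in default_run["records"]]
        res = state_welch_test(targets, default_study.states, default_study.chrom_lengths)
        assert ((res["p"] >= 0) & (res["p"] <= 1)).all()


class TestClassifyTss:
    def make_table(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "chrom", "pos", "strand", "cage_expression"]
        )

    def test_divergent_pair_within_1kb_is_bidirectional(self):
        table = self.make_table(
            [("gA", "c", 1000, "-", 50.0), ("gB", "c", 1500, "+", 30.0)]
        )
        out = classify_tss(table)
        assert set(out["tss_class"]) == {"bidirectional"}

    def test_distant_pair_unidirectional(self):
        table = self.make_table(
            [("gA", "c", 1000, "-", 50.0), ("gB", "c", 2500, "+", 30.0)]
        )
        out = classify_tss(table)
        assert set(out["tss_class"]) == {"unidirectional"}

    def test_convergent_orientation_not_bidirectional(self):
        # plus TSS upstream of minus TSS: transcripts run towards each other
        table = self.make_table(
            [("gA", "c", 1000, "+", 50.0), ("gB", "c", 1500, "-", 30.0)]
        )
        out = classify_tss(table)
        assert set(out["tss_class"]) == {"unidirectional"}

    def test_minor_tss_filtered_strictly(self):
        table = self.make_table(
            [
                ("g", "c", 100, "+", 100.0),
                ("g", "c", 600, "+", 0.5),   # 0.5 < 1% of 100 -> filtered
                ("g", "c", 900, "+", 1.0),   # exactly 1% -> kept
            ]
        )
        out = classify_tss(table)
        assert list(out["tss_class"]) == ["unidirectional", "filtered_minor", "unidirectional"]

    def test_negative_expression_rejected(self):
        with pytest.raises(ValueError):
            classify_tss(self.make_table([("g", "c", 100, "+", -1.0)]))

    def test_classes_partition_survivors(self, default_study):
        out = classify_tss(default_study.tss)
        assert set(out["tss_class"]) <= {"bidirectional", "unidirectional", "filtered_minor"}
        assert len(out) == len(default_study.tss)
        # divergent gene pairs exist in the default annotation
        assert (out["tss_class"] == "bidirectional").sum() >= 2


class TestTssMetaprofile:
    def test_no_mappings_near_tss_zero_profile(self):
        tss = pd.DataFrame(
            [("g", "c", 5000, "+", 10.0)],
            columns=["gene_id", "chrom", "pos", "strand", "cage_expression"],
        )
        classified = classify_tss(tss)
        profiles = tss_metaprofile([], classified, {"c": 10_000}, zscore=False)
        assert np.allclose(profiles["unidirectional"].values, 0.0)

    def test_single_centered_mapping_symmetric(self):
        rec = MappingRecord("c", 4990, 5010, "+", 1, 1, 1.0, "A" * 20)
        tss = pd.DataFrame(
            [("g", "c", 5000, "+", 10.0)],
            columns=["gene_id", "chrom", "pos", "strand", "cage_expression"],
        )
        classified = classify_tss(tss)
        prof = tss_metaprofile([rec], classified, {"c": 10_000}, zscore=False)[
            "unidirectional"
        ]
        assert np.allclose(prof.values, prof.values[::-1])
        assert prof.values.sum() > 0

    def test_empty_class_warns_and_skips(self):
        tss = pd.DataFrame(
            [("g", "c", 5000, "+", 10.0)],
            columns=["gene_id", "chrom", "pos", "strand", "cage_expression"],
        )
        classified = classify_tss(tss)
        with pytest.warns(UserWarning, match="bidirectional"):
            profiles = tss_metaprofile([], classified, {"c": 10_000})
        assert "bidirectional" not in profiles


def test_coverage_track_weights_and_depth():
    track = coverage_track([("c", 10, 20), ("c", 15, 25)], {"c": 40}, weights=[2.0, 1.0])
    assert track.integral_at("c", np.array([40]))[0] == pytest.approx(2 * 10 + 1 * 10)
    starts, ends, values = track.steps["c"]
    assert (starts[1:] >= ends[:-1]).all()
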