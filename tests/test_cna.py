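"""Copy-number profiling: binning, pooling, recentering, states, ploidy."""

import math

import numpy as np
import pandas as pd
import pytest

from ball_subtyper.cna import (
    BinTrack,
    CopyStateProfile,
    Probe,
    ProbeTrack,
    bin_depth,
    call_copy_states,
    classify_ploidy,
    detect_cnnloh,
    detect_focal_cna,
    detect_iamp21,
    expected_log2,
    pool_probes,
    recenter_baseline,
)
from ball_subtyper.intervals import GenomicInterval
from ball_subtyper.simulate import (
    PlantedLesion,
    SimKaryotype,
    TruthManifest,
    emit_baf_table,
    karyotype_for_count,
    simulate_fragments,
)
from test_targeted import make_aset


def sim(ref, karyotype, lesions=(), coverage=30.0, seed=23):
    truth = TruthManifest("cna", karyotype, list(lesions), seed=seed,
                          target_mean_coverage=coverage)
    return simulate_fragments(ref, truth)


def profile_for(ref, karyotype, lesions=(), coverage=30.0, seed=23):
    aset = sim(ref, karyotype, lesions, coverage, seed)
    track = recenter_baseline(pool_probes(bin_depth(aset, 1_000), 20))
    return track, call_copy_states(track, karyotype.tumor_fraction)


def synthetic_track(ref, chrom_levels, n_probes=10, probe_bp=20_000):
    """Hand-built probe track with given per-chromosome log2 levels."""
    probes = []
    for chrom, level in chrom_levels.items():
        for i in range(n_probes):
            probes.append(
                Probe(GenomicInterval(chrom, i * probe_bp, (i + 1) * probe_bp), level)
            )
    return ProbeTrack(probes=probes, probe_pool_size=20, bin_size=1_000, reference=ref)


class TestBinDepth:
    def test_single_fragment_hits_exactly_one_bin(self, mini_ref):
        aset = make_aset(mini_ref, [
            {"chrom1": "chrA", "start1": 12_345, "chrom2": "chrA", "start2": 12_545},
        ])
        track = bin_depth(aset, 1_000)
        assert track.counts["chrA"][12] == 1
        assert track.total_count == 1

    def test_empty_alignments_give_zero_track(self, mini_ref):
        aset = make_aset(mini_ref, [])
        track = bin_depth(aset, 1_000)
        assert track.total_count == 0

    def test_uniform_coverage_matches_poisson_expectation(self, mini_ref):
        aset = sim(mini_ref, SimKaryotype.diploid(mini_ref), coverage=30.0)
        track = bin_depth(aset, 1_000)
        expected = 30.0 * 1_000 / (2 * 150)  # fragments per bin
        counts = np.concatenate(list(track.counts.values()))
        assert counts.mean() == pytest.approx(expected, rel=0.02)
        # dispersion consistent with near-Poisson sampling
        assert counts.std() == pytest.approx(math.sqrt(expected), rel=0.25)

    def test_invalid_bin_size_rejected(self, mini_ref):
        aset = make_aset(mini_ref, [])
        with pytest.raises(ValueError):
            bin_depth(aset, 0)


class TestPoolProbes:
    def test_twenty_bins_pool_into_one_probe(self, mini_ref):
        counts = {c: np.full(100, 10, dtype="int64") for c in mini_ref.chrom_names}
        track = BinTrack(1_000, counts, mini_ref)
        probes = pool_probes(track, 20)
        per_chrom = [p for p in probes.probes if p.interval.chrom == "chrA"]
        assert len(per_chrom) == 5

    def test_uniform_counts_give_zero_log2(self, mini_ref):
        counts = {c: np.full(200, 33, dtype="int64") for c in mini_ref.chrom_names}
        probes = pool_probes(BinTrack(1_000, counts, mini_ref), 20)
        assert all(abs(p.log2_ratio) < 1e-12 for p in probes.probes)

    def test_probe_ratio_is_log2_of_mean_ratio(self, mini_ref):
        counts = {c: np.full(100, 100, dtype="int64") for c in mini_ref.chrom_names}
        counts["chrA"] = counts["chrA"].copy()
        counts["chrA"][:20] = 150
        track = pool_probes(BinTrack(1_000, counts, mini_ref), 20)
        first = track.probes[0]
        genome_mean = (150 * 20 + 100 * 480) / 500
        assert first.log2_ratio == pytest.approx(math.log2(150 / genome_mean), abs=1e-9)

    def test_all_zero_track_has_no_baseline(self, mini_ref):
        counts = {c: np.zeros(100, dtype="int64") for c in mini_ref.chrom_names}
        with pytest.raises(ValueError, match="baseline"):
            pool_probes(BinTrack(1_000, counts, mini_ref), 20)


class TestRecenterBaseline:
    def test_diploid_genome_offset_near_zero(self, mini_ref):
        track, _ = profile_for(mini_ref, SimKaryotype.diploid(mini_ref))
        assert abs(track.baseline_offset) < 0.05

    def test_single_trisomy_among_five_chromosomes_recentred_on_disomic(self, mini_ref):
        """One trisomy among five equal chromosomes biases the naive global
        mean by 10%; the modal (disomic) cluster defines the offset
        log2(2/2.2) and ends at ~0 after recentering."""
        copies = {c: 2 for c in mini_ref.chrom_names}
        copies["chrB"] = 3
        track, profile = profile_for(mini_ref, SimKaryotype(copies, 1.0))
        assert track.baseline_offset == pytest.approx(math.log2(2 / 2.2), abs=0.03)
        for chrom in ("chrA", "chrC", "chrD", "chrE"):
            assert abs(track.chrom_median(chrom)) < 0.05
        assert profile.per_chromosome_state["chrB"] == 3

    def test_hyperdiploid_recentering_restores_disomic_level(self, human_ref):
        """In a 55-chromosome genome the naive global mean sits above the
        disomic level; recentering puts disomic chromosomes at ~0 and
        trisomic ones at ~log2(3/2)."""
        kt = karyotype_for_count(human_ref, 55, tumor_fraction=1.0)
        track, profile = profile_for(human_ref, kt)
        disomic = [c for c, n in kt.per_chromosome_copy_number.items() if n == 2]
        trisomic = [c for c, n in kt.per_chromosome_copy_number.items() if n == 3]
        med_di = np.median([track.chrom_median(c) for c in disomic])
        med_tri = np.median([track.chrom_median(c) for c in trisomic])
        assert abs(med_di) < 0.05
        assert med_tri == pytest.approx(math.log2(1.5), abs=0.05)
        assert profile.chromosome_count == 55

    def test_no_modal_cluster_flags_ambiguous(self, mini_ref):
        levels = {c: i * 0.45 for i, c in enumerate(mini_ref.chrom_names)}
        track = recenter_baseline(synthetic_track(mini_ref, levels))
        assert track.baseline_ambiguous
        assert track.baseline_offset == 0.0


class TestCallCopyStates:
    @pytest.mark.parametrize(
        "level,purity,state",
        [(0.585, 1.0, 3), (0.322, 0.5, 3), (-1.0, 1.0, 1), (0.0, 1.0, 2), (1.0, 1.0, 4)],
    )
    def test_depth_law_inversion_analytic(self, mini_ref, level, purity, state):
        track = synthetic_track(mini_ref, {c: 0.0 for c in mini_ref.chrom_names[:4]})
        track.probes += synthetic_track(mini_ref, {"chrE": level}).probes
        profile = call_copy_states(track, purity)
        assert profile.per_chromosome_state["chrE"] == state

    def test_zero_purity_rejected(self, mini_ref):
        track = synthetic_track(mini_ref, {c: 0.0 for c in mini_ref.chrom_names})
        with pytest.raises(ValueError):
            call_copy_states(track, 0.0)

    @pytest.mark.parametrize("purity", [1.0, 0.5])
    @pytest.mark.parametrize("c", [1, 2, 3, 4])
    def test_simulated_states_recovered_exactly(self, mini_ref, purity, c):
        copies = {name: 2 for name in mini_ref.chrom_names}
        copies["chrD"] = c
        _, profile = profile_for(mini_ref, SimKaryotype(copies, purity))
        assert profile.per_chromosome_state["chrD"] == c

    def test_log2_monotone_in_copy_number(self, mini_ref):
        """Probe medians increase strictly with planted copy number."""
        copies = {"chrA": 1, "chrB": 2, "chrC": 3, "chrD": 4, "chrE": 2}
        track, _ = profile_for(mini_ref, SimKaryotype(copies, 1.0))
        meds = [track.chrom_median(c) for c in ("chrA", "chrB", "chrC", "chrD")]
        assert all(a < b for a, b in zip(meds, meds[1:]))


class TestClassifyPloidy:
    @pytest.mark.parametrize(
        "count,label",
        [(55, "HeH"), (35, "HoL"), (46, "diploid_range"), (25, "near_haploid"),
         (52, "HeH"), (70, "near_triploid"), (90, "near_tetraploid")],
    )
    def test_modal_number_ranges(self, count, label):
        profile = CopyStateProfile({"modal": count}, [], 1.0)
        assert classify_ploidy(profile).label == label

    def test_heh_triploid_overlap_with_duplication_signature_is_ambiguous(self):
        profile = CopyStateProfile({"modal": 60}, [], 1.0)
        assert classify_ploidy(profile).label == "HeH"
        assert classify_ploidy(profile, duplicated_hypodiploid_flag=True).label == "ambiguous"


class TestIamp21:
    def iamp_lesion(self, human_ref, copies=6):
        return PlantedLesion(
            kind="tandem_amplification", lesion_id="iamp",
            interval=GenomicInterval("chr21", 60_000, 200_000), copies=copies,
        )

    def test_planted_21q_amplification_recovered_with_probe_resolution(self, human_ref):
        kt = SimKaryotype.diploid(human_ref, 1.0)
        track, profile = profile_for(human_ref, kt, [self.iamp_lesion(human_ref)])
        lesion = detect_iamp21(track, profile)
        assert lesion is not None
        assert lesion.copy_state >= 5
        probe_bp = 20_000
        assert abs(lesion.extent.start - 60_000) <= probe_bp
        assert abs(lesion.extent.end - 200_000) <= probe_bp

    def test_whole_chromosome_trisomy_is_not_iamp21(self, human_ref):
        copies = {c: 2 for c in human_ref.chrom_names}
        copies["chr21"] = 5
        track, profile = profile_for(human_ref, SimKaryotype(copies, 1.0))
        assert detect_iamp21(track, profile) is None

    def test_flat_chromosome_gives_no_call(self, human_ref):
        track, profile = profile_for(human_ref, SimKaryotype.diploid(human_ref, 1.0))
        assert detect_iamp21(track, profile) is None


class TestFocalCna:
    def test_biallelic_deletion_called(self, human_ref):
        lesion = PlantedLesion(
            kind="deletion", lesion_id="cdkn2ab",
            interval=human_ref.locus("CDKN2A/B"), copies=0,
        )
        track, profile = profile_for(human_ref, SimKaryotype.diploid(human_ref, 1.0), [lesion])
        cnas, fusions = detect_focal_cna(track, profile)
        hit = {c.locus: c for c in cnas}["CDKN2A/B"]
        assert hit.type == "deletion"
        assert hit.biallelic
        assert fusions == []

    def test_par1_deletion_emits_p2ry8_crlf2_fusion(self, human_ref):
        lesion = PlantedLesion(
            kind="deletion", lesion_id="par1",
            interval=human_ref.locus("PAR1"), copies=1,
        )
        track, profile = profile_for(human_ref, SimKaryotype.diploid(human_ref, 0.9), [lesion])
        cnas, fusions = detect_focal_cna(track, profile)
        assert any(c.locus == "PAR1" and c.type == "deletion" for c in cnas)
        assert "P2RY8::CRLF2" in fusions

    def test_untouched_loci_silent(self, human_ref):
        track, profile = profile_for(human_ref, SimKaryotype.diploid(human_ref, 1.0))
        cnas, fusions = detect_focal_cna(track, profile)
        assert cnas == []
        assert fusions == []


class TestCnnLoh:
    def baf_and_track(self, human_ref, lesions, f=0.9, karyotype=None):
        kt = karyotype or SimKaryotype.diploid(human_ref, f)
        truth = TruthManifest("p", kt, lesions, seed=9, target_mean_coverage=30.0)
        baf = emit_baf_table(human_ref, truth, sites_per_chrom=30, depth=30)
        track, _ = profile_for(human_ref, kt, lesions)
        return baf, track

    def test_upd_chromosome_flagged(self, human_ref):
        upd = PlantedLesion(
            kind="upd", lesion_id="upd14",
            interval=GenomicInterval("chr14", 0, human_ref.chrom_length("chr14")),
        )
        baf, track = self.baf_and_track(human_ref, [upd])
        findings = detect_cnnloh(baf, track)
        assert any(iv.chrom == "chr14" and kind == "UPD" for iv, kind in findings)

    def test_normal_chromosomes_silent(self, human_ref):
        baf, track = self.baf_and_track(human_ref, [])
        assert detect_cnnloh(baf, track) == []

    def test_monosomy_not_reported_as_cnnloh(self, human_ref):
        """A lost chromosome shifts BAF too, but its depth is not neutral."""
        copies = {c: 2 for c in human_ref.chrom_names}
        copies["chr5"] = 1
        kt = SimKaryotype(copies, 0.9)
        baf, track = self.baf_and_track(human_ref, [], karyotype=kt)
        assert all(iv.chrom != "chr5" for iv, _ in detect_cnnloh(baf, track))

    def test_unpaired_mode_is_signalled(self, human_ref):
        _, track = self.baf_and_track(human_ref, [])
        with pytest.raises(ValueError, match="paired germline"):
            detect_cnnloh(None, track)


class TestExpectedLog2:
    def test_pure_tumor_levels(self):
        assert expected_log2(2, 1.0) == 0.0
        assert expected_log2(3, 1.0) == pytest.approx(math.log2(1.5))
        assert expected_log2(3, 0.5) == pytest.approx(math.log2(1.25))
        assert expected_log2(0, 1.0) <= -5.0
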