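"""SV filtration cascade: stage semantics, ordering, oracle equivalence."""

import pytest
from hypothesis import given, settings, strategies as st

from ball_subtyper.intervals import GenomicInterval, ShortlistEntry
from ball_subtyper.simulate import (
    PlantedLesion,
    SimKaryotype,
    TruthManifest,
    emit_germline_set,
    emit_sv_vcf,
)
from ball_subtyper.svcalls import Breakpoint, SVCall, dedup_calls
from ball_subtyper.svfilter import (
    CascadeConfig,
    filter_artifact_db,
    filter_population_frequency,
    intersect_shortlist,
    name_fusion,
    run_cascade,
    subtract_germline,
)


def call(cid="c1", typ="BND", bp1=("chr1", 1000), bp2=("chr2", 2000),
         af=None, art=None):
    return SVCall(
        id=cid, type=typ,
        breakpoint_1=Breakpoint(*bp1), breakpoint_2=Breakpoint(*bp2),
        population_af=af, artifact_freq=art,
    )


SHORTLIST = [
    ShortlistEntry("ETV6", GenomicInterval("chr12", 100_000, 150_000), "+", 5_000),
    ShortlistEntry("RUNX1", GenomicInterval("chr21", 300_000, 400_000), "+", 5_000),
    ShortlistEntry("REVG", GenomicInterval("chr2", 500_000, 550_000), "-", 5_000),
]


class TestFrequencyFilters:
    @pytest.mark.parametrize(
        "af,kept", [(0.03, False), (0.02, True), (0.019, True), (None, True)]
    )
    def test_population_threshold_is_strictly_above(self, af, kept):
        calls = [call(af=af)]
        k, d = filter_population_frequency(calls)
        assert (len(k) == 1) is kept
        assert len(k) + len(d) == 1

    @pytest.mark.parametrize("art,kept", [(0.5, False), (0.01, True), (None, True)])
    def test_artifact_db_same_rule(self, art, kept):
        k, d = filter_artifact_db([call(art=art)])
        assert (len(k) == 1) is kept

    def test_frequency_and_artifact_filters_commute(self):
        calls = [
            call(f"c{i}", af=af, art=art)
            for i, (af, art) in enumerate(
                [(None, None), (0.5, None), (None, 0.5), (0.01, 0.01), (0.5, 0.5)]
            )
        ]
        ab = filter_artifact_db(filter_population_frequency(calls)[0])[0]
        ba = filter_population_frequency(filter_artifact_db(calls)[0])[0]
        assert [c.id for c in ab] == [c.id for c in ba]

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_population_frequency([], threshold=1.5)


class TestGermlineSubtraction:
    def test_identical_translocation_dropped_with_shortlist_warning(self):
        leuk = [call("L1", bp1=("chr12", 120_000), bp2=("chr21", 350_000))]
        germ = [call("G1", bp1=("chr12", 120_300), bp2=("chr21", 349_800))]
        kept, dropped, warnings = subtract_germline(leuk, germ, shortlist=SHORTLIST)
        assert kept == []
        assert [c.id for c in dropped] == ["L1"]
        assert len(warnings) == 1 and "residual" in warnings[0]

    def test_leukemia_only_call_kept(self):
        leuk = [call("L1", typ="DEL", bp1=("chr1", 1000), bp2=("chr1", 5000))]
        kept, dropped, warnings = subtract_germline(leuk, [])
        assert [c.id for c in kept] == ["L1"]
        assert warnings == []

    def test_same_breakpoints_different_type_not_matched(self):
        leuk = [call("L1", typ="DEL", bp1=("chr1", 1000), bp2=("chr1", 5000))]
        germ = [call("G1", typ="DUP", bp1=("chr1", 1000), bp2=("chr1", 5000))]
        kept, dropped, _ = subtract_germline(leuk, germ)
        assert [c.id for c in kept] == ["L1"]

    def test_window_boundary(self):
        leuk = [call("L1", bp1=("chr1", 1000), bp2=("chr2", 2000))]
        near = [call("G1", bp1=("chr1", 2000), bp2=("chr2", 3000))]
        far = [call("G2", bp1=("chr1", 2001), bp2=("chr2", 2000))]
        assert subtract_germline(leuk, near, window=1000)[0] == []
        assert len(subtract_germline(leuk, far, window=1000)[0]) == 1


class TestShortlistIntersection:
    def test_breakpoint_3kb_upstream_kept_by_pad(self):
        c = call("up", bp1=("chr12", 97_000), bp2=("chr5", 1_000))
        kept, _ = intersect_shortlist([c], SHORTLIST)
        assert kept and kept[0].gene_context == ["ETV6"]

    def test_breakpoint_12kb_upstream_dropped(self):
        c = call("far", bp1=("chr12", 88_000), bp2=("chr5", 1_000))
        kept, dropped = intersect_shortlist([c], SHORTLIST)
        assert kept == [] and len(dropped) == 1

    def test_breakpoint_in_gene_body_kept(self):
        c = call("body", bp1=("chr21", 350_000), bp2=("chr5", 1_000))
        kept, _ = intersect_shortlist([c], SHORTLIST)
        assert kept[0].gene_context == ["RUNX1"]

    def test_reverse_strand_pad_extends_downstream_coordinate(self):
        # upstream of a '-' gene = higher coordinates
        c = call("rev", bp1=("chr2", 553_000), bp2=("chr5", 1_000))
        kept, _ = intersect_shortlist([c], SHORTLIST)
        assert kept[0].gene_context == ["REVG"]
        c2 = call("rev2", bp1=("chr2", 497_000), bp2=("chr5", 1_000))
        assert intersect_shortlist([c2], SHORTLIST)[0] == []

    def test_empty_shortlist_is_configuration_error(self):
        with pytest.raises(ValueError):
            intersect_shortlist([call()], [])


class TestFusionNaming:
    def test_two_gene_fusion_label(self):
        c = call("f", bp1=("chr12", 120_000), bp2=("chr21", 350_000))
        assert name_fusion(c, SHORTLIST) == "ETV6::RUNX1"

    def test_single_side_hit_gets_rearranged_label_with_partner_coords(self):
        c = call("f", bp1=("chr12", 120_000), bp2=("chr5", 42_000))
        assert name_fusion(c, SHORTLIST) == "ETV6-r(chr5:42001)"

    def test_intragenic_deletion_is_not_a_fusion(self):
        c = call("d", typ="DEL", bp1=("chr21", 310_000), bp2=("chr21", 330_000))
        assert name_fusion(c, SHORTLIST) is None

    def test_no_shortlist_hit_gives_none(self):
        c = call("n", bp1=("chr5", 1_000), bp2=("chr6", 1_000))
        assert name_fusion(c, SHORTLIST) is None


def brute_force_cascade(calls, germline, shortlist, cfg):
    """Independent conjunction-of-predicates oracle for the kept set."""
    trees = [(e, e.padded_interval()) for e in shortlist]
    out = []
    for c in calls:
        if c.population_af is not None and c.population_af > cfg.af_threshold:
            continue
        if c.artifact_freq is not None and c.artifact_freq > cfg.artifact_threshold:
            continue
        if germline is not None and cfg.paired:
            matched = False
            for g in germline:
                if g.type != c.type:
                    continue
                pairs = [
                    (c.breakpoint_1, g.breakpoint_1, c.breakpoint_2, g.breakpoint_2),
                    (c.breakpoint_1, g.breakpoint_2, c.breakpoint_2, g.breakpoint_1),
                ]
                for a1, b1, a2, b2 in pairs:
                    if (
                        a1.chrom == b1.chrom and abs(a1.pos - b1.pos) <= cfg.germline_window
                        and a2.chrom == b2.chrom and abs(a2.pos - b2.pos) <= cfg.germline_window
                    ):
                        matched = True
            if matched:
                continue
        hit = any(
            iv.contains(bp.chrom, bp.pos)
            for _, iv in trees
            for bp in c.breakpoints
        )
        if hit:
            out.append(c.id)
    return out


class TestCascade:
    def planted_truth(self, mini_ref):
        lesions = [
            PlantedLesion(kind="translocation", lesion_id="etv6_runx1",
                          breakpoint_1=("chrA", 25_000), breakpoint_2=("chrB", 25_000)),
            PlantedLesion(kind="translocation", lesion_id="bcr_abl1",
                          breakpoint_1=("chrD", 25_000), breakpoint_2=("chrC", 105_000)),
            PlantedLesion(kind="deletion", lesion_id="pax5_del",
                          interval=mini_ref.locus("PAX5"), copies=1),
        ]
        return TruthManifest("cascade", SimKaryotype.diploid(mini_ref), lesions,
                             seed=31, target_mean_coverage=30.0)

    def test_kept_set_matches_brute_force_oracle_with_1000_decoys(self, mini_ref):
        truth = self.planted_truth(mini_ref)
        calls = emit_sv_vcf(truth, mini_ref, background=1000, avoid_shortlist=False)
        shortlist = mini_ref.shortlist_entries()
        cfg = CascadeConfig(paired=False)
        kept, report = run_cascade(calls, None, shortlist, cfg)
        oracle = brute_force_cascade(calls, None, shortlist, cfg)
        assert sorted(c.id for c in kept) == sorted(oracle)
        planted = {c.id for c in kept if c.id.startswith("planted_")}
        assert planted == {"planted_etv6_runx1", "planted_bcr_abl1", "planted_pax5_del"}

    def test_counts_monotone_and_ledger_conserving(self, mini_ref):
        truth = self.planted_truth(mini_ref)
        calls = emit_sv_vcf(truth, mini_ref, background=500)
        germ = emit_germline_set(truth, calls, shared_fraction=0.5)
        kept, report = run_cascade(
            calls, germ, mini_ref.shortlist_entries(), CascadeConfig(paired=True)
        )
        counts = list(report.stage_counts.values())
        assert counts == sorted(counts, reverse=True)
        # dropped + kept reconstructs every stage transition
        stages = list(report.stage_counts)
        for prev, cur in zip(stages, stages[1:]):
            n_dropped = sum(1 for _, stage, _ in report.dropped if stage == cur)
            assert report.stage_counts[prev] - n_dropped == report.stage_counts[cur]

    def test_l_only_equals_paired_on_germline_free_input(self, mini_ref):
        truth = self.planted_truth(mini_ref)
        calls = emit_sv_vcf(truth, mini_ref, background=300)
        shortlist = mini_ref.shortlist_entries()
        only, _ = run_cascade(calls, None, shortlist, CascadeConfig(paired=False))
        paired, _ = run_cascade(calls, [], shortlist, CascadeConfig(paired=True))
        assert [c.id for c in only] == [c.id for c in paired]

    def test_driver_in_germline_lost_in_paired_mode_with_warning(self, mini_ref):
        """Residual disease in the paired sample silently subtracts the true
        driver; leukemia-only analysis still reports it."""
        truth = self.planted_truth(mini_ref)
        calls = emit_sv_vcf(truth, mini_ref, background=100)
        germ = emit_germline_set(
            truth, calls, shared_fraction=0.3, residual_lesion_ids=("etv6_runx1",)
        )
        shortlist = mini_ref.shortlist_entries()
        paired, report = run_cascade(calls, germ, shortlist, CascadeConfig(paired=True))
        only, _ = run_cascade(calls, None, shortlist, CascadeConfig(paired=False))
        assert "planted_etv6_runx1" not in {c.id for c in paired}
        assert "planted_etv6_runx1" in {c.id for c in only}
        assert any("residual" in w for w in report.warnings)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        afs=st.lists(
            st.one_of(st.none(), st.floats(0, 0.5, allow_nan=False)), min_size=0, max_size=40
        ),
        seed=st.integers(0, 10),
    )
    def test_cascade_never_invents_calls(self, afs, seed):
        calls = [
            call(f"c{i}", af=af,
                 bp1=("chr12", 100_000 + 997 * i * (seed + 1) % 400_000),
                 bp2=("chr21", 300_000 + 131 * i % 200_000))
            for i, af in enumerate(afs)
        ]
        kept, report = run_cascade(calls, None, SHORTLIST, CascadeConfig(paired=False))
        in_ids = {c.id for c in calls}
        assert {c.id for c in kept} <= in_ids
        assert report.stage_counts["raw"] == len(calls)


class TestDedup:
    def test_nearby_same_type_calls_merged_first_wins(self):
        a = call("first", bp1=("chr1", 1000), bp2=("chr2", 2000))
        b = call("dup", bp1=("chr1", 1030), bp2=("chr2", 2040))
        c = call("other", typ="DEL", bp1=("chr1", 1000), bp2=("chr1", 2000))
        assert [x.id for x in dedup_calls([a, b, c])] == ["first", "other"]
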