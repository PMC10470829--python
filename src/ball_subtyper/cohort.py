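"""Synthetic 12-sample validation cohort.

One sample per subgroup the pipeline must recover — the eight mandatory
subgroups (HeH, HoL, ETV6::RUNX1, TCF3::PBX1, Ph-positive, KMT2A-r,
ABL-class, iAMP21) and four emerging ones (CRLF2-r, PAX5-alt, ZNF384-r,
DUX4-r) — over the 23-chromosome miniature reference.  Conditions follow
the validation study's hardest printed cases: the ETV6::RUNX1 sample is
planted at tumor fraction 0.37 and the KMT2A::AFF1 sample at 0.14 (the
lowest blast counts in the cohort); the DUX4 sample carries an isolated
ERG deletion plus 126 targeted-fusion support pairs, so its subgroup is
reachable only through the targeted assay.
"""

from __future__ import annotations

from dataclasses import dataclass

from .downsample import downsample_every_third
from .fragments import AlignmentSet
from .intervals import GenomicInterval
from .reference import ToyReference, human_like_reference
from .simulate import (
    PlantedLesion,
    SimKaryotype,
    TruthManifest,
    emit_sv_vcf,
    karyotype_for_count,
    simulate_fragments,
)
from .workflow import SampleReport, WorkflowConfig, run_sample


@dataclass
class CohortSample:
    sample_id: str
    truth: TruthManifest
    expected_primary: str
    purity: float


def _bp(ref: ToyReference, gene: str, offset: int | None = None) -> tuple[str, int]:
    iv = ref.locus(gene)
    pos = (iv.start + iv.end) // 2 if offset is None else iv.start + offset
    return (iv.chrom, pos)


def _fusion(ref: ToyReference, lesion_id: str, gene5: str, gene3: str,
            pos3: tuple[str, int] | None = None) -> PlantedLesion:
    return PlantedLesion(
        kind="translocation",
        lesion_id=lesion_id,
        breakpoint_1=_bp(ref, gene5),
        breakpoint_2=pos3 if pos3 is not None else _bp(ref, gene3),
        genes=(gene5, gene3),
    )


def build_demo_cohort(
    seed: int, coverage: float = 90.0, ref: ToyReference | None = None
) -> tuple[ToyReference, list[CohortSample]]:
    """The 12 truth manifests; per-sample seeds derive from ``seed``."""
    ref = ref or human_like_reference()

    def kt(count: int, f: float) -> SimKaryotype:
        return karyotype_for_count(ref, count, tumor_fraction=f)

    def truth(i: int, sid: str, karyotype: SimKaryotype, lesions: list[PlantedLesion]) -> TruthManifest:
        return TruthManifest(
            sample_id=sid,
            karyotype=karyotype,
            lesions=lesions,
            seed=(seed * 1_000 + i) % (2**31),
            target_mean_coverage=coverage,
        )

    erg = ref.locus("ERG")
    pax5 = ref.locus("PAX5")
    chr21_len = ref.chrom_length("chr21")
    iamp_iv = GenomicInterval("chr21", int(chr21_len * 0.15), int(chr21_len * 0.5))

    samples = [
        CohortSample("S_HeH", truth(1, "S_HeH", kt(55, 0.9), []), "HeH", 0.9),
        CohortSample("S_HoL", truth(2, "S_HoL", kt(35, 0.85), []), "HoL", 0.85),
        CohortSample(
            "S_ETV6_RUNX1",
            truth(3, "S_ETV6_RUNX1", kt(46, 0.37),
                  [_fusion(ref, "t12_21", "ETV6", "RUNX1")]),
            "ETV6::RUNX1", 0.37,
        ),
        CohortSample(
            "S_TCF3_PBX1",
            truth(4, "S_TCF3_PBX1", kt(46, 0.9),
                  [_fusion(ref, "t1_19", "TCF3", "PBX1")]),
            "TCF3::PBX1", 0.9,
        ),
        CohortSample(
            "S_Ph",
            truth(5, "S_Ph", kt(46, 0.9), [_fusion(ref, "t9_22", "BCR", "ABL1")]),
            "Ph-positive", 0.9,
        ),
        CohortSample(
            "S_KMT2A",
            truth(6, "S_KMT2A", kt(46, 0.14),
                  [_fusion(ref, "t4_11", "KMT2A", "AFF1")]),
            "KMT2A-r", 0.14,
        ),
        CohortSample(
            "S_ABL_class",
            # breakpoint 3 kb upstream of ABL1: retained only by the
            # strand-aware 5 kb upstream pad of the shortlist filter
            truth(7, "S_ABL_class", kt(46, 0.9),
                  [_fusion(ref, "ranbp2_abl1", "RANBP2", "ABL1",
                           pos3=(ref.locus("ABL1").chrom, ref.locus("ABL1").start - 3_000))]),
            "ABL-class", 0.9,
        ),
        CohortSample(
            "S_iAMP21",
            truth(8, "S_iAMP21", kt(46, 0.9),
                  [PlantedLesion(kind="tandem_amplification", lesion_id="iamp21",
                                 interval=iamp_iv, copies=6)]),
            "iAMP21", 0.9,
        ),
        CohortSample(
            "S_CRLF2",
            truth(9, "S_CRLF2", kt(46, 0.9),
                  [_fusion(ref, "igh_crlf2", "IGH", "CRLF2"),
                   PlantedLesion(kind="deletion", lesion_id="pax5_del",
                                 interval=pax5, copies=1)]),
            "CRLF2-r", 0.9,
        ),
        CohortSample(
            "S_PAX5alt",
            truth(10, "S_PAX5alt", kt(46, 0.9),
                  [PlantedLesion(kind="deletion", lesion_id="pax5_del",
                                 interval=pax5, copies=1)]),
            "PAX5-alt", 0.9,
        ),
        CohortSample(
            "S_ZNF384",
            truth(11, "S_ZNF384", kt(46, 0.9),
                  [_fusion(ref, "tcf3_znf384", "TCF3", "ZNF384")]),
            "ZNF384-r", 0.9,
        ),
        CohortSample(
            "S_DUX4",
            truth(12, "S_DUX4", kt(46, 0.9),
                  [PlantedLesion(kind="deletion", lesion_id="erg_del",
                                 interval=erg, copies=1),
                   PlantedLesion(kind="targeted_fusion", lesion_id="igh_dux4",
                                 support_pairs=126)]),
            "DUX4-r", 0.9,
        ),
    ]
    return ref, samples


def run_cohort_sample(
    ref: ToyReference,
    sample: CohortSample,
    downsample: bool = False,
    background: int = 400,
) -> SampleReport:
    """Simulate, optionally down-sample to ~1/3 coverage, and analyse."""
    aset = simulate_fragments(ref, sample.truth)
    if downsample:
        aset = downsample_every_third(aset)
    sv_calls = emit_sv_vcf(sample.truth, ref, background=background)
    config = WorkflowConfig(purity=sample.purity, mode="L_only")
    return run_sample(config, aset, sv_calls, sample_id=sample.sample_id)
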