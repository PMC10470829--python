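"""Targeted discordant-read fusion detection for repetitive loci.

DUX4 sits inside the D4Z4 macrosatellite (with a homologous array on
10q26), so an IGH::DUX4 junction produces reads whose far side maps
ambiguously across the array copies — genome-wide SV callers miss it.  The
targeted detector instead (1) collects fragments with a primary read inside
the IGH anchor region that are discordant, then (2) keeps those that either
have their mate's primary alignment inside one of the multi-copy target
regions, or carry a secondary alignment there.  The supporting-pair count
separates positives (tens to hundreds of pairs) from negatives (single
digits) cleanly; the default calling threshold of 10 pairs sits in that gap.

Also implements the two-site SNV pileup assay (PAX5 P80R, IKZF1 N159Y
analogs) at fragment level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fragments import AlignmentSet
from .intervals import GenomicInterval
from .reference import DUX4_TARGETS_GRCH37, IGH_ANCHOR_GRCH37  # noqa: F401 (shipped defaults)

DEFAULT_FUSION_THRESHOLD = 10  # supporting pairs; positives >=31, negatives <=6


@dataclass
class DiscordantEvidence:
    anchor: GenomicInterval
    targets: list[GenomicInterval]
    supporting_pair_count: int
    supporting_fragment_ids: list[int]
    mechanism_breakdown: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.supporting_pair_count != len(self.supporting_fragment_ids):
            raise ValueError("count must equal number of supporting fragments")


@dataclass
class FusionCall:
    name: str
    evidence: DiscordantEvidence
    status: str  # positive / negative
    threshold_used: int

    @property
    def positive(self) -> bool:
        return self.status == "positive"


@dataclass
class SNVSite:
    chrom: str
    pos: int  # 1-based, as printed in variant nomenclature
    ref: str
    alt: str
    label: str  # e.g. "PAX5 P80R"


@dataclass
class SNVCall:
    site: SNVSite
    depth: int
    alt_count: int
    verdict: str  # detected / not_detected / insufficient_depth

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0


def _read_in_interval(chrom, start, read_len: int, iv: GenomicInterval):
    return (chrom == iv.chrom) & (start < iv.end) & (start + read_len > iv.start)


def extract_anchor_discordant(
    alignments: AlignmentSet,
    anchor: GenomicInterval,
    min_mapq: int = 0,
) -> AlignmentSet:
    """Fragments with >= 1 primary read inside the anchor that are discordant.

    Discordant means: not flagged proper pair, or mate on another
    chromosome, or |insert| beyond mean + 4 sd.  ``min_mapq`` defaults to 0
    because the repetitive far side forces low mapping quality; the filter
    is by region, not quality.
    """
    if anchor.chrom not in alignments.reference.chrom_names:
        raise ValueError(f"anchor chromosome {anchor.chrom!r} not in reference")
    df = alignments.fragments
    rl = alignments.read_len
    s1 = df["start1"].to_numpy()
    s2 = df["start2"].to_numpy()
    on1 = (df["chrom1"] == anchor.chrom).to_numpy()
    on2 = (df["chrom2"] == anchor.chrom).to_numpy()
    in_anchor = (
        (on1 & (s1 < anchor.end) & (s1 + rl > anchor.start)
         & (df["mapq1"].to_numpy() >= min_mapq))
        | (on2 & (s2 < anchor.end) & (s2 + rl > anchor.start)
           & (df["mapq2"].to_numpy() >= min_mapq))
    )
    insert_bound = alignments.insert_mean + 4.0 * alignments.insert_sd
    same_chrom = (df["chrom1"].cat.codes == df["chrom2"].cat.codes).to_numpy()
    insert = np.abs(np.maximum(s1, s2) + rl - np.minimum(s1, s2))
    discordant = (
        ~df["proper"].to_numpy()
        | ~same_chrom
        | (same_chrom & (insert > insert_bound))
    )
    return alignments.subset(in_anchor & discordant)


def count_target_links(
    candidates: AlignmentSet,
    targets: list[GenomicInterval],
    anchor: GenomicInterval | None = None,
) -> DiscordantEvidence:
    """Count candidate fragments linked to any target region.

    A fragment qualifies if its mate's primary alignment overlaps a target
    (clause i) or it carries a secondary alignment overlapping a target
    (clause ii).  Each fragment is counted once even if both clauses apply;
    the mechanism breakdown attributes such fragments to the mate clause.
    """
    df = candidates.fragments
    rl = candidates.read_len
    n = len(df)
    mate_hit = np.zeros(n, dtype=bool)
    sa_hit = np.zeros(n, dtype=bool)
    c1 = df["chrom1"].to_numpy()
    c2 = df["chrom2"].to_numpy()
    s1 = df["start1"].to_numpy()
    s2 = df["start2"].to_numpy()
    sa_c = df["sa_chrom"].to_numpy()
    sa_s = df["sa_start"].to_numpy()
    has_sa = df["sa_read"].to_numpy() > 0
    for iv in targets:
        mate_hit |= _read_in_interval(c1, s1, rl, iv) | _read_in_interval(c2, s2, rl, iv)
        sa_hit |= has_sa & (sa_c == iv.chrom) & (sa_s < iv.end) & (sa_s + rl > iv.start)
    supported = mate_hit | sa_hit
    frag_ids = sorted(int(i) for i in df.loc[supported, "frag_id"])
    return DiscordantEvidence(
        anchor=anchor,
        targets=list(targets),
        supporting_pair_count=int(supported.sum()),
        supporting_fragment_ids=frag_ids,
        mechanism_breakdown={
            "mate_in_target": int(mate_hit.sum()),
            "secondary_in_target": int((sa_hit & ~mate_hit).sum()),
        },
    )


def call_targeted_fusion(
    evidence: DiscordantEvidence,
    threshold: int = DEFAULT_FUSION_THRESHOLD,
    name: str = "IGH::DUX4",
) -> FusionCall:
    """Positive iff the supporting-pair count reaches the threshold."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    status = "positive" if evidence.supporting_pair_count >= threshold else "negative"
    return FusionCall(name=name, evidence=evidence, status=status, threshold_used=threshold)


def detect_targeted_fusion(
    alignments: AlignmentSet,
    anchor: GenomicInterval,
    targets: list[GenomicInterval],
    threshold: int = DEFAULT_FUSION_THRESHOLD,
    min_mapq: int = 0,
    name: str = "IGH::DUX4",
) -> FusionCall:
    """Full targeted assay: extract anchor discordants, link, call."""
    candidates = extract_anchor_discordant(alignments, anchor, min_mapq=min_mapq)
    evidence = count_target_links(candidates, targets, anchor=anchor)
    return call_targeted_fusion(evidence, threshold=threshold, name=name)


def snv_pileup_assay(
    alignments: AlignmentSet,
    site: SNVSite,
    min_depth: int = 10,
    min_vaf: float = 0.05,
    min_baseq: int = 20,
) -> SNVCall:
    """Fragment-level pileup at a targeted SNV site.

    Depth counts fragments with >= 1 read covering the position (overlapping
    mates count once, i.e. duplicate-aware overlap handling); alt counts come
    from the per-fragment allele annotation.  ``min_baseq`` is accepted for
    interface parity but has no effect on synthetic data, which carries no
    base qualities.
    """
    ref = alignments.reference
    if site.chrom not in ref.chrom_names:
        raise ValueError(f"SNV site chromosome {site.chrom!r} not in reference")
    pos0 = site.pos - 1
    if not (0 <= pos0 < ref.chrom_length(site.chrom)):
        raise ValueError(f"SNV site {site.label} position off reference")
    df = alignments.fragments
    rl = alignments.read_len
    cover = (
        ((df["chrom1"] == site.chrom) & (df["start1"] <= pos0) & (pos0 < df["start1"] + rl))
        | ((df["chrom2"] == site.chrom) & (df["start2"] <= pos0) & (pos0 < df["start2"] + rl))
    )
    depth = int(cover.sum())
    alt_count = int((cover & (df["snv_site"] == site.label) & df["snv_alt"]).sum())
    if depth < min_depth:
        verdict = "insufficient_depth"
    elif depth > 0 and alt_count / depth >= min_vaf and alt_count > 0:
        verdict = "detected"
    else:
        verdict = "not_detected"
    return SNVCall(site=site, depth=depth, alt_count=alt_count, verdict=verdict)
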