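"""Binned log2-ratio copy-number profiling and ploidy-class calling.

The track mimics the CGH-style display used for WGS aneuploidy review:
fragment starts are binned (default 1 kb), 20 bins are pooled into one
probe, and each probe's value is the log2 ratio of its mean bin count to
the genome-wide mean ("the diploid line is drawn at height 0").  For
aneuploid genomes the genome-wide mean is *not* the disomic level, so the
baseline is re-centred automatically on the modal cluster of per-chromosome
medians (the manual threshold adjustment of the original workflow,
automated and logged).

Copy states invert the depth law: at tumor fraction f a chromosome at copy
number c sits at log2((2(1-f) + c*f)/2) relative to the disomic baseline.
Ploidy classes follow clinical modal-number ranges; the HeH / near-triploid
overlap (58-67 chromosomes) resolves to HeH unless a duplicated-hypodiploid
signature is flagged, in which case the call is ambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragments import AlignmentSet
from .intervals import GenomicInterval
from .reference import ToyReference, UKALL_CNA_LOCI

#: Modal chromosome-number ranges for ploidy classes (inclusive).
PLOIDY_RANGES = {
    "near_haploid": (0, 29),
    "HoL": (30, 39),
    "diploid_range": (40, 50),
    "HeH": (51, 67),
    "near_triploid": (58, 80),
    "near_tetraploid": (81, 103),
}


@dataclass
class BinTrack:
    bin_size: int
    counts: dict[str, np.ndarray]  # chrom -> per-bin fragment counts
    reference: ToyReference

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be > 0")

    @property
    def total_count(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))


@dataclass
class Probe:
    interval: GenomicInterval
    log2_ratio: float  # NaN for masked zero-coverage probes


@dataclass
class ProbeTrack:
    probes: list[Probe]
    probe_pool_size: int
    bin_size: int
    reference: ToyReference
    baseline_offset: float = 0.0
    baseline_ambiguous: bool = False

    def chrom_values(self, chrom: str) -> np.ndarray:
        return np.array(
            [p.log2_ratio for p in self.probes if p.interval.chrom == chrom]
        )

    def chrom_median(self, chrom: str) -> float:
        vals = self.chrom_values(chrom)
        vals = vals[np.isfinite(vals)]
        return float(np.median(vals)) if len(vals) else math.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [p.interval.chrom for p in self.probes],
                "start": [p.interval.start for p in self.probes],
                "end": [p.interval.end for p in self.probes],
                "log2": [p.log2_ratio for p in self.probes],
            }
        )

    def write_bedgraph(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", header=False, index=False)


@dataclass
class CopyStateProfile:
    per_chromosome_state: dict[str, int]
    segment_states: list[tuple[GenomicInterval, int]]
    purity_assumed: float
    baseline_ambiguous: bool = False

    @property
    def chromosome_count(self) -> int:
        return sum(self.per_chromosome_state.values())


@dataclass
class PloidyClass:
    label: str
    chromosome_count: int
    rationale: str = ""


@dataclass
class CNALesion:
    locus: str
    type: str  # deletion / amplification
    extent: GenomicInterval
    biallelic: bool = False
    copy_state: int | None = None
    exons: str | None = None


# ---------------------------------------------------------------------------


def bin_depth(alignments: AlignmentSet, bin_size: int = 1_000) -> BinTrack:
    """Count fragments by the bin holding their leftmost mapped base."""
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    ref = alignments.reference
    left = alignments.fragment_leftmost()
    codes = left["chrom"].cat.codes.to_numpy()
    pos_all = left["pos"].to_numpy()
    counts: dict[str, np.ndarray] = {}
    for code, (chrom, length) in enumerate(ref.chromosomes):
        n_bins = math.ceil(length / bin_size)
        pos = pos_all[codes == code] // bin_size
        counts[chrom] = np.bincount(pos, minlength=n_bins).astype("int64")[:n_bins]
    return BinTrack(bin_size=bin_size, counts=counts, reference=ref)


def pool_probes(bins: BinTrack, pool_size: int = 20) -> ProbeTrack:
    """Pool consecutive bins into probes; probe value is the log2 ratio of
    the probe's mean bin count to the genome-wide mean bin count."""
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    all_counts = np.concatenate([c for c in bins.counts.values()])
    genome_mean = all_counts.mean() if len(all_counts) else 0.0
    if genome_mean <= 0:
        raise ValueError("all-zero bin track: no baseline to normalize against")
    probes: list[Probe] = []
    for chrom, counts in bins.counts.items():
        for i in range(0, len(counts), pool_size):
            chunk = counts[i : i + pool_size]
            start = i * bins.bin_size
            end = min((i + len(chunk)) * bins.bin_size, bins.reference.chrom_length(chrom))
            mean = chunk.mean()
            value = math.log2(mean / genome_mean) if mean > 0 else math.nan
            probes.append(Probe(GenomicInterval(chrom, start, end), value))
    return ProbeTrack(
        probes=probes,
        probe_pool_size=pool_size,
        bin_size=bins.bin_size,
        reference=bins.reference,
    )


def recenter_baseline(track: ProbeTrack, cluster_tol: float = 0.1) -> ProbeTrack:
    """Re-centre the diploid baseline on the modal cluster of chromosomes.

    The offset is the length-weighted centre of the per-chromosome-median
    cluster carrying the largest chromosome mass within ``cluster_tol``
    log2 units; ties break toward the cluster nearest 0.  If every
    chromosome sits in its own cluster the track is flagged ambiguous and
    the offset stays 0.
    """
    ref = track.reference
    medians = {c: track.chrom_median(c) for c in ref.chrom_names}
    lengths = {c: ref.chrom_length(c) for c in ref.chrom_names}
    valid = {c: m for c, m in medians.items() if math.isfinite(m)}
    if not valid:
        raise ValueError("no finite chromosome medians")
    best_mass, best_offset, best_members = -1.0, 0.0, 0
    for c0, m0 in valid.items():
        members = [c for c, m in valid.items() if abs(m - m0) <= cluster_tol]
        mass = sum(lengths[c] for c in members)
        offset = sum(medians[c] * lengths[c] for c in members) / mass
        if mass > best_mass or (
            mass == best_mass and abs(offset) < abs(best_offset)
        ):
            best_mass, best_offset, best_members = mass, offset, len(members)
    ambiguous = best_members <= 1 and len(valid) > 1
    offset = 0.0 if ambiguous else best_offset
    probes = [
        Probe(p.interval, p.log2_ratio - offset if math.isfinite(p.log2_ratio) else p.log2_ratio)
        for p in track.probes
    ]
    return ProbeTrack(
        probes=probes,
        probe_pool_size=track.probe_pool_size,
        bin_size=track.bin_size,
        reference=track.reference,
        baseline_offset=track.baseline_offset + offset,
        baseline_ambiguous=ambiguous,
    )


def expected_log2(c: int, purity: float) -> float:
    """Depth-law level for integer copy state c at the given tumor purity."""
    w = (2.0 * (1.0 - purity) + c * purity) / 2.0
    return math.log2(w) if w > 0 else -5.0


def _nearest_state(value: float, purity: float, max_state: int = 8) -> int:
    levels = np.array([expected_log2(c, purity) for c in range(max_state + 1)])
    return int(np.argmin(np.abs(levels - value)))


def call_copy_states(
    track: ProbeTrack,
    purity: float,
    max_state: int = 8,
    min_segment_probes: int = 3,
) -> CopyStateProfile:
    """Per-chromosome copy states by inverting the depth law, plus
    sub-chromosomal segments from runs of >= ``min_segment_probes``
    consecutive probes assigned to a different state."""
    if not (0.0 < purity <= 1.0):
        raise ValueError("purity must lie in (0, 1]; 0 carries no tumor signal")
    states: dict[str, int] = {}
    segments: list[tuple[GenomicInterval, int]] = []
    for chrom in track.reference.chrom_names:
        med = track.chrom_median(chrom)
        if not math.isfinite(med):
            states[chrom] = 2
            continue
        chrom_state = _nearest_state(med, purity, max_state)
        states[chrom] = chrom_state
        chrom_probes = [p for p in track.probes if p.interval.chrom == chrom]
        run: list[Probe] = []
        run_state: int | None = None

        def flush() -> None:
            if run_state is not None and run_state != chrom_state and len(run) >= min_segment_probes:
                segments.append(
                    (
                        GenomicInterval(chrom, run[0].interval.start, run[-1].interval.end),
                        run_state,
                    )
                )

        for p in chrom_probes:
            if not math.isfinite(p.log2_ratio):
                flush()
                run, run_state = [], None
                continue
            s = _nearest_state(p.log2_ratio, purity, max_state)
            if s == run_state:
                run.append(p)
            else:
                flush()
                run, run_state = [p], s
        flush()
    return CopyStateProfile(
        per_chromosome_state=states,
        segment_states=segments,
        purity_assumed=purity,
        baseline_ambiguous=track.baseline_ambiguous,
    )


def classify_ploidy(
    profile: CopyStateProfile,
    duplicated_hypodiploid_flag: bool = False,
) -> PloidyClass:
    """Map the chromosome count to a clinical ploidy class."""
    n = profile.chromosome_count
    heh_lo, heh_hi = PLOIDY_RANGES["HeH"]
    tri_lo, tri_hi = PLOIDY_RANGES["near_triploid"]
    if heh_lo <= n <= heh_hi:
        if n >= tri_lo and duplicated_hypodiploid_flag:
            return PloidyClass(
                "ambiguous", n,
                "count in HeH/near-triploid overlap with duplicated-hypodiploid signature",
            )
        return PloidyClass("HeH", n, f"modal number {n} in {heh_lo}-{heh_hi}")
    for label in ("near_haploid", "HoL", "diploid_range", "near_triploid", "near_tetraploid"):
        lo, hi = PLOIDY_RANGES[label]
        if lo <= n <= hi:
            return PloidyClass(label, n, f"modal number {n} in {lo}-{hi}")
    return PloidyClass("ambiguous", n, f"modal number {n} outside configured ranges")


def detect_iamp21(
    track: ProbeTrack,
    profile: CopyStateProfile,
    chrom: str = "chr21",
    min_state: int = 5,
    min_probes: int = 3,
) -> CNALesion | None:
    """Intrachromosomal amplification: a run of >= ``min_probes`` probes at
    copy state >= ``min_state`` (>= 3 extra copies) while the chromosome as
    a whole is below that state (a whole-chromosome gain is a trisomy, not
    iAMP21).  Boundaries are the first/last probe of the run."""
    if chrom not in profile.per_chromosome_state:
        return None
    if profile.per_chromosome_state[chrom] >= min_state:
        return None
    candidates = [
        (iv, state)
        for iv, state in profile.segment_states
        if iv.chrom == chrom and state >= min_state
    ]
    if not candidates:
        return None
    iv, state = max(candidates, key=lambda t: t[1])
    return CNALesion(
        locus="iAMP21", type="amplification", extent=iv, copy_state=state
    )


def detect_focal_cna(
    track: ProbeTrack,
    profile: CopyStateProfile,
    loci: dict[str, GenomicInterval] | None = None,
    min_probes: int = 3,
) -> tuple[list[CNALesion], list[str]]:
    """Deletion/amplification calls at shortlist loci from probe medians.

    A locus whose local copy state differs from its chromosome's state is
    reported; state 0 flags a biallelic deletion.  A PAR1 deletion is
    additionally emitted as the fusion label P2RY8::CRLF2 (juxtaposition of
    the genes flanking the deleted region).
    """
    if loci is None:
        loci = {
            name: iv
            for name, iv in track.reference.gene_loci().items()
            if name in set(UKALL_CNA_LOCI) | {"ERG"}
        }
    purity = profile.purity_assumed
    lesions: list[CNALesion] = []
    fusions: list[str] = []
    for name, iv in loci.items():
        # a masked (zero-coverage) probe inside a locus is evidence of a
        # biallelic deletion, not missing data: score it at the copy-0 level
        vals = np.array(
            [
                p.log2_ratio if math.isfinite(p.log2_ratio) else -5.0
                for p in track.probes
                if p.interval.chrom == iv.chrom and p.interval.overlaps(iv)
            ]
        )
        if len(vals) < min_probes:
            continue
        local_state = _nearest_state(float(np.median(vals)), purity)
        chrom_state = profile.per_chromosome_state.get(iv.chrom, 2)
        if local_state == chrom_state:
            continue
        kind = "deletion" if local_state < chrom_state else "amplification"
        lesions.append(
            CNALesion(
                locus=name,
                type=kind,
                extent=iv,
                biallelic=(local_state == 0),
                copy_state=local_state,
            )
        )
        if name == "PAR1" and kind == "deletion":
            fusions.append("P2RY8::CRLF2")
    return lesions, fusions


def detect_cnnloh(
    het_sites: pd.DataFrame,
    track: ProbeTrack,
    min_sites: int = 20,
    baf_dev_threshold: float = 0.3,
    log2_window: float = 0.1,
) -> list[tuple[GenomicInterval, str]]:
    """Copy-number-neutral LOH / UPD from allele imbalance at neutral depth.

    Paired mode only: ``het_sites`` must hold germline-heterozygous allele
    counts (chrom, pos, depth, alt_count).  A chromosome is flagged when the
    median |BAF - 0.5| exceeds the threshold while its median log2 stays
    within the neutral window; whole-chromosome extent is reported as UPD,
    a single-arm (half-chromosome) signal as CNN_LOH.
    """
    if het_sites is None:
        raise ValueError(
            "CNN-LOH/UPD detection requires a paired germline sample "
            "(het-site allele counts); unavailable in L-only mode"
        )
    required = {"chrom", "pos", "depth", "alt_count"}
    if not required.issubset(het_sites.columns):
        raise ValueError(f"het_sites must have columns {sorted(required)}")
    findings: list[tuple[GenomicInterval, str]] = []
    ref = track.reference
    for chrom in ref.chrom_names:
        sites = het_sites[het_sites["chrom"] == chrom]
        if len(sites) < min_sites:
            continue
        med_log2 = track.chrom_median(chrom)
        if not math.isfinite(med_log2) or abs(med_log2) >= log2_window:
            continue
        baf = sites["alt_count"].to_numpy() / np.maximum(sites["depth"].to_numpy(), 1)
        dev = np.abs(baf - 0.5)
        length = ref.chrom_length(chrom)
        if float(np.median(dev)) > baf_dev_threshold:
            findings.append((GenomicInterval(chrom, 0, length), "UPD"))
            continue
        # arm-level check: either half of the chromosome
        mid = length // 2
        for lo, hi in ((0, mid), (mid, length)):
            arm = sites[(sites["pos"] >= lo) & (sites["pos"] < hi)]
            if len(arm) >= min_sites // 2:
                baf_a = arm["alt_count"].to_numpy() / np.maximum(arm["depth"].to_numpy(), 1)
                if float(np.median(np.abs(baf_a - 0.5))) > baf_dev_threshold:
                    findings.append((GenomicInterval(chrom, lo, hi), "CNN_LOH"))
    return findings
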