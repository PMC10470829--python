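"""Sequential structural-variant filtration cascade.

Real leukemia WGS yields tens of thousands of raw SV calls per sample; the
clinically relevant handful is extracted by a fixed-order cascade:

1. population-frequency filter — calls with reference-cohort allele
   frequency strictly above 0.02 are discarded (unannotated calls are kept);
2. artifact-database filter — same rule keyed on the locally curated
   artifact frequency;
3. germline subtraction (paired L/N mode only) — a leukemia call matching a
   germline call of the same type with both breakpoints within a distance
   window is discarded; matches hitting the shortlist are logged as
   warnings, because residual disease in a "remission" sample silently
   removes true drivers;
4. shortlist intersection — a call is kept iff either breakpoint falls in a
   clinically relevant gene locus extended by a strand-aware upstream pad
   (default 5 kb), which rescues breakpoints immediately upstream of a gene.

Every stage returns (kept, dropped) and the cascade keeps a conserving
ledger: counts are monotone non-increasing and dropped + kept equals the
previous stage at every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .intervals import ShortlistEntry
from .svcalls import SVCall

DEFAULT_AF_THRESHOLD = 0.02


@dataclass
class FilterReport:
    stage_counts: dict[str, int] = field(default_factory=dict)
    dropped: list[tuple[str, str, str]] = field(default_factory=list)  # (id, stage, reason)
    warnings: list[str] = field(default_factory=list)

    def record_stage(self, stage: str, kept: list[SVCall], dropped: list[SVCall], reason_fn) -> None:
        previous = self.stage_counts.get(self._last_stage(), None)
        if previous is not None and len(kept) + len(dropped) != previous:
            raise AssertionError("ledger conservation violated")
        self.stage_counts[stage] = len(kept)
        for call in dropped:
            self.dropped.append((call.id, stage, reason_fn(call)))

    def _last_stage(self) -> str:
        return next(reversed(self.stage_counts)) if self.stage_counts else ""

    def to_dict(self) -> dict:
        return {
            "stage_counts": dict(self.stage_counts),
            "dropped": [list(d) for d in self.dropped],
            "warnings": list(self.warnings),
        }


@dataclass
class CascadeConfig:
    af_threshold: float = DEFAULT_AF_THRESHOLD
    artifact_threshold: float = DEFAULT_AF_THRESHOLD
    germline_window: int = 1_000  # bp per breakpoint, same SV type
    paired: bool = True


def filter_population_frequency(
    calls: list[SVCall], threshold: float = DEFAULT_AF_THRESHOLD
) -> tuple[list[SVCall], list[SVCall]]:
    """Drop calls whose population AF is strictly above the threshold;
    unannotated calls cannot exceed it and are kept."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    kept, dropped = [], []
    for call in calls:
        if call.population_af is not None and call.population_af > threshold:
            dropped.append(call)
        else:
            kept.append(call)
    return kept, dropped


def filter_artifact_db(
    calls: list[SVCall], threshold: float = DEFAULT_AF_THRESHOLD
) -> tuple[list[SVCall], list[SVCall]]:
    """Same rule as the population filter, keyed on the artifact-database
    frequency; calls absent from the database are kept."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    kept, dropped = [], []
    for call in calls:
        if call.artifact_freq is not None and call.artifact_freq > threshold:
            dropped.append(call)
        else:
            kept.append(call)
    return kept, dropped


def _matches_germline(call: SVCall, germline: list[SVCall], window: int) -> bool:
    for g in germline:
        if g.type != call.type:
            continue
        b1, b2 = call.breakpoint_1, call.breakpoint_2
        g1, g2 = g.breakpoint_1, g.breakpoint_2
        direct = (
            b1.chrom == g1.chrom and abs(b1.pos - g1.pos) <= window
            and b2.chrom == g2.chrom and abs(b2.pos - g2.pos) <= window
        )
        swapped = (
            b1.chrom == g2.chrom and abs(b1.pos - g2.pos) <= window
            and b2.chrom == g1.chrom and abs(b2.pos - g1.pos) <= window
        )
        if direct or swapped:
            return True
    return False


def subtract_germline(
    leukemia: list[SVCall],
    germline: list[SVCall],
    window: int = 1_000,
    shortlist: list[ShortlistEntry] | None = None,
) -> tuple[list[SVCall], list[SVCall], list[str]]:
    """Drop leukemia calls present in the paired germline set.

    Returns (kept, dropped, warnings); a dropped call whose breakpoints hit
    the shortlist triggers a warning — the pattern by which a pre-relapse
    "remission" sample can silently subtract a true driver rearrangement.
    """
    kept, dropped, warnings = [], [], []
    for call in leukemia:
        if _matches_germline(call, germline, window):
            dropped.append(call)
            if shortlist is not None:
                hits = _shortlist_hits(call, _build_tree(shortlist))
                if hits:
                    warnings.append(
                        f"germline subtraction removed shortlist variant {call.id} "
                        f"({call.type}, genes {sorted(hits)}); possible residual "
                        "disease in the paired sample"
                    )
        else:
            kept.append(call)
    return kept, dropped, warnings


def _build_tree(shortlist: list[ShortlistEntry]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for entry in shortlist:
        iv = entry.padded_interval()
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, entry.gene)
    return trees


def _shortlist_hits(call: SVCall, trees: dict[str, IntervalTree]) -> set[str]:
    hits: set[str] = set()
    for bp in call.breakpoints:
        tree = trees.get(bp.chrom)
        if tree is not None:
            hits |= {h.data for h in tree.at(bp.pos)}
    return hits


def intersect_shortlist(
    calls: list[SVCall], shortlist: list[ShortlistEntry]
) -> tuple[list[SVCall], list[SVCall]]:
    """Keep calls with >= 1 breakpoint inside a padded shortlist locus;
    the gene context of kept calls is populated with all hits."""
    if not shortlist:
        raise ValueError("shortlist must be non-empty")
    trees = _build_tree(shortlist)
    kept, dropped = [], []
    for call in calls:
        hits = _shortlist_hits(call, trees)
        if hits:
            call = call.copy()
            call.gene_context = sorted(hits)
            kept.append(call)
        else:
            dropped.append(call)
    return kept, dropped


def breakpoint_genes(call: SVCall, shortlist: list[ShortlistEntry]) -> tuple[set[str], set[str]]:
    """Shortlist genes hit by each breakpoint separately (padded intervals)."""
    trees = _build_tree(shortlist)
    out = []
    for bp in call.breakpoints:
        tree = trees.get(bp.chrom)
        out.append({h.data for h in tree.at(bp.pos)} if tree is not None else set())
    return out[0], out[1]


def name_fusion(call: SVCall, shortlist: list[ShortlistEntry]) -> str | None:
    """Fusion label for a shortlist-kept call.

    Two-gene calls get a 5'::3' label (breakpoint 1 is taken as the 5'
    partner; planted/parsed calls follow that convention).  Calls hitting
    the shortlist on one side only get a single-gene rearrangement label
    with partner coordinates.  A DEL/DUP entirely inside one gene is an
    intragenic event, not a fusion: returns None.
    """
    genes_1, genes_2 = breakpoint_genes(call, shortlist)
    if not genes_1 and not genes_2:
        return None

    def pick(genes: set[str], bp) -> str:
        # prefer the gene whose unpadded body contains the breakpoint,
        # then the smallest locus (most specific)
        entries = [e for e in shortlist if e.gene in genes]
        inside = [e for e in entries if e.interval.contains(bp.chrom, bp.pos)]
        pool = inside or entries
        return min(pool, key=lambda e: (len(e.interval), e.gene)).gene

    if genes_1 and genes_2:
        g1 = pick(genes_1, call.breakpoint_1)
        g2 = pick(genes_2, call.breakpoint_2)
        if g1 == g2:
            if call.type in ("DEL", "DUP", "INV"):
                return None  # intragenic event
            return f"{g1}-r({call.breakpoint_2.chrom}:{call.breakpoint_2.pos + 1})"
        return f"{g1}::{g2}"
    if genes_1:
        g = pick(genes_1, call.breakpoint_1)
        other = call.breakpoint_2
    else:
        g = pick(genes_2, call.breakpoint_2)
        other = call.breakpoint_1
    if call.type in ("DEL", "DUP", "INV"):
        return None
    return f"{g}-r({other.chrom}:{other.pos + 1})"


def run_cascade(
    leukemia: list[SVCall],
    germline: list[SVCall] | None,
    shortlist: list[ShortlistEntry],
    config: CascadeConfig | None = None,
) -> tuple[list[SVCall], FilterReport]:
    """Apply the full cascade in fixed order:
    frequency -> artifact -> (germline) -> shortlist."""
    config = config or CascadeConfig()
    report = FilterReport()
    report.stage_counts["raw"] = len(leukemia)

    kept, dropped = filter_population_frequency(leukemia, config.af_threshold)
    report.record_stage(
        "population_frequency", kept, dropped,
        lambda c: f"population AF {c.population_af:.4f} > {config.af_threshold}",
    )

    kept, dropped = filter_artifact_db(kept, config.artifact_threshold)
    report.record_stage(
        "artifact_db", kept, dropped,
        lambda c: f"artifact frequency {c.artifact_freq:.4f} > {config.artifact_threshold}",
    )

    if germline is not None and config.paired:
        kept, dropped, warnings = subtract_germline(
            kept, germline, window=config.germline_window, shortlist=shortlist
        )
        report.record_stage(
            "germline_subtraction", kept, dropped,
            lambda c: "matching germline call within window",
        )
        report.warnings.extend(warnings)

    kept, dropped = intersect_shortlist(kept, shortlist)
    report.record_stage(
        "shortlist", kept, dropped, lambda c: "no breakpoint in padded shortlist locus"
    )
    return kept, report
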