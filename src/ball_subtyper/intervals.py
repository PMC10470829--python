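"""Genomic intervals and region strings.

Internally everything is 0-based, half-open.  1-based inclusive coordinates
appear only in serialized region strings ("chr:start-end") and VCF records.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    label: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Any 1-bp overlap qualifies (half-open semantics)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def region_string(self) -> str:
        """1-based inclusive serialization, e.g. '14:106032614-107288051'."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"

    @classmethod
    def from_region_string(cls, region: str, label: str | None = None) -> "GenomicInterval":
        m = re.fullmatch(r"([^:]+):([\d,]+)-([\d,]+)", region.strip())
        if m is None:
            raise ValueError(f"cannot parse region string {region!r}")
        chrom = m.group(1)
        start = int(m.group(2).replace(",", "")) - 1
        end = int(m.group(3).replace(",", ""))
        return cls(chrom, start, end, label=label)


@dataclass
class ShortlistEntry:
    """A clinically relevant gene locus used as the final SV filter.

    ``upstream_pad`` extends the interval on the strand-upstream (5') side so
    that breakpoints immediately upstream of a gene are retained.
    """

    gene: str
    interval: GenomicInterval
    strand: str = "+"
    upstream_pad: int = 5_000

    def __post_init__(self) -> None:
        if self.upstream_pad < 0:
            raise ValueError("upstream_pad must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def padded_interval(self) -> GenomicInterval:
        if self.strand == "+":
            start = max(0, self.interval.start - self.upstream_pad)
            end = self.interval.end
        else:
            start = self.interval.start
            end = self.interval.end + self.upstream_pad
        return GenomicInterval(self.interval.chrom, start, end, label=self.gene)

    def contains_breakpoint(self, chrom: str, pos: int) -> bool:
        return self.padded_interval().contains(chrom, pos)


def read_shortlist_bed(path, upstream_pad: int = 5_000) -> list[ShortlistEntry]:
    """Read a shortlist from BED (chrom, start, end, name[, score, strand])."""
    entries: list[ShortlistEntry] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"shortlist BED line needs >=4 columns: {line!r}")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5] if len(parts) >= 6 else "+"
            entries.append(
                ShortlistEntry(
                    gene=name,
                    interval=GenomicInterval(chrom, start, end, label=name),
                    strand=strand,
                    upstream_pad=upstream_pad,
                )
            )
    return entries


def write_shortlist_bed(entries: list[ShortlistEntry], path) -> None:
    with open(path, "w") as fh:
        for e in entries:
            fh.write(
                f"{e.interval.chrom}\t{e.interval.start}\t{e.interval.end}"
                f"\t{e.gene}\t0\t{e.strand}\n"
            )
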