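"""Toy multi-chromosome references with named gene loci.

Two stock references are provided:

* :func:`build_toy_reference` — the default desk-scale genome (5 chromosomes
  x 2 Mb) with an "IGH" anchor locus and a two-copy "DUX4_arrays" target set
  on different chromosomes, emulating the multi-copy D4Z4 placement that
  makes DUX4 breakpoints map ambiguously.
* :func:`human_like_reference` — a 23-chromosome miniature (chr1..chr22,
  chrX) whose diploid chromosome count is 46, used for karyotype/ploidy
  experiments and the synthetic validation cohort.

Reference sequences carry no biological meaning here (no real D4Z4 repeat);
they exist only so FASTA/SAM outputs are well-formed and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval, ShortlistEntry

# The anchor/target coordinates of the targeted IGH::DUX4 assay on the real
# genome (GRCh37/hg19), shipped as defaults for use on real alignments.
IGH_ANCHOR_GRCH37 = GenomicInterval("14", 106_032_613, 107_288_051, label="IGH")
DUX4_TARGETS_GRCH37 = (
    GenomicInterval("4", 190_988_099, 191_007_000, label="DUX4_4q35"),
    GenomicInterval("10", 135_476_999, 135_500_000, label="DUX4_10q26"),
    GenomicInterval("GL000228.1", 6_999, 115_000, label="DUX4_GL000228"),
)


class ReferenceSpecError(ValueError):
    """Raised when a reference specification violates its invariants."""


@dataclass
class ToyReference:
    chromosomes: list[tuple[str, int]]
    named_loci: dict[str, tuple[GenomicInterval, ...]]
    assembly_label: str = "toy-GRCh37-mini"
    overlap_allowed: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        if len(lengths) != len(self.chromosomes):
            raise ReferenceSpecError("duplicate chromosome names")
        for name, ivs in self.named_loci.items():
            for iv in ivs:
                if iv.chrom not in lengths:
                    raise ReferenceSpecError(
                        f"locus {name} on unknown chromosome {iv.chrom}"
                    )
                if iv.end > lengths[iv.chrom]:
                    raise ReferenceSpecError(
                        f"locus {name} ({iv.region_string()}) extends beyond "
                        f"chromosome {iv.chrom} length {lengths[iv.chrom]}"
                    )
        self._check_overlaps()

    def _check_overlaps(self) -> None:
        flat = [
            (name, iv)
            for name, ivs in self.named_loci.items()
            for iv in ivs
        ]
        for i, (na, a) in enumerate(flat):
            for nb, b in flat[i + 1 :]:
                if na == nb:
                    continue
                if a.overlaps(b) and not (
                    na in self.overlap_allowed and nb in self.overlap_allowed
                ):
                    raise ReferenceSpecError(
                        f"loci {na} and {nb} overlap and are not flagged as allowed"
                    )

    # -- lookups ---------------------------------------------------------
    @property
    def chrom_names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    def chrom_length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(f"unknown chromosome {chrom!r}")

    @property
    def genome_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def loci(self, name: str) -> tuple[GenomicInterval, ...]:
        return self.named_loci[name]

    def locus(self, name: str) -> GenomicInterval:
        ivs = self.named_loci[name]
        if len(ivs) != 1:
            raise KeyError(f"locus {name!r} has {len(ivs)} intervals; use loci()")
        return ivs[0]

    def gene_loci(self) -> dict[str, GenomicInterval]:
        """Single-interval loci (genes); excludes multi-interval target sets."""
        return {
            name: ivs[0]
            for name, ivs in self.named_loci.items()
            if len(ivs) == 1
        }

    def shortlist_entries(
        self,
        genes: list[str] | None = None,
        upstream_pad: int = 5_000,
        strands: dict[str, str] | None = None,
    ) -> list[ShortlistEntry]:
        strands = strands or {}
        gene_loci = self.gene_loci()
        names = genes if genes is not None else sorted(gene_loci)
        return [
            ShortlistEntry(
                gene=g,
                interval=gene_loci[g],
                strand=strands.get(g, "+"),
                upstream_pad=upstream_pad,
            )
            for g in names
        ]

    # -- sequence --------------------------------------------------------
    def chrom_sequence(self, chrom: str, seed: int = 20_230_814) -> str:
        """Deterministic pseudo-random base sequence for a chromosome."""
        length = self.chrom_length(chrom)
        rng = np.random.default_rng(
            (seed + sum(ord(c) for c in chrom)) % (2**31)
        )
        bases = np.array(list("ACGT"))
        return "".join(bases[rng.integers(0, 4, size=length)])

    def write_fasta(self, path, line_width: int = 70, seed: int = 20_230_814) -> None:
        with open(path, "w") as fh:
            for chrom, _length in self.chromosomes:
                fh.write(f">{chrom}\n")
                seq = self.chrom_sequence(chrom, seed=seed)
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")


DEFAULT_TOY_SPEC: dict = {
    "chromosomes": [(c, 2_000_000) for c in ("chrA", "chrB", "chrC", "chrD", "chrE")],
    "loci": {
        # anchor + two-copy repetitive target set on distinct chromosomes
        "IGH": [("chrD", 800_000, 1_200_000)],
        "DUX4_arrays": [("chrA", 1_900_000, 1_950_000), ("chrE", 1_900_000, 1_980_000)],
        # shortlist genes used by fusion / focal-CNA tests
        "ETV6": [("chrA", 200_000, 300_000)],
        "CDKN2A/B": [("chrA", 600_000, 700_000)],
        "RUNX1": [("chrB", 200_000, 300_000)],
        "KMT2A": [("chrB", 600_000, 700_000)],
        "PAX5": [("chrB", 1_000_000, 1_100_000)],
        "IKZF1": [("chrB", 1_400_000, 1_500_000)],
        "TCF3": [("chrC", 200_000, 300_000)],
        "PBX1": [("chrC", 600_000, 700_000)],
        "ABL1": [("chrC", 1_000_000, 1_100_000)],
        "RANBP2": [("chrC", 1_400_000, 1_500_000)],
        "BCR": [("chrD", 200_000, 300_000)],
        "ERG": [("chrD", 400_000, 500_000)],
        "P2RY8": [("chrE", 150_000, 250_000)],
        "CRLF2": [("chrE", 300_000, 400_000)],
        "PAR1": [("chrE", 150_000, 400_000)],
    },
    "overlap_allowed": ["PAR1", "P2RY8", "CRLF2"],
    "assembly_label": "toy-GRCh37-mini",
    "anchor": "IGH",
    "targets": "DUX4_arrays",
}


def build_toy_reference(spec: dict | None = None) -> ToyReference:
    """Build a deterministic toy reference from a chromosome/locus spec.

    The spec must name >= 3 chromosomes, include the anchor locus, and a
    target set with >= 2 intervals on >= 2 distinct chromosomes.
    """
    spec = spec if spec is not None else DEFAULT_TOY_SPEC
    chromosomes = [(str(c), int(n)) for c, n in spec["chromosomes"]]
    if len(chromosomes) < 3:
        raise ReferenceSpecError("need >= 3 chromosomes")
    loci: dict[str, tuple[GenomicInterval, ...]] = {}
    for name, ivs in spec["loci"].items():
        loci[name] = tuple(
            GenomicInterval(chrom, int(s), int(e), label=name) for chrom, s, e in ivs
        )
    anchor = spec.get("anchor", "IGH")
    targets = spec.get("targets", "DUX4_arrays")
    if anchor not in loci:
        raise ReferenceSpecError(f"anchor locus {anchor!r} missing from spec")
    tgt = loci.get(targets, ())
    if len(tgt) < 2 or len({iv.chrom for iv in tgt}) < 2:
        raise ReferenceSpecError(
            f"target set {targets!r} needs >= 2 intervals on >= 2 chromosomes"
        )
    return ToyReference(
        chromosomes=chromosomes,
        named_loci=loci,
        assembly_label=spec.get("assembly_label", "toy-GRCh37-mini"),
        overlap_allowed=frozenset(spec.get("overlap_allowed", ())),
    )


def human_like_reference(chrom_length: int = 400_000) -> ToyReference:
    """23-chromosome miniature genome (diploid count 46) for karyotype work.

    Gene loci are placed on the chromosomes that carry their real-genome
    namesakes; coordinates are toy-scale and arbitrary.
    """
    s = chrom_length / 400_000  # locus layout scales with chromosome length

    def iv(chrom: str, a: int, b: int) -> list[tuple[str, int, int]]:
        return [(chrom, int(a * s), int(b * s))]

    chroms = [(f"chr{i}", chrom_length) for i in range(1, 23)] + [("chrX", chrom_length)]
    spec = {
        "chromosomes": chroms,
        "loci": {
            "PBX1": iv("chr1", 100_000, 180_000),
            "RANBP2": iv("chr2", 100_000, 180_000),
            "AFF1": iv("chr4", 60_000, 140_000),
            "EBF1": iv("chr5", 100_000, 180_000),
            "PDGFRB": iv("chr5", 220_000, 300_000),
            "IKZF1": iv("chr7", 100_000, 180_000),
            "ABL1": iv("chr9", 40_000, 110_000),
            "PAX5": iv("chr9", 140_000, 220_000),
            "CDKN2A/B": iv("chr9", 250_000, 330_000),
            "KMT2A": iv("chr11", 100_000, 180_000),
            "ETV6": iv("chr12", 60_000, 140_000),
            "ZNF384": iv("chr12", 180_000, 260_000),
            "BTG1": iv("chr12", 290_000, 360_000),
            "RB1": iv("chr13", 100_000, 180_000),
            "IGH": iv("chr14", 150_000, 280_000),
            "TCF3": iv("chr19", 100_000, 180_000),
            "RUNX1": iv("chr21", 60_000, 140_000),
            "ERG": iv("chr21", 250_000, 330_000),
            "BCR": iv("chr22", 100_000, 180_000),
            "P2RY8": iv("chrX", 50_000, 90_000),
            "CRLF2": iv("chrX", 110_000, 150_000),
            "PAR1": iv("chrX", 40_000, 160_000),
            "DUX4_arrays": iv("chr4", 340_000, 390_000) + iv("chr10", 340_000, 390_000),
        },
        "overlap_allowed": ["PAR1", "P2RY8", "CRLF2"],
        "assembly_label": "toy-GRCh37-mini-23",
    }
    return build_toy_reference(spec)


# The eight loci of the UKALL-CNA copy-number classifier.
UKALL_CNA_LOCI = (
    "IKZF1",
    "CDKN2A/B",
    "PAX5",
    "EBF1",
    "ETV6",
    "RB1",
    "BTG1",
    "PAR1",
)
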