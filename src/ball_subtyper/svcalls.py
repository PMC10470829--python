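"""Structural-variant calls and VCF 4.2 round-trip.

SV calling itself is out of scope (caller output is an *input* here);
this module defines the in-memory :class:`SVCall` the filtration cascade
operates on, plus VCF writing (pysam) and reading (cyvcf2).  Breakends are
serialized as BND mate pairs; DEL/DUP/INV as symbolic ALTs with END.
Population allele frequency and artifact-database frequency travel in
configurable INFO keys (defaults ``SWEGEN_AF`` and ``ARTIFACT_FREQ``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import cyvcf2
import pysam

from .reference import ToyReference

SV_TYPES = ("BND", "DEL", "DUP", "INV")

DEFAULT_AF_KEY = "SWEGEN_AF"
DEFAULT_ARTIFACT_KEY = "ARTIFACT_FREQ"


@dataclass
class Breakpoint:
    chrom: str
    pos: int  # 0-based
    orientation: str = "+"  # '+' = joined to the right of pos, '-' = left

    def as_tuple(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.orientation)


@dataclass
class SVCall:
    id: str
    type: str  # BND / DEL / DUP / INV
    breakpoint_1: Breakpoint
    breakpoint_2: Breakpoint
    caller: str = "unknown"
    population_af: float | None = None
    artifact_freq: float | None = None
    gene_context: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.type!r}")

    def copy(self) -> "SVCall":
        return replace(self, gene_context=list(self.gene_context))

    @property
    def breakpoints(self) -> tuple[Breakpoint, Breakpoint]:
        return (self.breakpoint_1, self.breakpoint_2)


def _vcf_header(ref: ToyReference, af_key: str, artifact_key: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in ref.chromosomes:
        header.contigs.add(name, length=length)
    header.add_meta(
        "INFO",
        items=[("ID", "SVTYPE"), ("Number", "1"), ("Type", "String"),
               ("Description", "Type of structural variant")],
    )
    header.add_meta(
        "INFO",
        items=[("ID", "END"), ("Number", "1"), ("Type", "Integer"),
               ("Description", "End position of the variant")],
    )
    header.add_meta(
        "INFO",
        items=[("ID", "MATEID"), ("Number", "1"), ("Type", "String"),
               ("Description", "ID of mate breakend")],
    )
    header.add_meta(
        "INFO",
        items=[("ID", "CALLER"), ("Number", "1"), ("Type", "String"),
               ("Description", "Source caller label")],
    )
    header.add_meta(
        "INFO",
        items=[("ID", af_key), ("Number", "1"), ("Type", "Float"),
               ("Description", "Population allele frequency")],
    )
    header.add_meta(
        "INFO",
        items=[("ID", artifact_key), ("Number", "1"), ("Type", "Float"),
               ("Description", "Locally observed artifact frequency")],
    )
    return header


def write_vcf(
    calls: list[SVCall],
    ref: ToyReference,
    path,
    af_key: str = DEFAULT_AF_KEY,
    artifact_key: str = DEFAULT_ARTIFACT_KEY,
) -> None:
    """Write calls as uncompressed VCF 4.2; BNDs expand to mate-pair records."""
    header = _vcf_header(ref, af_key, artifact_key)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in calls:
            common: dict = {"CALLER": call.caller}
            if call.population_af is not None:
                common[af_key] = call.population_af
            if call.artifact_freq is not None:
                common[artifact_key] = call.artifact_freq
            bp1, bp2 = call.breakpoint_1, call.breakpoint_2
            if call.type == "BND":
                for this, other, suffix, mate_suffix in (
                    (bp1, bp2, "_1", "_2"),
                    (bp2, bp1, "_2", "_1"),
                ):
                    # bracket notation: orientation of the joined side
                    mate_loc = f"{other.chrom}:{other.pos + 1}"
                    if other.orientation == "+":
                        alt = f"N[{mate_loc}["
                    else:
                        alt = f"N]{mate_loc}]"
                    rec = out.new_record(
                        contig=this.chrom, start=this.pos, alleles=("N", alt),
                        id=call.id + suffix,
                    )
                    rec.info["SVTYPE"] = "BND"
                    rec.info["MATEID"] = call.id + mate_suffix
                    for k, v in common.items():
                        rec.info[k] = v
                    rec.stop = this.pos + 1
                    out.write(rec)
            else:
                rec = out.new_record(
                    contig=bp1.chrom, start=bp1.pos,
                    alleles=("N", f"<{call.type}>"), id=call.id,
                )
                rec.info["SVTYPE"] = call.type
                for k, v in common.items():
                    rec.info[k] = v
                rec.stop = bp2.pos
                out.write(rec)


def read_vcf(
    path,
    af_key: str = DEFAULT_AF_KEY,
    artifact_key: str = DEFAULT_ARTIFACT_KEY,
) -> list[SVCall]:
    """Read SV calls; BND mate pairs are folded into single SVCall objects."""
    calls: list[SVCall] = []
    seen_bnd: set[str] = set()
    vcf = cyvcf2.VCF(str(path))
    try:
        for rec in vcf:
            svtype = rec.INFO.get("SVTYPE")
            if svtype is None:
                continue
            af = rec.INFO.get(af_key)
            art = rec.INFO.get(artifact_key)
            caller = rec.INFO.get("CALLER") or "unknown"
            if svtype == "BND":
                base = rec.ID.rsplit("_", 1)[0] if rec.ID else rec.ID
                if base in seen_bnd:
                    continue
                seen_bnd.add(base)
                alt = rec.ALT[0]
                # parse chrom:pos and bracket direction from the ALT string
                if "[" in alt:
                    loc, orient = alt.split("[")[1], "+"
                else:
                    loc, orient = alt.split("]")[1], "-"
                mchrom, mpos = loc.rsplit(":", 1)
                calls.append(
                    SVCall(
                        id=base,
                        type="BND",
                        breakpoint_1=Breakpoint(rec.CHROM, rec.POS - 1),
                        breakpoint_2=Breakpoint(mchrom, int(mpos) - 1, orient),
                        caller=caller,
                        population_af=float(af) if af is not None else None,
                        artifact_freq=float(art) if art is not None else None,
                    )
                )
            else:
                end = rec.INFO.get("END", rec.POS)
                calls.append(
                    SVCall(
                        id=rec.ID or f"sv{len(calls)}",
                        type=svtype,
                        breakpoint_1=Breakpoint(rec.CHROM, rec.POS - 1),
                        breakpoint_2=Breakpoint(rec.CHROM, int(end)),
                        caller=caller,
                        population_af=float(af) if af is not None else None,
                        artifact_freq=float(art) if art is not None else None,
                    )
                )
    finally:
        vcf.close()
    return calls


def dedup_calls(calls: list[SVCall], window: int = 50) -> list[SVCall]:
    """Optional multi-caller merge: drop same-type calls whose breakpoints
    both lie within ``window`` bp of an earlier call (first caller wins)."""
    kept: list[SVCall] = []
    for call in calls:
        duplicate = False
        for other in kept:
            if other.type != call.type:
                continue
            b1, b2 = call.breakpoint_1, call.breakpoint_2
            o1, o2 = other.breakpoint_1, other.breakpoint_2
            if (
                b1.chrom == o1.chrom
                and b2.chrom == o2.chrom
                and abs(b1.pos - o1.pos) <= window
                and abs(b2.pos - o2.pos) <= window
            ):
                duplicate = True
                break
        if not duplicate:
            kept.append(call)
    return kept
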