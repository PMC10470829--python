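"""Per-sample orchestration and cohort manifest handling.

:func:`run_sample` executes the full diagnostic sequence on one sample in a
fixed order — copy-number profiling, SV filtration cascade, targeted fusion
assay, targeted SNV assay, subgroup classification, DUX4 confirmation — and
returns a :class:`SampleReport` embedding every stage output plus an audit
trail (configuration echo, baseline offset, stage counts, warnings).
Warnings never alter calls.

Modes: ``L_N`` (paired leukemia/germline: germline SV subtraction and
CNN-LOH/UPD detection available) and ``L_only`` (both unavailable and
signalled as such, never silently skipped).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import pandas as pd

from .classify import (
    CNAProfile,
    FusionLesion,
    LesionSet,
    SubgroupCall,
    SubgroupRule,
    assign_subgroups,
    build_cna_profile,
    confirm_dux4,
    default_rules,
)
from .cna import (
    CNALesion,
    bin_depth,
    call_copy_states,
    classify_ploidy,
    detect_cnnloh,
    detect_focal_cna,
    detect_iamp21,
    pool_probes,
    recenter_baseline,
)
from .fragments import AlignmentSet
from .intervals import ShortlistEntry
from .svcalls import SVCall
from .svfilter import CascadeConfig, FilterReport, name_fusion, run_cascade
from .targeted import SNVSite, detect_targeted_fusion


@dataclass
class WorkflowConfig:
    purity: float = 1.0
    mode: str = "L_only"  # L_only / L_N
    bin_size: int = 1_000
    probe_pool: int = 20
    af_threshold: float = 0.02
    artifact_threshold: float = 0.02
    germline_window: int = 1_000
    upstream_pad: int = 5_000
    targeted_threshold: int = 10
    targeted_min_mapq: int = 0
    snv_min_depth: int = 10
    snv_min_vaf: float = 0.05
    iamp21_chrom: str = "chr21"
    snv_sites: list[SNVSite] = field(default_factory=list)
    rules: list[SubgroupRule] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValueError("purity must lie in (0, 1]")
        if self.mode not in ("L_only", "L_N"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def echo(self) -> dict:
        d = {k: v for k, v in asdict(self).items() if k not in ("snv_sites", "rules")}
        d["snv_sites"] = [s.label for s in self.snv_sites]
        d["n_rules"] = len(self.rules) if self.rules is not None else len(default_rules())
        return d


@dataclass
class SampleReport:
    sample_id: str
    mode: str
    coverage_class: str
    mean_coverage: float
    filter_report: FilterReport
    lesions: LesionSet
    subgroup: SubgroupCall
    cna_profile: CNAProfile
    baseline_offset: float
    warnings: list[str]
    config: dict

    def to_dict(self) -> dict:
        les = self.lesions
        return {
            "sample_id": self.sample_id,
            "mode": self.mode,
            "coverage_class": self.coverage_class,
            "mean_coverage": round(self.mean_coverage, 3),
            "stage_counts": dict(self.filter_report.stage_counts),
            "lesions": {
                "fusions": [f.label for f in les.fusions],
                "cnas": [
                    {
                        "locus": c.locus,
                        "type": c.type,
                        "biallelic": c.biallelic,
                        "copy_state": c.copy_state,
                    }
                    for c in les.cnas
                ],
                "ploidy": (
                    {
                        "label": les.ploidy.label,
                        "chromosome_count": les.ploidy.chromosome_count,
                    }
                    if les.ploidy
                    else None
                ),
                "targeted": [
                    {
                        "name": t.name,
                        "status": t.status,
                        "supporting_pairs": t.evidence.supporting_pair_count,
                    }
                    for t in les.targeted_calls
                ],
                "snvs": [
                    {
                        "label": s.site.label,
                        "depth": s.depth,
                        "alt_count": s.alt_count,
                        "verdict": s.verdict,
                    }
                    for s in les.snvs
                ],
                "cnnloh": [
                    {"region": iv.region_string(), "kind": kind}
                    for iv, kind in les.cnnloh
                ],
            },
            "subgroup": {
                "labels": list(self.subgroup.labels),
                "primary": self.subgroup.primary,
                "tier": self.subgroup.tier,
                "rationale": dict(self.subgroup.rationale),
                "unclassified": self.subgroup.unclassified,
            },
            "cna_profile": self.cna_profile.to_dict(),
            "baseline_offset": round(self.baseline_offset, 4),
            "warnings": list(self.warnings),
            "config": self.config,
        }


def run_sample(
    config: WorkflowConfig,
    alignments: AlignmentSet,
    sv_calls: list[SVCall],
    germline_calls: list[SVCall] | None = None,
    het_sites: pd.DataFrame | None = None,
    shortlist: list[ShortlistEntry] | None = None,
    sample_id: str = "sample",
) -> SampleReport:
    """Run the full per-sample analysis; deterministic given its inputs."""
    ref = alignments.reference
    warnings: list[str] = []
    if config.mode == "L_N" and germline_calls is None:
        raise ValueError("L_N mode requires a germline call set")
    if config.mode == "L_only" and germline_calls is not None:
        warnings.append("L_only mode: supplied germline call set ignored")
        germline_calls = None
    if shortlist is None:
        shortlist = ref.shortlist_entries(upstream_pad=config.upstream_pad)

    # 1. copy-number / ploidy profiling
    bins = bin_depth(alignments, config.bin_size)
    track = recenter_baseline(pool_probes(bins, config.probe_pool))
    if track.baseline_ambiguous:
        warnings.append("no modal chromosome cluster: baseline left at 0 (ambiguous)")
    profile = call_copy_states(track, config.purity)
    # modal-number ploidy classes assume a full chromosome complement;
    # on smaller toy genomes the count is reported but not classified
    full_karyotype = 2 * len(ref.chromosomes) >= 40
    ploidy = classify_ploidy(profile) if full_karyotype else None
    cnas: list[CNALesion] = []
    iamp = detect_iamp21(track, profile, chrom=config.iamp21_chrom)
    if iamp is not None:
        cnas.append(iamp)
    focal, cna_fusion_labels = detect_focal_cna(track, profile)
    cnas.extend(focal)

    # 2. SV filtration cascade
    cascade_cfg = CascadeConfig(
        af_threshold=config.af_threshold,
        artifact_threshold=config.artifact_threshold,
        germline_window=config.germline_window,
        paired=(config.mode == "L_N"),
    )
    kept_calls, filter_report = run_cascade(
        sv_calls, germline_calls, shortlist, cascade_cfg
    )
    warnings.extend(filter_report.warnings)

    # 3. fusion naming from kept SVs (+ intragenic DEL/DUP as CNA lesions)
    fusions = [FusionLesion.from_label(lbl) for lbl in cna_fusion_labels]
    seen_fusions = {f.label for f in fusions}
    for call in kept_calls:
        label = name_fusion(call, shortlist)
        if label is not None:
            if label not in seen_fusions:
                fusions.append(FusionLesion.from_label(label, lesion_id=call.id))
                seen_fusions.add(label)
        elif call.type in ("DEL", "DUP") and call.gene_context:
            locus = call.gene_context[0]
            kind = "deletion" if call.type == "DEL" else "amplification"
            if not any(c.locus == locus and c.type == kind for c in cnas):
                from .intervals import GenomicInterval

                cnas.append(
                    CNALesion(
                        locus=locus,
                        type=kind,
                        extent=GenomicInterval(
                            call.breakpoint_1.chrom,
                            call.breakpoint_1.pos,
                            max(call.breakpoint_2.pos, call.breakpoint_1.pos + 1),
                        ),
                    )
                )

    # 4. targeted fusion assay (requires anchor/target loci in the reference)
    targeted_calls = []
    if "IGH" in ref.named_loci and "DUX4_arrays" in ref.named_loci:
        targeted_calls.append(
            detect_targeted_fusion(
                alignments,
                ref.loci("IGH")[0],
                list(ref.loci("DUX4_arrays")),
                threshold=config.targeted_threshold,
                min_mapq=config.targeted_min_mapq,
            )
        )

    # 5. targeted SNV assay
    from .targeted import snv_pileup_assay

    snv_calls = [
        snv_pileup_assay(
            alignments, site,
            min_depth=config.snv_min_depth, min_vaf=config.snv_min_vaf,
        )
        for site in config.snv_sites
    ]

    # CNN-LOH / UPD (paired mode only; unavailability is signalled)
    cnnloh: list = []
    if config.mode == "L_N":
        if het_sites is not None:
            cnnloh = detect_cnnloh(het_sites, track)
        else:
            warnings.append("CNN-LOH/UPD unavailable: no germline het sites supplied")
    # 6. classification + DUX4 confirmation
    lesions = LesionSet(
        sample_id=sample_id,
        fusions=fusions,
        cnas=cnas,
        ploidy=ploidy,
        targeted_calls=targeted_calls,
        snvs=snv_calls,
        cnnloh=cnnloh,
    )
    subgroup = assign_subgroups(lesions, config.rules)
    for tcall in targeted_calls:
        if tcall.name == "IGH::DUX4":
            subgroup = confirm_dux4(subgroup, tcall)

    mean_cov = alignments.mean_coverage()
    return SampleReport(
        sample_id=sample_id,
        mode=config.mode,
        coverage_class="90x" if mean_cov >= 60 else "30x",
        mean_coverage=mean_cov,
        filter_report=filter_report,
        lesions=lesions,
        subgroup=subgroup,
        cna_profile=build_cna_profile(lesions.cnas),
        baseline_offset=track.baseline_offset,
        warnings=warnings,
        config=config.echo(),
    )


# -- report I/O -------------------------------------------------------------


def write_report(report: SampleReport, json_path, tsv_path=None) -> None:
    """Machine-readable JSON plus a human TSV summary, stable field order."""
    payload = report.to_dict()
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=False)
        fh.write("\n")
    if tsv_path is not None:
        rows: list[tuple[str, str, str]] = []
        rows.append(("sample", "id", payload["sample_id"]))
        rows.append(("sample", "mode", payload["mode"]))
        rows.append(("sample", "coverage", payload["coverage_class"]))
        for stage, count in payload["stage_counts"].items():
            rows.append(("sv_filter", stage, str(count)))
        for fz in payload["lesions"]["fusions"]:
            rows.append(("fusion", fz, "detected"))
        for c in payload["lesions"]["cnas"]:
            rows.append(("cna", c["locus"], c["type"] + (" (biallelic)" if c["biallelic"] else "")))
        if payload["lesions"]["ploidy"]:
            rows.append(
                ("ploidy", payload["lesions"]["ploidy"]["label"],
                 str(payload["lesions"]["ploidy"]["chromosome_count"]))
            )
        for t in payload["lesions"]["targeted"]:
            rows.append(("targeted", t["name"], f"{t['status']} ({t['supporting_pairs']} pairs)"))
        for s in payload["lesions"]["snvs"]:
            rows.append(("snv", s["label"], s["verdict"]))
        rows.append(("subgroup", "labels", ";".join(payload["subgroup"]["labels"]) or "unclassified"))
        rows.append(("cna_profile", "IKZF1plus", str(payload["cna_profile"]["ikzf1_plus"])))
        for w in payload["warnings"]:
            rows.append(("warning", "", w))
        with open(tsv_path, "w") as fh:
            fh.write("section\tname\tvalue\n")
            for r in rows:
                fh.write("\t".join(r) + "\n")


def read_report(json_path) -> dict:
    with open(json_path) as fh:
        return json.load(fh)


# -- cohort manifest --------------------------------------------------------


@dataclass
class ManifestRow:
    subgroup: str
    n_90x: int
    n_90x_paired: int
    n_30x: int
    total: int


@dataclass
class CohortManifest:
    rows: list[ManifestRow]

    @property
    def total(self) -> int:
        return sum(r.total for r in self.rows)

    @property
    def total_90x(self) -> int:
        return sum(r.n_90x for r in self.rows)

    @property
    def total_30x(self) -> int:
        return sum(r.n_30x for r in self.rows)

    def subgroup_total(self, label: str) -> int:
        for r in self.rows:
            if r.subgroup == label:
                return r.total
        raise KeyError(label)


def _parse_count(cell: str) -> tuple[int, int]:
    """Parse a count cell: '11', '27/23' (total/paired), '-', '–' or ''."""
    cell = cell.strip()
    if cell in ("", "-", "–"):
        return 0, 0
    if "/" in cell:
        a, b = cell.split("/", 1)
        return int(a), int(b)
    n = int(cell)
    return n, n


def parse_manifest(path) -> CohortManifest:
    """Parse a cohort manifest TSV (subgroup, n at 90x [L/N], n at 30x, sum).

    A final 'Sum' row, if present, is validated against the column totals;
    malformed rows are rejected with their line number.
    """
    rows: list[ManifestRow] = []
    sum_row: ManifestRow | None = None
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            return CohortManifest(rows=[])
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ValueError(f"line {lineno}: expected 4 columns, got {len(parts)}")
            try:
                n90, n90p = _parse_count(parts[1])
                n30, _ = _parse_count(parts[2])
                total, _ = _parse_count(parts[3])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer count ({exc})") from exc
            row = ManifestRow(parts[0].strip(), n90, n90p, n30, total)
            if row.subgroup.lower() == "sum":
                sum_row = row
            else:
                if row.total != row.n_90x + row.n_30x:
                    raise ValueError(
                        f"line {lineno}: total {row.total} != {row.n_90x} + {row.n_30x}"
                    )
                rows.append(row)
    manifest = CohortManifest(rows=rows)
    if sum_row is not None:
        if (
            sum_row.total != manifest.total
            or sum_row.n_90x != manifest.total_90x
            or sum_row.n_30x != manifest.total_30x
        ):
            raise ValueError(
                f"Sum row ({sum_row.n_90x}, {sum_row.n_30x}, {sum_row.total}) does not "
                f"match column totals ({manifest.total_90x}, {manifest.total_30x}, "
                f"{manifest.total})"
            )
    return manifest
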