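"""Synthetic WGS data with planted lesions and known truth.

Emulates the statistical structure of 90x leukemia / 30x germline paired-end
WGS (2 x 150 bp, ~350 bp inserts) over a toy reference:

* whole-chromosome copy-number states at a configurable tumor fraction f
  (per-chromosome expected depth proportional to ``(2(1-f) + c*f)/2``),
* focal deletions / duplications / tandem amplifications as local depth
  changes,
* translocations as discordant read pairs spanning the junction,
* targeted anchor->multi-copy-region fusions that emit an exact number of
  supporting pairs, split ~50/50 between the "mate mapped in target" and
  "secondary alignment in target" mechanisms (the two clauses of the
  targeted detector),
* targeted SNVs as fragment-level allele flags at a site,
* UPD/CNN-LOH as allele-imbalance at germline heterozygous sites.

The generator is deterministic: identical (reference, truth, seed) yields
identical output.  Structural-variant call sets are emitted separately
(:func:`emit_sv_vcf`) because the upstream callers are not re-implemented;
by default targeted-fusion lesions are *absent* from the emitted call set,
mirroring the repetitive-region blind spot that motivates the targeted
detector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .fragments import AlignmentSet
from .intervals import GenomicInterval
from .reference import ToyReference
from .svcalls import Breakpoint, SVCall

LESION_KINDS = (
    "translocation",
    "deletion",
    "duplication",
    "tandem_amplification",
    "targeted_fusion",
    "snv",
    "upd",
)


@dataclass
class FragmentModel:
    insert_mean: float = 350.0
    insert_sd: float = 50.0
    read_len: int = 150


@dataclass
class SimKaryotype:
    """Per-chromosome integer copy numbers at a given tumor fraction."""

    per_chromosome_copy_number: dict[str, int]
    tumor_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.tumor_fraction <= 1.0):
            raise ValueError("tumor_fraction must lie in [0, 1]")
        for chrom, c in self.per_chromosome_copy_number.items():
            if c < 0:
                raise ValueError(f"negative copy number for {chrom}")

    @property
    def chromosome_count(self) -> int:
        return sum(self.per_chromosome_copy_number.values())

    def copies(self, chrom: str) -> int:
        return self.per_chromosome_copy_number.get(chrom, 2)

    @classmethod
    def diploid(cls, ref: ToyReference, tumor_fraction: float = 1.0) -> "SimKaryotype":
        return cls({c: 2 for c in ref.chrom_names}, tumor_fraction)


# Canonical gain/loss orders used when planting a target chromosome count.
# Gains follow the chromosomes recurrently gained in high hyperdiploidy;
# losses follow those recurrently lost in low hypodiploidy.
_HEH_GAIN_ORDER = ["chrX", "chr4", "chr6", "chr10", "chr14", "chr17", "chr18",
                   "chr21", "chr8", "chr5", "chr1", "chr2", "chr3"]
_HOL_LOSS_ORDER = ["chr3", "chr5", "chr7", "chr8", "chr9", "chr13", "chr14",
                   "chr15", "chr16", "chr17", "chr20", "chr4", "chr12"]


def karyotype_for_count(
    ref: ToyReference, chromosome_count: int, tumor_fraction: float = 1.0
) -> SimKaryotype:
    """Karyotype with the requested total chromosome count (diploid base)."""
    copies = {c: 2 for c in ref.chrom_names}
    diploid = 2 * len(copies)
    delta = chromosome_count - diploid
    if delta > 0:
        order = [c for c in _HEH_GAIN_ORDER if c in copies] + [
            c for c in copies if c not in _HEH_GAIN_ORDER
        ]
        for i in range(delta):
            copies[order[i % len(order)]] += 1
    elif delta < 0:
        order = [c for c in _HOL_LOSS_ORDER if c in copies] + [
            c for c in copies if c not in _HOL_LOSS_ORDER
        ]
        i = 0
        for _ in range(-delta):
            while copies[order[i % len(order)]] <= 1:
                i += 1
            copies[order[i % len(order)]] -= 1
            i += 1
    kt = SimKaryotype(copies, tumor_fraction)
    assert kt.chromosome_count == chromosome_count
    return kt


@dataclass
class PlantedLesion:
    """Ground-truth lesion description; the oracle for recovery tests."""

    kind: str
    lesion_id: str
    interval: GenomicInterval | None = None          # focal CNA / snv / upd extent
    breakpoint_1: tuple[str, int] | None = None      # translocation / fusion
    breakpoint_2: tuple[str, int] | None = None
    copies: int | None = None                        # local copy state in tumor
    support_pairs: int | None = None                 # discordant pairs to emit
    vaf: float | None = None                         # snv allele fraction
    genes: tuple[str, str] | None = None             # intended 5'/3' partners

    def __post_init__(self) -> None:
        if self.kind not in LESION_KINDS:
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        if self.support_pairs is not None and self.support_pairs < 0:
            raise ValueError("support_pairs must be >= 0")
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise ValueError("vaf must lie in [0, 1]")


@dataclass
class TruthManifest:
    sample_id: str
    karyotype: SimKaryotype
    lesions: list[PlantedLesion]
    seed: int
    target_mean_coverage: float = 90.0

    def __post_init__(self) -> None:
        if self.target_mean_coverage <= 0:
            raise ValueError("target_mean_coverage must be > 0")
        ids = [l.lesion_id for l in self.lesions]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate lesion ids in manifest")

    def lesion(self, lesion_id: str) -> PlantedLesion:
        for l in self.lesions:
            if l.lesion_id == lesion_id:
                return l
        raise KeyError(lesion_id)

    def lesions_of_kind(self, *kinds: str) -> list[PlantedLesion]:
        return [l for l in self.lesions if l.kind in kinds]

    # JSON round-trip -----------------------------------------------------
    def to_json(self, path=None) -> str:
        def enc(obj):
            if isinstance(obj, GenomicInterval):
                return {"chrom": obj.chrom, "start": obj.start, "end": obj.end,
                        "label": obj.label}
            raise TypeError(type(obj))

        payload = {
            "sample_id": self.sample_id,
            "karyotype": {
                "per_chromosome_copy_number": self.karyotype.per_chromosome_copy_number,
                "tumor_fraction": self.karyotype.tumor_fraction,
                "chromosome_count": self.karyotype.chromosome_count,
            },
            "lesions": [
                {k: v for k, v in asdict(l).items() if v is not None}
                for l in self.lesions
            ],
            "seed": self.seed,
            "target_mean_coverage": self.target_mean_coverage,
        }
        text = json.dumps(payload, indent=2, default=enc)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "TruthManifest":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        lesions = []
        for l in payload["lesions"]:
            iv = l.get("interval")
            lesions.append(
                PlantedLesion(
                    kind=l["kind"],
                    lesion_id=l["lesion_id"],
                    interval=GenomicInterval(**iv) if iv else None,
                    breakpoint_1=tuple(l["breakpoint_1"]) if l.get("breakpoint_1") else None,
                    breakpoint_2=tuple(l["breakpoint_2"]) if l.get("breakpoint_2") else None,
                    copies=l.get("copies"),
                    support_pairs=l.get("support_pairs"),
                    vaf=l.get("vaf"),
                    genes=tuple(l["genes"]) if l.get("genes") else None,
                )
            )
        kt = payload["karyotype"]
        return cls(
            sample_id=payload["sample_id"],
            karyotype=SimKaryotype(
                kt["per_chromosome_copy_number"], kt["tumor_fraction"]
            ),
            lesions=lesions,
            seed=payload["seed"],
            target_mean_coverage=payload["target_mean_coverage"],
        )


def _copy_weight(c: int, f: float) -> float:
    """Expected depth relative to the diploid baseline for copy state c."""
    return (2.0 * (1.0 - f) + c * f) / 2.0


def _uniform_pairs(
    rng: np.random.Generator,
    n: int,
    length: int,
    model: FragmentModel,
    lo: int = 0,
    hi: int | None = None,
) -> dict[str, np.ndarray]:
    """n concordant fragments with leftmost base uniform in [lo, hi)."""
    hi = length if hi is None else hi
    rl = model.read_len
    ins = np.rint(rng.normal(model.insert_mean, model.insert_sd, size=n)).astype("int64")
    ins = np.clip(ins, 2 * rl, max(2 * rl, length - 1))
    upper = np.minimum(hi, length - ins)
    upper = np.maximum(upper, lo + 1)
    start1 = lo + np.floor(rng.random(n) * (upper - lo)).astype("int64")
    start2 = start1 + ins - rl
    return {"start1": start1, "start2": start2}


def simulate_fragments(
    ref: ToyReference,
    truth: TruthManifest,
    model: FragmentModel | None = None,
) -> AlignmentSet:
    """Generate an aligned fragment set realising the planted truth.

    ``target_mean_coverage`` is the diploid-baseline depth: a chromosome at
    copy state c and tumor fraction f receives depth
    ``target * (2(1-f) + c*f)/2``.  Fragment counts are deterministic
    (rounded expectations), positions are drawn from the seeded generator.
    """
    model = model or FragmentModel()
    f = truth.karyotype.tumor_fraction
    rng = np.random.default_rng(truth.seed % (2**31))
    rl = model.read_len
    d0 = truth.target_mean_coverage

    cats = ref.chrom_names
    chrom_code = {c: i for i, c in enumerate(cats)}
    blocks: list[dict[str, np.ndarray]] = []
    block_meta: list[dict] = []

    focal = truth.lesions_of_kind("deletion", "duplication", "tandem_amplification")
    for chrom, length in ref.chromosomes:
        c = truth.karyotype.copies(chrom)
        w = _copy_weight(c, f)
        n = int(round(d0 * w * length / (2 * rl)))
        block = _uniform_pairs(rng, n, length, model)
        keep = np.ones(n, dtype=bool)
        for lesion in focal:
            iv = lesion.interval
            if iv is None or iv.chrom != chrom:
                continue
            wl = _copy_weight(lesion.copies, f)
            ratio = wl / w if w > 0 else 0.0
            inside = (block["start1"] >= iv.start) & (block["start1"] < iv.end)
            if ratio < 1.0:
                drop = inside & (rng.random(n) >= ratio)
                keep &= ~drop
            elif ratio > 1.0:
                n_in = int(round(d0 * w * len(iv) / (2 * rl)))
                n_extra = int(round(n_in * (ratio - 1.0)))
                if n_extra > 0:
                    eb = _uniform_pairs(
                        rng, n_extra, length, model, lo=iv.start, hi=iv.end
                    )
                    blocks.append(eb)
                    block_meta.append(
                        {"n": n_extra, "chrom": chrom, "lesion_id": lesion.lesion_id}
                    )
        block = {k: v[keep] for k, v in block.items()}
        blocks.append(block)
        block_meta.append({"n": int(keep.sum()), "chrom": chrom, "lesion_id": ""})

    # discordant pairs for translocations --------------------------------
    sv_rows: list[dict] = []
    for lesion in truth.lesions_of_kind("translocation"):
        ca, pa = lesion.breakpoint_1
        cb, pb = lesion.breakpoint_2
        n_pairs = lesion.support_pairs
        if n_pairs is None:
            n_pairs = max(3, int(round(d0 * f / 4.0)))
        gap = max(1, int(model.insert_mean) - 2 * rl)
        off_a = rng.integers(0, gap, size=n_pairs)
        off_b = rng.integers(0, gap, size=n_pairs)
        s1 = np.clip(pa - rl - off_a, 0, ref.chrom_length(ca) - rl)
        s2 = np.clip(pb + off_b, 0, ref.chrom_length(cb) - rl)
        for i in range(n_pairs):
            sv_rows.append(
                {
                    "chrom1": ca, "start1": int(s1[i]),
                    "chrom2": cb, "start2": int(s2[i]),
                    "proper": False, "lesion_id": lesion.lesion_id,
                }
            )

    # targeted anchor->target fusions ------------------------------------
    anchor = ref.loci("IGH")[0]
    targets = ref.loci("DUX4_arrays")
    for lesion in truth.lesions_of_kind("targeted_fusion"):
        s = lesion.support_pairs or 0
        n_mate = (s + 1) // 2
        n_sa = s - n_mate
        # decoy primary mapping for the secondary-alignment mechanism: on
        # the anchor chromosome, well away from anchor and target intervals
        decoy_pos = 10_000 if anchor.start > 20_000 else anchor.end + 10_000
        for i in range(s):
            a_start = int(anchor.start + rng.integers(0, len(anchor) - rl))
            tgt = targets[i % len(targets)]
            t_start = int(tgt.start + rng.integers(0, max(1, len(tgt) - rl)))
            if i < n_mate:  # clause i: mate maps into a target region
                sv_rows.append(
                    {
                        "chrom1": anchor.chrom, "start1": a_start,
                        "chrom2": tgt.chrom, "start2": t_start,
                        "mapq2": 0, "proper": False,
                        "lesion_id": lesion.lesion_id,
                        "mechanism": "mate_in_target",
                    }
                )
            else:  # clause ii: secondary alignment in a target region
                sv_rows.append(
                    {
                        "chrom1": anchor.chrom, "start1": a_start,
                        "chrom2": anchor.chrom, "start2": decoy_pos,
                        "proper": False,
                        "sa_chrom": tgt.chrom, "sa_start": t_start, "sa_read": 1,
                        "lesion_id": lesion.lesion_id,
                        "mechanism": "secondary_in_target",
                    }
                )
        assert n_mate + n_sa == s

    # assemble ------------------------------------------------------------
    n_total = sum(m["n"] for m in block_meta)
    start1 = np.concatenate([b["start1"] for b in blocks]) if blocks else np.empty(0, "int64")
    start2 = np.concatenate([b["start2"] for b in blocks]) if blocks else np.empty(0, "int64")
    codes = np.concatenate(
        [np.full(m["n"], chrom_code[m["chrom"]], dtype="int8") for m in block_meta]
    ) if block_meta else np.empty(0, "int8")
    lesion_ids = np.concatenate(
        [np.full(m["n"], m["lesion_id"], dtype=object) for m in block_meta]
    ) if block_meta else np.empty(0, object)

    df = pd.DataFrame(
        {
            "chrom1": pd.Categorical.from_codes(codes, categories=cats),
            "start1": start1,
            "chrom2": pd.Categorical.from_codes(codes.copy(), categories=cats),
            "start2": start2,
        }
    )
    df["mapq1"] = np.int64(60)
    df["mapq2"] = np.int64(60)
    df["proper"] = True
    df["sa_chrom"] = pd.Categorical.from_codes(
        np.full(n_total, -1, dtype="int8"), categories=cats
    )
    df["sa_start"] = np.int64(-1)
    df["sa_read"] = np.int64(0)
    df["lesion_id"] = lesion_ids
    df["snv_site"] = ""
    df["snv_alt"] = False

    if sv_rows:
        sv_df = pd.DataFrame(sv_rows)
        for col, default in [
            ("mapq1", 60), ("mapq2", 60), ("sa_chrom", None), ("sa_start", -1),
            ("sa_read", 0), ("snv_site", ""), ("snv_alt", False),
        ]:
            if col not in sv_df.columns:
                sv_df[col] = default
            elif default is not None:
                sv_df[col] = sv_df[col].fillna(default)
        sv_df = sv_df.drop(columns=[c for c in ("mechanism",) if c in sv_df.columns])
        cat_dtype = pd.CategoricalDtype(categories=cats)
        for col in ("chrom1", "chrom2", "sa_chrom"):
            sv_df[col] = sv_df[col].astype(cat_dtype)
        for col in ("start1", "start2", "mapq1", "mapq2", "sa_start", "sa_read"):
            sv_df[col] = sv_df[col].astype("int64")
        sv_df["proper"] = sv_df["proper"].astype(bool)
        df = pd.concat([df, sv_df[df.columns]], ignore_index=True)

    df["frag_id"] = np.arange(len(df), dtype="int64")

    aset = AlignmentSet(
        df, ref, read_len=rl, insert_mean=model.insert_mean, insert_sd=model.insert_sd
    ).sorted_by_position(reassign_ids=True)

    # targeted SNV allele flags ------------------------------------------
    for lesion in truth.lesions_of_kind("snv"):
        iv = lesion.interval
        pos = iv.start
        fr = aset.fragments
        cover = (
            ((fr["chrom1"] == iv.chrom) & (fr["start1"] <= pos) & (pos < fr["start1"] + rl))
            | ((fr["chrom2"] == iv.chrom) & (fr["start2"] <= pos) & (pos < fr["start2"] + rl))
        ).to_numpy()
        n_cov = int(cover.sum())
        fr.loc[cover, "snv_site"] = iv.label or lesion.lesion_id
        fr.loc[cover, "snv_alt"] = rng.random(n_cov) < (lesion.vaf or 0.0)
    return aset


def emit_baf_table(
    ref: ToyReference,
    truth: TruthManifest,
    sites_per_chrom: int = 30,
    depth: float = 90.0,
    seed_offset: int = 101,
) -> pd.DataFrame:
    """Allele counts at germline heterozygous sites (paired mode only).

    Returns columns (chrom, pos, depth, alt_count).  Sites on a UPD
    chromosome drift toward homozygosity by the tumor fraction; sites in a
    deleted region lose the allele on the deleted homologue.
    """
    f = truth.karyotype.tumor_fraction
    rng = np.random.default_rng((truth.seed + seed_offset) % (2**31))
    rows = []
    upd_chroms = {
        l.interval.chrom for l in truth.lesions_of_kind("upd") if l.interval is not None
    }
    dels = [
        l for l in truth.lesions_of_kind("deletion")
        if l.interval is not None and (l.copies or 2) < 2
    ]
    for chrom, length in ref.chromosomes:
        c = truth.karyotype.copies(chrom)
        w = _copy_weight(c, f)
        positions = np.linspace(length * 0.02, length * 0.98, sites_per_chrom).astype(int)
        for pos in positions:
            p_alt = 0.5
            local_w = w
            if chrom in upd_chroms:
                # CNN-LOH: one parental allele replaced by the other
                sign = 1 if rng.random() < 0.5 else -1
                p_alt = 0.5 + sign * f / 2.0
            for lesion in dels:
                if lesion.interval.contains(chrom, int(pos)):
                    cl = lesion.copies or 1
                    local_w = _copy_weight(cl, f)
                    lost = rng.random() < 0.5
                    alt_copies = (1.0 - f) + f * (cl - 1 if lost else min(cl, 1))
                    p_alt = alt_copies / (2.0 * local_w) if local_w > 0 else 0.0
            d = max(1, int(rng.poisson(depth * local_w)))
            alt = int(rng.binomial(d, min(max(p_alt, 0.0), 1.0)))
            rows.append({"chrom": chrom, "pos": int(pos), "depth": d, "alt_count": alt})
    return pd.DataFrame(rows)


@dataclass
class DecoyAFModel:
    """Population-AF mixture for decoy SVs: a common and a rare component.

    Defaults: 60% common with AF ~ U(0.02, 0.5), 40% rare with
    AF ~ U(0, 0.02) — chosen so the 0.02 frequency filter has a visible,
    tunable effect (expected survival = rare weight).
    """

    common_weight: float = 0.6
    common_range: tuple[float, float] = (0.02, 0.5)
    rare_range: tuple[float, float] = (0.0, 0.02)

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        common = rng.random(n) < self.common_weight
        af = np.where(
            common,
            rng.uniform(*self.common_range, size=n),
            rng.uniform(*self.rare_range, size=n),
        )
        return af


def planted_sv_calls(truth: TruthManifest, include_targeted: bool = False) -> list[SVCall]:
    """SVCall representations of the planted structural lesions.

    Targeted (repetitive-region) fusions are excluded by default: the
    upstream caller ensemble they emulate does not report them, which is
    precisely why the targeted detector exists.
    """
    calls: list[SVCall] = []
    for lesion in truth.lesions:
        if (
            lesion.kind == "translocation"
            or (lesion.kind == "targeted_fusion" and include_targeted)
        ) and lesion.breakpoint_1 is not None and lesion.breakpoint_2 is not None:
            calls.append(
                SVCall(
                    id=f"planted_{lesion.lesion_id}",
                    type="BND",
                    breakpoint_1=Breakpoint(*lesion.breakpoint_1),
                    breakpoint_2=Breakpoint(*lesion.breakpoint_2),
                    caller="toysim",
                    population_af=None,
                )
            )
        elif lesion.kind == "deletion":
            iv = lesion.interval
            calls.append(
                SVCall(
                    id=f"planted_{lesion.lesion_id}",
                    type="DEL",
                    breakpoint_1=Breakpoint(iv.chrom, iv.start),
                    breakpoint_2=Breakpoint(iv.chrom, iv.end),
                    caller="toysim",
                    population_af=None,
                )
            )
        elif lesion.kind in ("duplication", "tandem_amplification"):
            iv = lesion.interval
            calls.append(
                SVCall(
                    id=f"planted_{lesion.lesion_id}",
                    type="DUP",
                    breakpoint_1=Breakpoint(iv.chrom, iv.start),
                    breakpoint_2=Breakpoint(iv.chrom, iv.end),
                    caller="toysim",
                    population_af=None,
                )
            )
    return calls


def emit_sv_vcf(
    truth: TruthManifest,
    ref: ToyReference,
    background: int = 1000,
    af_model: DecoyAFModel | None = None,
    seed: int | None = None,
    artifact_prob: float = 0.15,
    include_targeted: bool = False,
    avoid_shortlist: bool = True,
    avoid_pad: int = 6_000,
) -> list[SVCall]:
    """Planted SVs (no population AF) plus ``background`` decoy calls.

    Decoy AFs follow ``af_model``; a fraction ``artifact_prob`` of decoys
    additionally carries an artifact-database frequency ~ U(0, 0.1).
    Deterministic under the seed (defaults to the manifest seed).

    With ``avoid_shortlist`` (default), decoy breakpoints are rejected out
    of the named gene loci (plus a pad).  This is a scale correction: the
    toy genome packs its shortlist into ~20% of the sequence, whereas on
    the real genome shortlist loci cover a small fraction of a percent, so
    coincidental in-gene artifact calls — and in particular artifact
    breakends joining two driver genes — are vanishingly rare.
    """
    if background < 0:
        raise ValueError("background must be >= 0")
    af_model = af_model or DecoyAFModel()
    rng = np.random.default_rng(
        (truth.seed if seed is None else seed) % (2**31)
    )
    calls = planted_sv_calls(truth, include_targeted=include_targeted)
    if background == 0:
        return calls

    avoid: dict[str, list[tuple[int, int]]] = {}
    if avoid_shortlist:
        for ivs in ref.named_loci.values():
            for iv in ivs:
                avoid.setdefault(iv.chrom, []).append(
                    (max(0, iv.start - avoid_pad), iv.end + avoid_pad)
                )

    def clear(chrom: str, pos: int) -> bool:
        return all(not (s <= pos < e) for s, e in avoid.get(chrom, ()))

    def draw_pos(chrom: str, margin: int) -> int:
        # both ends of a symbolic event must stay clear of the loci
        length = ref.chrom_length(chrom)
        for _ in range(500):
            pos = int(rng.integers(0, max(1, length - margin - 1)))
            if clear(chrom, pos) and clear(chrom, pos + margin):
                return pos
        raise RuntimeError(f"no decoy position clear of loci on {chrom}")

    chrom_names = ref.chrom_names
    lengths = np.array([ref.chrom_length(c) for c in chrom_names], dtype=float)
    probs = lengths / lengths.sum()
    chrom_idx = rng.choice(len(chrom_names), size=background, p=probs)
    types = rng.choice(["DEL", "DUP", "INV", "BND"], size=background,
                       p=[0.45, 0.2, 0.1, 0.25])
    afs = af_model.draw(rng, background)
    has_artifact = rng.random(background) < artifact_prob
    artifact_freqs = rng.uniform(0.0, 0.1, size=background)
    sizes = np.minimum(
        np.rint(np.exp(rng.normal(7.0, 1.0, size=background))).astype(int) + 50,
        50_000,
    )
    for i in range(background):
        chrom = chrom_names[chrom_idx[i]]
        t = str(types[i])
        size = int(sizes[i])
        pos = draw_pos(chrom, size)
        if t == "BND":
            other = chrom_names[int(rng.integers(0, len(chrom_names)))]
            bp2 = Breakpoint(other, draw_pos(other, 0))
        else:
            bp2 = Breakpoint(chrom, pos + size)
        calls.append(
            SVCall(
                id=f"decoy{i}",
                type=t,
                breakpoint_1=Breakpoint(chrom, pos),
                breakpoint_2=bp2,
                caller="toysim",
                population_af=float(afs[i]),
                artifact_freq=float(artifact_freqs[i]) if has_artifact[i] else None,
            )
        )
    return calls


def emit_germline_set(
    truth: TruthManifest,
    tumor_calls: list[SVCall],
    shared_fraction: float = 0.5,
    seed: int | None = None,
    residual_lesion_ids: tuple[str, ...] = (),
) -> list[SVCall]:
    """Paired-normal call set: a shared fraction of the tumor decoys
    (germline polymorphisms) plus any planted lesions named in
    ``residual_lesion_ids`` (residual disease in the "remission" sample —
    reproduces the germline-subtraction pitfall)."""
    if not (0.0 <= shared_fraction <= 1.0):
        raise ValueError("shared_fraction must lie in [0, 1]")
    rng = np.random.default_rng(
        ((truth.seed if seed is None else seed) + 7919) % (2**31)
    )
    germline: list[SVCall] = []
    for call in tumor_calls:
        if call.id.startswith("decoy"):
            if rng.random() < shared_fraction:
                germline.append(call.copy())
        elif call.id.startswith("planted_"):
            lesion_id = call.id[len("planted_"):]
            if lesion_id in residual_lesion_ids:
                germline.append(call.copy())
    return germline
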