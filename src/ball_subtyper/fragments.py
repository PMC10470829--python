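"""Paired-end fragment container.

An :class:`AlignmentSet` holds one row per fragment (read pair) in a
pandas DataFrame, so coverage, binning, discordant-pair extraction and
down-sampling are vectorised.  Mates are co-emitted by construction, which
makes mate completeness (no orphan reads) structural rather than checked.

SAM import/export goes through pysam; reads are written without base calls
(SEQ "*") because the simulator has no base-level error model.  Fragment
annotations travel in tags: ``XL`` (planted lesion id), ``XV``
(``site|0/1`` allele flag at a targeted SNV site), and ``SA`` for the
secondary alignment of repeat-anchored reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .reference import ToyReference

#: DataFrame columns of the fragment table, in canonical order.
FRAGMENT_COLUMNS = [
    "frag_id",
    "chrom1",
    "start1",
    "chrom2",
    "start2",
    "mapq1",
    "mapq2",
    "proper",
    "sa_chrom",
    "sa_start",
    "sa_read",
    "lesion_id",
    "snv_site",
    "snv_alt",
]


def empty_fragment_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "frag_id": pd.Series(dtype="int64"),
            "chrom1": pd.Series(dtype="object"),
            "start1": pd.Series(dtype="int64"),
            "chrom2": pd.Series(dtype="object"),
            "start2": pd.Series(dtype="int64"),
            "mapq1": pd.Series(dtype="int64"),
            "mapq2": pd.Series(dtype="int64"),
            "proper": pd.Series(dtype="bool"),
            "sa_chrom": pd.Series(dtype="object"),
            "sa_start": pd.Series(dtype="int64"),
            "sa_read": pd.Series(dtype="int64"),
            "lesion_id": pd.Series(dtype="object"),
            "snv_site": pd.Series(dtype="object"),
            "snv_alt": pd.Series(dtype="bool"),
        }
    )


@dataclass
class AlignmentSet:
    """Coordinate-sorted set of aligned read pairs over a toy reference."""

    fragments: pd.DataFrame
    reference: ToyReference
    read_len: int = 150
    insert_mean: float = 350.0
    insert_sd: float = 50.0

    def __post_init__(self) -> None:
        missing = [c for c in FRAGMENT_COLUMNS if c not in self.fragments.columns]
        if missing:
            raise ValueError(f"fragment frame missing columns: {missing}")
        # chromosome columns are categorical over the reference's contigs:
        # positions sort/compare on int8 codes instead of strings
        cats = pd.CategoricalDtype(categories=self.reference.chrom_names)
        for col in ("chrom1", "chrom2", "sa_chrom"):
            if self.fragments[col].dtype != cats:
                self.fragments[col] = self.fragments[col].astype(cats)

    # -- basic accessors -------------------------------------------------
    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    @property
    def n_reads(self) -> int:
        return 2 * len(self.fragments)

    def subset(self, mask) -> "AlignmentSet":
        return AlignmentSet(
            self.fragments.loc[mask].reset_index(drop=True),
            self.reference,
            self.read_len,
            self.insert_mean,
            self.insert_sd,
        )

    # -- coverage --------------------------------------------------------
    def mean_coverage(self, chrom: str | None = None) -> float:
        """Mean per-base depth: aligned read bases / reference length."""
        df = self.fragments
        if chrom is None:
            n_reads = 2 * len(df)
            length = self.reference.genome_length
        else:
            length = self.reference.chrom_length(chrom)
            n_reads = int((df["chrom1"] == chrom).sum() + (df["chrom2"] == chrom).sum())
        if length == 0:
            return 0.0
        return n_reads * self.read_len / length

    def fragment_leftmost(self) -> pd.DataFrame:
        """Leftmost mapped base per fragment: (chrom, pos).

        Same-chromosome pairs use min(read starts); cross-chromosome
        (discordant) pairs are attributed to read 1.
        """
        df = self.fragments
        same = (df["chrom1"].cat.codes == df["chrom2"].cat.codes).to_numpy()
        pos = df["start1"].to_numpy().copy()
        np.minimum(pos, df["start2"].to_numpy(), where=same, out=pos)
        return pd.DataFrame({"chrom": df["chrom1"], "pos": pos})

    def sorted_by_position(self, reassign_ids: bool = True) -> "AlignmentSet":
        """Sort fragments by (chromosome order, leftmost pos); renumber ids."""
        left = self.fragment_leftmost()
        key = left["chrom"].cat.codes.to_numpy().astype("int64") * (
            max(l for _, l in self.reference.chromosomes) + 1
        ) + left["pos"].to_numpy()
        idx = np.argsort(key, kind="stable")
        df = self.fragments.iloc[idx].reset_index(drop=True)
        if reassign_ids:
            df = df.assign(frag_id=np.arange(len(df), dtype="int64"))
        return AlignmentSet(df, self.reference, self.read_len, self.insert_mean, self.insert_sd)

    # -- SAM round-trip --------------------------------------------------
    def _sam_header(self) -> pysam.AlignmentHeader:
        return pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "coordinate"},
                "SQ": [
                    {"SN": name, "LN": length}
                    for name, length in self.reference.chromosomes
                ],
            }
        )

    def to_sam(self, path) -> None:
        """Write a coordinate-sorted SAM file (two primary records/fragment)."""
        header = self._sam_header()
        tid = {name: i for i, (name, _) in enumerate(self.reference.chromosomes)}
        records: list[tuple[int, int, pysam.AlignedSegment]] = []
        rl = self.read_len
        for row in self.fragments.itertuples(index=False):
            for which in (1, 2):
                chrom = row.chrom1 if which == 1 else row.chrom2
                start = row.start1 if which == 1 else row.start2
                mchrom = row.chrom2 if which == 1 else row.chrom1
                mstart = row.start2 if which == 1 else row.start1
                a = pysam.AlignedSegment(header)
                a.query_name = f"frag{row.frag_id}"
                a.reference_id = tid[chrom]
                a.reference_start = int(start)
                a.mapping_quality = int(row.mapq1 if which == 1 else row.mapq2)
                a.cigarstring = f"{rl}M"
                a.next_reference_id = tid[mchrom]
                a.next_reference_start = int(mstart)
                flag = 0x1  # paired
                flag |= 0x40 if which == 1 else 0x80
                if row.proper:
                    flag |= 0x2
                # FR orientation: leftmost read forward, mate reverse
                fwd = start <= mstart
                if not fwd:
                    flag |= 0x10
                else:
                    flag |= 0x20
                a.flag = flag
                if chrom == mchrom:
                    a.template_length = int(
                        (mstart + rl - start) if fwd else -(start + rl - mstart)
                    )
                tags = []
                if row.sa_read == which and isinstance(row.sa_chrom, str):
                    tags.append(("SA", f"{row.sa_chrom},{int(row.sa_start) + 1},+,{rl}M,0,0;"))
                if isinstance(row.lesion_id, str) and row.lesion_id:
                    tags.append(("XL", row.lesion_id))
                if which == 1 and isinstance(row.snv_site, str) and row.snv_site:
                    tags.append(("XV", f"{row.snv_site}|{int(bool(row.snv_alt))}"))
                if tags:
                    a.set_tags(tags)
                records.append((tid[chrom], int(start), a))
        records.sort(key=lambda t: (t[0], t[1]))
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for _, _, a in records:
                out.write(a)

    @classmethod
    def from_sam(
        cls,
        path,
        reference: ToyReference,
        read_len: int = 150,
        insert_mean: float = 350.0,
        insert_sd: float = 50.0,
    ) -> "AlignmentSet":
        pairs: dict[str, dict] = {}
        with pysam.AlignmentFile(str(path), "r") as sam:
            for a in sam:
                if a.is_secondary or a.is_supplementary:
                    continue
                rec = pairs.setdefault(a.query_name, {})
                which = 1 if a.is_read1 else 2
                rec[f"chrom{which}"] = a.reference_name
                rec[f"start{which}"] = a.reference_start
                rec[f"mapq{which}"] = a.mapping_quality
                rec["proper"] = bool(a.flag & 0x2)
                if a.has_tag("SA"):
                    sa = a.get_tag("SA").split(";")[0].split(",")
                    rec["sa_chrom"] = sa[0]
                    rec["sa_start"] = int(sa[1]) - 1
                    rec["sa_read"] = which
                if a.has_tag("XL"):
                    rec["lesion_id"] = a.get_tag("XL")
                if a.has_tag("XV"):
                    site, alt = a.get_tag("XV").rsplit("|", 1)
                    rec["snv_site"] = site
                    rec["snv_alt"] = bool(int(alt))
        rows = []
        for qname, rec in pairs.items():
            if "chrom1" not in rec or "chrom2" not in rec:
                raise ValueError(f"orphan read for fragment {qname!r}")
            frag_id = int(qname.replace("frag", "")) if qname.startswith("frag") else len(rows)
            rows.append(
                {
                    "frag_id": frag_id,
                    "chrom1": rec["chrom1"],
                    "start1": rec["start1"],
                    "chrom2": rec["chrom2"],
                    "start2": rec["start2"],
                    "mapq1": rec.get("mapq1", 60),
                    "mapq2": rec.get("mapq2", 60),
                    "proper": rec.get("proper", True),
                    "sa_chrom": rec.get("sa_chrom", None),
                    "sa_start": rec.get("sa_start", -1),
                    "sa_read": rec.get("sa_read", 0),
                    "lesion_id": rec.get("lesion_id", ""),
                    "snv_site": rec.get("snv_site", ""),
                    "snv_alt": rec.get("snv_alt", False),
                }
            )
        if rows:
            df = pd.DataFrame(rows).sort_values("frag_id").reset_index(drop=True)
        else:
            df = empty_fragment_frame()
        return cls(df, reference, read_len, insert_mean, insert_sd)


def concat_alignment_sets(sets: list[AlignmentSet]) -> AlignmentSet:
    if not sets:
        raise ValueError("need at least one alignment set")
    base = sets[0]
    df = pd.concat([s.fragments for s in sets], ignore_index=True)
    return AlignmentSet(df, base.reference, base.read_len, base.insert_mean, base.insert_sd)
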