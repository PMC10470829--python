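"""Loaders for the shipped fixture tables.

The fixtures encode, in this package's vocabulary, the printed cohort
tables of the validation study: the sample manifest (counts per subgroup
and coverage arm), the 20-sample 30x leukemia-only validation set as
per-sample lesion inventories, and the CRLF2-rearranged B-other inventory.
"""

from __future__ import annotations

import json
from importlib import resources

from .classify import FusionLesion, LesionSet
from .cna import CNALesion, CopyStateProfile, classify_ploidy
from .intervals import GenomicInterval


def _fixture_path(name: str):
    return resources.files("ball_subtyper") / "fixtures" / name


def table1_path():
    """Path to the cohort-manifest fixture (samples per subgroup/coverage)."""
    return _fixture_path("table1.tsv")


def shortlist_gene_vocabulary() -> list[str]:
    text = _fixture_path("shortlist_genes.txt").read_text()
    return [l.strip() for l in text.splitlines() if l.strip() and not l.startswith("#")]


def _lesion_set_from_entry(entry: dict) -> LesionSet:
    placeholder = GenomicInterval("NA", 0, 1)
    cnas = [
        CNALesion(
            locus=c["locus"],
            type=c["type"],
            extent=placeholder,
            biallelic=bool(c.get("biallelic", False)),
            exons=c.get("exons"),
        )
        for c in entry.get("cnas", [])
    ]
    if entry.get("iamp21"):
        cnas.append(CNALesion(locus="iAMP21", type="amplification", extent=placeholder))
    ploidy = None
    count = entry.get("chromosome_count")
    if count is not None:
        profile = CopyStateProfile(
            per_chromosome_state={"modal": int(count)},
            segment_states=[],
            purity_assumed=1.0,
        )
        ploidy = classify_ploidy(profile)
    return LesionSet(
        sample_id=entry["sample_id"],
        fusions=[FusionLesion.from_label(lbl) for lbl in entry.get("fusions", [])],
        cnas=cnas,
        ploidy=ploidy,
    )


def load_table2_samples() -> list[tuple[LesionSet, dict]]:
    """The 20 validation-set samples as (LesionSet, expectation) pairs.

    The expectation dict carries the printed subgroup labels
    (``expected_labels`` / ``expected_primary``) and, for the sample whose
    only finding is an ERG deletion, the targeted-assay supporting-pair
    count that later confirmed its DUX4 rearrangement.
    """
    payload = json.loads(_fixture_path("table2_lesions.json").read_text())
    return [(_lesion_set_from_entry(e), e) for e in payload["samples"]]


def load_bother_samples() -> list[tuple[LesionSet, dict]]:
    """The CRLF2-rearranged B-other inventory as (LesionSet, entry) pairs."""
    payload = json.loads(_fixture_path("bother_lesions.json").read_text())
    return [(_lesion_set_from_entry(e), e) for e in payload["samples"]]
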