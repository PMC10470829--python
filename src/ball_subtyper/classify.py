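"""Rule-based assignment of B-ALL samples to genetic subgroups.

A per-sample :class:`LesionSet` (fusions, focal CNAs, ploidy class,
targeted-fusion calls, SNVs, CNN-LOH findings) is evaluated against a set
of declarative :class:`SubgroupRule` objects.  Rules are data: predicates
serialize to/from plain dicts (YAML/JSON-editable) so the vocabulary can be
extended without code changes.

Tiers:

* ``mandatory`` — subgroups stratifying treatment in current protocols
  (HeH, HoL, ETV6::RUNX1, TCF3::PBX1, BCR::ABL1, KMT2A-r, iAMP21,
  ABL-class);
* ``emerging`` — subgroups of the recent classifications that resolve
  B-other ALL (PAX5-alt, CRLF2-r, ZNF384-r, MEF2D-r, IGH::ID4, DUX4-r,
  ETV6::RUNX1-like, PAX5 P80R);
* ``suspect`` — signals that suggest but do not establish a subgroup: an
  isolated ERG deletion flags a probable DUX4 rearrangement, upgradeable
  by the targeted assay (:func:`confirm_dux4`).

Mandatory labels outrank emerging ones; fusion-defined subgroups outrank
ploidy classes (a Ph-positive hyperdiploid case is Ph+ first).  Emerging
labels are co-reported, never suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cna import CNALesion, PloidyClass
from .targeted import FusionCall, SNVCall

MANDATORY, EMERGING, SUSPECT = "mandatory", "emerging", "suspect"

ABL_CLASS_GENES = ("ABL1", "ABL2", "PDGFRB", "PDGFRA", "CSF1R")

#: The eight loci of the UKALL-CNA profile, in reporting order.
CNA_PROFILE_LOCI = ("IKZF1", "CDKN2A/B", "PAX5", "EBF1", "ETV6", "RB1", "BTG1", "PAR1")


@dataclass
class FusionLesion:
    """A gene fusion, 5' partner first; single-gene rearrangements leave
    the 3' side None (e.g. IGH-r with an unlisted partner)."""

    gene5: str
    gene3: str | None = None
    lesion_id: str = ""
    evidence: str = ""

    @property
    def label(self) -> str:
        return f"{self.gene5}::{self.gene3}" if self.gene3 else f"{self.gene5}-r"

    @property
    def genes(self) -> set[str]:
        return {g for g in (self.gene5, self.gene3) if g}

    @classmethod
    def from_label(cls, label: str, lesion_id: str = "") -> "FusionLesion":
        if "::" in label:
            g5, g3 = label.split("::", 1)
            return cls(g5.strip(), g3.strip(), lesion_id=lesion_id)
        gene = label.split("-r")[0].strip()
        return cls(gene, None, lesion_id=lesion_id)


@dataclass
class LesionSet:
    sample_id: str
    fusions: list[FusionLesion] = field(default_factory=list)
    cnas: list[CNALesion] = field(default_factory=list)
    ploidy: PloidyClass | None = None
    targeted_calls: list[FusionCall] = field(default_factory=list)
    snvs: list[SNVCall] = field(default_factory=list)
    snv_labels: list[str] = field(default_factory=list)  # detected-SNV labels
    cnnloh: list = field(default_factory=list)

    def detected_snv_labels(self) -> set[str]:
        labels = set(self.snv_labels)
        labels |= {c.site.label for c in self.snvs if c.verdict == "detected"}
        return labels


# -- predicates -------------------------------------------------------------


class Predicate:
    kind = "base"

    def evaluate(self, lesions: LesionSet) -> list[str] | None:
        """Return matched-lesion descriptions, or None if unsatisfied."""
        raise NotImplementedError

    def to_dict(self) -> dict:
        raise NotImplementedError

    @staticmethod
    def from_dict(d: dict) -> "Predicate":
        kind = d["kind"]
        cls = _PREDICATES[kind]
        return cls._from_dict(d)


@dataclass
class FusionPred(Predicate):
    """A fusion between two named genes (order-insensitive by default)."""

    gene_a: str
    gene_b: str
    ordered: bool = False
    kind = "fusion"

    def evaluate(self, lesions: LesionSet) -> list[str] | None:
        hits = []
        for fz in lesions.fusions:
            if self.ordered:
                if fz.gene5 == self.gene_a and fz.gene3 == self.gene_b:
                    hits.append(fz.label)
            elif fz.genes == {self.gene_a, self.gene_b}:
                hits.append(fz.label)
        return hits or None

    def to_dict(self) -> dict:
        return {"kind": self.kind, "gene_a": self.gene_a, "gene_b": self.gene_b,
                "ordered": self.ordered}

    @classmethod
    def _from_dict(cls, d: dict) -> "FusionPred":
        return cls(d["gene_a"], d["gene_b"], d.get("ordered", False))


@dataclass
class FusionPartnerPred(Predicate):
    """Any fusion involving one of ``genes``, excluding listed partners."""

    genes: tuple[str, ...]
    exclude_partners: tuple[str, ...] = ()
    kind = "fusion_partner"

    def evaluate(self, lesions: LesionSet) -> list[str] | None:
        hits = []
        gene_set = set(self.genes)
        for fz in lesions.fusions:
            involved = fz.genes & gene_set
            if not involved:
                continue
            partners = fz.genes - involved
            if partners & set(self.exclude_partners):
                continue
            hits.append(fz.label)
        return hits or None

    def to_dict(self) -> dict:
        return {"kind": self.kind, "genes": list(self.genes),
                "exclude_partners": list(self.exclude_partners)}

    @classmethod
    def _from_dict(cls, d: dict) -> "FusionPartnerPred":
        return cls(tuple(d["genes"]), tuple(d.get("exclude_partners", ())))


@dataclass
class CnaPred(Predicate):
    locus: str
    types: tuple[str, ...] = ("deletion",)
    kind = "cna"

    def evaluate(self, lesions: LesionSet) -> list[str] | None:
        hits = [
            f"{c.locus} {c.type}"
            for c in lesions.cnas
            if c.locus == self.locus and c.type in self.types
        ]
        return hits or None

    def to_dict(self) -> dict:
        return {"kind": self.kind, "locus": self.locus, "types": list(self.types)}

    @classmethod
    def _from_dict(cls, d: dict) -> "CnaPred":
        return cls(d["locus"], tuple(d.get("types", ("deletion",))))


@dataclass
class PloidyPred(Predicate):
    labels: tuple[str, ...]
    kind = "ploidy"

    def evaluate(self, lesions: LesionSet) -> list[str] | None:
        if lesions.ploidy is not None and lesions.ploidy.label in self.labels:
            return [f"ploidy {lesions.ploidy.label} ({lesions.ploidy.chromosome_count})"]
        return None

    def to_dict(self) -> dict:
        return {"kind": self.kind, "labels": list(self.labels)}

    @classmethod
    def _from_dict(cls, d: dict) -> "PloidyPred":
        return cls(tuple(d["labels"]))


@dataclass
class SnvPred(Predicate):
    label: str
    kind = "snv"

    def evaluate(self, lesions: LesionSet) -> list[str] | None:
        if self.label in lesions.detected_snv_labels():
            return [f"SNV {self.label}"]
        return None

    def to_dict(self) -> dict:
        return {"kind": self.kind, "label": self.label}

    @classmethod
    def _from_dict(cls, d: dict) -> "SnvPred":
        return cls(d["label"])


@dataclass
class TargetedPositivePred(Predicate):
    """A positive call from the targeted discordant-read assay."""

    name: str = "IGH::DUX4"
    kind = "targeted_positive"

    def evaluate(self, lesions: LesionSet) -> list[str] | None:
        hits = [
            f"targeted {c.name}: {c.evidence.supporting_pair_count} pairs"
            for c in lesions.targeted_calls
            if c.name == self.name and c.positive
        ]
        return hits or None

    def to_dict(self) -> dict:
        return {"kind": self.kind, "name": self.name}

    @classmethod
    def _from_dict(cls, d: dict) -> "TargetedPositivePred":
        return cls(d.get("name", "IGH::DUX4"))


@dataclass
class AnyOf(Predicate):
    branches: tuple[Predicate, ...]
    kind = "any_of"

    def evaluate(self, lesions: LesionSet) -> list[str] | None:
        hits: list[str] = []
        for b in self.branches:
            r = b.evaluate(lesions)
            if r:
                hits.extend(r)
        return hits or None

    def to_dict(self) -> dict:
        return {"kind": self.kind, "branches": [b.to_dict() for b in self.branches]}

    @classmethod
    def _from_dict(cls, d: dict) -> "AnyOf":
        return cls(tuple(Predicate.from_dict(b) for b in d["branches"]))


@dataclass
class AllOf(Predicate):
    branches: tuple[Predicate, ...]
    kind = "all_of"

    def evaluate(self, lesions: LesionSet) -> list[str] | None:
        hits: list[str] = []
        for b in self.branches:
            r = b.evaluate(lesions)
            if not r:
                return None
            hits.extend(r)
        return hits

    def to_dict(self) -> dict:
        return {"kind": self.kind, "branches": [b.to_dict() for b in self.branches]}

    @classmethod
    def _from_dict(cls, d: dict) -> "AllOf":
        return cls(tuple(Predicate.from_dict(b) for b in d["branches"]))


_PREDICATES = {
    cls.kind: cls
    for cls in (
        FusionPred, FusionPartnerPred, CnaPred, PloidyPred, SnvPred,
        TargetedPositivePred, AnyOf, AllOf,
    )
}


# -- rules ------------------------------------------------------------------


@dataclass
class SubgroupRule:
    label: str
    predicate: Predicate
    tier: str  # mandatory / emerging / suspect
    precedence: int
    enabled: bool = True

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "predicate": self.predicate.to_dict(),
            "tier": self.tier,
            "precedence": self.precedence,
            "enabled": self.enabled,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SubgroupRule":
        return cls(
            label=d["label"],
            predicate=Predicate.from_dict(d["predicate"]),
            tier=d["tier"],
            precedence=d["precedence"],
            enabled=d.get("enabled", True),
        )


def default_rules() -> list[SubgroupRule]:
    """The shipped rule set: 8 mandatory, 8 emerging, 1 suspect rule.

    The IKZF1-plus profile is a CNA profile, not a subgroup, and lives in
    :func:`build_cna_profile`.  The PAX5 P80R rule ships disabled: the SNV
    was assessed but defines no case in the reference workflow.
    """
    R = SubgroupRule
    rules = [
        # mandatory: fusion-defined subgroups outrank ploidy classes
        R("ETV6::RUNX1", FusionPred("ETV6", "RUNX1"), MANDATORY, 0),
        R("TCF3::PBX1", FusionPred("TCF3", "PBX1"), MANDATORY, 1),
        R("Ph-positive", FusionPred("BCR", "ABL1"), MANDATORY, 2),
        R("KMT2A-r", FusionPartnerPred(("KMT2A",)), MANDATORY, 3),
        R(
            "ABL-class",
            FusionPartnerPred(ABL_CLASS_GENES, exclude_partners=("BCR",)),
            MANDATORY, 4,
        ),
        R("iAMP21", CnaPred("iAMP21", ("amplification",)), MANDATORY, 5),
        R("HoL", PloidyPred(("HoL", "near_haploid")), MANDATORY, 6),
        R("HeH", PloidyPred(("HeH",)), MANDATORY, 7),
        # emerging subgroups among B-other ALL
        R(
            "CRLF2-r",
            AnyOf((FusionPred("IGH", "CRLF2"), FusionPred("P2RY8", "CRLF2"))),
            EMERGING, 10,
        ),
        R("ZNF384-r", FusionPartnerPred(("ZNF384",)), EMERGING, 11),
        R("MEF2D-r", FusionPartnerPred(("MEF2D",)), EMERGING, 12),
        R("IGH::ID4", FusionPred("IGH", "ID4"), EMERGING, 13),
        R("DUX4-r", TargetedPositivePred("IGH::DUX4"), EMERGING, 14),
        R(
            "ETV6::RUNX1-like",
            AnyOf((
                FusionPred("ETV6", "IKZF1"),
                FusionPred("FUS", "ERG"),
                AllOf((CnaPred("ETV6", ("deletion",)), FusionPartnerPred(("IKZF1",)))),
            )),
            EMERGING, 15,
        ),
        # PAX5-alt is often a secondary alteration: co-reported, but it
        # ranks after the fusion-defined emerging subgroups
        R(
            "PAX5-alt",
            AnyOf((
                FusionPartnerPred(("PAX5",)),
                CnaPred("PAX5", ("deletion", "amplification")),
            )),
            EMERGING, 16,
        ),
        R("PAX5 P80R", SnvPred("PAX5 P80R"), EMERGING, 17, enabled=False),
        # suspect: isolated ERG deletion signals DUX4-r, pending confirmation
        R(
            "DUX4-suspect (unconfirmed)",
            CnaPred("ERG", ("deletion",)),
            SUSPECT, 100,
        ),
    ]
    return rules


@dataclass
class SubgroupCall:
    sample_id: str
    labels: list[str]
    tier: str | None
    rationale: dict[str, list[str]]
    unclassified: bool

    @property
    def primary(self) -> str | None:
        return self.labels[0] if self.labels else None

    @property
    def class_defining(self) -> bool:
        """True if at least one mandatory or emerging label fired."""
        return self.tier in (MANDATORY, EMERGING)


def assign_subgroups(
    lesions: LesionSet, rules: list[SubgroupRule] | None = None
) -> SubgroupCall:
    """Evaluate all rules; order labels by (tier, precedence).

    Suspect rules fire only when no mandatory or emerging rule matched.
    An empty result is an unclassified call.
    """
    rules = rules if rules is not None else default_rules()
    tier_rank = {MANDATORY: 0, EMERGING: 1, SUSPECT: 2}
    satisfied: list[tuple[int, int, SubgroupRule, list[str]]] = []
    for rule in rules:
        if not rule.enabled or rule.tier == SUSPECT:
            continue
        if rule.tier not in tier_rank:
            raise ValueError(f"malformed rule {rule.label!r}: tier {rule.tier!r}")
        hits = rule.predicate.evaluate(lesions)
        if hits:
            satisfied.append((tier_rank[rule.tier], rule.precedence, rule, hits))
    if not satisfied:
        for rule in rules:
            if rule.enabled and rule.tier == SUSPECT:
                hits = rule.predicate.evaluate(lesions)
                if hits:
                    satisfied.append((tier_rank[SUSPECT], rule.precedence, rule, hits))
    satisfied.sort(key=lambda t: (t[0], t[1]))
    labels = [rule.label for _, _, rule, _ in satisfied]
    rationale = {rule.label: hits for _, _, rule, hits in satisfied}
    tier = satisfied[0][2].tier if satisfied else None
    return SubgroupCall(
        sample_id=lesions.sample_id,
        labels=labels,
        tier=tier,
        rationale=rationale,
        unclassified=not labels,
    )


def confirm_dux4(call: SubgroupCall, targeted: FusionCall) -> SubgroupCall:
    """Upgrade a DUX4-suspect (or unclassified) call on a positive targeted
    IGH::DUX4 result; a negative result leaves the call unchanged."""
    if targeted.name != "IGH::DUX4":
        raise ValueError("confirm_dux4 expects the IGH::DUX4 targeted call")
    if not targeted.positive:
        return call
    labels = [l for l in call.labels if not l.startswith("DUX4-suspect")]
    rationale = {k: v for k, v in call.rationale.items() if not k.startswith("DUX4-suspect")}
    if "DUX4-r" not in labels:
        labels.append("DUX4-r")
    rationale["DUX4-r"] = [
        f"targeted IGH::DUX4 positive: {targeted.evidence.supporting_pair_count} "
        f"supporting pairs (threshold {targeted.threshold_used})"
    ]
    tier = call.tier if call.tier in (MANDATORY, EMERGING) else EMERGING
    return SubgroupCall(
        sample_id=call.sample_id,
        labels=labels,
        tier=tier,
        rationale=rationale,
        unclassified=False,
    )


@dataclass
class CNAProfile:
    states: dict[str, str]  # locus -> normal / deletion / amplification
    ikzf1_plus: bool

    def to_dict(self) -> dict:
        return {"states": dict(self.states), "ikzf1_plus": self.ikzf1_plus}


def build_cna_profile(cnas: list[CNALesion]) -> CNAProfile:
    """UKALL-CNA eight-locus profile plus the IKZF1-plus flag.

    IKZF1-plus (encoded from its published definition; configurable data,
    not protocol of the reference workflow itself): IKZF1 deleted AND at
    least one of CDKN2A/B, PAX5, PAR1 deleted AND ERG not deleted.
    """
    states = {locus: "normal" for locus in CNA_PROFILE_LOCI}
    erg_deleted = False
    for c in cnas:
        locus = "CDKN2A/B" if c.locus in ("CDKN2A", "CDKN2B") else c.locus
        if locus in states and c.type in ("deletion", "amplification"):
            states[locus] = c.type
        if locus == "ERG" and c.type == "deletion":
            erg_deleted = True
    ikzf1_plus = (
        states["IKZF1"] == "deletion"
        and any(states[l] == "deletion" for l in ("CDKN2A/B", "PAX5", "PAR1"))
        and not erg_deleted
    )
    return CNAProfile(states=states, ikzf1_plus=ikzf1_plus)
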