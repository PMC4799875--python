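"""Pedigree-based co-segregation assessment and familial/sporadic labeling.

Co-segregation is defined operationally: at least two genotype-positive
family members sharing the same phenotype label.  The proband counts
toward the two (configurable).  Inheritance patterns are carried in the
catalog as reported by the source literature and are never inferred from
pedigrees; the only computed pedigree-structure check is the informational
X-linked consistency rule (no male-to-male transmission of carrier status
for X-chromosome genes such as TAZ).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from .catalog import Cosegregation


class PedigreeError(ValueError):
    pass


class Genotype(str, Enum):
    CARRIER = "carrier"
    NON_CARRIER = "non_carrier"
    UNKNOWN = "unknown"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


AFFECTED_PHENOTYPES = frozenset({"LVNC", "DCM", "HCM", "Barth", "CHD", "other"})
UNAFFECTED = "unaffected"


@dataclass(frozen=True)
class PedigreeMember:
    member_id: str
    genotype: Genotype = Genotype.UNKNOWN
    phenotype: str = UNAFFECTED
    sex: Sex = Sex.UNKNOWN
    proband: bool = False
    relation: str = ""
    parent_ids: tuple[str, ...] = ()

    @property
    def affected(self) -> bool:
        return self.phenotype in AFFECTED_PHENOTYPES


@dataclass(frozen=True)
class Pedigree:
    family_id: str
    variant_id: str
    members: tuple[PedigreeMember, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise PedigreeError(f"{self.family_id}: pedigree needs at least one member")
        ids = [m.member_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise PedigreeError(f"{self.family_id}: duplicate member_id")
        if sum(m.proband for m in self.members) != 1:
            raise PedigreeError(f"{self.family_id}: exactly one proband required")

    def member(self, member_id: str) -> PedigreeMember:
        for m in self.members:
            if m.member_id == member_id:
                return m
        raise PedigreeError(f"{self.family_id}: no member {member_id!r}")


def assess_cosegregation(
    pedigree: Pedigree,
    phenotype_set: frozenset[str] | set[str] = AFFECTED_PHENOTYPES,
    *,
    count_proband: bool = True,
    equivalence: frozenset[str] | None = None,
) -> Cosegregation:
    """Co-segregation call for one family.

    ``yes`` iff at least two genotype-positive members share a phenotype
    label from ``phenotype_set`` (strict label equality by default; pass
    ``equivalence`` to treat a set of labels, e.g. {LVNC, DCM}, as one
    spectrum).  ``not_assessed`` when fewer than two members have known
    genotype; ``no`` when genotype data exist but the criterion fails.
    """
    if not phenotype_set:
        raise PedigreeError("phenotype_set must be non-empty")
    known = [m for m in pedigree.members if m.genotype is not Genotype.UNKNOWN]
    if not count_proband:
        known = [m for m in known if not m.proband]
    if len(known) < 2:
        return Cosegregation.NOT_ASSESSED
    carriers = [m for m in known if m.genotype is Genotype.CARRIER]

    def label(m: PedigreeMember) -> str:
        if equivalence and m.phenotype in equivalence:
            return "|".join(sorted(equivalence))
        return m.phenotype

    by_label: dict[str, int] = {}
    for m in carriers:
        if m.phenotype in phenotype_set:
            by_label[label(m)] = by_label.get(label(m), 0) + 1
    return Cosegregation.YES if any(n >= 2 for n in by_label.values()) else Cosegregation.NO


def familial_label(pedigree: Pedigree) -> str:
    """``familial`` iff at least two members (any genotype) are affected."""
    n_affected = sum(m.affected for m in pedigree.members)
    return "familial" if n_affected >= 2 else "sporadic"


def xlinked_consistency(
    pedigree: Pedigree, gene: str, xlinked_genes: frozenset[str] = frozenset({"TAZ"})
) -> bool:
    """No male-to-male transmission of carrier status for X-linked genes.

    Informational check only — never alters classification.  Vacuously
    true for autosomal genes.
    """
    if gene.upper() not in xlinked_genes:
        return True
    carriers = {m.member_id for m in pedigree.members if m.genotype is Genotype.CARRIER}
    for m in pedigree.members:
        if m.member_id in carriers and m.sex is Sex.MALE:
            for pid in m.parent_ids:
                parent = pedigree.member(pid)
                if parent.sex is Sex.MALE and parent.member_id in carriers:
                    return False
    return True


# ---------------------------------------------------------------------------
# Pedigree TSV I/O — one row per member
# ---------------------------------------------------------------------------

_PED_COLUMNS = [
    "family_id", "variant_id", "member_id", "proband",
    "sex", "genotype", "phenotype", "relation", "parent_ids",
]


def read_pedigrees(path: str | Path) -> list[Pedigree]:
    path = Path(path)
    families: dict[tuple[str, str], list[PedigreeMember]] = {}
    order: list[tuple[str, str]] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_PED_COLUMNS[:7]) - set(reader.fieldnames or ())
        if missing:
            raise PedigreeError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            key = (row["family_id"], row["variant_id"])
            if key not in families:
                families[key] = []
                order.append(key)
            families[key].append(
                PedigreeMember(
                    member_id=row["member_id"],
                    genotype=Genotype(row["genotype"] or "unknown"),
                    phenotype=row["phenotype"] or UNAFFECTED,
                    sex=Sex(row["sex"] or "unknown"),
                    proband=row["proband"].strip().lower() in {"1", "true", "yes"},
                    relation=row.get("relation", "") or "",
                    parent_ids=tuple(
                        filter(None, (row.get("parent_ids", "") or "").split(","))
                    ),
                )
            )
    return [
        Pedigree(family_id=fam, variant_id=var, members=tuple(members))
        for (fam, var), members in ((k, families[k]) for k in order)
    ]


def write_pedigrees(pedigrees: list[Pedigree], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_PED_COLUMNS)
        for ped in pedigrees:
            for m in ped.members:
                writer.writerow(
                    [
                        ped.family_id, ped.variant_id, m.member_id,
                        "1" if m.proband else "0",
                        m.sex.value, m.genotype.value, m.phenotype,
                        m.relation, ",".join(m.parent_ids),
                    ]
                )
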