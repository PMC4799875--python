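"""Synthetic input generators: cohorts, alignment columns, pedigrees, fixture.

Every pipeline stage is testable without downloads:

* :func:`simulate_cohort` draws per-individual genotypes binomially at
  given true allele frequencies for an ESP-like cohort (6503 exomes:
  2203 African American + 4300 European American) or an ExAC-like cohort
  (60,706 exomes), with hemizygous males for X-linked genes, and records
  AC/AN/carrier counts exactly consistent with the drawn genotypes.
* :func:`simulate_alignment_column` substitutes each non-reference
  species independently with a tunable probability.
* :func:`simulate_pedigree` transmits a variant through a nuclear family
  under the variant's inheritance pattern with configurable penetrance.
* :func:`make_paper_fixture` builds the marginal-matched catalog of 60
  literature-reported LVNC variants in 12 genes together with matching
  population stores and pedigrees.  Variants named in the source
  literature are placed with their reported attributes; filler rows are
  flagged ``synthetic``.  The fixture is constructed so that the *real*
  pipeline — parsing, store lookup, four-tool prediction, consensus
  voting, pedigree assessment — independently re-derives every marginal.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .catalog import (
    Catalog,
    Cosegregation,
    Inheritance,
    Phenotype,
    VariantClass,
    VariantRecord,
    parse_protein_change,
)
from .population import CohortCounts, PopulationStore
from .predictors import AlignmentColumn, RESIDUES, grantham_distance
from .segregation import Genotype, Pedigree, PedigreeMember, Sex


class FixtureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """A background exome cohort: subpopulation sizes and ploidy rule."""

    cohort_id: str
    subpops: tuple[tuple[str, int], ...]
    x_linked: bool = False
    male_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.subpops or any(n <= 0 for _, n in self.subpops):
            raise FixtureError("every subpopulation needs n_individuals > 0")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise FixtureError("male_fraction must be in [0, 1]")

    @property
    def n_individuals(self) -> int:
        return sum(n for _, n in self.subpops)


#: The two cohorts emulated by default.
ESP_SPEC = CohortSpec(
    cohort_id="ESP",
    subpops=(("AfricanAmerican", 2203), ("EuropeanAmerican", 4300)),
)
EXAC_SPEC = CohortSpec(cohort_id="ExAC", subpops=(("ALL", 60706),))


def simulate_cohort(
    spec: CohortSpec,
    variants: Sequence[tuple[str, str, float]],
    seed: int | None = None,
) -> PopulationStore:
    """Draw genotypes for (gene, hgvs_p, true allele frequency) triples.

    Autosomal sites get two binomial draws per individual; X-linked sites
    one draw for males.  AC, AN and carrier counts are tallied from the
    drawn genotypes, so every store invariant holds by construction.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    store = PopulationStore()
    for gene, hgvs, freq in variants:
        if not 0.0 <= freq <= 0.5:
            raise FixtureError(f"{gene} {hgvs}: allele frequency {freq} outside [0, 0.5]")
        subpop_counts: dict[str, tuple[int, int]] = {}
        carriers = 0
        for name, n in spec.subpops:
            if spec.x_linked:
                n_males = int(round(n * spec.male_fraction))
                n_females = n - n_males
                g_m = rng.binomial(1, freq, size=n_males)
                g_f = rng.binomial(2, freq, size=n_females)
                ac = int(g_m.sum() + g_f.sum())
                an = n_males + 2 * n_females
                carriers += int((g_m > 0).sum() + (g_f > 0).sum())
            else:
                g = rng.binomial(2, freq, size=n)
                ac = int(g.sum())
                an = 2 * n
                carriers += int((g > 0).sum())
            subpop_counts[name] = (ac, an)
        store.add(
            gene,
            hgvs,
            CohortCounts(
                cohort_id=spec.cohort_id,
                subpop_counts=subpop_counts,
                carrier_count=carriers,
                n_individuals=spec.n_individuals,
            ),
        )
    return store


# ---------------------------------------------------------------------------
# Alignment columns
# ---------------------------------------------------------------------------


def simulate_alignment_column(
    n_species: int,
    substitution_prob: float,
    seed: int,
    reference_residue: str = "K",
) -> AlignmentColumn:
    """One alignment column: each non-reference species substituted
    independently with ``substitution_prob``, uniformly among the 19
    alternative residues."""
    if n_species < 2:
        raise FixtureError("need at least 2 species")
    if not 0.0 <= substitution_prob <= 1.0:
        raise FixtureError("substitution_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    alternatives = [r for r in RESIDUES if r != reference_residue]
    residues = {}
    for i in range(n_species - 1):
        if rng.random() < substitution_prob:
            residues[f"species_{i + 1}"] = alternatives[rng.integers(len(alternatives))]
        else:
            residues[f"species_{i + 1}"] = reference_residue
    return AlignmentColumn(reference_residue=reference_residue, species_residues=residues)


# ---------------------------------------------------------------------------
# Pedigrees
# ---------------------------------------------------------------------------


def simulate_pedigree(
    n_members: int,
    penetrance: float,
    variant: VariantRecord,
    seed: int,
    phenocopy_rate: float = 0.0,
    phenotype: str = "LVNC",
) -> Pedigree:
    """A nuclear family (two founders + children) segregating ``variant``.

    The transmitting founder is the mother for X-linked genes (no
    male-to-male transmission by construction), otherwise the father.
    Carriers are affected with probability ``penetrance``; non-carriers
    are phenocopies with probability ``phenocopy_rate``.
    """
    if n_members < 3:
        raise FixtureError("nuclear family needs at least 3 members")
    if not 0.0 <= penetrance <= 1.0 or not 0.0 <= phenocopy_rate <= 1.0:
        raise FixtureError("penetrance and phenocopy_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    x_linked = Inheritance.X_LINKED in variant.inheritance
    carrier_parent = "MO" if x_linked else "FA"

    def pheno(is_carrier: bool) -> str:
        if is_carrier:
            return phenotype if rng.random() < penetrance else "unaffected"
        return phenotype if rng.random() < phenocopy_rate else "unaffected"

    members = [
        PedigreeMember(
            member_id="FA", sex=Sex.MALE,
            genotype=Genotype.CARRIER if carrier_parent == "FA" else Genotype.NON_CARRIER,
            phenotype=pheno(carrier_parent == "FA"),
        ),
        PedigreeMember(
            member_id="MO", sex=Sex.FEMALE,
            genotype=Genotype.CARRIER if carrier_parent == "MO" else Genotype.NON_CARRIER,
            phenotype=pheno(carrier_parent == "MO"),
        ),
    ]
    for i in range(n_members - 2):
        inherited = bool(rng.random() < 0.5)
        sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
        if x_linked and inherited and sex is Sex.MALE:
            pass  # hemizygous carrier son of a carrier mother: allowed
        members.append(
            PedigreeMember(
                member_id=f"C{i + 1}",
                sex=sex,
                genotype=Genotype.CARRIER if inherited else Genotype.NON_CARRIER,
                phenotype=pheno(inherited),
                proband=(i == 0),
                parent_ids=("FA", "MO"),
            )
        )
    return Pedigree(
        family_id=f"SIM-{variant.variant_id}", variant_id=variant.variant_id,
        members=tuple(members),
    )


# ---------------------------------------------------------------------------
# The marginal-matched fixture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureSpec:
    """Marginal targets of the curated-catalog fixture."""

    n_variants: int = 60
    per_gene_counts: tuple[tuple[str, int], ...] = (
        ("MYH7", 24), ("MYBPC3", 7), ("TNNT2", 5), ("TAZ", 4), ("LDB3", 4),
        ("TNNI3", 4), ("MIB1", 3), ("PRDM16", 3), ("TPM1", 3),
        ("DTNA", 1), ("MYH7B", 1), ("CASQ2", 1),
    )
    n_nonsense: int = 4
    n_esp_positive: int = 9
    n_exac_positive: int = 18
    n_overlap: int = 8
    class_counts: tuple[tuple[str, int], ...] = (
        ("pathogenic", 29), ("VUS", 23), ("benign", 3), ("unclassifiable", 1),
    )
    esp_pathogenic: int = 4
    exac_pathogenic: int = 10
    myh7_pathogenic: int = 17
    myh7_benign: int = 0
    n_familial: int = 42
    n_cosegregating: int = 30
    seed: int = 20150720

    def validate(self) -> None:
        """Check mutual consistency of the marginal targets."""
        problems: list[str] = []
        gene_total = sum(n for _, n in self.per_gene_counts)
        if gene_total != self.n_variants:
            problems.append(
                f"per-gene counts sum to {gene_total}, not n_variants={self.n_variants}"
            )
        if self.n_overlap > min(self.n_esp_positive, self.n_exac_positive):
            problems.append("overlap exceeds min(ESP-positive, ExAC-positive)")
        n_analyzed = self.n_variants - self.n_nonsense
        class_total = sum(n for _, n in self.class_counts)
        if class_total != n_analyzed:
            problems.append(
                f"class counts sum to {class_total}, not analyzed={n_analyzed}"
            )
        classes = dict(self.class_counts)
        if self.esp_pathogenic > min(self.n_esp_positive, classes.get("pathogenic", 0)):
            problems.append("ESP-positive pathogenic count infeasible")
        if self.exac_pathogenic > min(self.n_exac_positive, classes.get("pathogenic", 0)):
            problems.append("ExAC-positive pathogenic count infeasible")
        myh7 = dict(self.per_gene_counts).get("MYH7", 0)
        if self.myh7_pathogenic + self.myh7_benign > myh7:
            problems.append("MYH7 class counts exceed MYH7 variant count")
        if self.n_cosegregating > self.n_familial:
            problems.append("co-segregating count exceeds familial count")
        if self.n_familial > self.n_variants:
            problems.append("familial count exceeds variant count")
        if problems:
            raise FixtureError("inconsistent fixture spec: " + "; ".join(problems))


DEFAULT_FIXTURE_SPEC = FixtureSpec()

# Heredity codes: fc = familial with co-segregation, fn = familial without,
# sp = sporadic.  Class codes: P pathogenic, V VUS, B benign,
# U unclassifiable (residue/isoform mismatch), N not analyzed (stop gain).
#
# Variants named in the source literature, with their reported attributes.
# hgvs may hold two changes (cis compound allele on one MYH7 haplotype).
_NAMED = [
    # gene, hgvs, class, esp, exac, heredity, inheritance, phenotypes
    ("MYH7", "p.R243H", "P", False, True, "fc", "AD", ("LVNC",)),
    ("MYH7", "p.R1359C", "P", False, True, "sp", "SP", ("LVNC",)),
    ("MYH7", "p.Y283D", "P", False, False, "fc", "AD", ("LVNC", "CHD")),
    ("MYH7", "p.M531R", "P", False, False, "sp", "SP", ("LVNC",)),
    ("MYH7", "p.R281T", "P", False, False, "fc", "AD", ("LVNC",)),
    ("MYH7", "p.D545N;p.D955N", "P", False, False, "fc", "AD", ("LVNC",)),
    ("MYBPC3", "p.G5R", "V", True, True, "sp", "SP", ("LVNC",)),
    ("MYBPC3", "p.G490R", "P", True, True, "fc", "AD", ("LVNC",)),
    ("MYBPC3", "p.R502W", "P", True, True, "fc", "AD", ("HCM", "LVNC")),
    ("MYBPC3", "p.G148R", "V", False, True, "sp", "SP", ("LVNC",)),
    ("MYBPC3", "p.R820W", "P", False, True, "fn", "AR", ("LVNC",)),
    ("MYBPC3", "p.P873L", "V", False, True, "sp", "SP", ("LVNC",)),
    ("TAZ", "p.G197R", "V", True, True, "fn", "XL", ("LVNC",)),
    ("TAZ", "p.G195*", "N", False, False, "fc", "XL", ("LVNC", "Barth", "DCM")),
    ("DTNA", "p.P121L", "B", False, True, "fc", "AD", ("LVNC",)),
    ("MYH7B", "p.R890C", "V", True, True, "fc", "AD", ("LVNC",)),
    ("CASQ2", "p.H244R", "P", True, True, "fc", "AD", ("LVNC",)),
    ("LDB3", "p.D626N", "U", False, False, "sp", "SP", ("LVNC",)),
    ("LDB3", "p.D117N", "V", True, True, "sp", "SP", ("LVNC",)),
    ("MIB1", "p.R530*", "N", False, False, "sp", "SP", ("LVNC",)),
    ("MIB1", "p.V943F", "V", True, False, "sp", "SP", ("LVNC",)),
    ("PRDM16", "p.K702*", "N", False, False, "fn", "AD", ("LVNC",)),
    ("TNNT2", "p.E96K", "P", True, True, "fn", "AD", ("LVNC", "DCM")),
    ("TNNT2", "p.R131W", "P", False, True, "sp", "SP", ("LVNC",)),
    ("TPM1", "p.D84N", "P", False, False, "sp", "SP", ("LVNC", "DCM")),
]

# Synthetic filler rows completing the marginal structure: the fourth
# stop gain (only three are named in the literature) and per-gene
# missense placeholders with assigned class / presence / heredity.
_SYNTH = [
    ("PRDM16", "N", False, False, "sp"),
    ("MIB1", "P", False, True, "fc"),
    ("PRDM16", "V", False, True, "fc"),
    ("TNNI3", "P", False, True, "fc"),
    ("TNNI3", "B", False, False, "sp"),
    ("TNNI3", "V", False, False, "fc"),
    ("TNNI3", "V", False, False, "sp"),
    ("TPM1", "B", False, False, "fn"),
    ("TPM1", "V", False, False, "fc"),
    ("MYBPC3", "V", False, False, "fc"),
    ("TAZ", "P", False, False, "fc"),
    ("TAZ", "V", False, False, "fn"),
    ("TNNT2", "P", False, False, "fc"),
    ("TNNT2", "V", False, False, "fn"),
    ("TNNT2", "V", False, False, "fc"),
    ("LDB3", "P", False, False, "fc"),
    ("LDB3", "V", False, False, "fn"),
    # 17 MYH7 placeholders: 10 pathogenic, 7 VUS
    *[("MYH7", "P", False, False, h) for h in
      ("fc", "fc", "fc", "fc", "fc", "fc", "fc", "fn", "fn", "sp")],
    *[("MYH7", "V", False, False, h) for h in
      ("fc", "fc", "fc", "fn", "fn", "sp", "sp")],
]

_INHERITANCE = {
    "AD": frozenset({Inheritance.AUTOSOMAL_DOMINANT}),
    "AR": frozenset({Inheritance.AUTOSOMAL_RECESSIVE}),
    "XL": frozenset({Inheritance.X_LINKED}),
    "SP": frozenset({Inheritance.SPORADIC}),
}

# Residue pairs with Grantham distance <= 100, used for benign placeholders
# (a benign consensus requires a conservative substitution).
_CONSERVATIVE_PAIRS = [("D", "N"), ("K", "R"), ("F", "Y"), ("E", "D"), ("T", "S")]
_ASSORTED_PAIRS = [
    ("G", "R"), ("D", "Y"), ("L", "P"), ("A", "T"), ("R", "W"),
    ("C", "Y"), ("S", "F"), ("E", "K"), ("H", "Q"), ("N", "I"),
    ("M", "K"), ("V", "D"), ("P", "S"), ("W", "L"), ("Q", "R"),
]


def _tool_labels_for(cls: str, changes) -> tuple[dict[str, str], bool | None]:
    """Raw tool labels that make the real consensus engine emit ``cls``.

    The Grantham vote is fixed by the residues themselves, so the other
    channels are chosen around it: pathogenic gets three pathogenic
    labels; VUS gets exactly one pathogenic vote in total; benign gets
    benign labels everywhere (feasible only for conservative pairs).
    """
    if cls in ("N", "U"):
        return {}, None
    score = max(grantham_distance(c.ref_residue, c.alt_residue) for c in changes)
    if cls == "P":
        return {"sift": "damaging", "polyphen2": "probably damaging"}, True
    if cls == "B":
        if score > 100:
            raise FixtureError(
                f"cannot build a benign variant from a radical substitution "
                f"({changes[0].raw}, distance {score:.0f})"
            )
        return {"sift": "tolerant", "polyphen2": "benign"}, False
    if cls == "V":
        # one pathogenic vote in total: Grantham's if radical, else SIFT's
        sift = "tolerant" if score > 100 else "damaging"
        return {"sift": sift, "polyphen2": "benign"}, False
    raise FixtureError(f"unknown class code {cls!r}")


@dataclass
class FixtureBundle:
    catalog: Catalog
    esp_store: PopulationStore
    exac_store: PopulationStore
    pedigrees: list[Pedigree]
    spec: FixtureSpec


def _build_records(spec: FixtureSpec) -> list[dict]:
    """Assemble the row plan: named variants plus synthetic placeholders."""
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    for gene, hgvs, cls, esp, exac, heredity, inh, phenos in _NAMED:
        rows.append(
            dict(gene=gene, hgvs=hgvs, cls=cls, esp=esp, exac=exac,
                 heredity=heredity, inh=inh, phenos=phenos, synthetic=False)
        )
    positions = iter(range(1001, 1001 + 10 * len(_SYNTH), 10))
    conservative = iter(_CONSERVATIVE_PAIRS)
    for gene, cls, esp, exac, heredity in _SYNTH:
        pos = next(positions)
        if cls == "N":
            ref = RESIDUES[rng.integers(len(RESIDUES))]
            hgvs = f"p.{ref}{pos}*"
        elif cls == "B":
            ref, alt = next(conservative)
            hgvs = f"p.{ref}{pos}{alt}"
        else:
            ref, alt = _ASSORTED_PAIRS[int(rng.integers(len(_ASSORTED_PAIRS)))]
            hgvs = f"p.{ref}{pos}{alt}"
        inh = "XL" if gene == "TAZ" else ("SP" if heredity == "sp" else "AD")
        rows.append(
            dict(gene=gene, hgvs=hgvs, cls=cls, esp=esp, exac=exac,
                 heredity=heredity, inh=inh, phenos=("LVNC",), synthetic=True)
        )
    return rows


def _check_plan(rows: list[dict], spec: FixtureSpec) -> None:
    """Verify that the row plan realizes every marginal of the spec."""
    problems: list[str] = []

    def n_var(row) -> int:
        return row["hgvs"].count(";") + 1

    total = sum(n_var(r) for r in rows)
    if total != spec.n_variants:
        problems.append(f"plan holds {total} variants, spec wants {spec.n_variants}")
    per_gene: dict[str, int] = {}
    for r in rows:
        per_gene[r["gene"]] = per_gene.get(r["gene"], 0) + n_var(r)
    if per_gene != dict(spec.per_gene_counts):
        problems.append(f"per-gene counts {per_gene} != spec {dict(spec.per_gene_counts)}")
    by_cls: dict[str, int] = {}
    for r in rows:
        by_cls[r["cls"]] = by_cls.get(r["cls"], 0) + n_var(r)
    want = {"P": 0, "V": 0, "B": 0, "U": 0}
    for name, n in spec.class_counts:
        want[{"pathogenic": "P", "VUS": "V", "benign": "B", "unclassifiable": "U"}[name]] = n
    want["N"] = spec.n_nonsense
    if by_cls != {k: v for k, v in want.items() if v}:
        problems.append(f"class plan {by_cls} != spec {want}")
    n_esp = sum(n_var(r) for r in rows if r["esp"])
    n_exac = sum(n_var(r) for r in rows if r["exac"])
    n_both = sum(n_var(r) for r in rows if r["esp"] and r["exac"])
    if (n_esp, n_exac, n_both) != (spec.n_esp_positive, spec.n_exac_positive, spec.n_overlap):
        problems.append(
            f"presence plan ({n_esp}, {n_exac}, {n_both}) != spec "
            f"({spec.n_esp_positive}, {spec.n_exac_positive}, {spec.n_overlap})"
        )
    esp_path = sum(n_var(r) for r in rows if r["esp"] and r["cls"] == "P")
    exac_path = sum(n_var(r) for r in rows if r["exac"] and r["cls"] == "P")
    myh7_path = sum(n_var(r) for r in rows if r["gene"] == "MYH7" and r["cls"] == "P")
    myh7_ben = sum(n_var(r) for r in rows if r["gene"] == "MYH7" and r["cls"] == "B")
    if (esp_path, exac_path) != (spec.esp_pathogenic, spec.exac_pathogenic):
        problems.append(f"stratified plan ESP {esp_path}, ExAC {exac_path} off target")
    if (myh7_path, myh7_ben) != (spec.myh7_pathogenic, spec.myh7_benign):
        problems.append(f"MYH7 plan ({myh7_path} P, {myh7_ben} B) off target")
    n_familial = sum(1 for r in rows if r["heredity"] in ("fc", "fn"))
    n_coseg = sum(1 for r in rows if r["heredity"] == "fc")
    if (n_familial, n_coseg) != (spec.n_familial, spec.n_cosegregating):
        problems.append(
            f"heredity plan ({n_familial} familial, {n_coseg} co-segregating) off target"
        )
    if problems:
        raise FixtureError(
            "fixture spec not realizable by the built-in row plan: " + "; ".join(problems)
        )


def _fixture_pedigree(variant_id: str, row: dict, family_no: int) -> Pedigree:
    """Deterministic small family matching the row's heredity code."""
    gene = row["gene"]
    x_linked = gene == "TAZ"
    pheno = "HCM" if "HCM" in row["phenos"] else "LVNC"
    fam = f"F{family_no:03d}"
    if row["heredity"] == "fc":
        # two genotype-positive members sharing the phenotype
        if x_linked:
            members = (
                PedigreeMember("FA", Genotype.NON_CARRIER, "unaffected", Sex.MALE),
                PedigreeMember("MO", Genotype.CARRIER, "unaffected", Sex.FEMALE),
                PedigreeMember("C1", Genotype.CARRIER, pheno, Sex.MALE, proband=True,
                               parent_ids=("FA", "MO")),
                PedigreeMember("C2", Genotype.CARRIER, pheno, Sex.MALE,
                               parent_ids=("FA", "MO")),
            )
        else:
            members = (
                PedigreeMember("MO", Genotype.NON_CARRIER, "unaffected", Sex.FEMALE),
                PedigreeMember("C1", Genotype.CARRIER, pheno, Sex.FEMALE, proband=True),
                PedigreeMember("C2", Genotype.CARRIER, pheno, Sex.MALE),
            )
    elif row["heredity"] == "fn":
        # two affected relatives, but only one genotype-positive
        members = (
            PedigreeMember("MO", Genotype.NON_CARRIER, "unaffected", Sex.FEMALE),
            PedigreeMember("C1", Genotype.CARRIER, pheno, Sex.FEMALE, proband=True),
            PedigreeMember("C2", Genotype.NON_CARRIER, "DCM", Sex.MALE),
        )
    else:  # sporadic: a single affected member
        members = (
            PedigreeMember("FA", Genotype.NON_CARRIER, "unaffected", Sex.MALE),
            PedigreeMember("MO", Genotype.NON_CARRIER, "unaffected", Sex.FEMALE),
            PedigreeMember("C1", Genotype.CARRIER, pheno, Sex.FEMALE, proband=True,
                           parent_ids=("FA", "MO")),
        )
    return Pedigree(family_id=fam, variant_id=variant_id, members=members)


def make_paper_fixture(spec: FixtureSpec = DEFAULT_FIXTURE_SPEC) -> FixtureBundle:
    """Catalog + population stores + pedigrees realizing the spec marginals.

    Raises :class:`FixtureError` when the spec is internally inconsistent,
    or when it asks for a marginal structure the built-in row plan does
    not realize.
    """
    spec.validate()
    rows = _build_records(spec)
    _check_plan(rows, spec)
    rng = np.random.default_rng(spec.seed + 1)

    records: list[VariantRecord] = []
    esp_store = PopulationStore()
    exac_store = PopulationStore()
    pedigrees: list[Pedigree] = []

    # Both stores must know every cohort even if a catalog variant is absent,
    # so seed each with a sentinel AC=0 entry.
    esp_store.add("_SENTINEL", "p.A1G", CohortCounts(
        cohort_id="ESP",
        subpop_counts={"AfricanAmerican": (0, 4406), "EuropeanAmerican": (0, 8600)},
        carrier_count=0, n_individuals=6503))
    exac_store.add("_SENTINEL", "p.A1G", CohortCounts(
        cohort_id="ExAC", subpop_counts={"ALL": (0, 121412)},
        carrier_count=0, n_individuals=60706))

    for i, row in enumerate(rows):
        gene, hgvs, cls = row["gene"], row["hgvs"], row["cls"]
        changes = tuple(parse_protein_change(h, gene) for h in hgvs.split(";"))
        labels, conserved = _tool_labels_for(cls, changes)
        variant_id = f"LVNC{i + 1:03d}"
        coseg = {"fc": Cosegregation.YES, "fn": Cosegregation.NO}.get(
            row["heredity"], Cosegregation.NOT_ASSESSED
        )
        record = VariantRecord(
            variant_id=variant_id,
            gene=gene,
            changes=changes,
            variant_class=(
                VariantClass.NONSENSE
                if any(c.is_stop_gain for c in changes)
                else VariantClass.MISSENSE
            ),
            inheritance=_INHERITANCE[row["inh"]],
            cosegregation=coseg,
            phenotypes=frozenset(Phenotype(p) for p in row["phenos"]),
            tool_labels=labels,
            conserved=conserved,
            esp_positive=row["esp"],
            exac_positive=row["exac"],
            residue_mismatch=(cls == "U"),
            synthetic=row["synthetic"],
        )
        records.append(record)

        if row["esp"]:
            # carriers beyond five exercise the plausibility rule once
            ac = 7 if hgvs == "p.V943F" else 1 + int(rng.integers(3))
            aa = int(rng.integers(ac + 1))
            esp_store.add(gene, hgvs, CohortCounts(
                cohort_id="ESP",
                subpop_counts={"AfricanAmerican": (aa, 4406),
                               "EuropeanAmerican": (ac - aa, 8600)},
                carrier_count=ac, n_individuals=6503))
        if row["exac"]:
            # the worked example: one allele of MYH7 p.R243H in 121,412
            ac = 1 if hgvs == "p.R243H" else 1 + int(rng.integers(6))
            exac_store.add(gene, hgvs, CohortCounts(
                cohort_id="ExAC", subpop_counts={"ALL": (ac, 121412)},
                carrier_count=ac, n_individuals=60706))

        pedigrees.append(_fixture_pedigree(variant_id, row, i + 1))

    catalog = Catalog(records=records, provenance=f"synthetic fixture seed={spec.seed}")
    return FixtureBundle(
        catalog=catalog, esp_store=esp_store, exac_store=exac_store,
        pedigrees=pedigrees, spec=spec,
    )
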