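"""Curated variant catalog: domain model, HGVS p. parsing, TSV I/O.

The catalog is the pipeline's central input: one row per reported
variant (or cis compound allele) carrying the gene symbol, the
protein-level change in one-letter HGVS shorthand (``p.R243H``), the
inheritance pattern and phenotypes reported in the source literature,
raw in-silico tool labels, and background-population presence flags.
Variants are keyed on (gene, HGVS p.) — the catalog carries no genomic
coordinates, because literature reports at protein level only.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
STOP = "*"

_HGVS_RE = re.compile(r"^p\.([A-Za-z])(\d+)([A-Za-z]|\*)$")


class CatalogError(ValueError):
    """Raised on malformed HGVS strings or invalid catalog contents."""


class VariantClass(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"


class Inheritance(str, Enum):
    AUTOSOMAL_DOMINANT = "autosomal_dominant"
    AUTOSOMAL_RECESSIVE = "autosomal_recessive"
    X_LINKED = "X_linked"
    SPORADIC = "sporadic"
    UNKNOWN = "unknown"


class Cosegregation(str, Enum):
    YES = "yes"
    NO = "no"
    NOT_ASSESSED = "not_assessed"


class Phenotype(str, Enum):
    LVNC = "LVNC"
    DCM = "DCM"
    HCM = "HCM"
    BARTH = "Barth"
    CHD = "CHD"
    OTHER = "other"


#: Recognised in-silico tool slots (raw labels are normalized downstream).
TOOL_NAMES = ("conservation", "grantham", "sift", "polyphen2")


@dataclass(frozen=True)
class ProteinChange:
    """A single amino-acid substitution in one-letter HGVS p. notation."""

    gene: str
    ref_residue: str
    position: int
    alt_residue: str
    raw: str

    def __post_init__(self) -> None:
        if not self.gene:
            raise CatalogError("gene symbol must be non-empty")
        if self.ref_residue not in AMINO_ACIDS:
            raise CatalogError(
                f"unknown reference residue {self.ref_residue!r} in {self.raw!r}"
            )
        if self.alt_residue not in AMINO_ACIDS and self.alt_residue != STOP:
            raise CatalogError(
                f"unknown alternate residue {self.alt_residue!r} in {self.raw!r}"
            )
        if self.position < 1:
            raise CatalogError(f"residue position must be >= 1, got {self.position}")
        if self.ref_residue == self.alt_residue:
            raise CatalogError(
                f"reference and alternate residues are identical in {self.raw!r}"
            )

    @property
    def is_stop_gain(self) -> bool:
        return self.alt_residue == STOP


def parse_protein_change(hgvs: str, gene: str) -> ProteinChange:
    """Parse one-letter HGVS protein shorthand, e.g. ``p.R243H`` or ``p.G195*``.

    Raises :class:`CatalogError` naming the offending token on malformed
    input, unknown residue letters, position 0, or identical ref/alt.
    """
    m = _HGVS_RE.match(hgvs.strip())
    if not m:
        raise CatalogError(f"malformed HGVS protein change: {hgvs!r}")
    ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
    return ProteinChange(
        gene=gene.upper(), ref_residue=ref, position=pos, alt_residue=alt, raw=hgvs.strip()
    )


def classify_variant_class(change: ProteinChange) -> VariantClass:
    """Nonsense iff the substitution creates a stop codon, else missense."""
    return VariantClass.NONSENSE if change.is_stop_gain else VariantClass.MISSENSE


@dataclass
class VariantRecord:
    """One curated literature variant (one catalog row).

    ``changes`` holds more than one entry only for cis compound alleles
    (two substitutions reported on the same allele); such a record counts
    as multiple variants in per-variant tallies.
    """

    variant_id: str
    gene: str
    changes: tuple[ProteinChange, ...]
    variant_class: VariantClass
    inheritance: frozenset[Inheritance] = frozenset()
    cosegregation: Cosegregation = Cosegregation.NOT_ASSESSED
    phenotypes: frozenset[Phenotype] = frozenset()
    tool_labels: dict[str, str] = field(default_factory=dict)
    conserved: bool | None = None
    grantham_score: float | None = None
    esp_positive: bool | None = None
    exac_positive: bool | None = None
    residue_mismatch: bool = False
    synthetic: bool = False
    citations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.gene:
            raise CatalogError(f"{self.variant_id}: gene symbol must be non-empty")
        if not self.changes:
            raise CatalogError(f"{self.variant_id}: at least one protein change required")
        has_stop = any(c.is_stop_gain for c in self.changes)
        if has_stop != (self.variant_class is VariantClass.NONSENSE):
            raise CatalogError(
                f"{self.variant_id}: variant_class {self.variant_class.value!r} "
                f"inconsistent with changes {[c.raw for c in self.changes]}"
            )
        unknown = set(self.tool_labels) - set(TOOL_NAMES)
        if unknown:
            raise CatalogError(f"{self.variant_id}: unknown tool labels {sorted(unknown)}")

    @property
    def hgvs_key(self) -> str:
        """Catalog key: semicolon-joined HGVS strings for cis compounds."""
        return ";".join(c.raw for c in self.changes)

    @property
    def n_variants(self) -> int:
        """Number of variants this record contributes to per-variant tallies."""
        return len(self.changes)


@dataclass
class Catalog:
    records: list[VariantRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        seen_ids: set[str] = set()
        for rec in self.records:
            key = (rec.gene, rec.hgvs_key)
            if key in seen:
                raise CatalogError(f"duplicate variant ({rec.gene}, {rec.hgvs_key})")
            if rec.variant_id in seen_ids:
                raise CatalogError(f"duplicate variant_id {rec.variant_id!r}")
            seen.add(key)
            seen_ids.add(rec.variant_id)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_variants(self) -> int:
        """Per-variant count: cis compound records count once per change."""
        return sum(rec.n_variants for rec in self.records)

    def __iter__(self):
        return iter(self.records)


# ---------------------------------------------------------------------------
# TSV I/O
#
# Dialect: UTF-8, tab-separated, header row. hgvs_p is semicolon-separated
# for cis compound alleles; inheritance and phenotypes are comma-separated;
# an empty cell means unknown/absent.
# ---------------------------------------------------------------------------

_COLUMNS = [
    "variant_id",
    "gene",
    "hgvs_p",
    "variant_class",
    "inheritance",
    "cosegregation",
    "phenotypes",
    "conservation_label",
    "sift_label",
    "polyphen_label",
    "conserved",
    "grantham_score",
    "esp_positive",
    "exac_positive",
    "residue_mismatch",
    "synthetic",
    "citations",
]

_REQUIRED = {"gene", "hgvs_p"}

_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def _parse_bool(cell: str, *, row: int, col: str, errors: list[str]) -> bool | None:
    if cell == "":
        return None
    v = _BOOL.get(cell.strip().lower())
    if v is None:
        errors.append(f"row {row}: column {col!r}: unrecognised boolean {cell!r}")
    return v


def _parse_enum_set(cell: str, enum_cls, *, row: int, col: str, errors: list[str]):
    out = set()
    for token in filter(None, (t.strip() for t in cell.split(","))):
        try:
            out.add(enum_cls(token))
        except ValueError:
            errors.append(f"row {row}: column {col!r}: unknown token {token!r}")
    return frozenset(out)


def _record_from_row(row: Mapping[str, str], rownum: int, errors: list[str]) -> VariantRecord | None:
    gene = row.get("gene", "").strip().upper()
    hgvs = row.get("hgvs_p", "").strip()
    if not gene or not hgvs:
        errors.append(f"row {rownum}: missing gene or hgvs_p")
        return None
    try:
        changes = tuple(parse_protein_change(h, gene) for h in hgvs.split(";"))
    except CatalogError as exc:
        errors.append(f"row {rownum}: {exc}")
        return None

    inherited_class = (
        VariantClass.NONSENSE
        if any(c.is_stop_gain for c in changes)
        else VariantClass.MISSENSE
    )
    cell = row.get("variant_class", "").strip()
    if cell:
        try:
            declared = VariantClass(cell)
        except ValueError:
            errors.append(f"row {rownum}: unknown variant_class {cell!r}")
            return None
        if declared is not inherited_class:
            errors.append(
                f"row {rownum}: declared variant_class {cell!r} contradicts HGVS {hgvs!r}"
            )
            return None

    coseg_cell = row.get("cosegregation", "").strip()
    try:
        coseg = Cosegregation(coseg_cell) if coseg_cell else Cosegregation.NOT_ASSESSED
    except ValueError:
        errors.append(f"row {rownum}: unknown cosegregation {coseg_cell!r}")
        return None

    tool_labels: dict[str, str] = {}
    for col, tool in (
        ("conservation_label", "conservation"),
        ("sift_label", "sift"),
        ("polyphen_label", "polyphen2"),
    ):
        cell = row.get(col, "").strip()
        if cell:
            tool_labels[tool] = cell

    grantham_cell = row.get("grantham_score", "").strip()
    grantham = None
    if grantham_cell:
        try:
            grantham = float(grantham_cell)
        except ValueError:
            errors.append(f"row {rownum}: bad grantham_score {grantham_cell!r}")
            return None

    n_before = len(errors)
    kwargs = dict(
        inheritance=_parse_enum_set(
            row.get("inheritance", ""), Inheritance, row=rownum, col="inheritance", errors=errors
        ),
        phenotypes=_parse_enum_set(
            row.get("phenotypes", ""), Phenotype, row=rownum, col="phenotypes", errors=errors
        ),
        conserved=_parse_bool(row.get("conserved", ""), row=rownum, col="conserved", errors=errors),
        esp_positive=_parse_bool(
            row.get("esp_positive", ""), row=rownum, col="esp_positive", errors=errors
        ),
        exac_positive=_parse_bool(
            row.get("exac_positive", ""), row=rownum, col="exac_positive", errors=errors
        ),
    )
    if len(errors) > n_before:
        return None

    variant_id = row.get("variant_id", "").strip() or f"{gene}:{hgvs}"
    try:
        return VariantRecord(
            variant_id=variant_id,
            gene=gene,
            changes=changes,
            variant_class=inherited_class,
            cosegregation=coseg,
            tool_labels=tool_labels,
            grantham_score=grantham,
            residue_mismatch=_parse_bool(
                row.get("residue_mismatch", "") or "false",
                row=rownum, col="residue_mismatch", errors=errors,
            )
            or False,
            synthetic=_parse_bool(
                row.get("synthetic", "") or "false",
                row=rownum, col="synthetic", errors=errors,
            )
            or False,
            citations=tuple(filter(None, (c.strip() for c in row.get("citations", "").split(",")))),
            **kwargs,
        )
    except CatalogError as exc:
        errors.append(f"row {rownum}: {exc}")
        return None


def read_catalog(path: str | Path, provenance: str | None = None) -> Catalog:
    """Load a catalog TSV, enforcing every record invariant.

    All validation failures across the file are collected and reported in
    one :class:`CatalogError`; the load never partially succeeds.
    """
    path = Path(path)
    errors: list[str] = []
    records: list[VariantRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise CatalogError(f"{path}: empty file (no header)")
        missing = _REQUIRED - set(reader.fieldnames)
        if missing:
            raise CatalogError(f"{path}: missing required columns {sorted(missing)}")
        for rownum, row in enumerate(reader, start=2):
            rec = _record_from_row(row, rownum, errors)
            if rec is not None:
                records.append(rec)
    if errors:
        raise CatalogError(f"{path}: {len(errors)} invalid rows:\n" + "\n".join(errors))
    try:
        return Catalog(records=records, provenance=provenance or str(path))
    except CatalogError as exc:
        raise CatalogError(f"{path}: {exc}") from exc


def _fmt_bool(v: bool | None) -> str:
    return "" if v is None else ("true" if v else "false")


def write_catalog(catalog: Catalog, path: str | Path) -> None:
    """Serialize a catalog so that :func:`read_catalog` round-trips it."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_COLUMNS)
        for rec in catalog:
            writer.writerow(
                [
                    rec.variant_id,
                    rec.gene,
                    rec.hgvs_key,
                    rec.variant_class.value,
                    ",".join(sorted(i.value for i in rec.inheritance)),
                    rec.cosegregation.value,
                    ",".join(sorted(p.value for p in rec.phenotypes)),
                    rec.tool_labels.get("conservation", ""),
                    rec.tool_labels.get("sift", ""),
                    rec.tool_labels.get("polyphen2", ""),
                    _fmt_bool(rec.conserved),
                    "" if rec.grantham_score is None else repr(rec.grantham_score),
                    _fmt_bool(rec.esp_positive),
                    _fmt_bool(rec.exac_positive),
                    _fmt_bool(rec.residue_mismatch),
                    _fmt_bool(rec.synthetic),
                    ",".join(rec.citations),
                ]
            )
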