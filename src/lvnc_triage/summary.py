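"""Aggregate reporting: the pipeline's headline statistics.

Collects per-gene tallies, background-population presence counts and
their overlap, consensus classification fractions (integer percents by
truncation toward zero), stratified pathogenic fractions (ESP-positive,
ExAC-positive, per-gene), and heredity counts into one deterministic,
JSON-serializable report with an internal self-consistency check.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

from .catalog import Catalog, Cosegregation
from .consensus import (
    Classification,
    ConsensusClassification,
    classification_fractions,
    truncated_percent,
)
from .population import PopulationPresence, presence_overlap
from .segregation import Pedigree, assess_cosegregation, familial_label


class SummaryError(ValueError):
    pass


def tally_by_gene(catalog: Catalog) -> dict[str, int]:
    """Per-variant counts per gene (cis compounds count once per change)."""
    out: dict[str, int] = {}
    for rec in catalog:
        out[rec.gene] = out.get(rec.gene, 0) + rec.n_variants
    return dict(sorted(out.items(), key=lambda kv: (-kv[1], kv[0])))


def stratified_pathogenicity(
    classifications: list[ConsensusClassification],
    catalog: Catalog,
    stratum,
) -> tuple[int, int, int | None]:
    """(n, n pathogenic, truncated percent) over variants in a stratum.

    ``stratum`` is a predicate over VariantRecord.  Counting is per
    variant; the percent is None for an empty stratum.
    """
    by_id = {c.variant_id: c for c in classifications}
    missing = [rec.variant_id for rec in catalog if rec.variant_id not in by_id]
    if missing:
        raise SummaryError(f"classifications missing for {missing[:3]}...")
    n = n_path = 0
    for rec in catalog:
        if not stratum(rec):
            continue
        n += rec.n_variants
        if by_id[rec.variant_id].classification is Classification.PATHOGENIC:
            n_path += rec.n_variants
    if n == 0:
        return 0, 0, None
    return n, n_path, truncated_percent(n_path, n)


@dataclass
class SummaryReport:
    n_variants: int
    n_genes: int
    per_gene_counts: dict[str, int]
    n_esp_positive: int
    n_exac_positive: int
    n_overlap: int
    n_analyzed: int
    class_counts: dict[str, int]
    class_percents: dict[str, int]
    stratified: dict[str, dict[str, int | None]]
    n_familial: int
    n_cosegregating: int
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sum(self.per_gene_counts.values()) != self.n_variants:
            raise SummaryError("per-gene counts do not sum to the variant total")
        if self.n_overlap > min(self.n_esp_positive, self.n_exac_positive):
            raise SummaryError("overlap exceeds a positive set")
        for name, s in self.stratified.items():
            if s["n_pathogenic"] > s["n"]:
                raise SummaryError(f"stratum {name}: pathogenic count exceeds stratum size")

    def to_json(self) -> str:
        """Deterministic serialization: stable key order, no float formatting drift."""
        payload = {
            "n_variants": self.n_variants,
            "n_genes": self.n_genes,
            "per_gene_counts": self.per_gene_counts,
            "n_esp_positive": self.n_esp_positive,
            "n_exac_positive": self.n_exac_positive,
            "n_overlap": self.n_overlap,
            "n_analyzed": self.n_analyzed,
            "class_counts": self.class_counts,
            "class_percents": self.class_percents,
            "stratified": self.stratified,
            "n_familial": self.n_familial,
            "n_cosegregating": self.n_cosegregating,
            "provenance": self.provenance,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_text(self) -> str:
        lines = [
            f"variants: {self.n_variants} in {self.n_genes} genes",
            f"ESP-positive: {self.n_esp_positive}  ExAC-positive: {self.n_exac_positive}"
            f"  overlap: {self.n_overlap}",
            f"analyzed (missense): {self.n_analyzed}",
        ]
        for cls in ("pathogenic", "VUS", "benign", "unclassifiable", "not_analyzed"):
            if cls in self.class_counts:
                pct = self.class_percents.get(cls)
                pct_s = f" ({pct}%)" if pct is not None else ""
                lines.append(f"  {cls}: {self.class_counts[cls]}{pct_s}")
        for name, s in self.stratified.items():
            if s["n"]:
                lines.append(
                    f"stratum {name}: {s['n_pathogenic']}/{s['n']} pathogenic"
                    f" ({s['percent']}%)"
                )
        lines.append(
            f"familial: {self.n_familial}  co-segregating: {self.n_cosegregating}"
        )
        return "\n".join(lines)


def build_report(
    catalog: Catalog,
    esp_presence: list[PopulationPresence],
    exac_presence: list[PopulationPresence],
    classifications: list[ConsensusClassification],
    pedigrees: list[Pedigree] | None = None,
    provenance: dict[str, str] | None = None,
) -> SummaryReport:
    """Aggregate every pipeline output into one deterministic report.

    Class counts are recomputed directly from the classification list and
    cross-checked against the fraction table (self-check at report time).
    """
    catalog_ids = {rec.variant_id for rec in catalog}
    for presence, label in ((esp_presence, "ESP"), (exac_presence, "ExAC")):
        if {p.variant_id for p in presence} != catalog_ids:
            raise SummaryError(f"{label} presence does not cover the catalog")

    genes = tally_by_gene(catalog)
    n_esp, n_exac, n_both = presence_overlap(esp_presence, exac_presence)

    fractions = classification_fractions(classifications, catalog, denominator="analyzed")
    class_counts = {cls.value: n for cls, (n, _) in fractions.items()}
    class_percents = {
        cls.value: pct
        for cls, (_, pct) in fractions.items()
        if cls is not Classification.NOT_ANALYZED
    }
    n_analyzed = sum(
        n for cls, (n, _) in fractions.items() if cls is not Classification.NOT_ANALYZED
    )
    # self-check: recompute counts independently of classification_fractions
    weights = {rec.variant_id: rec.n_variants for rec in catalog}
    recount: dict[str, int] = {}
    for c in classifications:
        recount[c.classification.value] = (
            recount.get(c.classification.value, 0) + weights.get(c.variant_id, 1)
        )
    if recount != class_counts:
        raise SummaryError(f"class-count self-check failed: {recount} != {class_counts}")

    esp_pos = {p.variant_id for p in esp_presence if p.present}
    exac_pos = {p.variant_id for p in exac_presence if p.present}
    strata = {
        "esp_positive": (lambda r: r.variant_id in esp_pos),
        "exac_positive": (lambda r: r.variant_id in exac_pos),
        "gene=MYH7": (lambda r: r.gene == "MYH7"),
    }
    stratified = {}
    for name, pred in strata.items():
        n, n_path, pct = stratified_pathogenicity(classifications, catalog, pred)
        stratified[name] = {"n": n, "n_pathogenic": n_path, "percent": pct}

    n_familial = n_coseg = 0
    for ped in pedigrees or []:
        if familial_label(ped) == "familial":
            n_familial += 1
            if assess_cosegregation(ped) is Cosegregation.YES:
                n_coseg += 1

    return SummaryReport(
        n_variants=catalog.n_variants,
        n_genes=len(genes),
        per_gene_counts=genes,
        n_esp_positive=n_esp,
        n_exac_positive=n_exac,
        n_overlap=n_both,
        n_analyzed=n_analyzed,
        class_counts=class_counts,
        class_percents=class_percents,
        stratified=stratified,
        n_familial=n_familial,
        n_cosegregating=n_coseg,
        provenance=provenance or {},
    )


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
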