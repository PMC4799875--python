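"""Background-population lookup: allele frequencies, presence, carrier rule.

A literature-reported variant is *positive* in a background cohort (an
ESP-like or ExAC-like exome store) when the store holds at least one
alternate allele for it; the presence dichotomy carries no frequency
floor.  The carrier-count plausibility rule encodes the judgement that a
variant carried by more than five persons in a large background cohort
is unlikely to be a monogenic cause of a rare cardiomyopathy.

Stores are local files only: a simple TSV of per-subpopulation allele
counts, or a minimal sites-only VCF with AC/AN INFO fields and a
GENE_HGVSP annotation tying each record to a protein-level key.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

from .catalog import Catalog

logger = logging.getLogger(__name__)


class PopulationError(ValueError):
    pass


@dataclass(frozen=True)
class CohortCounts:
    """Allele counts for one variant in one cohort, per subpopulation."""

    cohort_id: str
    subpop_counts: dict[str, tuple[int, int]]  # name -> (AC, AN)
    carrier_count: int
    n_individuals: int
    carriers_are_upper_bound: bool = False

    def __post_init__(self) -> None:
        for name, (ac, an) in self.subpop_counts.items():
            if ac < 0 or an <= 0:
                raise PopulationError(f"{name}: need AC >= 0 and AN > 0, got {ac}/{an}")
            if ac > an:
                raise PopulationError(f"{name}: AC {ac} exceeds AN {an}")
        if self.carrier_count < 0 or self.carrier_count > self.n_individuals:
            raise PopulationError(
                f"carrier_count {self.carrier_count} outside [0, {self.n_individuals}]"
            )
        if self.carrier_count > self.total_ac:
            raise PopulationError("carrier_count exceeds total allele count")
        if self.total_an > 2 * self.n_individuals:
            raise PopulationError("total AN exceeds 2 x cohort size")

    @property
    def total_ac(self) -> int:
        return sum(ac for ac, _ in self.subpop_counts.values())

    @property
    def total_an(self) -> int:
        return sum(an for _, an in self.subpop_counts.values())


@dataclass(frozen=True)
class PopulationPresence:
    variant_id: str
    cohort_id: str
    present: bool
    allele_frequency: float | None
    carrier_count: int
    unlikely_pathogenic: bool = False

    def __post_init__(self) -> None:
        if not self.present and (self.allele_frequency is not None or self.carrier_count != 0):
            raise PopulationError(
                f"{self.variant_id}: absent variants carry no frequency or carriers"
            )
        if self.unlikely_pathogenic and not self.present:
            raise PopulationError(f"{self.variant_id}: flag implies presence")


def allele_frequency(counts: CohortCounts) -> float:
    """Cohort-wide allele frequency (sum AC)/(sum AN), exact division.

    Computed as an exact rational and returned at full float precision;
    4-significant-figure rounding is presentation-layer only.
    """
    if counts.total_an == 0:
        raise PopulationError("allele frequency undefined at AN = 0")
    return float(Fraction(counts.total_ac, counts.total_an))


def format_af(af: float | None) -> str:
    """Display convention: 4 significant figures, plain decimal."""
    if af is None:
        return ""
    if af == 0:
        return "0"
    from decimal import Decimal

    return format(Decimal(f"{af:.4g}"), "f")


def _norm_key(gene: str, hgvs: str) -> tuple[str, str]:
    hgvs = hgvs.strip()
    if not hgvs.startswith("p."):
        hgvs = "p." + hgvs
    return gene.strip().upper(), hgvs


class PopulationStore:
    """In-memory allele-count store keyed on (gene, HGVS p.) per cohort."""

    def __init__(self) -> None:
        self._data: dict[str, dict[tuple[str, str], CohortCounts]] = {}
        self._cohort_sizes: dict[str, int] = {}

    @property
    def cohorts(self) -> tuple[str, ...]:
        return tuple(sorted(self._data))

    def add(self, gene: str, hgvs_p: str, counts: CohortCounts) -> None:
        key = _norm_key(gene, hgvs_p)
        cohort = self._data.setdefault(counts.cohort_id, {})
        if key in cohort:
            raise PopulationError(f"duplicate store entry {key} in {counts.cohort_id}")
        cohort[key] = counts
        self._cohort_sizes[counts.cohort_id] = max(
            self._cohort_sizes.get(counts.cohort_id, 0), counts.n_individuals
        )

    def get(self, cohort_id: str, gene: str, hgvs_p: str) -> CohortCounts | None:
        if cohort_id not in self._data:
            raise PopulationError(f"cohort {cohort_id!r} not in store")
        return self._data[cohort_id].get(_norm_key(gene, hgvs_p))

    def entries(self, cohort_id: str):
        """Iterate ((gene, hgvs_p), CohortCounts) pairs for one cohort."""
        if cohort_id not in self._data:
            raise PopulationError(f"cohort {cohort_id!r} not in store")
        yield from sorted(self._data[cohort_id].items())


def read_store_tsv(path: str | Path) -> PopulationStore:
    """Load a population store TSV.

    Columns: cohort, gene, hgvs_p, subpop, AC, AN, carrier_count
    (optional; approximated by AC when blank, an upper bound on persons),
    n_individuals.  Multiple subpopulation rows per (cohort, gene, hgvs_p)
    are aggregated into one record.
    """
    path = Path(path)
    rows: dict[tuple[str, str, str], dict] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"cohort", "gene", "hgvs_p", "subpop", "AC", "AN", "n_individuals"}
        missing = required - set(reader.fieldnames or ())
        if missing:
            raise PopulationError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            key = (row["cohort"], row["gene"], row["hgvs_p"])
            entry = rows.setdefault(
                key,
                {"subpops": {}, "carrier": 0, "carrier_known": True, "n_ind": 0},
            )
            entry["subpops"][row["subpop"]] = (int(row["AC"]), int(row["AN"]))
            cc = (row.get("carrier_count") or "").strip()
            if cc:
                entry["carrier"] += int(cc)
            else:
                entry["carrier_known"] = False
            entry["n_ind"] += int(row["n_individuals"])
    store = PopulationStore()
    for (cohort, gene, hgvs), entry in rows.items():
        total_ac = sum(ac for ac, _ in entry["subpops"].values())
        carrier = entry["carrier"] if entry["carrier_known"] else total_ac
        store.add(
            gene,
            hgvs,
            CohortCounts(
                cohort_id=cohort,
                subpop_counts=entry["subpops"],
                carrier_count=carrier,
                n_individuals=entry["n_ind"],
                carriers_are_upper_bound=not entry["carrier_known"],
            ),
        )
    return store


def write_store_tsv(store: PopulationStore, path: str | Path) -> None:
    """Serialize a store to the TSV dialect read by :func:`read_store_tsv`."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["cohort", "gene", "hgvs_p", "subpop", "AC", "AN", "carrier_count", "n_individuals"]
        )
        for cohort in store.cohorts:
            for (gene, hgvs), counts in store.entries(cohort):
                subpops = sorted(counts.subpop_counts.items())
                for i, (name, (ac, an)) in enumerate(subpops):
                    # carriers and cohort size are whole-cohort figures;
                    # attach them to the first subpop row to avoid double counting
                    writer.writerow(
                        [
                            cohort, gene, hgvs, name, ac, an,
                            "" if counts.carriers_are_upper_bound
                            else (counts.carrier_count if i == 0 else 0),
                            counts.n_individuals if i == 0 else 0,
                        ]
                    )


def read_store_vcf(path: str | Path, cohort_id: str, n_individuals: int) -> PopulationStore:
    """Load a minimal sites-only VCF (INFO keys AC, AN, GENE_HGVSP).

    Records lacking the GENE_HGVSP annotation are skipped with a warning;
    carriers are approximated by AC (upper bound) since a sites-only VCF
    carries no genotypes.
    """
    import pysam

    store = PopulationStore()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # pysam warns on missing index
        vcf = pysam.VariantFile(str(path))
        for rec in vcf:
            info = rec.info
            if "GENE_HGVSP" not in info:
                logger.warning("%s: record at %s:%s lacks GENE_HGVSP, skipped",
                               path, rec.chrom, rec.pos)
                continue
            gene_hgvsp = info["GENE_HGVSP"]
            if isinstance(gene_hgvsp, tuple):
                gene_hgvsp = gene_hgvsp[0]
            gene, _, hgvs = str(gene_hgvsp).partition("|")
            ac = info["AC"]
            ac = sum(ac) if isinstance(ac, tuple) else int(ac)
            an = int(info["AN"])
            store.add(
                gene,
                hgvs,
                CohortCounts(
                    cohort_id=cohort_id,
                    subpop_counts={"ALL": (ac, an)},
                    carrier_count=ac,
                    n_individuals=n_individuals,
                    carriers_are_upper_bound=True,
                ),
            )
    return store


def lookup_presence(
    catalog: Catalog, store: PopulationStore, cohort_id: str
) -> list[PopulationPresence]:
    """Presence of every catalog variant in one cohort (present iff AC >= 1)."""
    if cohort_id not in store.cohorts:
        raise PopulationError(f"cohort {cohort_id!r} not in store")
    out: list[PopulationPresence] = []
    for rec in catalog:
        counts = store.get(cohort_id, rec.gene, rec.hgvs_key)
        if counts is None or counts.total_ac == 0:
            out.append(
                PopulationPresence(
                    variant_id=rec.variant_id,
                    cohort_id=cohort_id,
                    present=False,
                    allele_frequency=None,
                    carrier_count=0,
                )
            )
        else:
            presence = PopulationPresence(
                variant_id=rec.variant_id,
                cohort_id=cohort_id,
                present=True,
                allele_frequency=allele_frequency(counts),
                carrier_count=counts.carrier_count,
            )
            out.append(
                PopulationPresence(
                    **{**presence.__dict__, "unlikely_pathogenic": carrier_filter(presence)}
                )
            )
    return out


def carrier_filter(presence: PopulationPresence, threshold: int = 5) -> bool:
    """True (unlikely pathogenic) iff carried by more than ``threshold`` persons."""
    if threshold < 0:
        raise PopulationError(f"threshold must be non-negative, got {threshold}")
    return presence.carrier_count > threshold


def presence_overlap(
    presence_a: list[PopulationPresence], presence_b: list[PopulationPresence]
) -> tuple[int, int, int]:
    """(n present in a, n present in b, n present in both) over a shared variant set."""
    ids_a = {p.variant_id for p in presence_a}
    ids_b = {p.variant_id for p in presence_b}
    if ids_a != ids_b or len(ids_a) != len(presence_a) or len(ids_b) != len(presence_b):
        raise PopulationError("presence lists must cover the same variant_id set exactly once")
    set_a = {p.variant_id for p in presence_a if p.present}
    set_b = {p.variant_id for p in presence_b if p.present}
    return len(set_a), len(set_b), len(set_a & set_b)
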