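#!/usr/bin/env python
"""Look up every catalog variant in the ESP-like and ExAC-like stores.

A variant is cohort-positive when the store holds at least one alternate
allele.  Also applies the carrier plausibility rule (more than five
carriers makes monogenic causality unlikely).  Writes
results/presence.tsv and prints the positive counts and their overlap.
"""

import csv
from pathlib import Path

from lvnc_triage import lookup_presence, presence_overlap, read_catalog
from lvnc_triage.population import format_af, read_store_tsv

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    catalog = read_catalog(BASE / "inputs" / "catalog.tsv")
    esp = lookup_presence(catalog, read_store_tsv(BASE / "inputs" / "esp_store.tsv"), "ESP")
    exac = lookup_presence(catalog, read_store_tsv(BASE / "inputs" / "exac_store.tsv"), "ExAC")

    with open(BASE / "presence.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["variant_id", "cohort", "present", "allele_frequency",
                    "carrier_count", "unlikely_pathogenic"])
        for p in esp + exac:
            w.writerow([p.variant_id, p.cohort_id, str(p.present).lower(),
                        format_af(p.allele_frequency), p.carrier_count,
                        str(p.unlikely_pathogenic).lower()])

    n_esp, n_exac, n_both = presence_overlap(esp, exac)
    print(f"ESP-positive: {n_esp} of {catalog.n_variants}")
    print(f"ExAC-positive: {n_exac} of {catalog.n_variants}")
    print(f"overlap (positive in both): {n_both} of the {n_esp} ESP-positive")
    flagged = [p for p in esp + exac if p.unlikely_pathogenic]
    print(f"carried by >5 persons (unlikely pathogenic): "
          f"{sorted({p.variant_id for p in flagged})}")


if __name__ == "__main__":
    main()
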