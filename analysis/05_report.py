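#!/usr/bin/env python
"""Aggregate everything into the summary report.

Re-runs lookup, prediction, consensus, and pedigree assessment on the
generated inputs and writes results/report.json plus a human-readable
results/report.txt.
"""

from pathlib import Path

from lvnc_triage import build_report, lookup_presence, read_catalog
from lvnc_triage.consensus import classify_catalog
from lvnc_triage.population import read_store_tsv
from lvnc_triage.segregation import read_pedigrees
from lvnc_triage.summary import file_checksum

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    inputs = BASE / "inputs"
    catalog = read_catalog(inputs / "catalog.tsv")
    esp = lookup_presence(catalog, read_store_tsv(inputs / "esp_store.tsv"), "ESP")
    exac = lookup_presence(catalog, read_store_tsv(inputs / "exac_store.tsv"), "ExAC")
    classifications = classify_catalog(catalog)
    pedigrees = read_pedigrees(inputs / "pedigrees.tsv")
    rep = build_report(
        catalog, esp, exac, classifications, pedigrees,
        provenance={name: file_checksum(inputs / f"{name}.tsv")
                    for name in ("catalog", "esp_store", "exac_store", "pedigrees")},
    )
    (BASE / "report.json").write_text(rep.to_json() + "\n")
    (BASE / "report.txt").write_text(rep.to_text() + "\n")
    print(rep.to_text())


if __name__ == "__main__":
    main()
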