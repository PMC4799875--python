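#!/usr/bin/env python
"""Run the four in-silico channels and the >=3-agreement consensus.

Stop gains are not analyzed (the tools apply to missense substitutions);
a residue/isoform mismatch is unclassifiable.  Writes
results/classifications.tsv and prints the class fractions with integer
percents truncated toward zero.
"""

import csv
from pathlib import Path

from lvnc_triage import read_catalog
from lvnc_triage.consensus import Classification, classification_fractions, classify_catalog

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    catalog = read_catalog(BASE / "inputs" / "catalog.tsv")
    classifications = classify_catalog(catalog)

    genes = {r.variant_id: r.gene for r in catalog}
    with open(BASE / "classifications.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["variant_id", "gene", "n_tools_available", "n_pathogenic_votes",
                    "classification", "flags"])
        for c in classifications:
            w.writerow([c.variant_id, genes[c.variant_id], c.n_tools_available,
                        c.n_pathogenic_votes, c.classification.value,
                        ",".join(sorted(c.flags))])

    fractions = classification_fractions(classifications, catalog)
    n_analyzed = sum(n for cls, (n, _) in fractions.items()
                     if cls is not Classification.NOT_ANALYZED)
    print(f"analyzed: {n_analyzed} missense variants "
          f"({fractions.get(Classification.NOT_ANALYZED, (0, 0))[0]} stop gains excluded)")
    for cls in (Classification.PATHOGENIC, Classification.VUS,
                Classification.BENIGN, Classification.UNCLASSIFIABLE):
        if cls in fractions:
            n, pct = fractions[cls]
            print(f"  {cls.value}: {n} ({pct}%)")


if __name__ == "__main__":
    main()
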