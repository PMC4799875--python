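# lvnc-triage

Left ventricular non-compaction (LVNC) is a rare cardiomyopathy for which
many candidate disease genes and variants have been reported, mostly from
single families or small case series. A substantial fraction of such
literature-reported variants later turn out to be present in healthy
background populations — a strong hint that they are not, by themselves,
the monogenic cause of the disease. `lvnc-triage` is a pipeline for
re-evaluating a curated catalog of reported LVNC-associated variants
against that standard of evidence. It is aimed at cardiogenetics groups
and variant curators who need a reproducible, scriptable version of the
classic triage workflow:

1. **Catalog curation** — one row per reported variant, keyed on
   (gene, HGVS p. change), e.g. `MYH7 p.R243H`, with the inheritance
   pattern, phenotypes, and raw in-silico labels from the source
   literature. Cis compound alleles (two substitutions on one haplotype)
   are one record counted as two variants.
2. **Background-population lookup** — presence of each variant in
   ESP-like (6503 exomes: 2203 African American + 4300 European American)
   and ExAC-like (60,706 exomes) allele-count stores. A variant is
   *cohort-positive* if the store holds ≥ 1 alternate allele; the allele
   frequency is AF = ΣAC / ΣAN over subpopulations. A variant carried by
   **more than five persons** is flagged unlikely to be pathogenic.
3. **Four-tool in-silico prediction** — conservation across species
   (conserved = zero substitutions → pathogenic), Grantham
   physicochemical distance
   D(a,b) = ρ·[α(c_a−c_b)² + β(p_a−p_b)² + γ(v_a−v_b)²]^{1/2}
   (ρ normalizes the mean of the 190 residue-pair distances to 100;
   D > 100 is a radical, i.e. pathogenic, substitution), and normalized
   categorical SIFT and PolyPhen-2 labels.
4. **Consensus classification** — pathogenic if ≥ 3 of 4 tools agree,
   VUS on 1–2 pathogenic votes, benign on 0 votes from a full panel.
   Stop gains are not analyzed; residue/isoform mismatches are
   unclassifiable. Integer percents are truncated toward zero.
5. **Co-segregation** — a family co-segregates when ≥ 2
   genotype-positive members share a phenotype label; families with ≥ 2
   affected members are familial, else sporadic.

## Worked example

The built-in generator (`lvnc_triage.synthetic_data.make_paper_fixture`)
produces a 60-variant catalog across 12 genes together with matching
population stores and pedigrees; 25 records are variants named in the
cardiomyopathy literature with their reported attributes, the remainder
are flagged synthetic placeholders. Running the numbered drivers:

```bash
python analysis/01_build_inputs.py
python analysis/02_population_lookup.py
python analysis/03_predict_classify.py
python analysis/04_segregation.py
python analysis/05_report.py
```

prints (abridged):

```
variants: 60 in 12 genes
ESP-positive: 9  ExAC-positive: 18  overlap: 8
analyzed (missense): 56
  pathogenic: 29 (51%)
  VUS: 23 (41%)
  benign: 3 (5%)
  unclassifiable: 1 (1%)
  not_analyzed: 4
stratum esp_positive: 4/9 pathogenic (44%)
stratum exac_positive: 10/18 pathogenic (55%)
stratum gene=MYH7: 17/24 pathogenic (70%)
familial: 42  co-segregating: 30
```

Reading: of 60 reported LVNC variants, 9 are found in the ESP-like cohort
and 18 in the ExAC-like cohort (8 in both) — those 19 distinct variants
are candidates for false-positive disease associations. Of the 56
missense variants, the four-tool consensus calls 51% pathogenic, 41% of
uncertain significance, and 5% benign. MYH7, the predominant gene (24/60
variants), has 17 pathogenic calls and no benign ones. `MYH7 p.R243H`
illustrates the tension the pipeline is built to expose: predicted
pathogenic with family co-segregation, yet present in the background
cohort at AF = 1/121412 = 0.000008236 — one carrier in 60,706 exomes
does not rule out causality under the more-than-five-persons rule.

The same stages are available as a CLI
(`varpop-triage validate|lookup|predict|classify|segregate|report|simulate`),
and every step as a library call.

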