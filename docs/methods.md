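# Methods

## The triage model

The pipeline treats each literature-reported LVNC variant as a hypothesis
to be weighed against three lines of evidence: background-population
frequency, in-silico functional prediction, and familial co-segregation.
All three operate at protein level — the catalog keys variants on
(gene symbol, one-letter HGVS p. change) and deliberately carries no
genomic coordinates, transcript identifiers, or isoform mapping, because
the upstream literature reports variants in exactly this shorthand. The
one known consequence is that an isoform mismatch cannot be resolved,
only recorded: such a variant is classified `unclassifiable` via an
explicit catalog annotation, never auto-detected.

A cis compound allele (two substitutions on one haplotype, e.g.
`MYH7 p.D545N;p.D955N`) is a single catalog record that contributes two
variants to every per-variant tally. Its consensus classification is
computed once for the allele, using the more radical of its two Grantham
distances.

## Population presence and the carrier rule

A variant is cohort-positive when the store holds at least one alternate
allele (AC ≥ 1) in any subpopulation; the dichotomy has no frequency
floor. Allele frequency is the exact rational ΣAC/ΣAN across
subpopulations, displayed at 4 significant figures. Carrier counts are
used by the plausibility rule — more than `threshold` carriers (default
5, strictly greater) flags the variant as unlikely pathogenic. When a
store carries no genotype-resolved carrier counts (sites-only VCF, blank
TSV column), carriers are approximated by AC, an upper bound on persons;
the store records which convention applied
(`CohortCounts.carriers_are_upper_bound`). X-linked genes (TAZ) are
handled by hemizygous male sampling in the simulator: AN is
n_males + 2·n_females and AF = AC/AN unchanged.

## The Grantham channel

The distance between residues a, b is

    D(a,b) = ρ · [ α(c_a−c_b)² + β(p_a−p_b)² + γ(v_a−v_b)² ]^(1/2)

over side-chain composition c (atomic-weight ratio of non-carbon
elements), polarity p, and molecular volume v, with α = 1.833,
β = 0.1018, γ = 0.000399 and ρ = 50.723. ρ scales the mean of the 190
unordered residue-pair distances to 100 (this build: 99.868), which makes
the radical/conservative cutoff interpretable: D > 100 is called
pathogenic, D ≤ 100 benign. The tie at exactly 100 goes to benign —
pathogenic requires strict excess — and the cutoff is a parameter. The
property table and constants ship as checksummed package assets, and
tests verify the engine entry-wise against brute-force evaluation of the
formula plus spot checks against the published integer matrix. (A
handful of entries of the historical printed matrix differ by ±1 from
exact recomputation; only formula-consistent entries are frozen in
tests.) The distance is undefined for stop gains, which bypass all four
channels.

## Conservation, SIFT, PolyPhen-2

Conservation is binary: a position with zero substitutions among non-gap
orthologous residues is conserved (pathogenic); one or more substitutions
make it benign; fewer than two usable residues yield `unavailable`. The
species panel is a free parameter — the pipeline accepts either a
precomputed conserved yes/no annotation (which wins when both are
present, mirroring how such labels are curated in practice) or an
alignment column/FASTA to compute the call. SIFT and PolyPhen-2 are
external tools whose categorical labels are normalized, never recomputed:
`damaging` → pathogenic, `tolerated`/`tolerant` → benign for SIFT;
`probably damaging`/`possibly damaging` → pathogenic, `benign` → benign
for PolyPhen-2; anything else is `unavailable`. Numeric SIFT scores are
out of scope because the upstream catalogs carry only categories.

## Consensus voting

Pathogenic on ≥ 3 pathogenic votes among available tools; VUS on 1–2;
benign on 0 — with the guard that benign requires the full four-tool
panel (a partial panel with no pathogenic votes is VUS, flagged
`incomplete_tool_panel`), since a variant should never be cleared on
partial evidence. Both the ≥ 3 threshold and the full-panel guard are
policy parameters. An `unavailable` call is never a vote.

Integer percents are truncated toward zero everywhere (10/18 → 55%).
This convention is forced by arithmetic: the 51/41/5 split of 56
analyzed variants has the unique integer solution (29, 23, 3) under
floor-percents and none under half-up rounding; the package applies it
uniformly, so 17/24 prints as 70%.

## Co-segregation

`yes` iff at least two genotype-positive members share a phenotype label
(strict label equality by default; an optional equivalence set can merge
labels such as {LVNC, DCM} into one spectrum for mixed-cardiomyopathy
families). The proband counts toward the two, configurably.
`not_assessed` when fewer than two genotypes are known; `no` otherwise.
Familial means ≥ 2 affected members regardless of genotype, so familial
and co-segregating are distinct facts. Inheritance patterns are catalog
annotations from the source literature, never inferred; the only
structural check computed is X-linked consistency (no male-to-male
carrier transmission), which is informational and never alters a
classification. No LOD-score co-segregation statistics are attempted.

## Synthetic data: what it emulates and what it does not

`simulate_cohort` draws per-individual genotypes binomially (two draws
autosomal, one for hemizygous males) at given true allele frequencies,
so AC/AN/carrier counts satisfy every store invariant by construction;
the default specs are a 6503-exome two-subpopulation cohort and a
60,706-exome cohort. It emulates sampling noise only — no linkage,
site-frequency spectrum, or population structure — so tests that pass on
it demonstrate correct counting and estimation, not robustness to real
cohort artefacts (call-rate variation, relatedness, batch effects).
`simulate_alignment_column` substitutes each non-reference species
independently with probability p, giving the closed-form conserved
fraction (1−p)^(n−1) used as a Monte-Carlo oracle.
`simulate_pedigree` builds nuclear families with configurable penetrance
and phenocopy rate (defaults: the generator transmits with probability
0.5 per child, no phenocopies).

`make_paper_fixture` assembles the study catalog: 60 variants in 12
genes (24 in MYH7), 4 stop gains, 9 ESP-positive and 18 ExAC-positive
with 8 overlapping, class counts (29 pathogenic, 23 VUS, 3 benign,
1 unclassifiable), stratified pathogenic counts 4/9, 10/18 and 17/24,
and 42 familial cases with 30 co-segregating. Twenty-five records are
variants named in the cardiomyopathy literature, placed with their
reported attributes (e.g. `MYH7 p.R243H` at one ExAC allele in 121,412 —
AF 0.000008236); filler rows are flagged `synthetic`, including the
fourth stop gain and all TNNI3 rows, since the public record names only
three stop gains and eleven of the twelve genes. Tool labels for each
row are chosen so that the *real* prediction and voting engines produce
the row's target class — the Grantham vote is fixed by the residues
themselves, so benign rows must use conservative substitutions (the
generator refuses radical ones). The fixture is deterministic given its
seed; the seed moves only placeholder residue choices and allele counts,
never the marginals. If a curator supplies a transcription of the real
variant catalog in the same TSV dialect, it can be loaded with
`read_catalog` and run through the identical pipeline in place of the
fixture.

## Numerical and testing choices

Allele frequencies are computed as exact rationals before conversion to
float; display rounding is presentation-only. Report JSON uses sorted
keys and integer fields, so identical inputs give byte-identical output.
Monte-Carlo test sizes (100–200 cohort seeds, 10,000 alignment columns,
300–400 pedigrees) keep the full suite under a few seconds while leaving
3-standard-error assertions well-powered; the binomial-interval coverage
check allows 95% observed coverage at nominal 99% to absorb the normal
approximation at extreme tails. Catalog loading is all-or-nothing: every
invalid row is diagnosed with its row number and the load fails, never
partially succeeding.

## Known limitations

- Protein-level keying cannot distinguish transcripts; isoform
  mismatches are recorded, not resolved.
- The carrier rule speaks of persons, but allele counts are the only
  datum in sites-only stores; the AC upper bound can over-flag
  homozygote-rich variants.
- The binary conservation call ignores substitution similarity and
  alignment depth.
- The fixture reproduces marginal structure, not the unpublished
  row-level source catalog; per-variant conclusions drawn from the
  synthetic placeholders are meaningless by design.
- The familial/sporadic split in the source literature contains a
  denominator inconsistency (39 of "41" LVNC-predominant families vs
  "42" familial forms); the package reports what its inputs contain and
  does not reconcile it.
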