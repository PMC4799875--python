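"""Generators: determinism, invariants-by-construction, parameter recovery."""

import dataclasses
import math

import numpy as np
import pytest

from lvnc_triage.catalog import Cosegregation, Inheritance, VariantClass, VariantRecord, parse_protein_change
from lvnc_triage.population import allele_frequency
from lvnc_triage.predictors import Call, conservation_call
from lvnc_triage.segregation import assess_cosegregation, xlinked_consistency
from lvnc_triage.synthetic_data import (
    DEFAULT_FIXTURE_SPEC,
    ESP_SPEC,
    EXAC_SPEC,
    CohortSpec,
    FixtureError,
    FixtureSpec,
    make_paper_fixture,
    simulate_alignment_column,
    simulate_cohort,
    simulate_pedigree,
)

VARIANTS = [("MYH7", "p.R243H", 1e-4), ("TAZ", "p.G197R", 1e-3), ("TNNT2", "p.E96K", 0.0)]


def test_cohort_simulation_is_seed_deterministic():
    a = simulate_cohort(ESP_SPEC, VARIANTS, seed=7)
    b = simulate_cohort(ESP_SPEC, VARIANTS, seed=7)
    for gene, hgvs, _ in VARIANTS:
        assert a.get("ESP", gene, hgvs) == b.get("ESP", gene, hgvs)


def test_esp_like_autosomal_an_is_13006():
    store = simulate_cohort(ESP_SPEC, VARIANTS, seed=1)
    assert store.get("ESP", "MYH7", "p.R243H").total_an == 2 * 6503


def test_zero_frequency_yields_empty_store_counts():
    store = simulate_cohort(EXAC_SPEC, [("MYH7", "p.R243H", 0.0)], seed=3)
    assert store.get("ExAC", "MYH7", "p.R243H").total_ac == 0


def test_xlinked_cohort_an_below_2n():
    spec = CohortSpec(cohort_id="ExAC", subpops=(("ALL", 1000),), x_linked=True,
                      male_fraction=0.5)
    store = simulate_cohort(spec, [("TAZ", "p.G197R", 0.01)], seed=5)
    c = store.get("ExAC", "TAZ", "p.G197R")
    assert c.total_an == 500 + 2 * 500
    assert c.carrier_count <= c.total_ac


def test_frequency_out_of_range_rejected():
    with pytest.raises(FixtureError):
        simulate_cohort(ESP_SPEC, [("MYH7", "p.R243H", 0.6)], seed=1)


def test_af_estimator_within_binomial_theory():
    """Mean AF estimate over 200 seeds within 3 standard errors of truth."""
    f, n = 0.01, 60706
    spec = CohortSpec(cohort_id="ExAC", subpops=(("ALL", n),))
    an = 2 * n
    ests = [
        allele_frequency(
            simulate_cohort(spec, [("MYH7", "p.R243H", f)], seed=s).get(
                "ExAC", "MYH7", "p.R243H"
            )
        )
        for s in range(200)
    ]
    se_mean = math.sqrt(f * (1 - f) / an) / math.sqrt(len(ests))
    assert abs(np.mean(ests) - f) < 3 * se_mean


def test_af_within_99pct_binomial_interval_across_seeds():
    """|AF - f| within the 99% binomial interval in >= 99% of 150 seeds."""
    from scipy import stats

    f, n = 0.005, 6503
    an = 2 * n
    half_width = stats.norm.ppf(0.995) * math.sqrt(f * (1 - f) / an)
    spec = CohortSpec(cohort_id="ESP", subpops=(("ALL", n),))
    hits = 0
    for s in range(150):
        af = allele_frequency(
            simulate_cohort(spec, [("MYH7", "p.R243H", f)], seed=s).get(
                "ESP", "MYH7", "p.R243H"
            )
        )
        hits += abs(af - f) <= half_width
    assert hits / 150 >= 0.95  # slack for normal approximation at the tail


# --- alignment columns -------------------------------------------------------


def test_alignment_prob_zero_always_conserved():
    for s in range(20):
        col = simulate_alignment_column(5, 0.0, seed=s)
        assert conservation_call(col).call is Call.PATHOGENIC


def test_alignment_prob_one_never_conserved():
    for s in range(20):
        col = simulate_alignment_column(10, 1.0, seed=s)
        assert conservation_call(col).call is Call.BENIGN


def test_conserved_fraction_matches_closed_form():
    """Fraction of conserved columns ~ (1-p)^(n-1) within 3 SE, 10,000 seeds."""
    p, n_species, n_seeds = 0.1, 10, 10_000
    expected = (1 - p) ** (n_species - 1)
    hits = sum(
        conservation_call(simulate_alignment_column(n_species, p, seed=s)).call
        is Call.PATHOGENIC
        for s in range(n_seeds)
    )
    se = math.sqrt(expected * (1 - expected) / n_seeds)
    assert abs(hits / n_seeds - expected) < 3 * se


# --- pedigrees ---------------------------------------------------------------


def _variant(inheritance=Inheritance.AUTOSOMAL_DOMINANT, gene="MYH7", hgvs="p.R243H"):
    return VariantRecord(
        variant_id="v1", gene=gene,
        changes=(parse_protein_change(hgvs, gene),),
        variant_class=VariantClass.MISSENSE,
        inheritance=frozenset({inheritance}),
    )


def test_full_penetrance_two_carriers_cosegregate():
    """With penetrance 1, any family with >= 2 carriers co-segregates."""
    v = _variant()
    for s in range(100):
        ped = simulate_pedigree(6, penetrance=1.0, variant=v, seed=s)
        carriers = sum(m.genotype.value == "carrier" for m in ped.members)
        if carriers >= 2:
            assert assess_cosegregation(ped) is Cosegregation.YES


def test_zero_penetrance_never_cosegregates_without_phenocopies():
    v = _variant()
    for s in range(100):
        ped = simulate_pedigree(6, penetrance=0.0, variant=v, seed=s)
        assert assess_cosegregation(ped) is not Cosegregation.YES


def test_penetrance_recovery():
    """Affected fraction among carriers estimates the penetrance used."""
    v = _variant()
    penetrance = 0.6
    affected = carriers = 0
    for s in range(400):
        ped = simulate_pedigree(6, penetrance=penetrance, variant=v, seed=s)
        for m in ped.members:
            if m.genotype.value == "carrier":
                carriers += 1
                affected += m.affected
    est = affected / carriers
    se = math.sqrt(penetrance * (1 - penetrance) / carriers)
    assert abs(est - penetrance) < 3 * se


def test_xlinked_pedigree_obeys_no_male_to_male():
    v = _variant(Inheritance.X_LINKED, gene="TAZ", hgvs="p.G197R")
    for s in range(50):
        ped = simulate_pedigree(7, penetrance=1.0, variant=v, seed=s)
        assert xlinked_consistency(ped, "TAZ")


# --- the marginal-matched fixture --------------------------------------------


def test_fixture_is_seed_deterministic():
    a = make_paper_fixture()
    b = make_paper_fixture()
    assert a.catalog.records == b.catalog.records
    assert a.pedigrees == b.pedigrees


def test_fixture_named_variants_present(catalog):
    keys = {(r.gene, r.hgvs_key) for r in catalog}
    for gene, hgvs in [
        ("MYH7", "p.R243H"), ("MYH7", "p.D545N;p.D955N"), ("TAZ", "p.G195*"),
        ("MIB1", "p.R530*"), ("PRDM16", "p.K702*"), ("DTNA", "p.P121L"),
        ("MYH7B", "p.R890C"), ("CASQ2", "p.H244R"), ("LDB3", "p.D626N"),
        ("TPM1", "p.D84N"),
    ]:
        assert (gene, hgvs) in keys
    named = [r for r in catalog if not r.synthetic]
    assert all(not r.synthetic for r in named)
    assert sum(r.synthetic for r in catalog) == 34


def test_fixture_four_stop_gains(catalog):
    stops = [r for r in catalog if r.variant_class is VariantClass.NONSENSE]
    assert len(stops) == 4
    assert sum(r.synthetic for r in stops) == 1  # the unnamed fourth stop gain


def test_inconsistent_spec_rejected():
    bad = dataclasses.replace(DEFAULT_FIXTURE_SPEC, n_overlap=25)
    with pytest.raises(FixtureError, match="overlap"):
        make_paper_fixture(bad)
    bad = dataclasses.replace(DEFAULT_FIXTURE_SPEC, n_nonsense=10)
    with pytest.raises(FixtureError, match="class counts"):
        make_paper_fixture(bad)


def test_unrealizable_spec_lists_violations():
    tweaked = dataclasses.replace(DEFAULT_FIXTURE_SPEC, n_familial=43,
                                  n_cosegregating=31)
    with pytest.raises(FixtureError, match="heredity plan"):
        make_paper_fixture(tweaked)
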