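"""Allele frequencies, presence lookup, carrier rule, store I/O."""

from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from lvnc_triage.population import (
    CohortCounts,
    PopulationError,
    PopulationPresence,
    PopulationStore,
    allele_frequency,
    carrier_filter,
    format_af,
    lookup_presence,
    presence_overlap,
    read_store_tsv,
    read_store_vcf,
    write_store_tsv,
)


def counts(ac, an, cohort="ExAC", carriers=None, n=60706):
    return CohortCounts(
        cohort_id=cohort,
        subpop_counts={"ALL": (ac, an)},
        carrier_count=min(ac, n) if carriers is None else carriers,
        n_individuals=n,
    )


def test_af_exact_rational():
    # oracle: exact rational 1/121412, matching the printed ExAC
    # frequency 0.000008236 for MYH7 p.R243H at 4 significant figures
    af = allele_frequency(counts(1, 121412))
    assert af == float(Fraction(1, 121412))
    assert format_af(af) == "0.000008236"


def test_af_bounds():
    assert allele_frequency(counts(0, 13006, cohort="ESP", n=6503)) == 0
    assert allele_frequency(counts(100, 100, n=100)) == 1


def test_af_sums_over_subpopulations():
    c = CohortCounts(
        cohort_id="ESP",
        subpop_counts={"AfricanAmerican": (1, 4406), "EuropeanAmerican": (2, 8600)},
        carrier_count=3,
        n_individuals=6503,
    )
    assert allele_frequency(c) == pytest.approx(3 / 13006)


@given(ac=st.integers(0, 1000), an=st.integers(1, 2000))
def test_af_in_unit_interval_and_monotone_in_ac(ac, an):
    ac = min(ac, an)
    af = allele_frequency(counts(ac, an, n=an))
    assert 0 <= af <= 1
    if ac < an:
        assert allele_frequency(counts(ac + 1, an, n=an)) > af


@pytest.mark.parametrize(
    "bad",
    [
        dict(ac=5, an=4),       # AC exceeds AN
        dict(ac=2, an=10, carriers=3),  # more carriers than alleles
        dict(ac=0, an=300, n=100),      # AN exceeds 2x cohort size
    ],
)
def test_count_invariants_enforced(bad):
    with pytest.raises(PopulationError):
        counts(bad["ac"], bad["an"], carriers=bad.get("carriers"), n=bad.get("n", 60706))


# --- carrier plausibility rule ---------------------------------------------


def presence(carriers, present=True):
    return PopulationPresence(
        variant_id="v", cohort_id="ExAC", present=present,
        allele_frequency=1e-5 if present else None,
        carrier_count=carriers if present else 0,
    )


@pytest.mark.parametrize("carriers,expected", [(6, True), (5, False), (0, False)])
def test_more_than_five_persons_rule(carriers, expected):
    assert carrier_filter(presence(carriers)) is expected


def test_carrier_filter_monotone_and_threshold_configurable():
    assert carrier_filter(presence(3), threshold=2)
    assert not carrier_filter(presence(3), threshold=3)
    with pytest.raises(PopulationError):
        carrier_filter(presence(3), threshold=-1)


# --- presence lookup and overlap -------------------------------------------


def test_fixture_presence_counts(presences):
    esp, exac = presences
    assert sum(p.present for p in esp) == 9
    assert sum(p.present for p in exac) == 18
    assert presence_overlap(esp, exac) == (9, 18, 8)


def test_empty_store_means_all_absent(catalog):
    store = PopulationStore()
    store.add("_SENTINEL", "p.A1G", counts(0, 100, n=100))
    out = lookup_presence(catalog, store, "ExAC")
    assert not any(p.present for p in out)


def test_unknown_cohort_is_configuration_error(catalog, bundle):
    with pytest.raises(PopulationError, match="cohort"):
        lookup_presence(catalog, bundle.esp_store, "gnomAD")


def test_overlap_requires_matching_variant_sets():
    a = [presence(1)]
    b = [
        PopulationPresence(variant_id="other", cohort_id="ESP", present=False,
                           allele_frequency=None, carrier_count=0)
    ]
    with pytest.raises(PopulationError):
        presence_overlap(a, b)


@given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=40))
def test_overlap_bound(flags):
    def mk(i, cohort, present):
        return PopulationPresence(
            variant_id=f"v{i}", cohort_id=cohort, present=present,
            allele_frequency=0.001 if present else None,
            carrier_count=1 if present else 0,
        )

    a = [mk(i, "ESP", fa) for i, (fa, _) in enumerate(flags)]
    b = [mk(i, "ExAC", fb) for i, (_, fb) in enumerate(flags)]
    n_a, n_b, n_both = presence_overlap(a, b)
    assert n_both <= min(n_a, n_b)
    assert n_both == sum(fa and fb for fa, fb in flags)


# --- store I/O --------------------------------------------------------------


def test_store_tsv_roundtrip(bundle, tmp_path, catalog):
    path = tmp_path / "exac.tsv"
    write_store_tsv(bundle.exac_store, path)
    reread = read_store_tsv(path)
    a = lookup_presence(catalog, bundle.exac_store, "ExAC")
    b = lookup_presence(catalog, reread, "ExAC")
    assert a == b


def test_minimal_vcf_reader(tmp_path, catalog):
    vcf = tmp_path / "store.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=AC,Number=A,Type=Integer,Description="Allele count">\n'
        '##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele number">\n'
        '##INFO=<ID=GENE_HGVSP,Number=1,Type=String,Description="gene|hgvs_p">\n'
        "##contig=<ID=14>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "14\t1000\t.\tG\tA\t.\t.\tAC=1;AN=121412;GENE_HGVSP=MYH7|p.R243H\n"
        "14\t2000\t.\tC\tT\t.\t.\tAC=3;AN=121412\n"  # no annotation: skipped
    )
    store = read_store_vcf(vcf, cohort_id="ExAC", n_individuals=60706)
    got = store.get("ExAC", "MYH7", "p.R243H")
    assert got is not None
    assert allele_frequency(got) == pytest.approx(8.236e-6, rel=1e-4)
    out = lookup_presence(catalog, store, "ExAC")
    assert sum(p.present for p in out) == 1
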