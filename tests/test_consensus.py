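"""Consensus voting rule, exhaustive oracle, and percent conventions."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from lvnc_triage.catalog import VariantClass, VariantRecord, parse_protein_change
from lvnc_triage.consensus import (
    Classification,
    ConsensusError,
    classification_fractions,
    classify_votes,
    consensus_classify,
    truncated_percent,
)
from lvnc_triage.predictors import Call, ToolPrediction

TOOLS = ("conservation", "grantham", "sift", "polyphen2")
STATES = (Call.PATHOGENIC, Call.BENIGN, Call.UNAVAILABLE)


def panel(calls):
    return [ToolPrediction(tool=t, raw_label="", call=c) for t, c in zip(TOOLS, calls)]


def oracle(calls):
    """Independent restatement of the voting rule, enumerating raw counts."""
    available = [c for c in calls if c is not Call.UNAVAILABLE]
    votes = sum(c is Call.PATHOGENIC for c in available)
    if votes >= 3:
        return Classification.PATHOGENIC
    if votes >= 1:
        return Classification.VUS
    if len(available) == 4:
        return Classification.BENIGN
    return Classification.VUS  # never benign on a partial panel


def test_consensus_equals_exhaustive_81_pattern_oracle():
    for calls in itertools.product(STATES, repeat=4):
        n_avail, n_votes, cls, flags = classify_votes(panel(calls))
        assert cls is oracle(calls), calls
        assert n_avail == sum(c is not Call.UNAVAILABLE for c in calls)
        assert n_votes == sum(c is Call.PATHOGENIC for c in calls)
        assert ("incomplete_tool_panel" in flags) == (n_avail < 4)


def test_three_votes_pathogenic_one_vote_vus():
    p, b = Call.PATHOGENIC, Call.BENIGN
    assert classify_votes(panel([p, p, p, b]))[2] is Classification.PATHOGENIC
    assert classify_votes(panel([b, p, b, b]))[2] is Classification.VUS
    assert classify_votes(panel([b, b, b, b]))[2] is Classification.BENIGN


def test_monotone_in_pathogenic_votes():
    """Flipping any benign call to pathogenic never moves the class down."""
    order = {Classification.BENIGN: 0, Classification.VUS: 1, Classification.PATHOGENIC: 2}
    for calls in itertools.product(STATES, repeat=4):
        base = classify_votes(panel(calls))[2]
        if base not in order:
            continue
        for i, c in enumerate(calls):
            if c is Call.BENIGN:
                flipped = list(calls)
                flipped[i] = Call.PATHOGENIC
                assert order[classify_votes(panel(flipped))[2]] >= order[base]


@given(st.permutations(range(4)))
def test_permutation_invariance(perm):
    calls = [Call.PATHOGENIC, Call.PATHOGENIC, Call.BENIGN, Call.UNAVAILABLE]
    reordered = [
        ToolPrediction(tool=TOOLS[i], raw_label="", call=calls[perm[i]]) for i in range(4)
    ]
    baseline = [
        ToolPrediction(tool=TOOLS[i], raw_label="", call=calls[i]) for i in range(4)
    ]
    assert classify_votes(reordered)[2] is classify_votes(baseline)[2]


def test_duplicate_tool_slot_rejected():
    preds = panel([Call.BENIGN] * 4)
    preds[1] = ToolPrediction(tool="sift", raw_label="", call=Call.BENIGN)
    with pytest.raises(ConsensusError, match="duplicate"):
        classify_votes(preds)


def test_stop_gain_is_not_analyzed():
    rec = VariantRecord(
        variant_id="v", gene="PRDM16",
        changes=(parse_protein_change("p.K702*", "PRDM16"),),
        variant_class=VariantClass.NONSENSE,
    )
    out = consensus_classify(rec)
    assert out.classification is Classification.NOT_ANALYZED
    assert out.n_tools_available == 0


def test_residue_mismatch_is_unclassifiable():
    rec = VariantRecord(
        variant_id="v", gene="LDB3",
        changes=(parse_protein_change("p.D626N", "LDB3"),),
        variant_class=VariantClass.MISSENSE,
        residue_mismatch=True,
    )
    assert consensus_classify(rec).classification is Classification.UNCLASSIFIABLE


# --- percent conventions ----------------------------------------------------


def test_truncation_not_rounding():
    assert truncated_percent(10, 18) == 55   # 55.6 prints as 55
    assert truncated_percent(29, 56) == 51   # 51.8 prints as 51
    assert truncated_percent(1, 1) == 100


def test_class_count_reconstruction_is_unique():
    """(29, 23, 3) is the only non-negative triple summing to 55 whose
    floor-percents over 56 analyzed variants are (51, 41, 5)."""
    solutions = [
        (p, v, b)
        for p in range(56)
        for v in range(56 - p)
        for b in [55 - p - v]
        if b >= 0
        and truncated_percent(p, 56) == 51
        and truncated_percent(v, 56) == 41
        and truncated_percent(b, 56) == 5
    ]
    assert solutions == [(29, 23, 3)]


def test_fixture_fractions(classifications, catalog):
    fr = classification_fractions(classifications, catalog)
    assert fr[Classification.PATHOGENIC] == (29, 51)
    assert fr[Classification.VUS] == (23, 41)
    assert fr[Classification.BENIGN] == (3, 5)
    assert fr[Classification.UNCLASSIFIABLE] == (1, 1)
    assert fr[Classification.NOT_ANALYZED][0] == 4


@given(
    st.lists(
        st.sampled_from(
            [Classification.PATHOGENIC, Classification.VUS, Classification.BENIGN]
        ),
        min_size=1,
        max_size=60,
    )
)
def test_truncated_percents_sum_between_97_and_100(classes):
    counts = {c: classes.count(c) for c in set(classes)}
    total = len(classes)
    pct_sum = sum(truncated_percent(n, total) for n in counts.values())
    assert 97 <= pct_sum <= 100  # each truncation loses < 1 point
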