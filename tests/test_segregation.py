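"""Segregation engine, enumeration oracle, and co-inheritance detection."""

import random

import pytest

from irida_twohit.segregation import (
    AMBIGUOUS, CIS, TRANS, UNINFORMATIVE, PhaseInconsistencyError,
    call_segregation, cross_subject_coinheritance, oracle_phase,
)
from tests.conftest import VARIANT, make_family, nuclear_family_configurations

A, V, AV, E = frozenset("A"), frozenset("V"), frozenset("AV"), frozenset()


# ---------------------------------------------------------------------------
# Engine verdicts on the published family patterns


def test_family5_pattern_is_trans(fixture_cohort, fixture_matrix):
    """The intron-2 splice variant is present in the symptomatic
    daughter but absent in her mother who shares the anchor: trans."""
    call = call_segregation("c.229+945C>T", "F5", fixture_cohort, fixture_matrix)
    assert call.verdict == TRANS
    by_subject = {s: (a, v) for s, a, v, _ in call.evidence}
    assert by_subject["24"] == (True, True)
    assert by_subject["8"] == (True, False)
    assert any("non-recombining" in n for n in call.notes)


def test_perfect_cooccurrence_in_family5_is_cis(fixture_cohort, fixture_matrix):
    call = call_segregation("c.363+149G>A", "F5", fixture_cohort, fixture_matrix)
    assert call.verdict == CIS


def test_variant_absent_in_family_is_uninformative(fixture_cohort, fixture_matrix):
    call = call_segregation("c.-7001G>A", "F5", fixture_cohort, fixture_matrix)
    assert call.verdict == UNINFORMATIVE


def test_singleton_family_never_guesses(fixture_cohort, fixture_matrix):
    call = call_segregation("c.-7001G>A", "iso_12", fixture_cohort, fixture_matrix)
    assert call.verdict == UNINFORMATIVE


def test_family_without_anchor_carrier_is_uninformative():
    cohort, matrix = make_family([("X", None, None, V, E),
                                  ("Y", None, None, E, E)])
    call = call_segregation(VARIANT, "X", cohort, matrix)
    assert call.verdict == UNINFORMATIVE
    assert any("no anchor" in n for n in call.notes)


def test_homozygous_carrier_forces_trans_with_note():
    cohort, matrix = make_family([("X", None, None, AV, V),
                                  ("Y", None, None, A, E)])
    call = call_segregation(VARIANT, "X", cohort, matrix)
    assert call.verdict == TRANS
    assert any("homozygous" in n.lower() for n in call.notes)


def test_verdict_invariant_under_subject_reordering():
    members = [("B", None, None, A, E), ("A", None, None, AV, E),
               ("C", None, None, E, V)]
    verdicts = set()
    for seed in range(5):
        shuffled = members[:]
        random.Random(seed).shuffle(shuffled)
        cohort, matrix = make_family(shuffled)
        verdicts.add(call_segregation(VARIANT, "X", cohort, matrix).verdict)
    assert len(verdicts) == 1


def test_adding_trans_evidence_never_turns_trans_into_cis():
    """Monotonicity: an extra anchor carrier lacking the variant can
    promote cis/ambiguous to trans but never the other way round."""
    base = [("P", None, None, AV, E), ("Q", None, None, AV, E)]
    cohort, matrix = make_family(base)
    assert call_segregation(VARIANT, "X", cohort, matrix).verdict == CIS
    cohort2, matrix2 = make_family(base + [("R", None, None, A, E)])
    assert call_segregation(VARIANT, "X", cohort2, matrix2).verdict == TRANS
    # and starting from trans, more members never flip it to cis
    cohort3, matrix3 = make_family(base + [("R", None, None, A, E),
                                           ("S", None, None, A, E)])
    assert call_segregation(VARIANT, "X", cohort3, matrix3).verdict == TRANS


# ---------------------------------------------------------------------------
# Enumeration oracle


def test_oracle_trio_transmitting_parent_without_variant_forces_trans():
    cohort, matrix = make_family([("F", None, None, A, E),
                                  ("M", None, None, V, E),
                                  ("C", "F", "M", A, V)])
    assert oracle_phase(VARIANT, "X", cohort, matrix) == TRANS


def test_oracle_duo_unrelated_by_marriage_is_ambiguous():
    """Two founders with no transmission between them carry anchor and
    variant; enumeration cannot resolve the phase."""
    cohort, matrix = make_family([("F", None, None, AV, E),
                                  ("M", None, None, E, E)])
    assert oracle_phase(VARIANT, "X", cohort, matrix) == AMBIGUOUS


def test_oracle_parent_and_child_both_carrying_both_is_ambiguous():
    """Child het anchor + het variant, parent with both: cis and trans
    transmissions are both consistent."""
    cohort, matrix = make_family([("M", None, None, AV, E),
                                  ("F", None, None, V, E),
                                  ("C", "F", "M", AV, E)])
    # C could have inherited (A,V) together from M (cis) or A from M and
    # V from F (trans); the observations admit both.
    assert oracle_phase(VARIANT, "X", cohort, matrix) == AMBIGUOUS


def test_oracle_detects_impossible_data():
    """Child carries the variant although neither parent does: no
    haplotype assignment fits (genotype error or de novo)."""
    cohort, matrix = make_family([("F", None, None, A, E),
                                  ("M", None, None, E, E),
                                  ("C", "F", "M", A, V)])
    with pytest.raises(PhaseInconsistencyError):
        oracle_phase(VARIANT, "X", cohort, matrix)


def test_engine_never_contradicted_by_oracle_on_all_small_pedigrees():
    """Exhaustive equivalence over every haplotype configuration of
    nuclear families up to 5 members (single anchor origin): decisive
    engine and oracle verdicts always agree, and the engine is never
    decisive where the oracle is ambiguous."""
    checked = 0
    for members in nuclear_family_configurations(max_children=3):
        cohort, matrix = make_family(members)
        engine = call_segregation(VARIANT, "X", cohort, matrix).verdict
        oracle = oracle_phase(VARIANT, "X", cohort, matrix)
        if engine in (TRANS, CIS):
            assert oracle == engine, (members, engine, oracle)
        checked += 1
    assert checked == 1344


# ---------------------------------------------------------------------------
# Cross-subject co-inheritance


def test_coinheritance_true_for_perfect_cooccurrence(fixture_cohort, fixture_matrix):
    ok, details = cross_subject_coinheritance("c.363+149G>A", fixture_cohort,
                                              fixture_matrix)
    assert ok and details["anchor"] == "c.497delT"
    assert details["variant_carriers"] == ["11", "24", "5", "8", "9"]


def test_coinheritance_true_for_two_unrelated_carriers(fixture_cohort,
                                                       fixture_matrix):
    ok, details = cross_subject_coinheritance("c.-5823C>T", fixture_cohort,
                                              fixture_matrix)
    assert ok and details["anchor"] == "c.431+5G>T"


def test_coinheritance_broken_by_anchor_carrier_lacking_variant(fixture_cohort,
                                                                fixture_matrix):
    """rs80140288 carriers both hold c.497delT, but anchor carrier ID 8
    lacks the variant: co-occurrence is imperfect."""
    ok, details = cross_subject_coinheritance("c.229+945C>T", fixture_cohort,
                                              fixture_matrix)
    assert not ok
    assert "8" in str(details["reason"])


def test_coinheritance_needs_two_carriers(fixture_cohort, fixture_matrix):
    ok, details = cross_subject_coinheritance("c.-7001G>A", fixture_cohort,
                                              fixture_matrix)
    assert not ok and "fewer than two" in details["reason"]
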