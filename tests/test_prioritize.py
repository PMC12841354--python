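"""Decision tree, class assignment, funnel bookkeeping."""

import pytest

from irida_twohit.cohort import CarriershipMatrix
from irida_twohit.fixture import (
    build_fixture_annotations, build_fixture_carriership, build_fixture_cohort,
)
from irida_twohit.hgvs import parse_hgvs_c
from irida_twohit.prioritize import (
    ASYMPTOMATIC_EXCLUSIVE, CIS_INHERITED, NON_PATHOGENIC, PipelineConfig,
    PipelineOrderingError, POSSIBLE_CONTRIBUTOR, POTENTIALLY_PATHOGENIC,
    TRACK_EXCLUSIVE, TRACK_SHARED_WT, UNCERTAIN, UNLIKELY_PATHOGENIC,
    ClassificationResult, assign_path_class, classify_familial,
    classify_isolated, run_pipeline,
)


def test_familial_trans_exclusive_is_potentially_pathogenic(fixture_result):
    r = fixture_result.results["c.230-938_230-937del"]
    assert r.category == POTENTIALLY_PATHOGENIC
    assert r.retained and r.track == TRACK_EXCLUSIVE and r.branch == "familial"


def test_familial_trans_shared_with_wt_is_uncertain(fixture_result):
    r = fixture_result.results["c.2278-31G>A"]
    assert r.category == UNCERTAIN
    assert r.retained and r.track == TRACK_SHARED_WT


def test_isolated_exclusive_retained(fixture_result):
    r = fixture_result.results["c.-7001G>A"]
    assert r.category == POTENTIALLY_PATHOGENIC
    assert r.retained and r.branch == "isolated" and r.track == TRACK_EXCLUSIVE


def test_isolated_shared_with_unrelated_wt_is_possible_contributor(fixture_result):
    r = fixture_result.results["c.-4578T>G"]
    assert r.category == POSSIBLE_CONTRIBUTOR
    assert r.retained and r.track == TRACK_SHARED_WT


def test_coinherited_variant_demoted_to_cis_but_kept_on_funnel(fixture_result):
    """The intron-3 variant riding with the frameshift anchor across all
    five carriers is likely benign (cis) yet still counts toward the
    isolated exclusive track."""
    r = fixture_result.results["c.363+149G>A"]
    assert r.category == CIS_INHERITED
    assert r.retained and r.path_class == 2
    assert any("co-inherited" in x or "likely benign" in x for x in r.rationale)


def test_asymptomatic_exclusive_track(fixture_result):
    for hgvs in ("c.363+750C>T", "c.1224-18G>T", "c.230-1580C>T"):
        r = fixture_result.results[hgvs]
        assert r.category == ASYMPTOMATIC_EXCLUSIVE
        assert not r.retained


def test_classify_familial_requires_segregation_calls(fixture_cohort,
                                                      fixture_matrix):
    with pytest.raises(PipelineOrderingError):
        classify_familial("c.229+945C>T", None, fixture_cohort, fixture_matrix)


def test_trans_in_unrelated_asymptomatic_rules_a_variant_out():
    """A variant trans-inherited in an asymptomatic subject of another
    family cannot explain the phenotype (non-pathogenic)."""
    from tests.conftest import make_family, VARIANT
    from irida_twohit.segregation import call_segregation

    A, V, AV, E = (frozenset("A"), frozenset("V"), frozenset("AV"), frozenset())
    cohort, matrix = make_family([("S", None, None, AV, E),
                                  ("T", None, None, A, E)])
    # flip T's status: the trans carrier is asymptomatic
    cohort.subjects["S"].status = "asymptomatic_monoallelic"
    calls = [call_segregation(VARIANT, "X", cohort, matrix)]
    r = classify_familial(VARIANT, calls, cohort, matrix)
    assert r.category == ASYMPTOMATIC_EXCLUSIVE  # no symptomatic carrier at all
    cohort.subjects["T"].status = "symptomatic_monoallelic"
    matrix.add_variant(parse_hgvs_c(VARIANT), {"T"})
    calls = [call_segregation(VARIANT, "X", cohort, matrix)]
    r = classify_familial(VARIANT, calls, cohort, matrix)
    assert r.category in (NON_PATHOGENIC, CIS_INHERITED, UNCERTAIN)


def test_isolated_variant_in_asymptomatic_is_unlikely_pathogenic(fixture_cohort):
    matrix = CarriershipMatrix(subject_ids=sorted(fixture_cohort.subjects))
    matrix.add_variant(parse_hgvs_c("c.229+99A>G"), {"12", "21"})  # 21 asympt
    r = classify_isolated("c.229+99A>G", fixture_cohort, matrix)
    assert r.category == UNLIKELY_PATHOGENIC and not r.retained


@pytest.mark.parametrize("hgvs, expected_class", [
    ("c.-7607_-7606dup", 1),  # MAF 39.86%: benign
    ("c.229+945C>T", 3),  # rare, exclusive trans, splice flag
    ("c.230-938_230-937del", 3),
    ("c.-7001G>A", 3),  # regulatory flag
    ("c.*503C>G", 3),
    ("c.1223+1526C>T", 2),  # rare + exclusive but no in-silico flag
    ("c.-7504C>T", 2),  # MAF 3.45%: above rarity gate, below benign cut
    ("c.-4578T>G", 1),  # 19.11%: benign even on the shared-WT track
])
def test_path_class_rules_on_fixture(fixture_result, hgvs, expected_class):
    assert fixture_result.results[hgvs].path_class == expected_class


def test_class_thresholds_are_configurable(fixture_cohort, fixture_matrix,
                                           transcript):
    cfg = PipelineConfig(benign_maf_threshold=50.0, rare_maf_threshold=0.5)
    res = run_pipeline(fixture_cohort, fixture_matrix,
                       build_fixture_annotations(), transcript, cfg)
    # 39.86% no longer clears the benign bar; 0.92% no longer counts rare
    assert res.results["c.-7607_-7606dup"].path_class == 2
    assert res.results["c.230-938_230-937del"].path_class == 2
    assert "c.230-938_230-937del" not in res.candidates


def test_classes_4_and_5_never_produced_for_noncoding(fixture_result):
    assert all(r.path_class in (1, 2, 3)
               for r in fixture_result.results.values())


def test_every_variant_gets_exactly_one_result(fixture_result, fixture_matrix):
    assert set(fixture_result.results) == set(fixture_matrix.variants)
    assert all(r.rationale for r in fixture_result.results.values())


def test_candidate_soundness_no_asymptomatic_carrier(fixture_result,
                                                     fixture_cohort,
                                                     fixture_matrix):
    for hgvs in fixture_result.candidates:
        statuses = {fixture_cohort.subjects[c].status
                    for c in fixture_matrix.carriers(hgvs)}
        assert "asymptomatic_monoallelic" not in statuses
        assert "wild_type" not in statuses


def test_results_independent_of_input_row_order(fixture_cohort, transcript):
    forward = build_fixture_carriership(fixture_cohort)
    reversed_matrix = CarriershipMatrix(subject_ids=forward.subject_ids)
    for hgvs in reversed(list(forward.variants)):
        reversed_matrix.add_variant(forward.variants[hgvs],
                                    forward.carriers(hgvs))
    ann = build_fixture_annotations()
    a = run_pipeline(fixture_cohort, forward, ann, transcript)
    b = run_pipeline(fixture_cohort, reversed_matrix, ann, transcript)
    assert a.funnel.to_dict() == b.funnel.to_dict()
    assert a.candidates == b.candidates
    assert {h: r.category for h, r in a.results.items()} == \
           {h: r.category for h, r in b.results.items()}


def test_funnel_conservation(fixture_result):
    f = fixture_result.funnel
    f.check()
    assert f.familial_retained == (f.trans_after_cis_exclusion
                                   - f.removed_by_unrelated_asymptomatic)
    assert f.total_exclusive_symptomatic == f.familial_retained + f.isolated_retained


def test_empty_carriership_gives_zero_counts(fixture_cohort, transcript):
    empty = CarriershipMatrix(subject_ids=sorted(fixture_cohort.subjects))
    res = run_pipeline(fixture_cohort, empty, {}, transcript)
    assert res.candidates == []
    assert res.funnel.total_variants == 0
    assert res.funnel.total_exclusive_symptomatic == 0


def test_region_exclusion_is_explicit_not_silent(fixture_cohort, fixture_matrix,
                                                 transcript):
    """Excluding a region (the allele-skew scenario) leaves an explicit
    result per excluded variant instead of dropping it."""
    cfg = PipelineConfig(excluded_regions=("intron_6",))
    res = run_pipeline(fixture_cohort, fixture_matrix,
                       build_fixture_annotations(), transcript, cfg)
    excluded = [h for h, r in res.results.items()
                if r.category == "excluded_region"]
    assert sorted(excluded) == sorted(
        h for h, d in res.annotations.items() if d.region == "intron_6")
    assert res.funnel.excluded_by_region == len(excluded) > 0
    assert set(res.results) == set(fixture_matrix.variants)


def test_ubiquitous_variant_is_class1(fixture_cohort, transcript):
    matrix = CarriershipMatrix(subject_ids=sorted(fixture_cohort.subjects))
    matrix.add_variant(parse_hgvs_c("c.229+77G>A").with_annotation(maf_percent=0.5),
                       set(fixture_cohort.subjects))
    res = run_pipeline(fixture_cohort, matrix,
                       {"c.229+77G>A": matrix.variants["c.229+77G>A"]}, transcript)
    r = res.results["c.229+77G>A"]
    assert r.category == "ubiquitous" and r.path_class == 1
    assert res.funnel.ubiquitous == 1
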