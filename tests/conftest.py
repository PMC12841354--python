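import itertools

import pytest

from irida_twohit.cohort import CarriershipMatrix, Cohort, Subject
from irida_twohit.fixture import (
    build_fixture_annotations, build_fixture_carriership, build_fixture_cohort,
)
from irida_twohit.hgvs import parse_hgvs_c
from irida_twohit.prioritize import run_pipeline
from irida_twohit.transcript import build_fixture_transcript


@pytest.fixture(scope="session")
def fixture_cohort():
    return build_fixture_cohort()


@pytest.fixture(scope="session")
def fixture_matrix(fixture_cohort):
    return build_fixture_carriership(fixture_cohort)


@pytest.fixture(scope="session")
def transcript():
    return build_fixture_transcript()


@pytest.fixture(scope="session")
def fixture_result(fixture_cohort, fixture_matrix, transcript):
    return run_pipeline(fixture_cohort, fixture_matrix,
                        build_fixture_annotations(), transcript)


ANCHOR = "c.100A>G"
VARIANT = "c.229+5C>T"


def make_family(members):
    """Build a one-family cohort plus carriership from member tuples
    ``(sid, father, mother, hap1, hap2)`` where haps are sets drawn from
    {"A", "V"} (anchor / variant)."""
    cohort = Cohort()
    haps = {}
    for sid, fa, mo, h1, h2 in members:
        has_anchor = "A" in (h1 | h2)
        cohort.add(Subject(
            subject_id=sid, family_id="X", father_id=fa, mother_id=mo,
            status="symptomatic_monoallelic" if has_anchor else "wild_type",
            anchor_variant=ANCHOR if has_anchor else None,
            anchor_class=5 if has_anchor else None))
        haps[sid] = (h1, h2)
    matrix = CarriershipMatrix(subject_ids=sorted(cohort.subjects))
    carriers = {s for s, (h1, h2) in haps.items() if "V" in (h1 | h2)}
    hom = {s for s, (h1, h2) in haps.items() if "V" in h1 and "V" in h2}
    matrix.add_variant(parse_hgvs_c(VARIANT), carriers, hom)
    return cohort, matrix


def nuclear_family_configurations(max_children=3):
    """All haplotype configurations of a nuclear family with a single
    anchor-introducing founder (father hap1) and the variant free on any
    founder haplotype, over 1..max_children children (<= 5 members)."""
    v_states = (frozenset(), frozenset("V"))
    for n_children in range(1, max_children + 1):
        for f2, m1, m2 in itertools.product(v_states, repeat=3):
            for fv1 in (False, True):
                f1 = frozenset({"A"} | ({"V"} if fv1 else set()))
                for choices in itertools.product(
                        itertools.product((0, 1), repeat=2), repeat=n_children):
                    members = [("F", None, None, f1, f2),
                               ("M", None, None, m1, m2)]
                    f_haps, m_haps = (f1, f2), (m1, m2)
                    for i, (pi, mi) in enumerate(choices):
                        members.append((f"C{i}", "F", "M", f_haps[pi], m_haps[mi]))
                    yield members
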