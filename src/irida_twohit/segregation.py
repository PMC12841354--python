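"""Within-family cis/trans phase inference for a second hit vs the anchor.

The engine uses presence/absence segregation: among relatives sharing
the family's exonic anchor variant, a non-coding variant present in one
anchor carrier but absent in another must lie on the non-anchor
haplotype (trans), because the anchor copies in one family are assumed
identical by descent and the intragenic span is treated as
non-recombining. Perfect co-occurrence of variant and anchor across all
members instead indicates cis. A brute-force haplotype-enumeration
oracle over small pedigrees provides an independent check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cohort import CarriershipMatrix, Cohort

NO_RECOMBINATION_NOTE = ("assumes a single non-recombining intragenic segment and "
                         "identical-by-descent anchor copies within the family")

TRANS, CIS, AMBIGUOUS, UNINFORMATIVE = "trans", "cis", "ambiguous", "uninformative"


@dataclass
class SegregationCall:
    variant: str
    family_id: str
    verdict: str
    evidence: list = field(default_factory=list)  # (subject, anchor?, variant?, role)
    notes: list = field(default_factory=list)

    def to_record(self) -> dict:
        return {
            "variant": self.variant,
            "family": self.family_id,
            "verdict": self.verdict,
            "evidence": [
                {"subject": s, "anchor_present": a, "variant_present": v, "role": r}
                for (s, a, v, r) in self.evidence
            ],
            "notes": list(self.notes),
        }


class PhaseInconsistencyError(ValueError):
    """No haplotype assignment fits the data (genotype error or de novo)."""


def call_segregation(variant: str, family_id: str, cohort: Cohort,
                     carriership: CarriershipMatrix) -> SegregationCall:
    """Phase verdict for (variant, family) from presence/absence patterns.

    trans: some anchor carrier has the variant while another anchor
    carrier lacks it (or an anchor carrier is homozygous for the
    variant, which puts a copy on the non-anchor haplotype either way).
    cis: >= 2 anchor carriers and the variant co-occurs perfectly with
    the anchor across every member. Families with < 2 members are
    uninformative — phase is never guessed for singletons.
    """
    members = cohort.members(family_id)
    notes = [NO_RECOMBINATION_NOTE]
    anchor = cohort.family_anchor(family_id)
    evidence = []
    carriers_in_family = []
    for m in sorted(members):
        s = cohort.subjects[m]
        a = s.is_monoallelic and s.anchor_variant == anchor and anchor is not None
        v = carriership.is_present(variant, m)
        if v:
            carriers_in_family.append(m)
        role = "anchor_carrier" if a else ("wild_type" if s.status == "wild_type"
                                           else "non_anchor")
        evidence.append((m, bool(a), v, role))

    def done(verdict):
        return SegregationCall(variant, family_id, verdict, evidence, notes)

    if anchor is None:
        notes.append("no anchor in family")
        return done(UNINFORMATIVE)
    if len(members) < 2:
        notes.append("singleton family: phase not inferable")
        return done(UNINFORMATIVE)
    if not carriers_in_family:
        notes.append("variant absent in every family member")
        return done(UNINFORMATIVE)

    anchor_with = [m for (m, a, v, _r) in evidence if a and v]
    anchor_without = [m for (m, a, v, _r) in evidence if a and not v]
    hom = carriership.hom_carriers(variant) & set(anchor_with)
    if hom:
        notes.append(f"homozygous variant carrier(s) {sorted(hom)}: a copy lies on "
                     "the non-anchor haplotype by necessity")
        return done(TRANS)
    if anchor_with and anchor_without:
        evidence = [(m, a, v, ("trans_evidence_absence" if (a and not v and m in anchor_without)
                               else r)) for (m, a, v, r) in evidence]
        return done(TRANS)
    perfect = all(a == v for (_m, a, v, _r) in evidence)
    if perfect and len(anchor_with) >= 2:
        return done(CIS)
    notes.append("pattern compatible with both phases")
    return done(AMBIGUOUS)


# ---------------------------------------------------------------------------
# Brute-force haplotype enumeration oracle

_A, _V = "A", "V"
_STATES = (frozenset(), frozenset({_A}), frozenset({_V}), frozenset({_A, _V}))


def _consistent(h1, h2, anchor_present: bool, variant_present: bool,
                variant_hom: bool) -> bool:
    """Copy-count consistency of a haplotype pair with the observations.

    Anchor carriers are monoallelic by definition (exactly one anchor
    copy); the variant has two copies when the genotype says homozygous,
    otherwise exactly one when present.
    """
    a_copies = (_A in h1) + (_A in h2)
    v_copies = (_V in h1) + (_V in h2)
    if a_copies != (1 if anchor_present else 0):
        return False
    return v_copies == (2 if variant_hom else 1 if variant_present else 0)


def _pedigree_order(cohort: Cohort, members: list) -> list:
    ordered, placed = [], set()
    pending = list(members)
    while pending:
        progressed = False
        for m in list(pending):
            s = cohort.subjects[m]
            deps = [p for p in (s.father_id, s.mother_id) if p in members]
            if all(p in placed for p in deps):
                ordered.append(m)
                placed.add(m)
                pending.remove(m)
                progressed = True
        if not progressed:  # pedigree loop; treat remaining as founders
            ordered.extend(pending)
            break
    return ordered


def oracle_phase(variant: str, family_id: str, cohort: Cohort,
                 carriership: CarriershipMatrix) -> str:
    """Exhaustive phasing by enumeration of haplotype assignments.

    Each member's two haplotypes each carry a subset of {anchor,
    variant}; founders are unconstrained, children must inherit one
    whole haplotype from each in-pedigree parent (no recombination
    within the locus). Copy counts follow the observational model of
    the cohort: anchor carriers hold exactly one anchor copy
    (monoallelic by definition), the variant is homozygous only when
    the genotype says so. A member whose variant copy sits on both
    haplotypes necessarily has a trans copy and counts as trans, the
    same convention the presence/absence engine uses. Returns ``trans``
    if every assignment consistent with the observations is trans,
    ``cis`` if every one is cis, ``ambiguous`` otherwise, and
    ``uninformative`` if no member joins both alleles in any
    assignment. Raises :class:`PhaseInconsistencyError` when nothing
    fits.
    """
    members = cohort.members(family_id)
    anchor = cohort.family_anchor(family_id)
    if anchor is None or len(members) < 2:
        return UNINFORMATIVE
    hom = carriership.hom_carriers(variant)
    obs = {}
    for m in members:
        s = cohort.subjects[m]
        a = s.is_monoallelic and s.anchor_variant == anchor
        obs[m] = (bool(a), carriership.is_present(variant, m), m in hom)

    order = _pedigree_order(cohort, members)
    phases = set()
    any_consistent = False

    def classify(assigned: dict):
        # The two-hit question is whether a trans copy exists in some
        # anchor carrier, so a trans copy anywhere (including the second
        # copy of a homozygous carrier) dominates the assignment label.
        has_trans = has_cis = False
        for (h1, h2) in assigned.values():
            if _A not in h1 | h2 or _V not in h1 | h2:
                continue
            anchor_hap, other_hap = (h1, h2) if _A in h1 else (h2, h1)
            has_trans = has_trans or _V in other_hap
            has_cis = has_cis or _V in anchor_hap
        if has_trans:
            phases.add(TRANS)
        elif has_cis:
            phases.add(CIS)

    def recurse(i: int, assigned: dict):
        nonlocal any_consistent
        if i == len(order):
            any_consistent = True
            classify(assigned)
            return
        m = order[i]
        s = cohort.subjects[m]
        a_pres, v_pres, v_hom = obs[m]
        father = s.father_id if s.father_id in assigned else None
        mother = s.mother_id if s.mother_id in assigned else None
        pat_opts = assigned[father] if father else _STATES
        mat_opts = assigned[mother] if mother else _STATES
        for h1 in pat_opts:
            for h2 in mat_opts:
                if _consistent(h1, h2, a_pres, v_pres, v_hom):
                    assigned[m] = (h1, h2)
                    recurse(i + 1, assigned)
                    del assigned[m]

    recurse(0, {})
    if not any_consistent:
        raise PhaseInconsistencyError(
            f"no haplotype assignment fits {variant} in family {family_id}")
    if not phases:
        return UNINFORMATIVE
    if phases == {TRANS}:
        return TRANS
    if phases == {CIS}:
        return CIS
    return AMBIGUOUS


# ---------------------------------------------------------------------------
# Cross-subject co-inheritance (population-level cis evidence)


def cross_subject_coinheritance(variant: str, cohort: Cohort,
                                carriership: CarriershipMatrix):
    """Detect likely co-inheritance of a variant with one shared anchor.

    True iff the variant's cohort-wide carrier set coincides exactly
    with the carrier set of one anchor (every variant carrier has that
    anchor and every carrier of that anchor has the variant) with at
    least two carriers; perfect co-occurrence across unrelated carriers
    suggests the variant rides on the anchor haplotype (linkage
    disequilibrium). Returns ``(verdict, details)``.
    """
    carriers = carriership.carriers(variant)
    details = {"variant_carriers": sorted(carriers)}
    if len(carriers) < 2:
        details["reason"] = "fewer than two carriers"
        return False, details
    anchors = {cohort.subjects[c].anchor_variant for c in carriers}
    if len(anchors) != 1 or None in anchors:
        details["reason"] = "carriers do not share a single anchor"
        return False, details
    anchor = anchors.pop()
    anchor_carriers = set(cohort.anchor_carriers(anchor))
    details["anchor"] = anchor
    details["anchor_carriers"] = sorted(anchor_carriers)
    if carriers == anchor_carriers:
        details["reason"] = "perfect co-occurrence with anchor carrier set"
        return True, details
    details["reason"] = ("imperfect co-occurrence: anchor carriers "
                         f"{sorted(anchor_carriers - carriers)} lack the variant")
    return False, details
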