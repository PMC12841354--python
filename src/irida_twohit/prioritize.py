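"""Two-branch decision tree for candidate non-coding modifier variants.

The model is a two-hit hypothesis: a pathogenic exonic anchor variant
(class >= 3) is the first hit, and a trans-inherited loss-of-function
non-coding variant may be the second. Variants seen inside families are
classified from segregation verdicts (familial branch); variants seen
in isolated symptomatic subjects are classified by cohort-wide
exclusivity (isolated branch). A rule-based 1-5 pathogenicity class is
then assigned from prevalence (MAF) and in-silico flags; class-3
variants on the retained exclusive tracks form the candidate list.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import pandas as pd

from .cohort import CarriershipMatrix, Cohort
from .hgvs import VariantDescriptor
from .segregation import (
    AMBIGUOUS, CIS, TRANS, UNINFORMATIVE,
    SegregationCall, call_segregation, cross_subject_coinheritance,
)
from .transcript import TranscriptModel, assign_region

# Figure-style categories
POTENTIALLY_PATHOGENIC = "potentially_pathogenic"
NON_PATHOGENIC = "non_pathogenic"
CIS_INHERITED = "cis_inherited"
UNCERTAIN = "uncertain_significance"
UNLIKELY_PATHOGENIC = "unlikely_pathogenic"
POSSIBLE_CONTRIBUTOR = "possible_contributor"
ASYMPTOMATIC_EXCLUSIVE = "asymptomatic_exclusive"
UBIQUITOUS = "ubiquitous"
EXCLUDED = "excluded_region"

TRACK_EXCLUSIVE = "exclusive_symptomatic"
TRACK_SHARED_WT = "shared_with_wt"


@dataclass
class PipelineConfig:
    benign_maf_threshold: float = 5.0  # percent; >= is class 1
    rare_maf_threshold: float = 1.0  # percent; candidate rarity gate
    strict_samples: bool = True
    excluded_regions: tuple = ()  # e.g. ("intron_6",) for allele-skew regions

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "excluded_regions" in d:
            d["excluded_regions"] = tuple(d["excluded_regions"])
        return cls(**d)


@dataclass
class ClassificationResult:
    variant: str
    branch: str  # familial | isolated | none
    category: str
    track: Optional[str] = None
    retained: bool = False
    path_class: Optional[int] = None
    rationale: list = field(default_factory=list)
    verdicts: dict = field(default_factory=dict)  # family -> segregation verdict

    def add(self, rule: str) -> None:
        self.rationale.append(rule)


class PipelineOrderingError(RuntimeError):
    pass


def _carrier_statuses(variant: str, cohort: Cohort, carriership: CarriershipMatrix):
    carriers = carriership.carriers(variant)
    by = {"symptomatic_monoallelic": set(), "asymptomatic_monoallelic": set(),
          "wild_type": set()}
    for c in carriers:
        by[cohort.subjects[c].status].add(c)
    return carriers, by


def classify_familial(variant: str, calls: list, cohort: Cohort,
                      carriership: CarriershipMatrix) -> ClassificationResult:
    """Familial-branch category from per-family segregation verdicts.

    Trans in a symptomatic subject, with no asymptomatic subject of any
    family carrying it in trans, retains the variant (exclusive track,
    or shared-with-WT when a wild-type subject also carries it). Trans
    in an asymptomatic subject of another family rules it out; perfect
    co-occurrence yields a cis verdict; carriership confined to
    asymptomatic subjects marks the protective-track output.
    """
    if calls is None:
        raise PipelineOrderingError(f"{variant}: segregation must run before "
                                    "familial classification")
    res = ClassificationResult(variant=variant, branch="familial",
                               category=UNCERTAIN)
    res.verdicts = {c.family_id: c.verdict for c in calls}
    carriers, by = _carrier_statuses(variant, cohort, carriership)

    def fam_carriers(call, status):
        return [m for (m, _a, v, _r) in call.evidence
                if v and cohort.subjects[m].status == status]

    trans_sympt, trans_asympt = [], []
    any_cis = False
    for c in calls:
        if c.verdict == TRANS:
            trans_sympt += fam_carriers(c, "symptomatic_monoallelic")
            trans_asympt += fam_carriers(c, "asymptomatic_monoallelic")
        elif c.verdict == CIS:
            any_cis = True
    for c in calls:
        res.add(f"family {c.family_id}: {c.verdict}")

    if trans_asympt and not by["symptomatic_monoallelic"]:
        res.category = ASYMPTOMATIC_EXCLUSIVE
        res.add(f"trans in asymptomatic {sorted(set(trans_asympt))}, no symptomatic "
                "carrier anywhere: exclusive to asymptomatic subjects")
    elif trans_asympt:
        res.category = NON_PATHOGENIC
        res.add(f"trans in asymptomatic subject(s) {sorted(set(trans_asympt))}: "
                "cannot explain the phenotype")
    elif trans_sympt:
        res.retained = True
        if by["wild_type"]:
            res.category = UNCERTAIN
            res.track = TRACK_SHARED_WT
            res.add(f"trans in symptomatic {sorted(set(trans_sympt))} but also carried "
                    f"by wild-type {sorted(by['wild_type'])}: uncertain significance")
        else:
            res.category = POTENTIALLY_PATHOGENIC
            res.track = TRACK_EXCLUSIVE
            res.add(f"trans in symptomatic {sorted(set(trans_sympt))}, never in any "
                    "asymptomatic subject: potentially explanatory")
    elif any_cis:
        res.category = CIS_INHERITED
        res.add("cis with the anchor in every informative family: unlikely to "
                "contribute to expression")
    else:
        res.category = UNCERTAIN
        res.add("no decisive segregation verdict in any family")
    return res


def classify_isolated(variant: str, cohort: Cohort,
                      carriership: CarriershipMatrix) -> ClassificationResult:
    """Isolated-branch category from cohort-wide exclusivity.

    Exclusivity is judged against asymptomatic monoallelic subjects (the
    source cohort's usage): a variant absent from all of them is retained, on
    the exclusive track or — when wild-type subjects carry it — on the
    shared-with-unrelated-WT track. Perfect co-occurrence with a shared
    anchor across carriers demotes an exclusive variant to cis
    (likely benign), though it stays on its funnel track.
    """
    res = ClassificationResult(variant=variant, branch="isolated",
                               category=UNCERTAIN)
    carriers, by = _carrier_statuses(variant, cohort, carriership)
    res.add(f"carriers: {sorted(carriers)}")
    if by["asymptomatic_monoallelic"]:
        res.category = UNLIKELY_PATHOGENIC
        res.add(f"also carried by asymptomatic {sorted(by['asymptomatic_monoallelic'])}: "
                "unlikely pathogenic")
        return res
    res.retained = True
    if by["wild_type"]:
        res.category = POSSIBLE_CONTRIBUTOR
        res.track = TRACK_SHARED_WT
        res.add(f"carried by unrelated wild-type {sorted(by['wild_type'])}: "
                "possible contributor, significance uncertain")
    else:
        res.category = POTENTIALLY_PATHOGENIC
        res.track = TRACK_EXCLUSIVE
        res.add("exclusive to symptomatic subjects cohort-wide")
        coinherited, details = cross_subject_coinheritance(variant, cohort, carriership)
        if coinherited:
            res.category = CIS_INHERITED
            res.add(f"perfect co-occurrence with anchor {details['anchor']} across "
                    f"carriers {details['variant_carriers']}: likely co-inherited "
                    "(cis), likely benign")
    return res


def assign_path_class(result: ClassificationResult, descriptor: VariantDescriptor,
                      config: PipelineConfig = PipelineConfig()) -> int:
    """Rule-based pathogenicity class (1-5) for a non-coding variant.

    Class 1: prevalent (MAF >= benign threshold) or ubiquitous.
    Class 3: retained on an exclusive (potentially pathogenic) track,
    rare (MAF < rarity gate; missing MAF counts as rare), and carrying
    an in-silico splice or regulatory flag. Everything else is class 2.
    Classes 4-5 describe input exonic anchors and are never produced
    for non-coding variants.
    """
    maf = descriptor.maf_percent
    if result.category == UBIQUITOUS:
        result.add("observed in all subjects: benign (class 1)")
        return 1
    if maf is not None and maf >= config.benign_maf_threshold:
        result.add(f"MAF {maf:g}% >= {config.benign_maf_threshold:g}%: benign (class 1)")
        return 1
    rare = maf is None or maf < config.rare_maf_threshold
    flagged = descriptor.splice_flag or descriptor.regulatory_flag
    on_candidate_track = (result.retained and result.track == TRACK_EXCLUSIVE
                          and result.category == POTENTIALLY_PATHOGENIC)
    if on_candidate_track and rare and flagged:
        effect = "splicing" if descriptor.splice_flag else "regulatory region"
        result.add(f"rare (MAF {'-' if maf is None else f'{maf:g}%'}), exclusive track, "
                   f"predicted {effect} effect: VUS (class 3)")
        return 3
    if not flagged:
        result.add("no predicted splice or regulatory effect: class 2")
    elif not rare:
        result.add(f"MAF {maf:g}% above rarity gate "
                   f"{config.rare_maf_threshold:g}%: class 2")
    else:
        result.add("not on an exclusive retained track: class 2")
    return 2


@dataclass
class FunnelCounts:
    total_variants: int = 0
    non_coding: int = 0
    within_families: int = 0
    trans_after_cis_exclusion: int = 0
    removed_by_unrelated_asymptomatic: int = 0
    familial_exclusive_symptomatic: int = 0
    familial_shared_with_wt: int = 0
    isolated_exclusive: int = 0
    isolated_shared_with_unrelated_wt: int = 0
    total_exclusive_symptomatic: int = 0
    candidates_class3: int = 0
    asymptomatic_exclusive: int = 0
    ubiquitous: int = 0
    excluded_by_region: int = 0

    @property
    def familial_retained(self) -> int:
        return self.familial_exclusive_symptomatic + self.familial_shared_with_wt

    @property
    def isolated_retained(self) -> int:
        return self.isolated_exclusive + self.isolated_shared_with_unrelated_wt

    def check(self) -> None:
        assert self.familial_retained == (self.trans_after_cis_exclusion
                                          - self.removed_by_unrelated_asymptomatic)
        assert self.total_exclusive_symptomatic == (self.familial_retained
                                                    + self.isolated_retained)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["familial_retained"] = self.familial_retained
        d["isolated_retained"] = self.isolated_retained
        return d


@dataclass
class PipelineResult:
    results: dict  # hgvs -> ClassificationResult (final, after branch merge)
    funnel: FunnelCounts
    candidates: list  # hgvs of class-3 candidates, transcript order
    segregation_calls: dict  # hgvs -> list[SegregationCall]
    annotations: dict  # hgvs -> VariantDescriptor (region set)

    def classification_frame(self) -> pd.DataFrame:
        rows = []
        for hgvs in sorted(self.results, key=lambda h: self.annotations[h].sort_key()):
            r = self.results[hgvs]
            d = self.annotations[hgvs]
            rows.append({
                "hgvs_c": hgvs, "rsid": d.rsid or "-", "region": d.region,
                "maf_percent": "-" if d.maf_percent is None else d.maf_percent,
                "branch": r.branch, "category": r.category,
                "track": r.track or "-", "retained": int(r.retained),
                "path_class": r.path_class,
                "rationale": " | ".join(r.rationale),
            })
        return pd.DataFrame(rows)

    def candidate_frame(self) -> pd.DataFrame:
        rows = []
        for hgvs in self.candidates:
            d = self.annotations[hgvs]
            r = self.results[hgvs]
            evidence = ("Family segregation" if r.branch == "familial"
                        else "Isolated subject")
            rows.append({
                "variant": hgvs, "rsid": d.rsid or "-",
                "maf_percent": "-" if d.maf_percent is None else d.maf_percent,
                "region": d.region, "evidence": evidence,
            })
        return pd.DataFrame(rows,
                            columns=["variant", "rsid", "maf_percent", "region",
                                     "evidence"])


def run_pipeline(cohort: Cohort, carriership: CarriershipMatrix,
                 annotations: dict, transcript: TranscriptModel,
                 config: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Run the full funnel: annotate, segregate, classify, count.

    ``annotations`` maps canonical HGVS to :class:`VariantDescriptor`
    carrying rsID, MAF and in-silico flags. Every carried variant gets
    exactly one final result; exclusions (configured regions) are
    explicit results, never silent drops. Deterministic and independent
    of input ordering.
    """
    annotated = {}
    for hgvs in carriership.variant_ids():
        base = annotations.get(hgvs, carriership.variants[hgvs])
        annotated[hgvs] = assign_region(base, transcript)

    all_subjects = set(cohort.subjects)
    multi_fams = cohort.multi_member_families()
    results: dict = {}
    seg_calls: dict = {}
    funnel = FunnelCounts(total_variants=len(annotated))
    funnel.non_coding = sum(1 for d in annotated.values()
                            if d.region is None or not str(d.region).startswith("exon"))

    trans_sympt_variants = set()
    removed_variants = set()

    for hgvs in carriership.variant_ids():
        d = annotated[hgvs]
        carriers, by = _carrier_statuses(hgvs, cohort, carriership)

        if d.region in config.excluded_regions:
            r = ClassificationResult(variant=hgvs, branch="none", category=EXCLUDED)
            r.add(f"region {d.region} excluded by configuration")
            funnel.excluded_by_region += 1
            results[hgvs] = r
            continue

        if carriers == all_subjects and len(all_subjects) > 1:
            r = ClassificationResult(variant=hgvs, branch="none", category=UBIQUITOUS)
            r.add("observed in all subjects")
            funnel.ubiquitous += 1
            r.path_class = assign_path_class(r, d, config)
            results[hgvs] = r
            continue

        fam_presence = any(not cohort.is_isolated(c) for c in carriers)
        iso_sympt_presence = any(cohort.is_isolated(c) and cohort.subjects[c].is_symptomatic
                                 for c in carriers)

        fam_res = None
        if fam_presence:
            funnel.within_families += 1
            calls = [call_segregation(hgvs, f, cohort, carriership)
                     for f in multi_fams
                     if any(m in carriers for m in cohort.members(f))]
            seg_calls[hgvs] = calls
            fam_res = classify_familial(hgvs, calls, cohort, carriership)
            if fam_res.category in (POTENTIALLY_PATHOGENIC, UNCERTAIN) and fam_res.retained:
                trans_sympt_variants.add(hgvs)
            elif fam_res.category == NON_PATHOGENIC:
                trans_sympt_variants.add(hgvs)
                removed_variants.add(hgvs)

        iso_res = None
        fam_decisive = fam_res is not None and (
            fam_res.retained or fam_res.category in (NON_PATHOGENIC,
                                                     ASYMPTOMATIC_EXCLUSIVE))
        if iso_sympt_presence and (not fam_decisive or fam_res.retained):
            iso_res = classify_isolated(hgvs, cohort, carriership)

        # Branch merge: a variant retained by the familial branch is
        # counted there (dual-branch variants stay in the familial
        # tally); when both branches produced a result, the more
        # conservative (lower-class) category wins, both rationales kept.
        final: ClassificationResult
        if fam_res is not None and fam_decisive:
            final = fam_res
            if iso_res is not None:
                fam_class = assign_path_class(fam_res, d, config)
                iso_class = assign_path_class(iso_res, d, config)
                if iso_class < fam_class:
                    final = iso_res
                    final.branch = "familial" if fam_res.retained else "isolated"
                final.rationale = fam_res.rationale + ["[isolated branch] " + x
                                                       for x in iso_res.rationale]
                final.path_class = min(fam_class, iso_class)
            final.verdicts = fam_res.verdicts
        elif iso_res is not None:
            final = iso_res
            if fam_res is not None:
                final.verdicts = fam_res.verdicts
                final.rationale = (["[familial branch] " + x for x in fam_res.rationale]
                                   + final.rationale)
        elif fam_res is not None:
            final = fam_res
        else:
            # carried only by non-symptomatic singletons: keep explicit
            final = ClassificationResult(variant=hgvs, branch="none",
                                         category=UNCERTAIN)
            final.add(f"carriers {sorted(carriers)} support no branch")
        if final.path_class is None:
            final.path_class = assign_path_class(final, d, config)
        results[hgvs] = final

    # Funnel bookkeeping from final results
    for hgvs, r in results.items():
        if r.category == ASYMPTOMATIC_EXCLUSIVE:
            funnel.asymptomatic_exclusive += 1
        if not r.retained:
            continue
        if r.branch == "familial":
            if r.track == TRACK_SHARED_WT:
                funnel.familial_shared_with_wt += 1
            else:
                funnel.familial_exclusive_symptomatic += 1
        else:
            if r.track == TRACK_SHARED_WT:
                funnel.isolated_shared_with_unrelated_wt += 1
            else:
                funnel.isolated_exclusive += 1
    funnel.trans_after_cis_exclusion = sum(
        1 for h in trans_sympt_variants
        if (results[h].retained and results[h].branch == "familial")
        or h in removed_variants)
    funnel.removed_by_unrelated_asymptomatic = len(removed_variants)
    funnel.total_exclusive_symptomatic = (funnel.familial_retained
                                          + funnel.isolated_retained)
    funnel.candidates_class3 = 0

    candidates = []
    for hgvs in sorted(results, key=lambda h: annotated[h].sort_key()):
        r = results[hgvs]
        if (r.retained and r.path_class == 3 and r.track == TRACK_EXCLUSIVE
                and r.category == POTENTIALLY_PATHOGENIC):
            candidates.append(hgvs)
    funnel.candidates_class3 = len(candidates)
    funnel.check()
    return PipelineResult(results=results, funnel=funnel, candidates=candidates,
                          segregation_calls=seg_calls, annotations=annotated)
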