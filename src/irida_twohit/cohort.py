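"""Subjects, families, phenotype status and variant carriership.

The cohort is read from a six-column PED file plus a subject-metadata
TSV (status, exonic anchor variant, anchor pathogenicity class).
Carriership is a variant x subject presence matrix, loadable from a
wide TSV or from a single-locus VCF (any non-reference genotype counts
as present; zygosity is kept only as a homozygosity flag because the
downstream segregation logic reasons about carriership, not dosage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .hgvs import VariantDescriptor, parse_hgvs_c

log = logging.getLogger(__name__)

STATUSES = ("symptomatic_monoallelic", "asymptomatic_monoallelic", "wild_type")
MONOALLELIC = ("symptomatic_monoallelic", "asymptomatic_monoallelic")


class CohortValidationError(ValueError):
    pass


@dataclass
class Subject:
    subject_id: str
    family_id: str
    sex: str = "0"  # PED code: 1 male, 2 female, 0 unknown
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    status: str = "wild_type"
    anchor_variant: Optional[str] = None  # HGVS of the exonic first hit
    anchor_class: Optional[int] = None  # pathogenicity class 3-5

    @property
    def is_monoallelic(self) -> bool:
        return self.status in MONOALLELIC

    @property
    def is_symptomatic(self) -> bool:
        return self.status == "symptomatic_monoallelic"


@dataclass
class Cohort:
    subjects: dict = field(default_factory=dict)  # subject_id -> Subject
    provenance: dict = field(default_factory=dict)  # free-form notes per subject/family

    def add(self, s: Subject) -> None:
        if s.subject_id in self.subjects:
            raise CohortValidationError(f"duplicate subject id {s.subject_id}")
        self.subjects[s.subject_id] = s

    # -- views -------------------------------------------------------
    @property
    def families(self) -> dict:
        fams: dict = {}
        for s in self.subjects.values():
            fams.setdefault(s.family_id, []).append(s.subject_id)
        return {f: sorted(ms) for f, ms in sorted(fams.items())}

    def members(self, family_id: str) -> list:
        return self.families.get(family_id, [])

    def multi_member_families(self) -> list:
        return [f for f, ms in self.families.items() if len(ms) >= 2]

    def is_isolated(self, subject_id: str) -> bool:
        return len(self.members(self.subjects[subject_id].family_id)) == 1

    def family_anchor(self, family_id: str) -> Optional[str]:
        anchors = {self.subjects[m].anchor_variant
                   for m in self.members(family_id)
                   if self.subjects[m].is_monoallelic}
        return sorted(anchors)[0] if anchors else None

    def by_status(self, status: str) -> list:
        return sorted(s.subject_id for s in self.subjects.values() if s.status == status)

    def anchor_carriers(self, anchor: str) -> list:
        return sorted(s.subject_id for s in self.subjects.values()
                      if s.is_monoallelic and s.anchor_variant == anchor)

    def census(self) -> dict:
        sym = self.by_status("symptomatic_monoallelic")
        return {
            "total": len(self.subjects),
            "symptomatic": len(sym),
            "symptomatic_familial": sum(not self.is_isolated(s) for s in sym),
            "symptomatic_isolated": sum(self.is_isolated(s) for s in sym),
            "asymptomatic": len(self.by_status("asymptomatic_monoallelic")),
            "wild_type": len(self.by_status("wild_type")),
            "families_multi": len(self.multi_member_families()),
        }

    # -- validation --------------------------------------------------
    def validate(self) -> None:
        errors = []
        for s in self.subjects.values():
            for pid, role in ((s.father_id, "father"), (s.mother_id, "mother")):
                if pid and pid not in self.subjects:
                    errors.append(f"{s.subject_id}: unknown {role} id {pid}")
                elif pid and self.subjects[pid].family_id != s.family_id:
                    errors.append(f"{s.subject_id}: {role} {pid} in another family")
            if s.status == "wild_type" and s.anchor_variant:
                errors.append(f"{s.subject_id}: wild_type subject carries anchor "
                              f"{s.anchor_variant}")
            if s.is_monoallelic and not s.anchor_variant:
                errors.append(f"{s.subject_id}: monoallelic status without anchor variant")
            if s.anchor_class is not None and not 3 <= s.anchor_class <= 5:
                errors.append(f"{s.subject_id}: anchor_class {s.anchor_class} not in 3..5")
        # Mendelian anchor check: a monoallelic child with both parents in
        # the cohort must share its anchor with at least one parent.
        for s in self.subjects.values():
            if not s.is_monoallelic:
                continue
            parents = [self.subjects[p] for p in (s.father_id, s.mother_id)
                       if p and p in self.subjects]
            if s.father_id and s.mother_id and len(parents) == 2:
                if not any(p.anchor_variant == s.anchor_variant for p in parents):
                    errors.append(f"{s.subject_id}: anchor {s.anchor_variant} carried "
                                  f"by neither parent")
        if errors:
            raise CohortValidationError("; ".join(errors))


def read_cohort(ped_path, metadata_path) -> Cohort:
    """Build a validated :class:`Cohort` from a PED file plus metadata TSV.

    The PED is the standard six-column dialect (family, individual,
    father, mother, sex, phenotype); the TSV adds ``status``,
    ``anchor_hgvs`` and ``anchor_class`` per subject. Subjects with PED
    family ``0`` (or absent) get a singleton pseudo-family so downstream
    operations are uniform.
    """
    cohort = Cohort()
    ped_path = Path(ped_path)
    if ped_path.stat().st_size == 0:
        return cohort
    ped = pd.read_csv(ped_path, sep="\t", header=None, dtype=str,
                      names=["family", "individual", "father", "mother", "sex", "phenotype"],
                      comment="#")
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"subject_id": str}).set_index("subject_id")

    for row in ped.itertuples(index=False):
        sid = str(row.individual)
        fam = str(row.family)
        if fam in ("0", ".", "", "nan"):
            fam = f"iso_{sid}"
        if sid not in meta.index:
            raise CohortValidationError(f"subject {sid} missing from metadata table")
        m = meta.loc[sid]
        anchor = m.get("anchor_hgvs")
        if pd.isna(anchor) or anchor in ("", "-"):
            anchor = None
        klass = m.get("anchor_class")
        klass = None if pd.isna(klass) else int(klass)
        status = str(m["status"])
        if status not in STATUSES:
            raise CohortValidationError(f"subject {sid}: unknown status {status!r}")
        cohort.add(Subject(
            subject_id=sid, family_id=fam, sex=str(row.sex),
            father_id=None if str(row.father) in ("0", "nan") else str(row.father),
            mother_id=None if str(row.mother) in ("0", "nan") else str(row.mother),
            status=status, anchor_variant=anchor, anchor_class=klass,
        ))
    cohort.validate()
    return cohort


@dataclass
class CarriershipMatrix:
    """Boolean variant x subject carriership (>= 1 alternate allele)."""

    variants: dict = field(default_factory=dict)  # canonical hgvs -> VariantDescriptor
    subject_ids: list = field(default_factory=list)
    _present: dict = field(default_factory=dict)  # hgvs -> set of subject ids
    _hom: dict = field(default_factory=dict)  # hgvs -> set of hom-alt subject ids
    missing_genotype_count: int = 0

    def add_variant(self, v: VariantDescriptor, carriers: Iterable[str],
                    hom: Iterable[str] = ()) -> None:
        """Register carriership; re-adding a variant unions carriers (dedup)."""
        key = v.serialize()
        if key not in self.variants:
            self.variants[key] = v
        self._present.setdefault(key, set()).update(carriers)
        self._hom.setdefault(key, set()).update(hom)

    def carriers(self, hgvs: str) -> set:
        return set(self._present.get(hgvs, set()))

    def hom_carriers(self, hgvs: str) -> set:
        return set(self._hom.get(hgvs, set()))

    def is_present(self, hgvs: str, subject_id: str) -> bool:
        return subject_id in self._present.get(hgvs, set())

    def variant_ids(self) -> list:
        return sorted(self.variants, key=lambda h: self.variants[h].sort_key())

    def to_frame(self) -> pd.DataFrame:
        ids = self.variant_ids()
        return pd.DataFrame(
            [[int(s in self._present[v]) for s in self.subject_ids] for v in ids],
            index=pd.Index(ids, name="hgvs_c"), columns=self.subject_ids,
        )


def read_carriership(path, cohort: Cohort, *, strict: bool = True) -> CarriershipMatrix:
    """Load carriership from a wide TSV matrix or a single-locus VCF.

    TSV layout: first column ``hgvs_c``, one 0/1 column per subject.
    VCF: any non-reference genotype call is present; missing genotypes
    count as absent (conservative for trans evidence, which needs an
    observed absence) and are tallied. Unknown samples are an error in
    strict mode, a logged skip otherwise.
    """
    path = Path(path)
    if path.suffix in (".vcf", ".bcf", ".gz"):
        return _read_vcf(path, cohort, strict=strict)
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("hgvs_c")
    matrix = CarriershipMatrix(subject_ids=sorted(cohort.subjects))
    unknown = [c for c in df.columns if c not in cohort.subjects]
    if unknown:
        if strict:
            raise CohortValidationError(f"samples not in cohort: {unknown}")
        log.warning("skipping %d samples not in cohort: %s", len(unknown), unknown)
        df = df.drop(columns=unknown)
    for hgvs, row in df.iterrows():
        v = parse_hgvs_c(hgvs)
        carriers = {s for s, val in row.items() if str(val) not in ("0", "nan", "")}
        matrix.add_variant(v, carriers)
    return matrix


def _read_vcf(path, cohort: Cohort, *, strict: bool) -> CarriershipMatrix:
    import pysam

    matrix = CarriershipMatrix(subject_ids=sorted(cohort.subjects))
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        unknown = [s for s in samples if s not in cohort.subjects]
        if unknown and strict:
            raise CohortValidationError(f"VCF samples not in cohort: {unknown}")
        keep = [s for s in samples if s in cohort.subjects]
        if unknown:
            log.warning("skipping %d VCF samples not in cohort: %s", len(unknown), unknown)
        for rec in vcf:
            hgvs = rec.id if rec.id and rec.id.startswith("c.") else rec.info.get("HGVSC")
            if hgvs is None:
                raise CohortValidationError(
                    f"VCF record at {rec.chrom}:{rec.pos} lacks an HGVS c. id")
            v = parse_hgvs_c(str(hgvs))
            carriers, hom = set(), set()
            for s in keep:
                gt = rec.samples[s].get("GT") or ()
                alleles = [a for a in gt if a is not None]
                if len(alleles) < len(gt) or not alleles:
                    matrix.missing_genotype_count += 1
                if any(a > 0 for a in alleles):
                    carriers.add(s)
                    if len(alleles) >= 2 and all(a > 0 for a in alleles):
                        hom.add(s)
            matrix.add_variant(v, carriers, hom)
    if matrix.missing_genotype_count:
        log.warning("%d missing genotype calls treated as absent",
                    matrix.missing_genotype_count)
    return matrix


# ---------------------------------------------------------------------------
# IRIDA phenotype criteria


@dataclass
class LabPanel:
    """Laboratory work-up of one subject, as used by the phenotype criteria.

    TSAT is transferrin saturation in percent. The TSAT/hepcidin-ratio
    percentile, when provided, is supportive evidence only and never
    gates the verdict.
    """

    tsat_percent: float
    on_iron_supplementation: bool
    microcytic_anemia: bool
    inflammation_present: bool
    oral_iron_refractory: bool
    tsat_hepcidin_ratio_percentile: Optional[float] = None

    def __post_init__(self):
        if not 0 <= self.tsat_percent <= 100:
            raise ValueError(f"tsat_percent out of [0, 100]: {self.tsat_percent}")
        p = self.tsat_hepcidin_ratio_percentile
        if p is not None and not 0 <= p <= 100:
            raise ValueError(f"ratio percentile out of [0, 100]: {p}")


def meets_irida_phenotype(lab: LabPanel):
    """IRIDA phenotype verdict: microcytic anemia, TSAT < 10% (or < 15%
    under iron supplementation), no inflammation, and refractoriness to
    oral iron. Returns ``(verdict, trail)`` where the trail lists each
    criterion with its outcome. Pure function of the panel.
    """
    trail = []
    tsat_cut = 15.0 if lab.on_iron_supplementation else 10.0
    low_iron = lab.tsat_percent < tsat_cut
    trail.append(("microcytic_anemia", lab.microcytic_anemia))
    trail.append((f"tsat {lab.tsat_percent:g}% < {tsat_cut:g}%"
                  f"{' (on supplementation)' if lab.on_iron_supplementation else ''}",
                  low_iron))
    trail.append(("no_inflammation", not lab.inflammation_present))
    trail.append(("oral_iron_refractory", lab.oral_iron_refractory))
    verdict = (lab.microcytic_anemia and low_iron
               and not lab.inflammation_present and lab.oral_iron_refractory)
    if lab.tsat_hepcidin_ratio_percentile is not None:
        trail.append((f"supportive: TSAT/hepcidin ratio percentile "
                      f"{lab.tsat_hepcidin_ratio_percentile:g} <= 2.5",
                      lab.tsat_hepcidin_ratio_percentile <= 2.5))
    return verdict, trail
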