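"""Synthetic pedigrees with phased haplotypes under a two-hit model.

Families and isolated subjects are generated with known phase so every
pipeline stage can be validated against ground truth. Each family is
ascertained the way the real cohort was: a symptomatic proband plus
anchor-side relatives (the anchor-transmitting parent and siblings);
the second, unsequenced parent contributes gametes but is not emitted.
The anchor enters each family on exactly one founder haplotype, the
planted second hit (one distinct rare non-coding variant per family,
flagged as a predicted splice effect) arrives — when present — on a
haplotype of the unsequenced parent and is therefore always in trans
with the anchor. Background variants are drawn per haplotype from
their configured minor allele frequencies. Phenotype follows the
two-hit penetrance model: P(symptomatic | anchor + trans hit) =
``penetrance``, P(symptomatic | anchor only) = ``phenocopy_rate``;
subjects without the anchor are labelled wild type.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .cohort import CarriershipMatrix, Cohort, Subject
from .hgvs import parse_hgvs_c
from .prioritize import PipelineResult
from .segregation import CIS, TRANS
from .transcript import TranscriptModel, build_fixture_transcript

ANCHOR_HGVS = "c.497delT"  # exonic first hit used for all simulated subjects


@dataclass
class SimConfig:
    """Study-condition parameters for the generator.

    Defaults mirror the real cohort's shape: six families, nine
    isolated symptomatic subjects, small families. ``second_hit_rate``
    is the probability that a proband's genome carries a planted trans
    non-coding hit; penetrance and phenocopy rate parameterize
    P(phenotype | genotype).
    """

    n_families: int = 6
    members_per_family: int = 3  # proband + anchor parent + (m-2) siblings
    n_isolated: int = 9
    anchor_maf_percent: float = 0.05
    background_variant_count: int = 40
    background_maf_min_percent: float = 0.05
    background_maf_max_percent: float = 25.0
    background_flag_rate: float = 0.0  # fraction of background variants flagged
    second_hit_rate: float = 0.5
    planted_hit_maf_percent: float = 0.1
    penetrance: float = 1.0
    phenocopy_rate: float = 0.0
    genotype_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("second_hit_rate", "penetrance", "phenocopy_rate",
                     "genotype_missing_rate", "background_flag_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.n_families + self.n_isolated == 0:
            raise ValueError("degenerate config: no subjects to simulate")
        if self.n_families and self.members_per_family < 2:
            raise ValueError("families need at least 2 emitted members")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class GroundTruth:
    """Phased truth: haplotypes, per-subject phase vs anchor, variant roles."""

    haplotypes: dict = field(default_factory=dict)  # sid -> (set, set) of hgvs
    roles: dict = field(default_factory=dict)  # hgvs -> anchor|planted_trans_hit|background
    planted_hits: dict = field(default_factory=dict)  # hgvs -> family_id / iso sid

    def phase(self, hgvs: str, subject_id: str):
        """cis/trans/both of a variant vs the anchor within one subject."""
        h1, h2 = self.haplotypes[subject_id]
        has = (hgvs in h1, hgvs in h2)
        anc = (ANCHOR_HGVS in h1, ANCHOR_HGVS in h2)
        if not any(has) or not any(anc):
            return None
        if all(has):
            return "both"
        same = (has[0] and anc[0]) or (has[1] and anc[1])
        return CIS if same else TRANS

    def family_truth_phase(self, hgvs: str, members: list):
        phases = {p for p in (self.phase(hgvs, m) for m in members) if p}
        if not phases:
            return None
        if phases == {CIS}:
            return CIS
        if phases == {TRANS}:
            return TRANS
        return "mixed"

    def to_json(self) -> str:
        return json.dumps({
            "haplotypes": {s: [sorted(h1), sorted(h2)]
                           for s, (h1, h2) in sorted(self.haplotypes.items())},
            "roles": dict(sorted(self.roles.items())),
            "planted_hits": dict(sorted(self.planted_hits.items())),
        }, sort_keys=True, indent=1)


def _intronic_positions(t: TranscriptModel, n: int, rng) -> list:
    """Distinct intronic/UTR HGVS names across the transcript span."""
    names = []
    seen = set()
    bases = "ACGT"
    while len(names) < n:
        k = int(rng.integers(0, len(t.exon_ends_c)))
        end = t.exon_ends_c[k]
        off = int(rng.integers(1, 900))
        ref, alt = rng.choice(list(bases), size=2, replace=False)
        hgvs = f"c.{end}+{off}{ref}>{alt}"
        if hgvs not in seen and hgvs != ANCHOR_HGVS:
            seen.add(hgvs)
            names.append(hgvs)
    return names


@dataclass
class SimOutput:
    cohort: Cohort
    carriership: CarriershipMatrix
    annotations: dict
    truth: GroundTruth
    config: SimConfig


def simulate_cohort(config: SimConfig) -> SimOutput:
    """Generate (Cohort, CarriershipMatrix, annotations, GroundTruth).

    One master seed governs everything; each family and each isolated
    subject draws from its own deterministic substream, so adding a
    family never perturbs earlier families.
    """
    # Stable spawn keys: unit i always draws from the same substream, so
    # adding families or isolated subjects never perturbs earlier ones.
    n_units = config.n_families + config.n_isolated

    def stream(key: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(key,)))

    names_rng = stream(1_000_000)
    miss_rng = stream(1_000_001)
    maf_rng = stream(1_000_002)

    transcript = build_fixture_transcript()
    n_bg = config.background_variant_count
    # Names are drawn sequentially, so the background panel and the hit
    # name of unit i do not depend on how many units follow.
    bg_names = _intronic_positions(transcript, n_bg + n_units, names_rng)
    hit_names = bg_names[n_bg:]
    bg_names = bg_names[:n_bg]
    bg_maf = np.exp(maf_rng.uniform(
        np.log(config.background_maf_min_percent),
        np.log(config.background_maf_max_percent), size=n_bg))
    bg_flagged = maf_rng.random(n_bg) < config.background_flag_rate

    truth = GroundTruth()
    truth.roles[ANCHOR_HGVS] = "anchor"
    for name in bg_names:
        truth.roles[name] = "background"

    cohort = Cohort()
    haplos: dict = {}

    def draw_background(rng):
        return {bg_names[i] for i in range(n_bg)
                if rng.random() < bg_maf[i] / 100.0}

    def assign_status(sid, fam, rng, h1, h2, mother=None):
        carries_anchor = ANCHOR_HGVS in h1 or ANCHOR_HGVS in h2
        hit = truth.planted_hits
        has_trans_hit = any(
            (v in h1 and ANCHOR_HGVS not in h1 and ANCHOR_HGVS in h2)
            or (v in h2 and ANCHOR_HGVS not in h2 and ANCHOR_HGVS in h1)
            for v in hit)
        if not carries_anchor:
            status = "wild_type"
        else:
            p = config.penetrance if has_trans_hit else config.phenocopy_rate
            status = ("symptomatic_monoallelic" if rng.random() < p
                      else "asymptomatic_monoallelic")
        cohort.add(Subject(
            subject_id=sid, family_id=fam, sex="0", mother_id=mother,
            status=status,
            anchor_variant=ANCHOR_HGVS if carries_anchor else None,
            anchor_class=5 if carries_anchor else None))
        haplos[sid] = (h1, h2)

    for fi in range(config.n_families):
        rng = stream(fi)
        fam = f"SF{fi + 1}"
        hit_name = hit_names[fi]
        planted = rng.random() < config.second_hit_rate
        if planted:
            truth.roles[hit_name] = "planted_trans_hit"
            truth.planted_hits[hit_name] = fam

        # Anchor-transmitting parent (emitted): anchor on haplotype 1.
        p1_h1 = draw_background(rng) | {ANCHOR_HGVS}
        p1_h2 = draw_background(rng)
        # Unsequenced other parent: contributes gametes only.
        p2_h1 = draw_background(rng) | ({hit_name} if planted else set())
        p2_h2 = draw_background(rng)
        parent_id = f"{fam}_P"
        assign_status(parent_id, fam, rng, frozenset(p1_h1), frozenset(p1_h2))

        # Proband inherits the anchor haplotype and (if planted) the hit.
        assign_status(f"{fam}_C1", fam, rng, frozenset(p1_h1), frozenset(p2_h1),
                      mother=parent_id)
        for ci in range(2, config.members_per_family):
            h_mat = p1_h1 if rng.random() < 0.5 else p1_h2
            h_pat = p2_h1 if rng.random() < 0.5 else p2_h2
            assign_status(f"{fam}_C{ci}", fam, rng, frozenset(h_mat),
                          frozenset(h_pat), mother=parent_id)

    for ii in range(config.n_isolated):
        rng = stream(config.n_families + ii)
        sid = f"SI{ii + 1}"
        hit_name = hit_names[config.n_families + ii]
        planted = rng.random() < config.second_hit_rate
        if planted:
            truth.roles[hit_name] = "planted_trans_hit"
            truth.planted_hits[hit_name] = sid
        h1 = draw_background(rng) | {ANCHOR_HGVS}
        h2 = draw_background(rng) | ({hit_name} if planted else set())
        assign_status(sid, f"iso_{sid}", rng, frozenset(h1), frozenset(h2))

    cohort.validate()
    for sid, (h1, h2) in haplos.items():
        truth.haplotypes[sid] = (set(h1), set(h2))

    # Carriership matrix from haplotypes, with optional missingness.
    matrix = CarriershipMatrix(subject_ids=sorted(cohort.subjects))
    annotations = {}
    all_names = bg_names + [h for h in truth.planted_hits]
    for i, name in enumerate(bg_names):
        annotations[name] = parse_hgvs_c(name).with_annotation(
            rsid=f"sim_bg{i}", maf_percent=round(float(bg_maf[i]), 4),
            splice_flag=bool(bg_flagged[i]))
    for name in truth.planted_hits:
        annotations[name] = parse_hgvs_c(name).with_annotation(
            rsid="sim_hit", maf_percent=config.planted_hit_maf_percent,
            splice_flag=True)
    for name in sorted(all_names):
        carriers, hom = set(), set()
        for sid, (h1, h2) in truth.haplotypes.items():
            present = name in h1 or name in h2
            if present and miss_rng.random() < config.genotype_missing_rate:
                matrix.missing_genotype_count += 1
                continue
            if present:
                carriers.add(sid)
                if name in h1 and name in h2:
                    hom.add(sid)
        if carriers:
            matrix.add_variant(annotations[name], carriers, hom)
    return SimOutput(cohort=cohort, carriership=matrix, annotations=annotations,
                     truth=truth, config=config)


# ---------------------------------------------------------------------------
# File emission


def write_sim_outputs(sim: SimOutput, outdir) -> dict:
    """Emit VCF + PED + metadata TSV + annotation TSV + truth JSON."""
    import pandas as pd
    import pysam

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / n for k, n in [
        ("vcf", "cohort.vcf"), ("ped", "cohort.ped"), ("metadata", "subjects.tsv"),
        ("annotations", "annotations.tsv"), ("truth", "truth.json"),
        ("config", "sim_config.yaml")]}

    cohort, matrix = sim.cohort, sim.carriership
    with open(paths["ped"], "w") as fh:
        for sid in sorted(cohort.subjects):
            s = cohort.subjects[sid]
            fam = "0" if s.family_id.startswith("iso_") else s.family_id
            fh.write("\t".join([fam, sid, s.father_id or "0", s.mother_id or "0",
                                s.sex, "2" if s.is_symptomatic else "1"]) + "\n")
    pd.DataFrame([{
        "subject_id": sid, "status": s.status, "anchor_hgvs": s.anchor_variant or "-",
        "anchor_class": s.anchor_class or ""}
        for sid, s in sorted(cohort.subjects.items())
    ]).to_csv(paths["metadata"], sep="\t", index=False)

    pd.DataFrame([{
        "hgvs_c": h, "rsid": v.rsid or "-",
        "maf_percent": "-" if v.maf_percent is None else v.maf_percent,
        "splice_flag": int(v.splice_flag), "regulatory_flag": int(v.regulatory_flag)}
        for h, v in sorted(sim.annotations.items())
    ]).to_csv(paths["annotations"], sep="\t", index=False)

    header = pysam.VariantHeader()
    header.add_line("##source=irida_twohit.simulate")
    header.contigs.add("TMPRSS6_locus", length=100000)
    header.add_line('##INFO=<ID=HGVSC,Number=1,Type=String,Description='
                    '"HGVS coding-coordinate name">')
    header.formats.add("GT", 1, "String", "Genotype")
    samples = sorted(cohort.subjects)
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(paths["vcf"]), "w", header=header) as vcf:
        for pos0, hgvs in enumerate(matrix.variant_ids()):
            rec = vcf.new_record(contig="TMPRSS6_locus", start=pos0 + 100,
                                 alleles=("A", "T"), id=hgvs)
            rec.info["HGVSC"] = hgvs
            carriers = matrix.carriers(hgvs)
            hom = matrix.hom_carriers(hgvs)
            for s in samples:
                rec.samples[s]["GT"] = ((1, 1) if s in hom
                                        else (0, 1) if s in carriers else (0, 0))
            vcf.write(rec)
    paths["truth"].write_text(sim.truth.to_json())
    paths["config"].write_text(yaml.safe_dump(asdict(sim.config), sort_keys=True))
    return paths


# ---------------------------------------------------------------------------
# Recovery scoring


def score_recovery(result: PipelineResult, sim: SimOutput) -> dict:
    """Compare pipeline output against simulated ground truth.

    A planted hit is *recoverable* when the decision rules can possibly
    retain it: its family provides trans evidence (an anchor-carrying
    member lacking it — always true for isolated subjects, where
    exclusivity substitutes for segregation) and no asymptomatic or
    wild-type subject carries it. Sensitivity is candidates recovered
    over recoverable hits; phase accuracy is the fraction of decisive
    engine verdicts that match the truth phase.
    """
    cohort, matrix, truth = sim.cohort, sim.carriership, sim.truth
    recoverable, recovered = [], []
    for hgvs, origin in truth.planted_hits.items():
        carriers = matrix.carriers(hgvs)
        sympt = [c for c in carriers if cohort.subjects[c].is_symptomatic]
        bad = [c for c in carriers if not cohort.subjects[c].is_symptomatic]
        if not sympt or bad:
            continue
        if origin in cohort.families:  # familial hit: needs trans evidence
            members = cohort.members(origin)
            ev = [m for m in members
                  if cohort.subjects[m].is_monoallelic
                  and not matrix.is_present(hgvs, m)]
            if not ev:
                continue
        recoverable.append(hgvs)
        if hgvs in result.candidates:
            recovered.append(hgvs)

    false_candidates = [h for h in result.candidates if h not in truth.planted_hits]
    asympt_carried_candidates = [
        h for h in result.candidates
        if any(cohort.subjects[c].status == "asymptomatic_monoallelic"
               for c in matrix.carriers(h))]

    decisive, correct = 0, 0
    for hgvs, calls in result.segregation_calls.items():
        for call in calls:
            if call.verdict not in (TRANS, CIS):
                continue
            t = truth.family_truth_phase(hgvs, cohort.members(call.family_id))
            if t in (TRANS, CIS):
                decisive += 1
                correct += int(t == call.verdict)
    return {
        "planted_hits": len(truth.planted_hits),
        "recoverable": len(recoverable),
        "recovered": len(recovered),
        "sensitivity": (len(recovered) / len(recoverable)) if recoverable else None,
        "false_positive_count": len(false_candidates),
        "asymptomatic_carried_candidates": len(asympt_carried_candidates),
        "phase_decisive": decisive,
        "phase_accuracy": (correct / decisive) if decisive else None,
    }
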