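"""The packaged study cohort: 27 subjects, 38 annotated non-coding variants.

Encodes the published monoallelic-IRIDA cohort — six families plus nine
isolated symptomatic subjects, each carrying one exonic TMPRSS6 anchor
variant — together with per-variant carriership, gnomAD-style MAFs and
in-silico splice/regulatory flags, exactly as printed in the source
tables. Every record carries a ``provenance`` string naming the table
or narrative section it was transcribed from, so downstream checks are
auditable. Pedigree links beyond the two stated parent-child pairs
(mother 8 -> daughter 24; mother 15 -> daughter 1) are deliberately
absent: the remaining members are related-within-family with unstated
topology. Unnamed relatives required by the published census are
assigned otherwise-unused subject ids (16, 17, 22, 25) and flagged as
such in their provenance notes.

Two printed region labels conflict with the exon layout implied by the
variant names themselves; these are kept and surfaced through
:func:`region_label_conflicts`, never silently resolved.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .cohort import CarriershipMatrix, Cohort, Subject
from .hgvs import parse_hgvs_c
from .transcript import UPSTREAM_REGIONS, build_fixture_transcript

# Exonic anchor variants (first hits). Pathogenicity classes are not
# printed per anchor; null alleles get class 5, the near-splice change
# class 4, missense changes class 3 (only "class >= 3" is load-bearing).
ANCHOR_CLASSES = {
    "c.497delT": 5,
    "del_prom_exon1-3": 5,
    "c.863+1G>T": 5,
    "c.431+5G>T": 4,
    "c.1654G>A": 3,
    "c.1346G>A": 3,
    "c.2105G>A": 3,
    "c.1805G>C": 3,
    "c.1714G>A": 3,
    "c.1336C>T": 3,
}

# (subject_id, family_id, sex, father, mother, status, anchor, provenance)
_S, _A, _W = "symptomatic_monoallelic", "asymptomatic_monoallelic", "wild_type"
_SUBJECTS = [
    # Family 1 — anchor c.2105G>A (printed c.2105G>T in two other tables)
    ("1", "F1", "2", None, "15", _S, "c.2105G>A", "tables: carrier rows for ID 1"),
    ("15", "F1", "2", None, None, _A, "c.2105G>A",
     "asymptomatic mother of ID 1 (narrative); family labelled c.2105G>T elsewhere"),
    ("28", "F1", "0", None, None, _W, None, "wild-type relative of ID 1 (tables)"),
    # Family 2 — anchor: promoter-exon1-3 deletion
    ("2", "F2", "0", None, None, _S, "del_prom_exon1-3", "table: row for ID 2"),
    ("16", "F2", "0", None, None, _A, "del_prom_exon1-3",
     "unnamed asymptomatic relative required by the census"),
    ("17", "F2", "0", None, None, _A, "del_prom_exon1-3",
     "unnamed asymptomatic relative required by the census"),
    # Family 3 — anchor c.1654G>A
    ("20", "F3", "0", None, None, _S, "c.1654G>A", "tables: carrier rows for ID 20"),
    ("21", "F3", "0", None, None, _A, "c.1654G>A",
     "asymptomatic carrier of the protective-track variants"),
    ("22", "F3", "0", None, None, _A, "c.1654G>A",
     "unnamed asymptomatic relative required by the census"),
    ("25", "F3", "0", None, None, _W, None,
     "unnamed wild-type relative required by the census"),
    # Family 4 — anchor c.1346G>A
    ("7", "F4", "0", None, None, _S, "c.1346G>A", "tables: carrier rows for ID 7"),
    ("23", "F4", "0", None, None, _A, "c.1346G>A", "asymptomatic member of Family 4"),
    ("29", "F4", "0", None, None, _W, None, "wild-type relative (tables)"),
    ("30", "F4", "0", None, None, _W, None, "wild-type co-carrier with ID 23"),
    # Family 5 — anchor c.497delT; stated mother-daughter pair
    ("8", "F5", "2", None, None, _S, "c.497delT", "symptomatic mother (narrative)"),
    ("24", "F5", "2", None, "8", _S, "c.497delT", "symptomatic daughter (narrative)"),
    # Family 6 — anchor c.863+1G>T
    ("10", "F6", "0", None, None, _S, "c.863+1G>T", "table: carrier row for ID 10"),
    ("26", "F6", "0", None, None, _A, "c.863+1G>T",
     "asymptomatic relative (mentioned as asymptomatic in the exome narrative)"),
    # Isolated symptomatic subjects
    ("3", "iso_3", "0", None, None, _S, "c.1336C>T",
     "isolated; anchor printed c.1336C>T thrice, c.1714G>A once (conflict noted)"),
    ("4", "iso_4", "0", None, None, _S, "c.1714G>A", "isolated (tables)"),
    ("5", "iso_5", "0", None, None, _S, "c.497delT", "isolated (tables)"),
    ("6", "iso_6", "0", None, None, _S, "c.1654G>A",
     "isolated; anchor not printed, assigned a recurrent cohort anchor"),
    ("9", "iso_9", "0", None, None, _S, "c.497delT", "isolated (tables)"),
    ("11", "iso_11", "0", None, None, _S, "c.497delT", "isolated (tables)"),
    ("12", "iso_12", "0", None, None, _S, "c.1805G>C", "isolated (tables)"),
    ("14", "iso_14", "0", None, None, _S, "c.431+5G>T", "isolated (tables)"),
    ("31", "iso_31", "0", None, None, _S, "c.431+5G>T", "isolated (tables)"),
]

# Variant annotation + carriership, one row per printed table row:
# (hgvs, rsid, maf_percent, printed_region, splice, regulatory, carriers, provenance)
UPSTREAM = "5'UTR/PR"
_VARIANTS = [
    # --- trans-inherited within families, exclusive to symptomatic subjects
    ("c.-7504C>T", "rs115067778", 3.45, UPSTREAM, False, False, ["20"],
     "familial table, exclusive section"),
    ("c.-7293C>T", "rs74839029", 3.62, UPSTREAM, False, False, ["20"],
     "familial table, exclusive section"),
    ("c.-5224G>A", "rs59744498", 3.37, UPSTREAM, False, False, ["20"],
     "familial table, exclusive section"),
    ("c.-3094C>T", "rs77087103", 2.25, UPSTREAM, False, False, ["20"],
     "familial table, exclusive section"),
    ("c.230-938_230-937del", "rs146953827", 0.92, "intron_2", True, False, ["2"],
     "familial table; candidate table: predicted splice effect"),
    ("c.229+945C>T", "rs80140288", 0.53, "intron_2", True, False, ["9", "24"],
     "familial table (* also in isolated ID 9); candidate table: splice effect"),
    ("c.658+1123_658+1135delinsC", None, None, "intron_6", False, False, ["3", "24"],
     "familial table (** also in isolated ID 3); MAF not referenced"),
    ("c.1000+517C>T", "rs57746379", 2.09, "intron_8", False, False, ["20"],
     "familial table, exclusive section"),
    ("c.1223+1526C>T", "rs539552983", 0.016, "intron_10", False, False, ["8"],
     "familial table, exclusive section"),
    ("c.1868+368G>A", "rs148550682", 1.46, "intron_15", False, False, ["10"],
     "familial table, exclusive section"),
    # --- trans-inherited within families, also in related wild-type subjects
    ("c.-7607_-7606dup", "rs71324841", 39.86, UPSTREAM, False, False,
     ["3", "7", "29", "8", "20"],
     "familial table, shared-with-WT section; prevalent-variant narrative"),
    ("c.230-1353_230-1329dup", "rs140612996", 18.15, "intron_2", False, False,
     ["7", "29"], "familial table, shared-with-WT section"),
    ("c.363+543C>G", "rs13058647", 0.0067, "intron_3", False, False, ["7", "29"],
     "familial table, shared-with-WT section"),
    ("c.2278-31G>A", "rs41283231", 0.16, "intron_17", False, False, ["1", "28"],
     "familial table, shared-with-WT section"),
    # --- isolated branch, exclusive to symptomatic subjects
    ("c.-7609_-7606dup", "rs71324841", 13.82, UPSTREAM, False, False, ["14"],
     "isolated table, exclusive section"),
    ("c.-7001G>A", "rs78987624", 0.15, UPSTREAM, False, True, ["12"],
     "isolated table; candidate table: promoter region (EPD)"),
    ("c.-5823C>T", "rs190894261", 0.16, UPSTREAM, False, False, ["14", "31"],
     "isolated table; co-inheritance narrative: no predicted splice effect"),
    ("c.*503C>G", "rs117575523", 0.057, "3UTR", True, False, ["3"],
     "isolated table; candidate table: predicted splice effect, 3'UTR"),
    ("c.229+1413A>G", "rs228908", 7.95, "intron_2", False, False, ["12"],
     "isolated table, exclusive section"),
    ("c.363+149G>A", "rs572610055", 0.10, "intron_3", False, False,
     ["5", "8", "9", "11", "24"],
     "isolated table; co-inheritance narrative: likely benign, rides with c.497delT"),
    ("c.658+1019T>C", "rs73160067", 1.08, "intron_6", False, False, ["4"],
     "isolated table, exclusive section"),
    ("c.658+1439G>A", None, None, "intron_6", False, False, ["3"],
     "isolated table, exclusive section; MAF not referenced"),
    ("c.1223+3059C>T", "rs147597581", 0.089, "intron_10", False, False,
     ["5", "8", "9", "11", "24", "31"],
     "isolated table; co-inheritance narrative (also in ID 31, anchor c.431+5G>T)"),
    ("c.1223+3418C>T", "rs566491190", 0.0032, "intron_10", False, False, ["14"],
     "isolated table, exclusive section"),
    ("c.1582+762_1582+765dupCATC", "rs558830761", 1.05, "intron_13", False, False,
     ["11"], "isolated table, exclusive section"),
    # --- isolated branch, shared with unrelated wild-type subjects
    ("c.-4578T>G", "rs228913", 19.11, UPSTREAM, False, False,
     ["12", "14", "31", "29"], "isolated table, shared-with-unrelated-WT section"),
    ("c.-3586A>G", "rs1883276", 19.30, UPSTREAM, False, False,
     ["12", "14", "31", "29"], "isolated table, shared-with-unrelated-WT section"),
    ("c.-1064T>C", "rs228909", 21.68, UPSTREAM, False, False,
     ["12", "14", "31", "29"], "isolated table, shared-with-unrelated-WT section"),
    ("c.229+210G>A", "rs5995380", 20.62, "intron_2", False, False,
     ["12", "14", "31", "29"], "isolated table, shared-with-unrelated-WT section"),
    ("c.363+409G>C", "rs867039861", 0.25, "intron_3", False, False, ["4", "29"],
     "isolated table, shared-with-unrelated-WT section"),
    ("c.658+1166_658+1169delTATC", "rs746732095", 7.72, "intron_6", False, False,
     ["4", "28"], "isolated table, shared-with-unrelated-WT section"),
    # --- trans-inherited, exclusive to asymptomatic subjects
    ("c.230-1580C>T", "rs543987633", 0.064, "intron_2", False, False, ["23", "30"],
     "asymptomatic-exclusive table"),
    ("c.363+750C>T", None, 12.32, "intron_3", False, False, ["21"],
     "asymptomatic-exclusive table; no rsID printed"),
    ("c.431+238G>A", "rs75746329", 1.12, "intron_4", False, False, ["21"],
     "asymptomatic-exclusive table"),
    ("c.658+1123A>C", None, None, "intron_6", False, False, ["21"],
     "asymptomatic-exclusive table; MAF not referenced"),
    ("c.864-342T>A", None, None, "intron_8", False, False, ["21"],
     "asymptomatic-exclusive table; printed label conflicts with c.863+1G>T boundary"),
    ("c.1000+633C>A", None, None, "intron_10", False, False, ["21"],
     "asymptomatic-exclusive table; printed label conflicts with c.1000+ numbering"),
    ("c.1224-18G>T", "rs9610642", 0.067, "intron_10", False, False, ["15"],
     "asymptomatic-exclusive table"),
]

#: The four published candidate variants (class-3 VUS), transcript order.
CANDIDATE_RSIDS = ("rs78987624", "rs80140288", "rs146953827", "rs117575523")

FAMILY5_SYMPTOMATIC = ("8", "24")


def build_fixture_cohort() -> Cohort:
    cohort = Cohort()
    for sid, fam, sex, fa, mo, status, anchor, prov in _SUBJECTS:
        cohort.add(Subject(subject_id=sid, family_id=fam, sex=sex,
                           father_id=fa, mother_id=mo, status=status,
                           anchor_variant=anchor,
                           anchor_class=ANCHOR_CLASSES.get(anchor)))
        cohort.provenance[sid] = prov
    cohort.validate()
    return cohort


def build_fixture_carriership(cohort: Cohort | None = None) -> CarriershipMatrix:
    cohort = cohort or build_fixture_cohort()
    matrix = CarriershipMatrix(subject_ids=sorted(cohort.subjects))
    for hgvs, rsid, maf, _label, splice, reg, carriers, _prov in _VARIANTS:
        v = parse_hgvs_c(hgvs).with_annotation(
            rsid=rsid, maf_percent=maf, splice_flag=splice, regulatory_flag=reg)
        matrix.add_variant(v, carriers)
    return matrix


def build_fixture_annotations() -> dict:
    ann = {}
    for hgvs, rsid, maf, _label, splice, reg, _carriers, _prov in _VARIANTS:
        v = parse_hgvs_c(hgvs).with_annotation(
            rsid=rsid, maf_percent=maf, splice_flag=splice, regulatory_flag=reg)
        ann[v.serialize()] = v
    return ann


def printed_region_labels() -> dict:
    return {hgvs: label for hgvs, _r, _m, label, _s, _g, _c, _p in _VARIANTS}


def region_label_conflicts() -> dict:
    """Printed region labels that disagree with the coordinate-derived region.

    The merged upstream label refines to either promoter or 5'UTR and is
    not a conflict. Returns ``{hgvs: (printed, derived)}``.
    """
    t = build_fixture_transcript()
    conflicts = {}
    for hgvs, _r, _m, label, _s, _g, _c, _p in _VARIANTS:
        from .transcript import assign_region
        derived = assign_region(parse_hgvs_c(hgvs), t).region
        if label == UPSTREAM:
            ok = derived in UPSTREAM_REGIONS
        else:
            ok = derived == label
        if not ok:
            conflicts[hgvs] = (label, derived)
    return conflicts


def variant_provenance() -> dict:
    return {hgvs: prov for hgvs, _r, _m, _l, _s, _g, _c, prov in _VARIANTS}


# ---------------------------------------------------------------------------
# File emission (same formats the pipeline reads)


def write_fixture(outdir) -> dict:
    """Materialize the fixture as PED + metadata TSV + carriership TSV +
    annotation TSV + transcript YAML. Returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = build_fixture_cohort()
    matrix = build_fixture_carriership(cohort)

    ped_rows = []
    meta_rows = []
    for sid in sorted(cohort.subjects, key=lambda s: int(s)):
        s = cohort.subjects[sid]
        fam = "0" if s.family_id.startswith("iso_") else s.family_id
        ped_rows.append([fam, sid, s.father_id or "0", s.mother_id or "0", s.sex,
                         "2" if s.is_symptomatic else "1"])
        meta_rows.append({
            "subject_id": sid, "status": s.status,
            "anchor_hgvs": s.anchor_variant or "-",
            "anchor_class": "" if s.anchor_class is None else s.anchor_class,
            "provenance": cohort.provenance.get(sid, ""),
        })
    paths = {
        "ped": outdir / "cohort.ped",
        "metadata": outdir / "subjects.tsv",
        "carriership": outdir / "carriership.tsv",
        "annotations": outdir / "annotations.tsv",
        "transcript": outdir / "transcript.yaml",
    }
    with open(paths["ped"], "w") as fh:
        for row in ped_rows:
            fh.write("\t".join(map(str, row)) + "\n")
    pd.DataFrame(meta_rows).to_csv(paths["metadata"], sep="\t", index=False)

    ids = matrix.variant_ids()
    frame = matrix.to_frame()
    frame.to_csv(paths["carriership"], sep="\t")

    labels = printed_region_labels()
    prov = variant_provenance()
    ann_rows = []
    for hgvs in ids:
        v = matrix.variants[hgvs]
        ann_rows.append({
            "hgvs_c": hgvs, "rsid": v.rsid or "-",
            "maf_percent": "-" if v.maf_percent is None else v.maf_percent,
            "splice_flag": int(v.splice_flag),
            "regulatory_flag": int(v.regulatory_flag),
            "printed_region": labels[hgvs], "provenance": prov[hgvs],
        })
    pd.DataFrame(ann_rows).to_csv(paths["annotations"], sep="\t", index=False)
    build_fixture_transcript().to_yaml(paths["transcript"])
    return paths


def read_annotations(path) -> dict:
    """Load an annotation TSV (hgvs_c, rsid, maf_percent, flags) into
    descriptors keyed by canonical HGVS."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    ann = {}
    for row in df.itertuples(index=False):
        maf = None if row.maf_percent in ("-", "", None) else float(row.maf_percent)
        rsid = None if row.rsid in ("-", "", None) else row.rsid
        v = parse_hgvs_c(row.hgvs_c).with_annotation(
            rsid=rsid, maf_percent=maf,
            splice_flag=bool(int(row.splice_flag)),
            regulatory_flag=bool(int(row.regulatory_flag)))
        ann[v.serialize()] = v
    return ann
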