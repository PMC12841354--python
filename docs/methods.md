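# Methods

## Model

The pipeline operationalizes a two-hit model for monoallelic IRIDA. Each
subject carries at most one exonic *TMPRSS6* anchor variant
(pathogenicity class 3–5); the hypothesis under test is that a
loss-of-function non-coding variant on the opposite haplotype (in trans)
contributes to phenotype expression. Three assumptions drive all phase
inference:

1. **Monoallelic anchor.** Anchor carriers hold exactly one anchor copy.
2. **Single ancestral anchor origin per family.** All anchor copies in
   one family are identical by descent, so the anchor marks one shared
   haplotype.
3. **No intragenic recombination.** The gene locus is one non-recombining
   segment; haplotypes are transmitted whole.

Under these assumptions, presence/absence carriership is enough for
phase: a variant present in one anchor carrier but absent in a relative
with the same anchor cannot ride on the shared anchor haplotype
(*trans*); a variant that co-occurs perfectly with the anchor across all
family members (≥ 2 anchor carriers, absent from every non-carrier) is
called *cis*. Homozygous variant carriership places a copy on the
non-anchor haplotype by necessity and is called trans with an explicit
homozygosity note. Families with fewer than two members are always
`uninformative` — phase is never guessed for singletons. Any
anchor-carrying relative lacking the variant counts as trans evidence
regardless of phenotype (the published families include a symptomatic
mother–daughter pair where exactly this configuration is informative).

The same assumptions justify the population-level cis test
(`cross_subject_coinheritance`): a variant whose cohort-wide carrier set
coincides exactly with the carrier set of one anchor, across unrelated
subjects, is likely co-inherited with that anchor (linkage
disequilibrium) and demoted to cis/likely-benign. Equality of the two
carrier sets is required — one anchor carrier lacking the variant breaks
the inference.

## Decision tree

Variants seen inside multi-member families go through the familial
branch: trans in a symptomatic subject and never trans in any
asymptomatic subject → retained (potentially pathogenic; a wild-type
carrier moves it to the shared-with-WT/uncertain track); trans in an
asymptomatic subject of any family → non-pathogenic; perfect
co-occurrence → cis-inherited. Variants carried by isolated symptomatic
subjects (and familial-cis variants that re-enter through isolated
carriers) go through the exclusivity branch: any asymptomatic carrier →
unlikely pathogenic; wild-type carriers only → possible contributor
(shared-with-unrelated-WT track); otherwise retained exclusive, with
cis demotion when the co-inheritance test fires. "Exclusive to
symptomatic subjects" throughout means exclusive with respect to
asymptomatic monoallelic subjects — the retained shared-with-WT tracks
are included in the branch totals, matching the source analysis's usage.
Variants observed in all subjects form a separate `ubiquitous` category
(automatically benign), and region-based exclusions (e.g. a PCR
allele-skew region) are explicit per-variant results, never silent
drops. A variant retained by the familial branch but also carried by
isolated subjects is counted in the familial branch; when both branches
classify a variant, the lower (more conservative) class wins and both
rationales are kept.

Exclusivity filters run first and the class gate last; on the packaged
cohort the opposite order changes nothing because class assignment
depends only on track membership, MAF and flags.

## Pathogenicity classes

Rule-based, 1–5; classes 4–5 describe input exonic anchors and are
never produced for non-coding variants.

| parameter | default | meaning |
|---|---|---|
| `benign_maf_threshold` | 5 % | MAF at or above → class 1 (benign) |
| `rare_maf_threshold` | 1 % | rarity gate for class 3; missing MAF ("-") counts as rare |
| in-silico flags | input columns | `splice_flag`, `regulatory_flag` — consumed as booleans from external predictors, never computed here |

Class 3 (VUS, the candidate set) requires all three: an exclusive
retained track, rarity, and at least one in-silico flag. The flag
requirement is deliberate: rare trans-exclusive variants without any
predicted effect (e.g. an intron-10 variant at MAF 0.016 %) are real
observations but not actionable candidates, and the published candidate
set is exactly the flagged subset. Unreferenced MAFs are kept as
missing and treated as rare, because the source analysis retains such
variants.

## Coordinates and regions

All positions are HGVS c. (1-based, no base 0); no genomic lift-over is
attempted because none is needed for a single-transcript analysis. The
transcript model is configurable (YAML): exon ends in coding
coordinates, CDS length, 5'UTR extent, promoter window, 3'UTR extent.
The packaged model has 18 exons with boundaries pinned by the intronic
variant names themselves (c.229+/c.230−, c.363+, c.431+, c.658+,
c.863+1, c.1000+, c.1223+/c.1224−, c.1582+, c.1868+, c.2278−);
unpinned boundaries are plausible placeholders that nothing downstream
depends on. The annotation source labels promoter and 5'UTR jointly
("5'UTR/PR"); the model splits this merged upstream region at c.-200
(a typical 5'UTR scale) purely for display — no rule distinguishes the
two sub-regions, and the regulatory flag of the one promoter candidate
is an input, not derived from the window. Two printed intron labels
contradict the exon numbering implied by other variant names
(c.864-342 vs the c.863+1 boundary; c.1000+633 vs c.1000+517); the
fixture keeps both printed labels and flags the conflicts instead of
resolving them silently.

## Enumeration oracle

`oracle_phase` enumerates every assignment of anchor and variant copies
to the two haplotypes of each family member, subject to: whole-haplotype
Mendelian transmission for members with in-pedigree parents; exactly one
anchor copy per carrier (assumption 1); variant copy counts taken from
the genotype (homozygous only when the genotype says so). An assignment
counts as trans when any member holds a variant copy on the non-anchor
haplotype — the two-hit question is whether a trans copy exists, so a
homozygous carrier's second copy decides. The oracle returns a verdict
only when all consistent assignments agree, and raises on impossible
data (genotype error / de novo).

On fully genotyped nuclear pedigrees with a single anchor-introducing
founder — the generative situation the engine's assumptions describe —
the engine and the oracle were compared exhaustively over every
haplotype configuration up to 5 members (1,344 cases): decisive verdicts
always agree and the engine is never decisive where the oracle is
ambiguous. When key relatives are unsequenced (the ascertained-family
situation), the engine's IBD reasoning goes beyond what enumeration of
the partial pedigree can certify; this is the method's inferential leap,
and its failure mode is documented below.

## Synthetic cohorts

The simulator emulates the study's ascertainment: each family is emitted
as a symptomatic proband plus anchor-side relatives (the
anchor-transmitting parent and optional siblings); the second parent
contributes gametes but is not part of the cohort. The anchor enters on
one founder haplotype; the planted second hit (one distinct rare variant
per family or isolated subject, flagged as a predicted splice effect,
MAF 0.1 %) arrives on a haplotype of the unsequenced parent and is
therefore in trans by construction. Background variants are drawn per
haplotype from log-uniform MAFs (0.05–25 %). Phenotype follows the
penetrance model: P(symptomatic | anchor + trans hit) = `penetrance`
(default 1), P(symptomatic | anchor only) = `phenocopy_rate` (default
0); non-carriers are wild type. Defaults mirror the real cohort's
shape: 6 families of 3 emitted members, 9 isolated subjects,
`second_hit_rate` 0.5 (the hypothesis probability; validation runs set
it to 1), 40 background variants. One seed governs everything; each
family and isolated subject draws from a deterministic substream keyed
by its index, so adding units never perturbs earlier ones, and fixed
seeds give byte-identical output files.

`score_recovery` counts a planted hit as *recoverable* when the decision
rules could possibly retain it: the family provides trans evidence (an
anchor-carrying member lacking the hit; for isolated subjects
exclusivity substitutes) and no asymptomatic or wild-type subject
carries it. A hit that leaks into a wild-type sibling is by design
demoted to the shared-with-WT track — the same call the source analysis
makes — and is excluded from the sensitivity denominator. Under full
penetrance and complete genotyping, sensitivity over recoverable hits
is 1.0 and no candidate is ever carried by an asymptomatic subject.

What the simulator does **not** model: recombination within the locus,
sequencing error, population structure, de novo events, and phenocopies
among non-carriers. Passing tests therefore show that the decision
rules are internally sound under the model's own assumptions, not that
those assumptions hold in any real cohort.

## Known limitations

- **Common variants in partially sequenced families.** A common variant
  entering a family on several founder haplotypes can show perfect
  co-occurrence with the anchor and be called cis while a trans copy
  exists (the enumeration oracle correctly reports ambiguity there).
  Decisive verdicts on rare, single-origin variants are unaffected;
  simulation puts overall phase accuracy of decisive verdicts near
  0.95 with this failure mode included (see
  `analysis/04_simulation_validation.py`).
- **Missing genotypes are treated as absent** — conservative for trans
  evidence (which needs an observed absence) but able to fabricate
  absence; phase accuracy degrades monotonically with missingness.
- The phenotype operation records the supportive TSAT/hepcidin-ratio
  percentile but never gates on it; lab-panel data are optional and the
  packaged cohort relies on the published status labels.
- Funnel stages upstream of the packaged variant tables (total variant
  yield of sequencing, pre-exclusion trans counts) require raw genotypes
  that were never published; the funnel object computes the
  corresponding internal-consistency quantities on whatever input it is
  given, and its conservation invariants are asserted on every run.
- Pedigree links beyond the two published parent–child pairs are
  unknown; fixture members are related-within-family with unstated
  topology, which the engine tolerates (it needs family membership and
  anchor carriership only) but the enumeration oracle then cannot
  certify.
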