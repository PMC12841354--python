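"""Materialize the packaged study cohort and check its census.

Writes the cohort files (PED, subject metadata, carriership matrix,
variant annotations, transcript model) under results/fixture/ and
prints the subject census: 27 subjects — 16 symptomatic monoallelic
(7 familial + 9 isolated), 7 asymptomatic monoallelic, 4 wild type —
plus the two printed region labels that conflict with the coordinate-
derived exon layout.
"""

from pathlib import Path

from irida_twohit.fixture import (
    build_fixture_cohort, region_label_conflicts, write_fixture,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "fixture"


def main():
    paths = write_fixture(OUT)
    cohort = build_fixture_cohort()
    census = cohort.census()
    print("Fixture written to", OUT)
    for label, p in sorted(paths.items()):
        print(f"  {label}: {p.name}")
    print("\nCohort census:")
    for k, v in census.items():
        print(f"  {k}: {v}")
    conflicts = region_label_conflicts()
    print(f"\nPrinted-vs-derived region label conflicts ({len(conflicts)}):")
    for hgvs, (printed, derived) in sorted(conflicts.items()):
        print(f"  {hgvs}: printed {printed}, derived {derived}")


if __name__ == "__main__":
    main()
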