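"""Transcript coordinate model and gene-region assignment.

A :class:`TranscriptModel` describes a single transcript entirely in
HGVS coding coordinates: exon ends, CDS span, 5'UTR extent, an optional
promoter window upstream of the 5'UTR, and a 3'UTR extent. Every
parseable position inside the modeled span maps to exactly one region
(promoter, 5UTR, exon_k, intron_k, 3UTR). No genomic lift-over is
attempted; the model is single-transcript and strand-agnostic.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, replace
from pathlib import Path
import yaml

from .hgvs import VariantDescriptor


class RegionAssignmentError(ValueError):
    pass


class OutOfSpanError(RegionAssignmentError):
    pass


@dataclass(frozen=True)
class TranscriptModel:
    name: str
    exon_ends_c: tuple  # last coding base of exons 1..n-1 (ascending)
    cds_end: int  # coding length = last base of the final exon
    utr5_extent: int  # most-negative c. position still called 5'UTR
    promoter_window: tuple  # (most-negative, least-negative) promoter c. span
    utr3_extent: int  # largest * position considered 3'UTR

    def __post_init__(self):
        ends = tuple(self.exon_ends_c)
        if list(ends) != sorted(set(ends)):
            raise ValueError("exon_ends_c must be strictly increasing")
        if ends and ends[-1] >= self.cds_end:
            raise ValueError("last internal exon end must precede cds_end")
        if self.utr5_extent >= 0:
            raise ValueError("utr5_extent must be negative")
        lo, hi = self.promoter_window
        if not (lo <= hi < self.utr5_extent):
            raise ValueError("promoter_window must lie strictly upstream of utr5_extent")
        if self.utr3_extent < 1:
            raise ValueError("utr3_extent must be >= 1")
        object.__setattr__(self, "exon_ends_c", ends)

    @property
    def n_exons(self) -> int:
        return len(self.exon_ends_c) + 1

    def exon_of(self, pos: int) -> int:
        """1-based exon index of a coding position in [1, cds_end]."""
        if not 1 <= pos <= self.cds_end:
            raise OutOfSpanError(f"c.{pos} outside CDS [1, {self.cds_end}]")
        return bisect.bisect_left(self.exon_ends_c, pos) + 1

    def region_of(self, anchor: int, offset: int = 0, utr3: bool = False) -> str:
        """Region of a single (anchor, offset, utr3) coordinate.

        Intronic offsets are only meaningful at exon-boundary anchors;
        an offset at a non-boundary anchor raises
        :class:`RegionAssignmentError` (callers keep the variant with
        region ``unresolved`` and report the inconsistency).
        """
        if utr3:
            if anchor > self.utr3_extent:
                raise OutOfSpanError(f"c.*{anchor} beyond 3'UTR extent *{self.utr3_extent}")
            return "3UTR"
        if offset == 0:
            if anchor >= 1:
                if anchor > self.cds_end:
                    raise OutOfSpanError(f"c.{anchor} beyond coding length {self.cds_end}")
                return f"exon_{self.exon_of(anchor)}"
            if anchor >= self.utr5_extent:
                return "5UTR"
            if anchor >= self.promoter_window[0]:
                return "promoter"
            raise OutOfSpanError(
                f"c.{anchor} upstream of promoter window {self.promoter_window}")
        # Intron k lies between exon k (ending at exon_ends_c[k-1]) and exon k+1.
        if offset > 0:
            if anchor in self.exon_ends_c:
                return f"intron_{self.exon_ends_c.index(anchor) + 1}"
            raise RegionAssignmentError(
                f"c.{anchor}{offset:+d}: c.{anchor} is not an exon end of {self.name}")
        starts = [e + 1 for e in self.exon_ends_c]
        if anchor in starts:
            return f"intron_{starts.index(anchor) + 1}"
        raise RegionAssignmentError(
            f"c.{anchor}{offset:+d}: c.{anchor} is not an exon start of {self.name}")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "exon_ends_c": list(self.exon_ends_c),
            "cds_end": self.cds_end,
            "utr5_extent": self.utr5_extent,
            "promoter_window": list(self.promoter_window),
            "utr3_extent": self.utr3_extent,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TranscriptModel":
        return cls(
            name=d["name"],
            exon_ends_c=tuple(d["exon_ends_c"]),
            cds_end=int(d["cds_end"]),
            utr5_extent=int(d["utr5_extent"]),
            promoter_window=tuple(d["promoter_window"]),
            utr3_extent=int(d["utr3_extent"]),
        )

    @classmethod
    def from_yaml(cls, path) -> "TranscriptModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


#: Upstream super-region: the annotation sources label promoter and
#: 5'UTR jointly ("5'UTR/PR"); both refine this merged label.
UPSTREAM_REGIONS = ("promoter", "5UTR")


def assign_region(v: VariantDescriptor, t: TranscriptModel) -> VariantDescriptor:
    """Return a copy of ``v`` with its region set from coordinates alone.

    Ranged edits are assigned from their start coordinate; a range whose
    two ends fall in different regions keeps the start region with a
    note. Coordinate/model inconsistencies yield region ``unresolved``
    with the error recorded in ``notes`` (reported, never dropped).
    """
    notes = list(v.notes)
    try:
        region = t.region_of(v.anchor_pos, v.offset, v.utr3)
    except OutOfSpanError:
        raise
    except RegionAssignmentError as exc:
        return replace(v, region="unresolved", notes=notes + [str(exc)])
    if v.is_range:
        try:
            end_region = t.region_of(v.end_anchor_pos, v.end_offset, v.end_utr3)
        except RegionAssignmentError as exc:
            end_region = None
            notes.append(f"range end unresolved: {exc}")
        if end_region is not None and end_region != region:
            notes.append(f"range spans {region}..{end_region}; assigned from start")
    return replace(v, region=region, notes=notes)


def build_fixture_transcript() -> TranscriptModel:
    """The packaged TMPRSS6 reference-transcript layout (NM_153609.3 style).

    Exon boundaries are fixed by the intronic variant anchors observed
    at this locus (c.229+, c.230-, c.363+, c.431+, c.658+, c.863+1,
    c.864-, c.1000+, c.1223+, c.1224-, c.1582+, c.1868+, c.2278-);
    boundaries not pinned by any observed variant (exons 1, 5, 9, 11,
    12, 14, 16) are plausible placeholders and nothing downstream
    depends on them. 18 exons, coding length 2436 nt.
    """
    return TranscriptModel(
        name="tmprss6_fixture",
        exon_ends_c=(78, 229, 363, 431, 532, 658, 863, 1000, 1128, 1223,
                     1324, 1453, 1582, 1716, 1868, 2020, 2277),
        cds_end=2436,
        utr5_extent=-200,
        promoter_window=(-12000, -201),
        utr3_extent=2000,
    )
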