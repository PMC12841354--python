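"""Parsing and serialization of HGVS coding-coordinate (``c.``) variant names.

Supports the subset of the HGVS nomenclature needed for single-gene
non-coding variant analysis: substitutions, deletions, duplications,
insertions and deletion-insertions, at exonic, intronic (``+``/``-``
offsets), upstream (``-N``) and 3'UTR (``*N``) positions, including
ranged edits with mixed offsets. Protein and genomic descriptions are
out of scope and rejected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional


class HgvsParseError(ValueError):
    """Raised for variant descriptions this grammar cannot represent."""

    def __init__(self, text: str, reason: str):
        self.text = text
        self.reason = reason
        super().__init__(f"cannot parse {text!r}: {reason}")


class EditKind(str, Enum):
    SNV = "SNV"
    DEL = "del"
    DUP = "dup"
    DELINS = "delins"
    INS = "ins"


# A coding-coordinate point: optional * (3'UTR), signed anchor, optional
# intronic offset. "230-938" parses as anchor 230 / offset -938 while a
# bare "-7607" is an upstream anchor (no offset can follow an upstream
# or 3'UTR anchor in this data model).
_POINT = r"(?P<{p}star>\*)?(?P<{p}anchor>-?\d+)(?P<{p}off>[+-]\d+)?"

_EDIT = (
    r"(?:(?P<ref>[ACGT])>(?P<alt>[ACGT])"
    r"|delins(?P<delins_seq>[ACGT]+)"
    r"|del(?P<del_ins_del>[ACGT]*)ins(?P<del_ins_ins>[ACGT]+)"
    r"|del(?P<del_seq>[ACGT]*)"
    r"|dup(?P<dup_seq>[ACGT]*)"
    r"|ins(?P<ins_seq>[ACGT]+))"
)

_HGVS_C = re.compile(
    r"^c\."
    + _POINT.format(p="s")
    + r"(?:_" + _POINT.format(p="e") + r")?"
    + _EDIT
    + r"$"
)


@dataclass
class VariantDescriptor:
    """A parsed coding-coordinate variant plus its annotation payload.

    ``anchor_pos`` is the signed coding position (negative = upstream of
    the CDS); ``utr3`` marks the ``*`` prefix, in which case
    ``anchor_pos`` counts from the stop codon. ``offset`` is the signed
    intronic offset (0 for exonic/UTR positions). ``end_*`` mirror the
    start coordinates for ranged edits.
    """

    hgvs_c: str
    anchor_pos: int
    offset: int = 0
    utr3: bool = False
    end_anchor_pos: Optional[int] = None
    end_offset: int = 0
    end_utr3: bool = False
    edit_kind: EditKind = EditKind.SNV
    ref: Optional[str] = None
    alt: Optional[str] = None
    deleted: Optional[str] = None
    inserted: Optional[str] = None
    rsid: Optional[str] = None
    region: Optional[str] = None
    maf_percent: Optional[float] = None
    splice_flag: bool = False
    regulatory_flag: bool = False
    notes: list = field(default_factory=list)

    def __post_init__(self):
        if self.offset != 0 and self.utr3:
            raise HgvsParseError(self.hgvs_c, "3'UTR position with intronic offset")
        if self.utr3 and self.anchor_pos <= 0:
            raise HgvsParseError(self.hgvs_c, "3'UTR (*) position must be positive")
        if self.maf_percent is not None and not (0.0 <= self.maf_percent <= 100.0):
            raise ValueError(f"maf_percent out of [0, 100]: {self.maf_percent}")

    @property
    def is_range(self) -> bool:
        return self.end_anchor_pos is not None

    @property
    def is_rare(self) -> bool:
        """Missing MAF ('-' in annotation sources) is treated as rare."""
        return self.maf_percent is None or self.maf_percent < 1.0

    def sort_key(self) -> tuple:
        # Map 3'UTR positions after the CDS span so variants order along
        # the transcript; good enough for deterministic output.
        base = self.anchor_pos + (10**7 if self.utr3 else 0)
        return (base, self.offset, self.hgvs_c)

    def serialize(self) -> str:
        """Re-serialize to canonical HGVS c. text (round-trips the input)."""

        def point(anchor: int, off: int, star: bool) -> str:
            s = ("*" if star else "") + str(anchor)
            if off:
                s += f"{off:+d}"
            return s

        s = "c." + point(self.anchor_pos, self.offset, self.utr3)
        if self.is_range:
            s += "_" + point(self.end_anchor_pos, self.end_offset, self.end_utr3)
        k = self.edit_kind
        if k is EditKind.SNV:
            s += f"{self.ref}>{self.alt}"
        elif k is EditKind.DEL:
            s += "del" + (self.deleted or "")
        elif k is EditKind.DUP:
            s += "dup" + (self.inserted or "")
        elif k is EditKind.DELINS:
            if self.deleted:
                s += f"del{self.deleted}ins{self.inserted}"
            else:
                s += f"delins{self.inserted}"
        elif k is EditKind.INS:
            s += "ins" + (self.inserted or "")
        return s

    def with_annotation(self, rsid=None, maf_percent=None, splice_flag=False,
                        regulatory_flag=False) -> "VariantDescriptor":
        return replace(self, rsid=rsid, maf_percent=maf_percent,
                       splice_flag=splice_flag, regulatory_flag=regulatory_flag)


def _genomic_order(anchor: int, off: int, star: bool) -> tuple:
    return (anchor + (10**7 if star else 0), off)


def parse_hgvs_c(text: str) -> VariantDescriptor:
    """Parse an HGVS ``c.`` description into a :class:`VariantDescriptor`.

    Only coordinates and the edit are filled in; region assignment and
    annotation happen downstream. Unparseable input raises
    :class:`HgvsParseError` — never a silent skip.
    """
    text = text.strip()
    if not text.startswith("c."):
        prefix = text.split(".", 1)[0] if "." in text else text[:2]
        raise HgvsParseError(text, f"not a coding-coordinate description (prefix {prefix!r})")
    m = _HGVS_C.match(text)
    if m is None:
        raise HgvsParseError(text, "does not match the supported c. grammar")
    g = m.groupdict()

    anchor = int(g["sanchor"])
    offset = int(g["soff"]) if g["soff"] else 0
    star = g["sstar"] is not None
    end_anchor = int(g["eanchor"]) if g["eanchor"] is not None else None
    end_offset = int(g["eoff"]) if g["eoff"] else 0
    end_star = g["estar"] is not None

    kw: dict = {}
    if g["ref"] is not None:
        kind = EditKind.SNV
        kw.update(ref=g["ref"], alt=g["alt"])
        if end_anchor is not None:
            raise HgvsParseError(text, "substitution cannot span a range")
    elif g["delins_seq"] is not None:
        kind = EditKind.DELINS
        kw.update(inserted=g["delins_seq"])
    elif g["del_ins_ins"] is not None:
        kind = EditKind.DELINS
        kw.update(deleted=g["del_ins_del"] or None, inserted=g["del_ins_ins"])
    elif g["del_seq"] is not None:
        kind = EditKind.DEL
        kw.update(deleted=g["del_seq"] or None)
    elif g["dup_seq"] is not None:
        kind = EditKind.DUP
        kw.update(inserted=g["dup_seq"] or None)
    elif g["ins_seq"] is not None:
        kind = EditKind.INS
        kw.update(inserted=g["ins_seq"])
        if end_anchor is None:
            raise HgvsParseError(text, "insertion requires a flanking range")
    else:  # pragma: no cover - the regex cannot reach this
        raise HgvsParseError(text, "unsupported edit kind")

    if end_anchor is not None:
        if _genomic_order(end_anchor, end_offset, end_star) < _genomic_order(anchor, offset, star):
            raise HgvsParseError(text, "range end precedes range start")

    v = VariantDescriptor(
        hgvs_c=text, anchor_pos=anchor, offset=offset, utr3=star,
        end_anchor_pos=end_anchor, end_offset=end_offset, end_utr3=end_star,
        edit_kind=kind, **kw,
    )
    if v.serialize() != text:
        raise HgvsParseError(text, f"non-canonical form (canonical: {v.serialize()!r})")
    return v
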