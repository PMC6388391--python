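"""A small parser/formatter for coding-DNA (``c.``) variant notation.

The grammar covers the notations that occur in small-mutation screens of a
single transcript: substitutions, deletions, duplications, insertions and
deletion-insertions, with intron offsets (``c.186+2T>C``), UTR anchors
(``c.-12C>T``, ``c.*45A>G``) and range forms mixing offsets
(``c.9164-3_9164-1delCAG``).  Parsing round-trips: formatting a parsed
variant reproduces the canonical form of the input.

Deliberately not a general HGVS engine: protein-level notation, genomic
coordinates, alleles and repeats are out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Literal

from .errors import HgvsParseError, ValidationError

Anchor = Literal["cds", "utr5", "utr3"]

_POS = r"(?P<{p}>[-*]?\d+)(?P<{o}>[+-]\d+)?"
_POS_RE = re.compile(r"^([-*]?)(\d+)([+-]\d+)?$")

_PATTERNS = {
    "substitution": re.compile(
        r"^c\.(?P<start>[-*]?\d+(?:[+-]\d+)?)(?P<ref>[ACGT])>(?P<alt>[ACGT])$"
    ),
    "delins": re.compile(
        r"^c\.(?P<start>[-*]?\d+(?:[+-]\d+)?)(?:_(?P<end>[-*]?\d+(?:[+-]\d+)?))?"
        r"delins(?P<seq>[ACGT]+)$"
    ),
    "deletion": re.compile(
        r"^c\.(?P<start>[-*]?\d+(?:[+-]\d+)?)(?:_(?P<end>[-*]?\d+(?:[+-]\d+)?))?"
        r"del(?P<seq>[ACGT]*)$"
    ),
    "duplication": re.compile(
        r"^c\.(?P<start>[-*]?\d+(?:[+-]\d+)?)(?:_(?P<end>[-*]?\d+(?:[+-]\d+)?))?"
        r"dup(?P<seq>[ACGT]*)$"
    ),
    "insertion": re.compile(
        r"^c\.(?P<start>[-*]?\d+(?:[+-]\d+)?)_(?P<end>[-*]?\d+(?:[+-]\d+)?)"
        r"ins(?P<seq>[ACGT]+)$"
    ),
}


@dataclass(frozen=True, order=True)
class Position:
    """One endpoint of a coding-coordinate interval.

    ``base`` is the 1-based anchor position (CDS position for ``cds``,
    distance into the UTR for ``utr5``/``utr3``); ``offset`` is the signed
    intron offset, 0 for exonic positions.
    """

    base: int
    offset: int = 0
    anchor: Anchor = "cds"

    def __str__(self) -> str:
        prefix = {"cds": "", "utr5": "-", "utr3": "*"}[self.anchor]
        s = f"{prefix}{self.base}"
        if self.offset:
            s += f"{self.offset:+d}"
        return s

    @property
    def is_exonic(self) -> bool:
        return self.offset == 0 and self.anchor == "cds"

    def sort_key(self) -> tuple[int, int, int]:
        anchor_rank = {"utr5": -1, "cds": 0, "utr3": 1}[self.anchor]
        base = -self.base if self.anchor == "utr5" else self.base
        return (anchor_rank, base, self.offset)


def _parse_position(token: str) -> Position:
    m = _POS_RE.match(token)
    if not m:
        raise HgvsParseError(f"bad position token {token!r}", token=token)
    prefix, digits, off = m.groups()
    anchor: Anchor = {"": "cds", "-": "utr5", "*": "utr3"}[prefix]
    return Position(int(digits), int(off) if off else 0, anchor)


@dataclass(frozen=True)
class CodingVariant:
    """A parsed coding-DNA variant."""

    raw: str
    kind: Literal["substitution", "deletion", "duplication", "insertion", "delins"]
    start: Position
    end: Position
    ref_allele: str = ""
    alt_allele: str = ""

    def __str__(self) -> str:
        return format_hgvs(self)

    @property
    def is_intronic(self) -> bool:
        return self.start.offset != 0 or self.end.offset != 0

    @property
    def is_utr(self) -> bool:
        return self.start.anchor != "cds" or self.end.anchor != "cds"

    def net_length_change(self, model=None) -> int:
        """Inserted minus deleted length; needs exonic endpoints for bare del."""
        if self.kind == "substitution":
            return 0
        if self.kind in ("duplication", "insertion"):
            return len(self.alt_allele) if self.alt_allele else self._span_length()
        if self.kind == "deletion":
            return -(len(self.ref_allele) if self.ref_allele else self._span_length())
        # delins
        return len(self.alt_allele) - (
            len(self.ref_allele) if self.ref_allele else self._span_length()
        )

    def _span_length(self) -> int:
        if not (self.start.is_exonic and self.end.is_exonic):
            raise ValidationError(
                f"{self.raw}: span length undefined across intron/UTR boundaries "
                "without an explicit sequence"
            )
        return self.end.base - self.start.base + 1


def parse_hgvs(text: str) -> CodingVariant:
    """Parse a ``c.`` variant string into a :class:`CodingVariant`."""
    token = text.strip().replace(" ", "")
    if not token.startswith("c."):
        raise HgvsParseError(f"{text!r}: expected a 'c.' coding variant", token=token)
    for kind, pat in _PATTERNS.items():
        m = pat.match(token)
        if not m:
            continue
        start = _parse_position(m.group("start"))
        end_tok = m.groupdict().get("end")
        end = _parse_position(end_tok) if end_tok else start
        if end.sort_key() < start.sort_key():
            raise HgvsParseError(f"{text!r}: end precedes start", token=end_tok)
        seq = m.groupdict().get("seq") or ""
        if kind == "substitution":
            ref, alt = m.group("ref"), m.group("alt")
            if ref == alt:
                raise HgvsParseError(f"{text!r}: identical ref and alt", token=ref)
            v = CodingVariant(token, kind, start, end, ref, alt)
        elif kind == "deletion":
            v = CodingVariant(token, kind, start, end, ref_allele=seq)
        elif kind in ("duplication", "insertion"):
            if kind == "insertion" and _span(start, end) != 2:
                raise HgvsParseError(
                    f"{text!r}: insertion requires flanking positions N_N+1",
                    token=end_tok,
                )
            v = CodingVariant(token, kind, start, end, alt_allele=seq)
        else:  # delins
            v = CodingVariant(token, kind, start, end, alt_allele=seq)
        return v
    raise HgvsParseError(f"unsupported notation {text!r}", token=token)


def _span(start: Position, end: Position) -> int | None:
    if start.anchor != end.anchor or start.offset or end.offset:
        if (start.base, start.anchor) == (end.base, end.anchor):
            return end.offset - start.offset + 1
        return None
    return end.base - start.base + 1


def format_hgvs(v: CodingVariant) -> str:
    """Canonical text for a variant; inverse of :func:`parse_hgvs`."""
    pos = str(v.start) if v.start == v.end else f"{v.start}_{v.end}"
    if v.kind == "substitution":
        return f"c.{v.start}{v.ref_allele}>{v.alt_allele}"
    if v.kind == "deletion":
        return f"c.{pos}del{v.ref_allele}"
    if v.kind == "duplication":
        return f"c.{pos}dup{v.alt_allele}"
    if v.kind == "insertion":
        return f"c.{pos}ins{v.alt_allele}"
    return f"c.{pos}delins{v.alt_allele}"
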