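"""Per-variant consequence annotation.

Computes every attribute a small-mutation spectrum reports per variant:
consequence class, host exon and protein domain, codon index/position,
transition vs transversion, CpG dinucleotide context, the premature stop
codon (PTC) introduced by a nonsense change, the first hidden PTC downstream
of a frameshift, and the splice-site class of intronic changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

from .errors import ContractError, CoordinateError, ReferenceMismatchError
from .gene_model import STOP_CODONS, TranscriptModel
from .hgvs import CodingVariant, parse_hgvs

Consequence = Literal[
    "nonsense", "missense", "synonymous", "frameshift", "inframe_indel", "splicing", "utr"
]

PURINES = {"A", "G"}


def codon_position(pos: int) -> int:
    """Position (1|2|3) of a coding coordinate within its codon."""
    if pos < 1:
        raise CoordinateError(f"coding position {pos} < 1")
    return (pos - 1) % 3 + 1


def substitution_class(ref: str, alt: str) -> str:
    """'transition' (purine<->purine or pyrimidine<->pyrimidine) or 'transversion'."""
    if ref == alt:
        raise ContractError("identical ref and alt bases")
    if ref not in "ACGT" or alt not in "ACGT":
        raise ContractError(f"bases must be ACGT, got {ref}>{alt}")
    return "transition" if (ref in PURINES) == (alt in PURINES) else "transversion"


def is_cpg_site(model: TranscriptModel, v: CodingVariant) -> bool:
    """True when the substituted reference base sits in a CpG dinucleotide.

    Covers both deamination classes: a reference C immediately followed by G,
    or a reference G immediately preceded by C (the opposite-strand event).
    A variant at the CDS boundary with no adjacent base on the needed side is
    simply not a CpG site.
    """
    if v.kind != "substitution" or not (v.start.is_exonic and v.start.anchor == "cds"):
        raise ContractError("CpG context is defined for exonic substitutions only")
    pos = v.start.base
    cds = model.cds_sequence
    ref = cds[pos - 1]
    if ref == "C":
        return pos < len(cds) and cds[pos] == "G"
    if ref == "G":
        return pos > 1 and cds[pos - 2] == "C"
    return False


@dataclass(frozen=True)
class SpliceSiteCall:
    side: Literal["donor", "acceptor"]
    conservation: Literal["core_1_2", "near_3_5", "spanning", "other"]
    consensus_exon: int


def classify_splice_site(model: TranscriptModel, v: CodingVariant) -> SpliceSiteCall:
    """Classify an intronic variant by splice side and conservation zone.

    Positive intron offsets lie after the upstream exon (donor side),
    negative offsets before the downstream exon (acceptor side).  |offset|
    1-2 is the near-invariant core, 3-5 the conserved neighbourhood; a range
    crossing the core boundary (including into the exon) is 'spanning'.
    The variant is attributed to its consensus exon: the upstream exon for
    donor-side changes, the downstream exon for acceptor-side ones; a range
    reaching into an exon is attributed to that exon.
    """
    offsets = [p.offset for p in (v.start, v.end)]
    if not any(offsets):
        raise ContractError(f"{v.raw}: not an intronic variant")
    nonzero = [o for o in offsets if o]
    side: Literal["donor", "acceptor"] = "donor" if nonzero[0] > 0 else "acceptor"
    # consensus exon: exonic endpoint wins; else the offset anchor's exon
    if v.start.is_exonic:
        exon = model.exon_of_coding_position(v.start.base)
    elif v.end.is_exonic:
        exon = model.exon_of_coding_position(v.end.base)
    else:
        exon = model.exon_of_coding_position(v.start.base)
    if v.start == v.end:
        a = abs(v.start.offset)
        cons = "core_1_2" if a <= 2 else ("near_3_5" if a <= 5 else "other")
    else:
        mags = sorted(abs(o) for o in offsets)
        if 0 in offsets:  # reaches into the exon across the core zone
            cons = "spanning"
        elif mags[0] <= 2 and mags[1] >= 3:
            cons = "spanning"
        elif mags[1] <= 2:
            cons = "core_1_2"
        elif mags[0] >= 3 and mags[1] <= 5:
            cons = "near_3_5"
        else:
            cons = "other"
    return SpliceSiteCall(side, cons, exon)


@dataclass(frozen=True)
class HiddenPtc:
    stop: str
    codon_index: int          # codon number in the mutant reading frame
    codons_from_site: int     # 1 = the first codon touched by the indel


def apply_indel(cds: str, v: CodingVariant) -> tuple[str, int]:
    """Apply an exonic indel to the CDS.

    Returns the mutant sequence and the 1-based position (in the mutant) of
    the first base at which it can differ from the reference reading.
    """
    if not (v.start.is_exonic and v.end.is_exonic):
        raise ContractError(f"{v.raw}: indel endpoints must be exonic")
    s, e = v.start.base, v.end.base
    if v.kind == "deletion":
        return cds[: s - 1] + cds[e:], s
    if v.kind == "duplication":
        seq = v.alt_allele or cds[s - 1 : e]
        return cds[:e] + seq + cds[e:], e + 1
    if v.kind == "insertion":
        return cds[:s] + v.alt_allele + cds[s:], s + 1
    if v.kind == "delins":
        return cds[: s - 1] + v.alt_allele + cds[e:], s
    raise ContractError(f"{v.raw}: not an indel")


def first_hidden_ptc(model: TranscriptModel, v: CodingVariant) -> Optional[HiddenPtc]:
    """First stop codon read in the shifted frame downstream of a frameshift.

    The indel is applied to the CDS and codons are re-read starting at the
    first codon the indel touches; the first stop encountered is returned
    with its codon distance from that point.  ``None`` means read-through to
    the end of the mutated CDS (the PTC, if any, lies in the 3' UTR).
    """
    if v.kind == "substitution":
        raise ContractError("first_hidden_ptc applies to frameshift indels")
    if v.net_length_change() % 3 == 0:
        raise ContractError(f"{v.raw}: in-frame indel has no frameshift PTC")
    mutant, first_changed = apply_indel(model.cds_sequence, v)
    k = (first_changed - 1) // 3 + 1  # first affected codon, 1-based
    for i in range(k - 1, len(mutant) // 3):
        codon = mutant[3 * i : 3 * i + 3]
        if codon in STOP_CODONS:
            return HiddenPtc(codon, i + 1, i + 2 - k)
    return None


def normalize_indel(
    model: TranscriptModel, v: CodingVariant, three_prime: bool = False
) -> CodingVariant:
    """Shift an ambiguously placed exonic deletion/duplication to a canonical
    position.

    Default is left-most placement (keeps hand-checkable oracles simple);
    ``three_prime=True`` applies the 3'-most placement instead.  Variants
    other than fully exonic deletions/duplications are returned unchanged.
    """
    if v.kind not in ("deletion", "duplication") or not (
        v.start.is_exonic and v.end.is_exonic and v.start.anchor == "cds"
    ):
        return v
    cds = model.cds_sequence
    s, e = v.start.base, v.end.base
    if three_prime:
        while e < len(cds) and cds[e] == cds[s - 1]:
            s += 1
            e += 1
    else:
        while s > 1 and cds[s - 2] == cds[e - 1]:
            s -= 1
            e -= 1
    if (s, e) == (v.start.base, v.end.base):
        return v
    seq = cds[s - 1 : e]
    from dataclasses import replace

    from .hgvs import Position, format_hgvs

    moved = replace(
        v,
        start=Position(s),
        end=Position(e),
        ref_allele=seq if v.kind == "deletion" else "",
        alt_allele=seq if v.kind == "duplication" else "",
    )
    return replace(moved, raw=format_hgvs(moved))


@dataclass(frozen=True)
class AnnotatedVariant:
    """Full per-variant annotation."""

    variant: CodingVariant
    consequence: Consequence
    host_exon: Optional[int]
    domain: Optional[str]
    codon_index: Optional[int] = None
    codon_pos: Optional[int] = None
    ref_codon: Optional[str] = None
    alt_codon: Optional[str] = None
    ptc: str = "none"
    hidden_ptc: Optional[HiddenPtc] = None
    cpg: bool = False
    substitution_class: str = "not_applicable"
    splice: Optional[SpliceSiteCall] = None


def ptc_codon(model: TranscriptModel, v: CodingVariant) -> str:
    """Stop codon introduced by a nonsense substitution."""
    ann = classify_variant(model, v)
    if ann.consequence != "nonsense":
        raise ContractError(f"{v.raw}: not a nonsense variant ({ann.consequence})")
    return ann.alt_codon  # type: ignore[return-value]


def classify_variant(model: TranscriptModel, v: CodingVariant | str) -> AnnotatedVariant:
    """Assign the consequence class and populate every per-variant field.

    Dispatch: any non-zero intron offset -> splicing (this includes range
    deletions spanning an exon boundary, which remove intronic bases); a UTR
    anchor -> utr; exonic substitutions by codon comparison; exonic indels by
    net length mod 3.  The reference allele of an exonic substitution is
    checked against the CDS and a mismatch raises
    :class:`~dmdkit.errors.ReferenceMismatchError`.
    """
    if isinstance(v, str):
        v = parse_hgvs(v)
    if v.is_intronic:
        call = classify_splice_site(model, v)
        return AnnotatedVariant(
            v,
            "splicing",
            call.consensus_exon,
            model.domain_of_exon(call.consensus_exon),
            splice=call,
        )
    if v.is_utr:
        return AnnotatedVariant(v, "utr", None, None)
    pos = v.start.base
    if not 1 <= pos <= model.coding_length or not 1 <= v.end.base <= model.coding_length:
        raise CoordinateError(f"{v.raw}: position outside CDS 1..{model.coding_length}")
    exon = model.exon_of_coding_position(pos)
    domain = model.domain_of_exon(exon)
    if v.kind == "substitution":
        cds = model.cds_sequence
        if cds[pos - 1] != v.ref_allele:
            raise ReferenceMismatchError(
                f"{v.raw}: reference base at c.{pos} is {cds[pos - 1]}, "
                f"not {v.ref_allele} (wrong transcript model?)"
            )
        ci = (pos - 1) // 3 + 1
        cp = codon_position(pos)
        ref_codon = model.codon(ci)
        alt_codon = ref_codon[: cp - 1] + v.alt_allele + ref_codon[cp:]
        if ref_codon in STOP_CODONS:
            cons: Consequence = "synonymous" if alt_codon in STOP_CODONS else "missense"
        elif alt_codon in STOP_CODONS:
            cons = "nonsense"
        else:
            cons = "synonymous" if _aa(ref_codon) == _aa(alt_codon) else "missense"
        return AnnotatedVariant(
            v,
            cons,
            exon,
            domain,
            codon_index=ci,
            codon_pos=cp,
            ref_codon=ref_codon,
            alt_codon=alt_codon,
            ptc=alt_codon if cons == "nonsense" else "none",
            cpg=is_cpg_site(model, v),
            substitution_class=substitution_class(v.ref_allele, v.alt_allele),
        )
    # exonic indel
    net = v.net_length_change()
    if net % 3 != 0:
        return AnnotatedVariant(
            v,
            "frameshift",
            exon,
            domain,
            hidden_ptc=first_hidden_ptc(model, v),
        )
    return AnnotatedVariant(v, "inframe_indel", exon, domain)


_CODON_TABLE: dict[str, str] = {}


def _aa(codon: str) -> str:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE[codon]
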