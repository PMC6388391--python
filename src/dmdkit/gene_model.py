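"""Transcript model: exon table, CDS sequence and protein-domain spans.

All public interfaces speak 1-based coding (HGVS ``c.``) coordinates counted
over the CDS only; untranslated regions are not part of the coordinate map
(UTR variants are handled as a distinct class by the variant parser).

The dystrophin transcript this layout mirrors has 79 exons and four protein
domains: the actin-binding domain (ABD, exons 1-8), the central rod domain
(RD, exons 9-62), the cysteine-rich domain (CRD, exons 63-69) and the
C-terminal domain (CTD, exons 70-79).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO

from .errors import CoordinateError, ValidationError

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: Domain layout of the reference dystrophin transcript (79 exons).
DMD_DOMAIN_LAYOUT = (("ABD", 1, 8), ("RD", 9, 62), ("CRD", 63, 69), ("CTD", 70, 79))


@dataclass(frozen=True)
class ExonDef:
    """Coding portion of one exon.

    ``cds_start``/``cds_end`` are 1-based inclusive coding coordinates;
    ``start_phase`` is the cumulative preceding coding length mod 3.
    """

    index: int
    cds_start: int
    cds_end: int
    start_phase: int = 0

    @property
    def coding_length(self) -> int:
        return self.cds_end - self.cds_start + 1


@dataclass(frozen=True)
class DomainSpan:
    name: str
    first_exon: int
    last_exon: int

    def __post_init__(self) -> None:
        if self.first_exon > self.last_exon:
            raise ValidationError(
                f"domain {self.name}: first_exon {self.first_exon} > last_exon {self.last_exon}"
            )


@dataclass(frozen=True)
class TranscriptModel:
    """Validated exon table + CDS + domain map for one transcript."""

    transcript_label: str
    exons: tuple[ExonDef, ...]
    cds_sequence: str
    domains: tuple[DomainSpan, ...]
    provenance: Literal["real", "synthetic"] = "synthetic"
    _starts: tuple[int, ...] = field(init=False, repr=False, compare=False, default=())

    def __post_init__(self) -> None:
        _validate_model(self)
        object.__setattr__(self, "_starts", tuple(e.cds_start for e in self.exons))

    # -- basic properties -------------------------------------------------

    @property
    def coding_length(self) -> int:
        return len(self.cds_sequence)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon(self, index: int) -> ExonDef:
        if not 1 <= index <= self.n_exons:
            raise CoordinateError(f"exon index {index} outside 1..{self.n_exons}")
        return self.exons[index - 1]

    # -- coordinate queries ------------------------------------------------

    def exon_of_coding_position(self, pos: int) -> int:
        """Exon index whose coding span contains 1-based position ``pos``."""
        if not 1 <= pos <= self.coding_length:
            raise CoordinateError(
                f"coding position {pos} outside 1..{self.coding_length}"
            )
        i = bisect.bisect_right(self._starts, pos)
        return i  # exon i (1-based) since spans are contiguous and ordered

    def domain_of_exon(self, exon: int) -> str:
        if not 1 <= exon <= self.n_exons:
            raise CoordinateError(f"exon {exon} outside 1..{self.n_exons}")
        for d in self.domains:
            if d.first_exon <= exon <= d.last_exon:
                return d.name
        raise ValidationError(f"exon {exon} not covered by any domain span")

    def cumulative_phase(self, exon: int) -> int:
        """Cumulative coding length of exons before ``exon``, mod 3.

        ``exon`` may be N+1, meaning the phase after the last exon (always 0
        for a valid model).
        """
        if not 1 <= exon <= self.n_exons + 1:
            raise CoordinateError(f"exon {exon} outside 1..{self.n_exons + 1}")
        if exon == self.n_exons + 1:
            return self.coding_length % 3
        return (self.exons[exon - 1].cds_start - 1) % 3

    def codon(self, codon_index: int) -> str:
        """1-based codon lookup in the CDS."""
        if not 1 <= codon_index <= self.coding_length // 3:
            raise CoordinateError(f"codon {codon_index} outside CDS")
        return self.cds_sequence[3 * (codon_index - 1) : 3 * codon_index]


def _validate_model(m: TranscriptModel) -> None:
    seq = m.cds_sequence
    if set(seq) - set("ACGT"):
        bad = sorted(set(seq) - set("ACGT"))
        raise ValidationError(f"CDS contains non-ACGT characters: {bad}")
    if len(seq) % 3 != 0:
        raise ValidationError(f"CDS length {len(seq)} not divisible by 3")
    if not seq.startswith("ATG"):
        raise ValidationError("CDS does not begin with ATG")
    if seq[-3:] not in STOP_CODONS:
        raise ValidationError(f"CDS final codon {seq[-3:]} is not a stop codon")
    if not m.exons:
        raise ValidationError("empty exon table")
    expected_start = 1
    phase = 0
    for k, e in enumerate(m.exons, start=1):
        if e.index != k:
            raise ValidationError(f"exon indices not contiguous at position {k}")
        if e.cds_start != expected_start:
            raise ValidationError(
                f"exon {k}: coding span starts at {e.cds_start}, expected {expected_start}"
            )
        if e.cds_end < e.cds_start:
            raise ValidationError(f"exon {k}: empty or inverted coding span")
        if e.start_phase != phase:
            raise ValidationError(
                f"exon {k}: start_phase {e.start_phase} != cumulative phase {phase}"
            )
        phase = (phase + e.coding_length) % 3
        expected_start = e.cds_end + 1
    total = expected_start - 1
    if total != len(seq):
        raise ValidationError(
            f"exon coding lengths sum to {total} but CDS length is {len(seq)}"
        )
    # domain spans partition 1..N
    covered: list[int] = []
    for d in m.domains:
        covered.extend(range(d.first_exon, d.last_exon + 1))
    if sorted(covered) != list(range(1, len(m.exons) + 1)):
        raise ValidationError("domain spans do not partition the exon range")


def make_model(
    label: str,
    coding_lengths: Sequence[int],
    cds_sequence: str,
    domains: Iterable[tuple[str, int, int]] | None = None,
    provenance: Literal["real", "synthetic"] = "synthetic",
) -> TranscriptModel:
    """Build a model from per-exon coding lengths (convenience constructor)."""
    exons = []
    start = 1
    phase = 0
    for i, ln in enumerate(coding_lengths, start=1):
        exons.append(ExonDef(i, start, start + ln - 1, start_phase=phase))
        start += ln
        phase = (phase + ln) % 3
    if domains is None:
        domains = proportional_domains(len(exons))
    spans = tuple(DomainSpan(n, a, b) for n, a, b in domains)
    return TranscriptModel(label, tuple(exons), cds_sequence, spans, provenance)


def proportional_domains(n_exons: int) -> tuple[tuple[str, int, int], ...]:
    """Assign the four-domain dystrophin layout proportionally to ``n_exons``.

    For 79 exons this reproduces the reference layout exactly.
    """
    if n_exons < 4:
        raise ValidationError("need at least 4 exons for a four-domain layout")
    b1 = min(max(round(n_exons * 8 / 79), 1), n_exons - 3)
    b2 = min(max(round(n_exons * 62 / 79), b1 + 1), n_exons - 2)
    b3 = min(max(round(n_exons * 69 / 79), b2 + 1), n_exons - 1)
    return (
        ("ABD", 1, b1),
        ("RD", b1 + 1, b2),
        ("CRD", b2 + 1, b3),
        ("CTD", b3 + 1, n_exons),
    )


# -- loading -----------------------------------------------------------------


def load_transcript_model(
    *,
    cds_fasta: str | Path | None = None,
    exon_table: str | Path | None = None,
    genbank: str | Path | None = None,
    transcript_label: str | None = None,
    provenance: Literal["real", "synthetic"] = "real",
) -> TranscriptModel:
    """Load a transcript model from reference files.

    Two layouts are supported: a single-record CDS FASTA plus a tab-separated
    exon table with columns ``exon_index``, ``cds_start``, ``cds_end``
    (1-based inclusive), or a GenBank flat record whose CDS feature and
    ``exon`` features carry the same information.
    """
    if genbank is not None:
        return _load_genbank(Path(genbank), provenance)
    if cds_fasta is None or exon_table is None:
        raise ValidationError("provide either genbank= or both cds_fasta= and exon_table=")
    records = list(SeqIO.parse(str(cds_fasta), "fasta"))
    if len(records) != 1:
        raise ValidationError(f"expected a single-record FASTA, found {len(records)}")
    seq = str(records[0].seq).upper()
    label = transcript_label or records[0].id
    rows = _read_exon_table(Path(exon_table))
    lengths = [end - start + 1 for _, start, end in rows]
    starts = [start for _, start, end in rows]
    # validate the table's own spans before rebuilding
    exp = 1
    for (idx, start, end), ln in zip(rows, lengths):
        if start != exp:
            raise ValidationError(
                f"exon {idx}: span starts at {start}, expected {exp} (gap or overlap)"
            )
        exp = end + 1
    del starts
    return make_model(label, lengths, seq, provenance=provenance)


def _read_exon_table(path: Path) -> list[tuple[int, int, int]]:
    rows = []
    for ln_no, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if ln_no == 1 and parts[0] == "exon_index":
            continue
        if len(parts) < 3:
            raise ValidationError(f"{path}:{ln_no}: expected 3 tab-separated columns")
        try:
            rows.append((int(parts[0]), int(parts[1]), int(parts[2])))
        except ValueError as exc:
            raise ValidationError(f"{path}:{ln_no}: non-integer field") from exc
    rows.sort()
    if [r[0] for r in rows] != list(range(1, len(rows) + 1)):
        raise ValidationError(f"{path}: exon indices are not 1..N contiguous")
    return rows


def _load_genbank(path: Path, provenance: str) -> TranscriptModel:
    record = SeqIO.read(str(path), "genbank")
    cds_feats = [f for f in record.features if f.type == "CDS"]
    if len(cds_feats) != 1:
        raise ValidationError(f"{path}: expected exactly one CDS feature")
    cds = cds_feats[0]
    cds_start = int(cds.location.start)  # 0-based on the record
    cds_end = int(cds.location.end)
    seq = str(record.seq[cds_start:cds_end]).upper()
    lengths = []
    for f in record.features:
        if f.type != "exon":
            continue
        a = max(int(f.location.start), cds_start)
        b = min(int(f.location.end), cds_end)
        if b > a:
            lengths.append(b - a)
    if not lengths:
        raise ValidationError(f"{path}: no exon features overlapping the CDS")
    return make_model(record.id, lengths, seq, provenance=provenance)  # type: ignore[arg-type]


def write_exon_table(model: TranscriptModel, path: str | Path) -> None:
    lines = ["exon_index\tcds_start\tcds_end"]
    lines += [f"{e.index}\t{e.cds_start}\t{e.cds_end}" for e in model.exons]
    Path(path).write_text("\n".join(lines) + "\n")


def write_cds_fasta(model: TranscriptModel, path: str | Path) -> None:
    body = "\n".join(
        model.cds_sequence[i : i + 60] for i in range(0, len(model.cds_sequence), 60)
    )
    Path(path).write_text(f">{model.transcript_label}\n{body}\n")
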