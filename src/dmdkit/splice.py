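"""Splicing-regulatory-element (SRE) scanning and the splicing grade.

An exonic substitution can disturb splicing by creating an exonic splicing
silencer (ESS) or destroying an exonic splicing enhancer (ESE).  The binary
SRE-change score is 1 when either event is detected and 0 otherwise; the
splicing classification grade multiplies that score by the in-frame flag of
the host exon (1 when skipping the exon preserves the reading frame).
Grade 1 marks potential for *beneficial* spontaneous exon skipping; grade 0
means no skipping, or skipping that would shift the frame.

The packaged motif library is a deliberately small, versioned approximation:
four consensus-derived enhancer weight matrices (motif lengths matching the
classic SR-protein profiles) and a silencer hexamer word set.  Scans over it
are deterministic, but it is not a replica of any web predictor's rule set;
when per-variant calls from an external predictor are available they can be
supplied as an override table, which is the fidelity path.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .errors import ContractError, ValidationError
from .gene_model import TranscriptModel
from .hgvs import CodingVariant, format_hgvs, parse_hgvs
from .skipping import is_inframe_skip
from .errors import UnsupportedSkipError

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class EseMatrix:
    name: str
    weights: np.ndarray  # shape (4, L), rows A,C,G,T
    threshold: float

    @property
    def length(self) -> int:
        return self.weights.shape[1]

    def score(self, word: str) -> float:
        return float(
            sum(self.weights[_BASE_INDEX[b], j] for j, b in enumerate(word))
        )

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.weights.argmax(axis=0))


@dataclass(frozen=True)
class SreMotifLibrary:
    ese_matrices: tuple[EseMatrix, ...]
    ess_words: frozenset[str]
    version_tag: str

    def __post_init__(self) -> None:
        if not self.ess_words:
            raise ValidationError("empty ESS word set")
        if any(m.length < 1 for m in self.ese_matrices):
            raise ValidationError("ESE matrix with no columns")
        if any(not np.isfinite(m.threshold) for m in self.ese_matrices):
            raise ValidationError("non-finite ESE threshold")

    @property
    def max_motif_length(self) -> int:
        word_len = max(map(len, self.ess_words))
        mat_len = max((m.length for m in self.ese_matrices), default=0)
        return max(word_len, mat_len)


@dataclass(frozen=True)
class MotifHit:
    kind: Literal["ESS", "ESE"]
    name: str       # ESS: the word itself; ESE: matrix name
    offset: int     # 0-based start within the scanned window
    length: int
    score: float    # ESS hits score 1.0 (exact match)


def scan_sre(window: str, lib: SreMotifLibrary) -> list[MotifHit]:
    """All ESS word matches and above-threshold ESE matrix hits in a window."""
    if set(window) - set("ACGT"):
        raise ValidationError("window contains non-ACGT characters")
    hits: list[MotifHit] = []
    for word in sorted(lib.ess_words):
        L = len(word)
        start = window.find(word)
        while start != -1:
            hits.append(MotifHit("ESS", word, start, L, 1.0))
            start = window.find(word, start + 1)
    for mat in lib.ese_matrices:
        L = mat.length
        for off in range(len(window) - L + 1):
            s = mat.score(window[off : off + L])
            if s >= mat.threshold:
                hits.append(MotifHit("ESE", mat.name, off, L, s))
    hits.sort(key=lambda h: (h.offset, h.kind, h.name))
    return hits


@dataclass(frozen=True)
class SreChangeReport:
    gained_ess: tuple[tuple[str, int], ...]                      # (word, offset)
    lost_ese: tuple[tuple[str, int, float, float], ...]          # (name, offset, ref, alt)
    hsf_score: int

    def __post_init__(self) -> None:
        expected = 1 if (self.gained_ess or self.lost_ese) else 0
        if self.hsf_score != expected:
            raise ValidationError("hsf_score inconsistent with gained/lost lists")


def sre_change(
    ref_window: str, alt_window: str, var_offset: int, lib: SreMotifLibrary
) -> SreChangeReport:
    """Diff motif hits between a reference and a mutant window.

    A 'new ESS' is a silencer hit present in the mutant but not at the same
    offset in the reference; a 'broken ESE' is an above-threshold enhancer
    hit overlapping the variant in the reference that is no longer a hit at
    the same offset in the mutant.  A hit merely shifting position counts as
    one lost plus one gained (simplest deterministic diff).
    """
    if len(ref_window) != len(alt_window):
        raise ContractError("windows must have equal length (substitutions only)")
    ref_hits = scan_sre(ref_window, lib)
    alt_hits = scan_sre(alt_window, lib)
    ref_ess = {(h.name, h.offset) for h in ref_hits if h.kind == "ESS"}
    alt_ess = {(h.name, h.offset) for h in alt_hits if h.kind == "ESS"}
    gained = tuple(sorted(alt_ess - ref_ess))
    alt_ese = {(h.name, h.offset) for h in alt_hits if h.kind == "ESE"}
    matrices = {m.name: m for m in lib.ese_matrices}
    lost = []
    for h in ref_hits:
        if h.kind != "ESE":
            continue
        if not (h.offset <= var_offset < h.offset + h.length):
            continue  # must overlap the variant to be 'broken' by it
        if (h.name, h.offset) in alt_ese:
            continue
        alt_score = matrices[h.name].score(
            alt_window[h.offset : h.offset + h.length]
        )
        lost.append((h.name, h.offset, h.score, alt_score))
    lost_t = tuple(sorted(lost))
    return SreChangeReport(gained, lost_t, 1 if (gained or lost_t) else 0)


def hsf_change_score(
    model: TranscriptModel, v: CodingVariant | str, lib: SreMotifLibrary
) -> SreChangeReport:
    """Binary SRE-change score for an exonic substitution.

    The scanned window is centered on the variant with radius (longest motif
    - 1) and truncated at the host exon's coding boundaries — SREs are
    exonic elements, so intronic flank is never scanned.
    """
    if isinstance(v, str):
        v = parse_hgvs(v)
    if v.kind != "substitution" or not v.start.is_exonic or v.start.anchor != "cds":
        raise ContractError(f"{v.raw}: SRE-change score is defined for exonic substitutions")
    pos = v.start.base
    exon = model.exon(model.exon_of_coding_position(pos))
    radius = lib.max_motif_length - 1
    lo = max(exon.cds_start, pos - radius)
    hi = min(exon.cds_end, pos + radius)
    ref_window = model.cds_sequence[lo - 1 : hi]
    k = pos - lo
    if ref_window[k] != v.ref_allele:
        from .errors import ReferenceMismatchError

        raise ReferenceMismatchError(
            f"{v.raw}: reference base at c.{pos} is {ref_window[k]}, not {v.ref_allele}"
        )
    alt_window = ref_window[:k] + v.alt_allele + ref_window[k + 1 :]
    return sre_change(ref_window, alt_window, k, lib)


@dataclass(frozen=True)
class SpliceGrade:
    orf_flag: int
    hsf_score: int
    grade: int

    def __post_init__(self) -> None:
        if self.grade != self.orf_flag * self.hsf_score:
            raise ValidationError("grade != orf_flag * hsf_score")


def splicing_grade(orf_flag: int, hsf_score: int) -> SpliceGrade:
    """Grade = in-frame flag x binary SRE-change score (both in {0,1})."""
    if orf_flag not in (0, 1) or hsf_score not in (0, 1):
        raise ContractError("orf_flag and hsf_score must be 0 or 1")
    return SpliceGrade(orf_flag, hsf_score, orf_flag * hsf_score)


def grade_variant(
    model: TranscriptModel,
    v: CodingVariant | str,
    lib: Optional[SreMotifLibrary] = None,
    override: Optional[pd.DataFrame] = None,
) -> SpliceGrade:
    """Splicing classification grade of an exonic substitution.

    The in-frame flag is 1 when skipping the host exon preserves the reading
    frame (terminal exons, which cannot be skipped, score 0).  The SRE score
    comes from the motif library, or from an ``override`` table (columns
    ``hgvs_c``, ``new_ess``, ``broken_ese``) when supplied — the override
    wins when both are given.
    """
    if isinstance(v, str):
        v = parse_hgvs(v)
    host = model.exon_of_coding_position(v.start.base)
    try:
        orf = is_inframe_skip(model, {host})
    except UnsupportedSkipError:
        orf = 0  # terminal exon: skipping cannot be beneficial
    if override is not None:
        key = format_hgvs(v)
        rows = override.loc[override["hgvs_c"].isin([key, v.raw])]
        if rows.empty:
            raise ValidationError(
                f"override table has no row for {key} and no motif library was used"
            )
        r = rows.iloc[0]
        hsf = 1 if (int(r["new_ess"]) or int(r["broken_ese"])) else 0
    elif lib is not None:
        hsf = hsf_change_score(model, v, lib).hsf_score
    else:
        raise ValidationError("supply a motif library or an override table")
    return splicing_grade(orf, hsf)


# -- library IO --------------------------------------------------------------


def load_motif_library(path: str | Path) -> SreMotifLibrary:
    """Read a motif library from the versioned tab-separated format."""
    words: set[str] = set()
    matrices: list[EseMatrix] = []
    version = "unversioned"
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if line.startswith("#version"):
            version = line.split(None, 1)[1].strip()
        elif line.startswith("#"):
            continue
        elif line.startswith("WORDS"):
            while i < len(lines) and lines[i].strip() and not lines[i].startswith(
                ("MATRIX", "WORDS", "#")
            ):
                w = lines[i].strip()
                if set(w) - set("ACGT"):
                    raise ValidationError(f"bad ESS word {w!r}")
                words.add(w)
                i += 1
        elif line.startswith("MATRIX"):
            _, name, thr = line.split("\t")
            rows = {}
            for _ in range(4):
                parts = lines[i].strip().split("\t")
                rows[parts[0]] = [float(x) for x in parts[1:]]
                i += 1
            weights = np.array([rows[b] for b in "ACGT"])
            matrices.append(EseMatrix(name, weights, float(thr)))
        else:
            raise ValidationError(f"unrecognized library line: {line!r}")
    return SreMotifLibrary(tuple(matrices), frozenset(words), version)


def default_library() -> SreMotifLibrary:
    """The packaged simplified SRE library."""
    ref = resources.files("dmdkit").joinpath("data/sre_motifs_v1.tsv")
    with resources.as_file(ref) as path:
        return load_motif_library(path)


def load_override_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"hgvs_c", "new_ess", "broken_ese"} - set(df.columns)
    if missing:
        raise ValidationError(f"override table missing columns: {sorted(missing)}")
    return df
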