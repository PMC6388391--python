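"""Reading-frame checker and exon-skipping strategy planner.

The frame rule is length-based: removing a contiguous exon block leaves the
open reading frame intact iff the summed coding length of the block is a
multiple of 3 (equivalently, the cumulative phase before the block equals
the phase after it).  Stop codons created at the novel exon junction are not
part of the rule; a diagnostic flag reports them without affecting results.

Strategies are minimal contiguous in-frame blocks of at most ``cap`` exons
(default 3) containing the mutated exon.  The first and last coding exons
are unskippable (start codon, stop codon / 3' end); patients whose mutation
lies there count as uncovered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import UnsupportedSkipError, ValidationError
from .gene_model import STOP_CODONS, TranscriptModel


def is_inframe_skip(model: TranscriptModel, exon_set: Iterable[int]) -> int:
    """1 if removing ``exon_set`` preserves the reading frame, else 0."""
    exons = sorted(set(exon_set))
    if not exons:
        raise ValidationError("empty exon set")
    for e in exons:
        model.exon(e)  # range check
    if 1 in exons or model.n_exons in exons:
        raise UnsupportedSkipError(
            "cannot skip the first or last coding exon (start/stop codon loss)"
        )
    total = sum(model.exon(e).coding_length for e in exons)
    return 1 if total % 3 == 0 else 0


def junction_creates_stop(model: TranscriptModel, first: int, last: int) -> bool:
    """Diagnostic: does joining exon first-1 to exon last+1 create a stop codon?

    Only meaningful for in-frame blocks; checks the codons spanning the novel
    junction in the skipped transcript.
    """
    cds = model.cds_sequence
    left_end = model.exon(first).cds_start - 1   # last kept base before block
    right_start = model.exon(last).cds_end       # first kept base index (0-based) after
    skipped = cds[:left_end] + cds[right_start:]
    phase = left_end % 3
    start = left_end - phase
    for i in range(start, min(start + 6, len(skipped) - 2), 3):
        if skipped[i : i + 3] in STOP_CODONS:
            return True
    return False


@dataclass(frozen=True)
class SkipPlan:
    """Minimal in-frame skip blocks for one mutated exon."""

    mutated_exon: int
    candidate_blocks: tuple[tuple[tuple[int, int], int], ...]  # ((first,last), in_frame)
    minimal_blocks: tuple[tuple[int, int], ...]
    selected_block: Optional[tuple[int, int]]
    strategy_size: Optional[int]
    junction_stop: bool = False

    @property
    def covered(self) -> bool:
        return self.selected_block is not None


def skip_plans(model: TranscriptModel, mutated_exon: int, cap: int = 3) -> SkipPlan:
    """Enumerate contiguous blocks of size <= cap containing the mutated exon.

    Minimal in-frame blocks are those of smallest size; among equals the
    tie-break prefers the smallest total skipped coding length, then the
    lowest starting exon (preserves the most protein, deterministic).
    """
    model.exon(mutated_exon)
    if mutated_exon in (1, model.n_exons):
        raise UnsupportedSkipError(
            f"exon {mutated_exon} is the first or last coding exon and cannot be skipped"
        )
    candidates: list[tuple[tuple[int, int], int]] = []
    for size in range(1, cap + 1):
        for first in range(mutated_exon - size + 1, mutated_exon + 1):
            last = first + size - 1
            if first < 2 or last > model.n_exons - 1:
                continue  # clipped at gene ends / unskippable terminal exons
            block = (first, last)
            try:
                flag = is_inframe_skip(model, range(first, last + 1))
            except UnsupportedSkipError:
                continue
            candidates.append((block, flag))
    inframe = [b for b, f in candidates if f]
    if not inframe:
        return SkipPlan(mutated_exon, tuple(candidates), (), None, None)
    min_size = min(b[1] - b[0] + 1 for b in inframe)
    minimal = tuple(b for b in inframe if b[1] - b[0] + 1 == min_size)

    def block_length(b: tuple[int, int]) -> int:
        return sum(model.exon(e).coding_length for e in range(b[0], b[1] + 1))

    selected = min(minimal, key=lambda b: (block_length(b), b[0]))
    return SkipPlan(
        mutated_exon,
        tuple(candidates),
        minimal,
        selected,
        min_size,
        junction_stop=junction_creates_stop(model, *selected),
    )


def plan_for_variant(model: TranscriptModel, annotated, cap: int = 3) -> Optional[SkipPlan]:
    """Skip plan for an annotated variant, or None when planning does not apply.

    Splicing variants are excluded entirely (they can themselves cause exon
    skipping or intron retention, making planned skipping unreliable); UTR
    variants have no host exon.  Terminal-exon mutations yield an uncovered
    plan rather than an error.
    """
    if annotated.consequence in ("splicing", "utr"):
        return None
    exon = annotated.host_exon
    try:
        return skip_plans(model, exon, cap=cap)
    except UnsupportedSkipError:
        return SkipPlan(exon, (), (), None, None)


@dataclass
class CoverageResult:
    n_patients: int
    coverage: dict[int, float]            # cap -> fraction covered by size<=cap
    block_ranking: pd.DataFrame = field(repr=False)


def cohort_skip_coverage(
    plans: Sequence[SkipPlan], weights: Sequence[int] | None = None
) -> CoverageResult:
    """Cumulative coverage of single/double/triple skipping and block ranking.

    ``plans`` carries one entry per eligible patient (truncating or missense
    mutation); ``weights`` multiplies patients carrying the same plan.
    """
    if not plans:
        raise ValidationError("empty cohort: no skip plans to summarize")
    if weights is None:
        weights = [1] * len(plans)
    if len(weights) != len(plans):
        raise ValidationError("weights length does not match plans")
    total = sum(weights)
    max_cap = 3
    cov = {}
    for cap in range(1, max_cap + 1):
        covered = sum(
            w
            for p, w in zip(plans, weights)
            if p.strategy_size is not None and p.strategy_size <= cap
        )
        cov[cap] = 100.0 * covered / total
    rows: dict[tuple[int, int], int] = {}
    for p, w in zip(plans, weights):
        if p.selected_block is not None:
            rows[p.selected_block] = rows.get(p.selected_block, 0) + w
    ranking = pd.DataFrame(
        [
            {
                "first_exon": b[0],
                "last_exon": b[1],
                "strategy_size": b[1] - b[0] + 1,
                "n_patients": n,
                "pct_patients": 100.0 * n / total,
            }
            for b, n in rows.items()
        ]
    )
    if not ranking.empty:
        ranking = ranking.sort_values(
            ["n_patients", "first_exon"], ascending=[False, True]
        ).reset_index(drop=True)
    return CoverageResult(total, cov, ranking)
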