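"""Synthetic transcripts and cohorts.

The generator emulates the statistical structure of a small-mutation
dystrophinopathy cohort: the mutation-class mixture (~52/24/17/5/1 %
nonsense/splicing/frameshift/missense/UTR), CpG enrichment among nonsense
changes, a grade-to-phenotype effect with a configurable odds ratio, a
truncating-vs-non-truncating severity effect, and age-dependent serum
creatinine separation between the severe (DMD/IMD) and mild (BMD) groups.
Every simulated variant is emitted as a coding-HGVS string that round-trips
through the parser and re-annotates to its intended class.

All randomness flows from one seeded generator; a fixed seed reproduces the
cohort bit-for-bit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import is_cpg_site  # noqa: F401  (re-exported convenience)
from .errors import ValidationError
from .gene_model import (
    STOP_CODONS,
    TranscriptModel,
    load_transcript_model,
    make_model,
    write_cds_fasta,
    write_exon_table,
)
from .hgvs import parse_hgvs
from .splice import SreMotifLibrary, default_library, grade_variant

_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)


def make_synthetic_transcript(
    n_exons: int,
    length_spec: Optional[Sequence[int]] = None,
    seed: int = 0,
    label: str = "SYNTH",
) -> TranscriptModel:
    """Random valid transcript model with no internal in-frame stop codons.

    ``length_spec`` fixes per-exon coding lengths; otherwise lengths are
    sampled in the 60-240 nt range with roughly half of exons a multiple of
    3 (mirroring the roughly even split of frame-preserving exons in the
    dystrophin gene).  The last exon is adjusted so the total is divisible
    by 3.  Domains follow the four-domain layout proportionally.
    """
    if n_exons < 3:
        raise ValidationError("need at least 3 exons")
    rng = np.random.default_rng(seed)
    if length_spec is not None:
        lengths = list(int(x) for x in length_spec)
        if len(lengths) != n_exons:
            raise ValidationError("length_spec size differs from n_exons")
        if any(x < 3 for x in lengths):
            raise ValidationError("exon coding lengths must be >= 3")
        if sum(lengths) % 3 != 0:
            raise ValidationError("length_spec total must be divisible by 3")
    else:
        lengths = []
        for _ in range(n_exons):
            base = 3 * int(rng.integers(20, 81))
            if rng.random() < 0.45:  # out-of-frame exon
                base += int(rng.integers(1, 3))
            lengths.append(base)
        lengths[-1] += (3 - sum(lengths) % 3) % 3
    n_codons = sum(lengths) // 3
    body = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
    codons = ["ATG"] + [_SENSE_CODONS[i] for i in body] + [
        ("TAA", "TAG", "TGA")[int(rng.integers(3))]
    ]
    cds = "".join(codons)
    return make_model(label, lengths, cds, provenance="synthetic")


def dmd_like_transcript(seed: int = 0) -> TranscriptModel:
    """A 79-exon synthetic stand-in with the dystrophin domain layout."""
    return make_synthetic_transcript(79, seed=seed, label=f"SYNTH-DMD-79.{seed}")


@dataclass(frozen=True)
class ScrnParams:
    """Age-linear Gaussian model for serum creatinine (µmol/L).

    ``severe_unit_or`` is the per-unit odds ratio of the severe phenotype
    implied by the within-age Gaussian shift: with equal residual sd, the
    logistic slope of severe vs SCRN equals shift/sd^2, so the shift is
    derived as ln(OR) * sd^2.
    """

    intercept: float = 15.0
    age_slope: float = 1.3
    sd: float = 1.5
    severe_unit_or: float = 1.9

    @property
    def severe_shift(self) -> float:
        return math.log(self.severe_unit_or) * self.sd**2


@dataclass(frozen=True)
class CohortSimulationParams:
    n_patients: int = 115
    class_mixture: tuple[float, ...] = (0.52, 0.24, 0.17, 0.05, 0.01, 0.01)
    """nonsense, splicing, frameshift, missense, utr, other(synonymous)."""
    cpg_enrichment: float = 0.42
    grade_phenotype_or: float = 12.0
    truncating_phenotype_or: float = 1 / 0.314
    grade1_severe_prob: float = 0.52
    imd_fraction_of_severe: float = 0.106
    scrn_model: ScrnParams = field(default_factory=ScrnParams)
    pending_rate: float = 0.15
    missing_scrn_rate: float = 0.12
    biopsy_rate: float = 0.22
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if abs(sum(self.class_mixture) - 1.0) > 1e-9:
            raise ValidationError("class mixture must sum to 1")
        for name in ("cpg_enrichment", "pending_rate", "missing_scrn_rate", "biopsy_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")


_CLASSES = ("nonsense", "splicing", "frameshift", "missense", "utr", "other")


class _SitePools:
    """Per-model caches: nonsense-capable sites split by CpG context, and
    per-site splicing grades (computed once through the real grade pipeline)."""

    def __init__(self, model: TranscriptModel, lib: SreMotifLibrary):
        self.model = model
        self.lib = lib
        cds = model.cds_sequence
        cpg_pool: list[tuple[int, str, str]] = []
        plain_pool: list[tuple[int, str, str]] = []
        n_codons = len(cds) // 3
        for ci in range(2, n_codons):  # skip start and stop codons
            codon = cds[3 * (ci - 1) : 3 * ci]
            for cp in range(3):
                pos = 3 * (ci - 1) + cp + 1
                ref = codon[cp]
                for alt in "ACGT":
                    if alt == ref:
                        continue
                    mut = codon[:cp] + alt + codon[cp + 1 :]
                    if mut not in STOP_CODONS:
                        continue
                    is_cpg = (ref == "C" and pos < len(cds) and cds[pos] == "G") or (
                        ref == "G" and pos > 1 and cds[pos - 2] == "C"
                    )
                    (cpg_pool if is_cpg else plain_pool).append((pos, ref, alt))
        if not cpg_pool or not plain_pool:
            raise ValidationError("model too small to host nonsense variants")
        self.cpg_pool = cpg_pool
        self.plain_pool = plain_pool
        self._grades: dict[tuple[int, str], int] = {}

    def grade(self, pos: int, ref: str, alt: str) -> int:
        key = (pos, alt)
        if key not in self._grades:
            g = grade_variant(self.model, f"c.{pos}{ref}>{alt}", lib=self.lib)
            self._grades[key] = g.grade
        return self._grades[key]


_POOL_CACHE: dict[tuple[int, str], _SitePools] = {}


def _pools(model: TranscriptModel, lib: SreMotifLibrary) -> _SitePools:
    key = (id(model), lib.version_tag)
    if key not in _POOL_CACHE:
        if len(_POOL_CACHE) > 8:
            _POOL_CACHE.clear()
        _POOL_CACHE[key] = _SitePools(model, lib)
    return _POOL_CACHE[key]


_SPLICE_OFFSETS = (1, 2, 3, 4, 5)
_SPLICE_OFFSET_P = (0.45, 0.30, 0.10, 0.08, 0.07)


def simulate_cohort(
    model: TranscriptModel,
    params: CohortSimulationParams = CohortSimulationParams(),
    lib: Optional[SreMotifLibrary] = None,
) -> pd.DataFrame:
    """Draw a synthetic patient cohort (one row per patient).

    Mutation class follows the mixture; nonsense sites are sampled from
    stop-capable codons respecting CpG enrichment and graded through the
    real SRE/frame pipeline; phenotype is a logistic draw calibrated so the
    population grade-to-phenotype odds ratio among nonsense patients equals
    ``grade_phenotype_or`` and the truncating-vs-non-truncating odds ratio
    matches its target; serum creatinine follows the age-linear Gaussian
    model given the (latent) severity.
    """
    if lib is None:
        lib = default_library()
    rng = np.random.default_rng(params.seed)
    pools = _pools(model, lib)
    cds = model.cds_sequence
    L = model.coding_length

    p1 = params.grade1_severe_prob
    odds1 = p1 / (1 - p1)
    odds0 = params.grade_phenotype_or * odds1
    p0 = odds0 / (1 + odds0)
    p_nontrunc = 0.5
    odds_t = params.truncating_phenotype_or * p_nontrunc / (1 - p_nontrunc)
    p_trunc = odds_t / (1 + odds_t)

    rows = []
    classes = rng.choice(len(_CLASSES), size=params.n_patients, p=params.class_mixture)
    for i, ci in enumerate(classes):
        cls = _CLASSES[ci]
        rec: dict = {
            "patient_id": f"S{i + 1:04d}",
            "mutation_class": cls,
            "host_exon": None,
            "domain": None,
            "grade": np.nan,
            "cpg": np.nan,
            "ptc_type": None,
            "indel_kind": None,
            "splice_side": None,
            "splice_conservation": None,
        }
        if cls == "nonsense":
            pool = pools.cpg_pool if rng.random() < params.cpg_enrichment else pools.plain_pool
            pos, ref, alt = pool[int(rng.integers(len(pool)))]
            rec["hgvs_c"] = f"c.{pos}{ref}>{alt}"
            rec["host_exon"] = model.exon_of_coding_position(pos)
            rec["cpg"] = pool is pools.cpg_pool
            cp = (pos - 1) % 3
            codon = cds[pos - 1 - cp : pos + 2 - cp]
            rec["ptc_type"] = codon[:cp] + alt + codon[cp + 1 :]
            rec["grade"] = pools.grade(pos, ref, alt)
            p_severe = p1 if rec["grade"] == 1 else p0
        elif cls == "frameshift":
            kind = "deletion" if rng.random() < 0.7 else "duplication"
            if kind == "deletion":
                k = int(rng.choice([1, 2, 4], p=[0.6, 0.25, 0.15]))
            else:
                k = 1
            pos = int(rng.integers(4, L - 60))
            if kind == "deletion":
                seq = cds[pos - 1 : pos + k - 1]
                rec["hgvs_c"] = (
                    f"c.{pos}del{seq}" if k == 1 else f"c.{pos}_{pos + k - 1}del{seq}"
                )
            else:
                rec["hgvs_c"] = f"c.{pos}dup{cds[pos - 1]}"
            rec["indel_kind"] = kind
            rec["host_exon"] = model.exon_of_coding_position(pos)
            from .annotate import first_hidden_ptc

            hp = first_hidden_ptc(model, parse_hgvs(rec["hgvs_c"]))
            rec["ptc_type"] = hp.stop if hp else "none"
            p_severe = p_trunc
        elif cls == "splicing":
            off = int(rng.choice(_SPLICE_OFFSETS, p=_SPLICE_OFFSET_P))
            if rng.random() < 0.5:  # donor side
                e = int(rng.integers(1, model.n_exons))
                pos = model.exon(e).cds_end
                ref = "G" if off == 1 else ("T" if off == 2 else "ACGT"[int(rng.integers(4))])
                alt = _other_base(rng, ref)
                rec["hgvs_c"] = f"c.{pos}+{off}{ref}>{alt}"
                rec["splice_side"] = "donor"
            else:
                e = int(rng.integers(2, model.n_exons + 1))
                pos = model.exon(e).cds_start
                ref = "G" if off == 1 else ("A" if off == 2 else "ACGT"[int(rng.integers(4))])
                alt = _other_base(rng, ref)
                rec["hgvs_c"] = f"c.{pos}-{off}{ref}>{alt}"
                rec["splice_side"] = "acceptor"
            rec["splice_conservation"] = "core_1_2" if off <= 2 else "near_3_5"
            rec["host_exon"] = e
            p_severe = p_nontrunc
        elif cls == "missense":
            pos, ref, alt = _sample_missense(rng, cds)
            rec["hgvs_c"] = f"c.{pos}{ref}>{alt}"
            rec["host_exon"] = model.exon_of_coding_position(pos)
            p_severe = p_nontrunc
        elif cls == "utr":
            k = int(rng.integers(1, 200))
            ref = "ACGT"[int(rng.integers(4))]
            rec["hgvs_c"] = f"c.-{k}{ref}>{_other_base(rng, ref)}"
            p_severe = p_nontrunc
        else:  # 'other': synonymous substitution
            pos, ref, alt = _sample_synonymous(rng, cds)
            rec["hgvs_c"] = f"c.{pos}{ref}>{alt}"
            rec["host_exon"] = model.exon_of_coding_position(pos)
            p_severe = p_nontrunc
        if rec["host_exon"] is not None:
            rec["domain"] = model.domain_of_exon(int(rec["host_exon"]))

        severe = rng.random() < p_severe
        if severe:
            phen = "IMD" if rng.random() < params.imd_fraction_of_severe else "DMD"
        else:
            phen = "BMD"
        pending = rng.random() < params.pending_rate
        age_exam = round(float(rng.uniform(1.0, 16.0)), 1)
        sm = params.scrn_model
        scrn = sm.intercept + sm.age_slope * age_exam + sm.severe_shift * severe
        scrn = round(max(2.0, scrn + float(rng.normal(0, sm.sd))), 2)
        if rng.random() < params.missing_scrn_rate:
            scrn = np.nan
        ck = round(float(np.exp(rng.normal(9.3 if severe else 8.6, 0.5))), 0)
        rec.update(
            phenotype="pending" if pending else phen,
            latent_severe=bool(severe),
            age_exam=age_exam,
            age_onset=round(float(rng.uniform(1, 5) if severe else rng.uniform(2, 9)), 1),
            age_loa=np.nan,
            ambulant=True,
            scrn=scrn,
            ck=ck,
            mother_carrier=(
                "unknown"
                if rng.random() < 0.2
                else ("carrier" if rng.random() < 0.66 else "non_carrier")
            ),
            pathogenicity_ok=True,
        )
        if phen == "DMD" and age_exam > 10 and not pending:
            rec["age_loa"] = round(float(rng.uniform(8.0, 12.9)), 1)
            rec["ambulant"] = False
        elif phen == "IMD" and age_exam > 14 and not pending:
            rec["age_loa"] = round(float(rng.uniform(13.0, 15.9)), 1)
            rec["ambulant"] = False
        if rng.random() < params.biopsy_rate:
            if cls == "nonsense":
                if rec["grade"] == 1:
                    rec["dystrophin_staining"] = (
                        "patchy" if rng.random() < 0.5 else "absent"
                    )
                else:
                    rec["dystrophin_staining"] = "absent"
            else:
                rec["dystrophin_staining"] = (
                    "absent" if severe or rng.random() < 0.4 else "patchy"
                )
        else:
            rec["dystrophin_staining"] = "unknown"
        rows.append(rec)
    df = pd.DataFrame(rows)
    front = ["patient_id", "hgvs_c", "mutation_class", "phenotype"]
    return df[front + [c for c in df.columns if c not in front]]


def _other_base(rng: np.random.Generator, ref: str) -> str:
    others = [b for b in "ACGT" if b != ref]
    return others[int(rng.integers(3))]


def _sample_missense(rng: np.random.Generator, cds: str) -> tuple[int, str, str]:
    from .annotate import _aa

    n_codons = len(cds) // 3
    while True:
        ci = int(rng.integers(2, n_codons))
        cp = int(rng.integers(3))
        pos = 3 * (ci - 1) + cp + 1
        codon = cds[3 * (ci - 1) : 3 * ci]
        ref = codon[cp]
        alt = _other_base(rng, ref)
        mut = codon[:cp] + alt + codon[cp + 1 :]
        if mut not in STOP_CODONS and _aa(mut) != _aa(codon):
            return pos, ref, alt


def _sample_synonymous(rng: np.random.Generator, cds: str) -> tuple[int, str, str]:
    from .annotate import _aa

    n_codons = len(cds) // 3
    while True:
        ci = int(rng.integers(2, n_codons))
        codon = cds[3 * (ci - 1) : 3 * ci]
        cp = 2  # third position holds nearly all synonymous changes
        pos = 3 * (ci - 1) + cp + 1
        ref = codon[cp]
        alt = _other_base(rng, ref)
        mut = codon[:cp] + alt + codon[cp + 1 :]
        if mut not in STOP_CODONS and _aa(mut) == _aa(codon):
            return pos, ref, alt


def cohort_to_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic CSV emission (fixed column order, no index)."""
    df.to_csv(path, index=False)


def build_real_fixture(
    cds_fasta: str | Path,
    exon_table: str | Path,
    out_dir: str | Path,
    transcript_label: str = "NM_004006.2",
) -> TranscriptModel:
    """Validate user-supplied reference files and write a packaged fixture.

    A one-time path, outside the test suite: the reference CDS FASTA and
    exon table are supplied by the user (e.g. derived from the public
    dystrophin transcript record), validated, and re-written in the
    package's canonical exon-table + FASTA layout.  A file labelled as the
    dystrophin transcript is expected to carry 79 exons; any other count is
    a warning, not a failure.
    """
    model = load_transcript_model(
        cds_fasta=cds_fasta,
        exon_table=exon_table,
        transcript_label=transcript_label,
        provenance="real",
    )
    if "NM_004006" in transcript_label and model.n_exons != 79:
        warnings.warn(
            f"fixture labelled {transcript_label} has {model.n_exons} exons, expected 79",
            stacklevel=2,
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_exon_table(model, out / "exons.tsv")
    write_cds_fasta(model, out / "cds.fasta")
    return model
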