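"""End-to-end pipeline: annotate -> grade -> skip-plan -> cohort statistics.

Consumes a transcript model, a cohort CSV (column ``hgvs_c`` plus clinical
fields) and either a motif library or a per-variant override table; writes
tidy CSV outputs plus a single JSON report.  Every output table carries a
provenance comment (tool version, seed, input digests).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .annotate import classify_variant
from .errors import DmdKitError, ValidationError
from .gene_model import TranscriptModel, load_transcript_model
from .hgvs import parse_hgvs
from .skipping import cohort_skip_coverage, plan_for_variant
from .splice import (
    SreMotifLibrary,
    default_library,
    grade_variant,
    load_motif_library,
    load_override_table,
)
from .stats import add_severity, run_association, scrn_logistic
from .summaries import summarize_cohort

log = logging.getLogger("dmdkit")


@dataclass
class RunConfig:
    cohort: Path
    out_dir: Path
    model_cds: Optional[Path] = None
    model_exons: Optional[Path] = None
    motif_library: Optional[Path] = None
    override_table: Optional[Path] = None
    seed: int = 0
    hgvs_3prime: bool = False
    zero_correction: bool = False
    skip_cap: int = 3
    model: Optional[TranscriptModel] = field(default=None, repr=False)

    def resolve_model(self) -> TranscriptModel:
        if self.model is not None:
            return self.model
        if self.model_cds is None or self.model_exons is None:
            raise ValidationError("run config needs model_cds and model_exons (or model)")
        return load_transcript_model(
            cds_fasta=self.model_cds, exon_table=self.model_exons
        )

    def resolve_library(self) -> tuple[Optional[SreMotifLibrary], Optional[pd.DataFrame]]:
        if self.override_table is not None:
            return None, load_override_table(self.override_table)
        if self.motif_library is not None:
            return load_motif_library(self.motif_library), None
        return default_library(), None


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def _write(df: pd.DataFrame, path: Path, provenance: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {provenance}\n")
        df.to_csv(fh, index=False)


def annotate_cohort(
    model: TranscriptModel, cohort: pd.DataFrame, three_prime: bool = False
) -> pd.DataFrame:
    """Annotation table: one row per patient, one column per variant field."""
    from .annotate import normalize_indel

    rows = []
    for _, rec in cohort.iterrows():
        v = parse_hgvs(rec["hgvs_c"])
        if three_prime:
            v = normalize_indel(model, v, three_prime=True)
        ann = classify_variant(model, v)
        rows.append(
            {
                "patient_id": rec.get("patient_id", ""),
                "hgvs_c": rec["hgvs_c"],
                "mutation_class": ann.consequence,
                "host_exon": ann.host_exon,
                "domain": ann.domain,
                "codon_index": ann.codon_index,
                "codon_pos": ann.codon_pos,
                "ref_codon": ann.ref_codon,
                "alt_codon": ann.alt_codon,
                "ptc_type": (
                    ann.ptc
                    if ann.ptc != "none"
                    else (ann.hidden_ptc.stop if ann.hidden_ptc else None)
                ),
                "hidden_ptc_distance": (
                    ann.hidden_ptc.codons_from_site if ann.hidden_ptc else None
                ),
                "cpg": ann.cpg if ann.consequence in ("nonsense", "missense", "synonymous") else None,
                "substitution_class": ann.substitution_class,
                "splice_side": ann.splice.side if ann.splice else None,
                "splice_conservation": ann.splice.conservation if ann.splice else None,
                "indel_kind": (
                    ann.variant.kind if ann.consequence == "frameshift" else None
                ),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns it as a dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        model = config.resolve_model()
        lib, override = config.resolve_library()
        cohort = pd.read_csv(config.cohort, comment="#")
        if "hgvs_c" not in cohort.columns:
            raise ValidationError("cohort CSV lacks required column 'hgvs_c'")
        prov = (
            f"dmdkit {__version__} seed={config.seed} "
            f"cohort_sha={_digest(Path(config.cohort))} model={model.transcript_label}"
        )
        log.info("loaded cohort: %d rows; model %s (%d exons)",
                 len(cohort), model.transcript_label, model.n_exons)

        stage = "annotate"
        ann = annotate_cohort(model, cohort, three_prime=config.hgvs_3prime)
        _write(ann, out / "annotations.csv", prov)

        stage = "grade"
        grades = []
        for _, row in ann.iterrows():
            if row["mutation_class"] not in ("nonsense", "missense", "synonymous"):
                grades.append(None)
                continue
            g = grade_variant(model, row["hgvs_c"], lib=lib, override=override)
            grades.append(g.grade)
        ann["grade"] = grades
        _write(ann[["patient_id", "hgvs_c", "grade"]], out / "grades.csv", prov)

        stage = "skip-plan"
        merged = cohort.drop(
            columns=[c for c in ann.columns if c in cohort.columns and c not in ("patient_id", "hgvs_c")],
            errors="ignore",
        ).merge(ann, on=[c for c in ("patient_id", "hgvs_c") if c in cohort.columns], how="left")
        eligible = merged[merged["mutation_class"].isin(["nonsense", "frameshift", "missense"])]
        plans = []
        plan_rows = []
        for _, row in eligible.iterrows():
            annv = classify_variant(model, parse_hgvs(row["hgvs_c"]))
            plan = plan_for_variant(model, annv, cap=config.skip_cap)
            plans.append(plan)
            plan_rows.append(
                {
                    "patient_id": row.get("patient_id", ""),
                    "hgvs_c": row["hgvs_c"],
                    "mutated_exon": plan.mutated_exon if plan else None,
                    "selected_block": (
                        f"{plan.selected_block[0]}-{plan.selected_block[1]}"
                        if plan and plan.selected_block
                        else None
                    ),
                    "strategy_size": plan.strategy_size if plan else None,
                }
            )
        _write(pd.DataFrame(plan_rows), out / "skip_plans.csv", prov)

        stage = "skip-coverage"
        plans = [p for p in plans if p is not None]
        report: dict = {"seed": config.seed, "n_patients": len(cohort)}
        if plans:
            cov = cohort_skip_coverage(plans)
            _write(cov.block_ranking, out / "skip_block_ranking.csv", prov)
            report["skip_coverage_pct"] = {str(k): round(v, 2) for k, v in cov.coverage.items()}

        stage = "cohort-stats"
        merged = add_severity(merged)
        merged["truncating"] = merged["mutation_class"].isin(["nonsense", "frameshift"])
        assoc = {}
        try:
            res = run_association(
                merged, "truncating", "severity", zero_correction=config.zero_correction
            )
            assoc["truncating_x_severity"] = {
                "test": res.test,
                "p_value": res.p_value,
                "or": res.or_value,
            }
        except (ValidationError, DmdKitError) as exc:
            assoc["truncating_x_severity"] = {"error": str(exc)}
        nons = merged[merged["mutation_class"] == "nonsense"]
        try:
            res = run_association(
                nons, "grade", "severity", zero_correction=config.zero_correction
            )
            assoc["grade_x_severity_nonsense"] = {
                "test": res.test,
                "p_value": res.p_value,
                "or": res.or_value,
            }
        except (ValidationError, DmdKitError) as exc:
            assoc["grade_x_severity_nonsense"] = {"error": str(exc)}
        report["associations"] = assoc
        if {"scrn", "age_exam"} <= set(merged.columns):
            lr = scrn_logistic(merged, predictor="scrn")
            report["scrn_logistic"] = {
                "status": lr.status,
                "n_used": lr.n_used,
                "n_dropped_missing": lr.n_dropped_missing,
            }
            if lr.status == "ok":
                report["scrn_logistic"]["scrn_or"] = float(lr.coef_table.loc["scrn", "or"])
                report["scrn_logistic"]["scrn_or_ci"] = [
                    float(lr.coef_table.loc["scrn", "or_ci_low"]),
                    float(lr.coef_table.loc["scrn", "or_ci_high"]),
                ]

        stage = "summaries"
        summaries = summarize_cohort(merged)
        for name, table in summaries.items():
            _write(table, out / f"summary_{name}.csv", prov)
        report["summaries_written"] = sorted(summaries)
        report["provenance"] = prov
        (out / "report.json").write_text(json.dumps(report, indent=2, default=_json_default))
        return report
    except DmdKitError as exc:
        raise DmdKitError(f"pipeline stage '{stage}' failed: {exc}") from exc


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
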