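"""Cohort summary tables: the figure- and table-level breakdowns of a
small-mutation spectrum (class mixture, carrier status, positional and
domain distributions, CpG split, indel and PTC breakdowns, splice-side
counts, grade crosstabs)."""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .errors import ValidationError
from .stats import add_severity

#: canonical ordering of mutation classes in spectrum outputs
CLASS_ORDER = ["nonsense", "splicing", "frameshift", "missense", "utr", "other"]

#: cohort columns each summary needs
_REQUIRED = {
    "class_distribution": ["mutation_class"],
    "carrier_status": ["mother_carrier", "mutation_class"],
    "positional": ["host_exon", "domain", "mutation_class"],
    "cpg": ["mutation_class", "cpg"],
    "indels": ["mutation_class", "indel_kind"],
    "ptc": ["mutation_class", "ptc_type"],
    "splice_sides": ["mutation_class", "splice_side"],
    "grade_staining": ["mutation_class", "grade", "dystrophin_staining"],
    "domain_phenotype": ["mutation_class", "domain", "phenotype"],
    "grade_domain_phenotype": ["mutation_class", "grade", "domain", "phenotype"],
}


def _pct(counts: pd.Series) -> pd.DataFrame:
    total = counts.sum()
    return pd.DataFrame(
        {"n": counts, "pct": (100.0 * counts / total).round(2)}
    )


def _canon_class(s: pd.Series) -> pd.Series:
    return s.where(s.isin(CLASS_ORDER[:-1]), "other")


def summarize_cohort(cohort: pd.DataFrame, which: Optional[list[str]] = None) -> dict:
    """Build every summary the cohort columns support (or the named ones).

    Raises a validation error listing the missing columns when a requested
    summary cannot be built.  Returns a dict of tidy DataFrames.
    """
    names = which or [k for k, cols in _REQUIRED.items() if set(cols) <= set(cohort.columns)]
    missing_any = {
        name: sorted(set(_REQUIRED[name]) - set(cohort.columns)) for name in names
    }
    bad = {k: v for k, v in missing_any.items() if v}
    if bad:
        raise ValidationError(f"missing annotation columns: {bad}")
    df = cohort.copy()
    df["mutation_class"] = _canon_class(df["mutation_class"])
    if "phenotype" in df.columns:
        df = add_severity(df)
    out: dict[str, pd.DataFrame] = {}
    for name in names:
        out[name] = _BUILDERS[name](df)
    return out


def _class_distribution(df: pd.DataFrame) -> pd.DataFrame:
    blocks = {"all": _pct(df["mutation_class"].value_counts())}
    if "severity" in df.columns:
        for grp, sub in df.dropna(subset=["severity"]).groupby("severity"):
            blocks[grp] = _pct(sub["mutation_class"].value_counts())
    return (
        pd.concat(blocks, names=["group", "mutation_class"])
        .reset_index()
        .sort_values(["group", "n"], ascending=[True, False])
        .reset_index(drop=True)
    )


def _carrier_status(df: pd.DataFrame) -> pd.DataFrame:
    known = df[df["mother_carrier"] != "unknown"]
    blocks = {"all": _pct(known["mother_carrier"].value_counts())}
    if "severity" in df.columns:
        for grp, sub in known.dropna(subset=["severity"]).groupby("severity"):
            blocks[grp] = _pct(sub["mother_carrier"].value_counts())
    for cls, sub in known.groupby("mutation_class"):
        blocks[cls] = _pct(sub["mother_carrier"].value_counts())
    return pd.concat(blocks, names=["group", "mother_carrier"]).reset_index()


def _positional(df: pd.DataFrame) -> pd.DataFrame:
    """Per-exon counts with splice variants attributed to consensus exons."""
    sub = df.dropna(subset=["host_exon"])
    tab = (
        sub.groupby(["host_exon", "mutation_class"]).size().rename("n").reset_index()
    )
    tab["host_exon"] = tab["host_exon"].astype(int)
    return tab.sort_values(["host_exon", "mutation_class"]).reset_index(drop=True)


def _cpg(df: pd.DataFrame) -> pd.DataFrame:
    nons = df[df["mutation_class"] == "nonsense"]
    return _pct(nons["cpg"].map({True: "CpG", False: "non-CpG"}).value_counts())


def _indels(df: pd.DataFrame) -> pd.DataFrame:
    fs = df[df["mutation_class"] == "frameshift"]
    return _pct(fs["indel_kind"].value_counts())


def _ptc(df: pd.DataFrame) -> pd.DataFrame:
    """Stop-codon type ratios for truncating, nonsense and frameshift groups."""
    trunc = df[df["mutation_class"].isin(["nonsense", "frameshift"])]
    blocks = {"truncating": _pct(trunc["ptc_type"].value_counts())}
    for cls in ("nonsense", "frameshift"):
        blocks[cls] = _pct(trunc.loc[trunc["mutation_class"] == cls, "ptc_type"].value_counts())
    return pd.concat(blocks, names=["group", "ptc_type"]).reset_index()


def _splice_sides(df: pd.DataFrame) -> pd.DataFrame:
    sp = df[df["mutation_class"] == "splicing"]
    return _pct(sp["splice_side"].value_counts())


def _grade_staining(df: pd.DataFrame) -> pd.DataFrame:
    nons = df[
        (df["mutation_class"] == "nonsense")
        & (df["dystrophin_staining"].isin(["absent", "patchy"]))
    ].dropna(subset=["grade"])
    return (
        nons.groupby(["grade", "dystrophin_staining"]).size().rename("n").reset_index()
    )


def _domain_phenotype(df: pd.DataFrame) -> pd.DataFrame:
    sub = df.dropna(subset=["severity"])
    return (
        sub.groupby(["mutation_class", "domain", "severity"], dropna=False)
        .size()
        .rename("n")
        .reset_index()
    )


def _grade_domain_phenotype(df: pd.DataFrame) -> pd.DataFrame:
    nons = df[df["mutation_class"] == "nonsense"].dropna(subset=["severity", "grade"])
    return (
        nons.groupby(["domain", "grade", "severity"]).size().rename("n").reset_index()
    )


_BUILDERS = {
    "class_distribution": _class_distribution,
    "carrier_status": _carrier_status,
    "positional": _positional,
    "cpg": _cpg,
    "indels": _indels,
    "ptc": _ptc,
    "splice_sides": _splice_sides,
    "grade_staining": _grade_staining,
    "domain_phenotype": _domain_phenotype,
    "grade_domain_phenotype": _grade_domain_phenotype,
}
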