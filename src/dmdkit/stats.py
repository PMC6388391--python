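"""Cohort statistics: phenotype classification, contingency-table
association with the classical test-dispatch rule, Woolf odds-ratio
intervals, and the serum-biomarker logistic stage.

Phenotype classes follow the clinical convention for dystrophinopathies:
loss of ambulation (LOA) before 13 years -> DMD, at 13-15 years -> IMD
(intermediate), at >= 16 years -> BMD; for still-ambulant patients,
onset of weakness by age 5 -> DMD, nearly normal or very mild dysfunction
after age 5 -> BMD, intermediate motor severity -> IMD; otherwise pending.
DMD and IMD are merged into one severe (DMD/IMD) group for contrasts;
pending patients are excluded from phenotype contrasts but kept in
spectrum summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ContractError, ValidationError

SEVERE = ("DMD", "IMD")


@dataclass(frozen=True)
class PatientRecord:
    """One patient row of a cohort table."""

    id: str
    hgvs_c: str
    phenotype: Literal["DMD", "IMD", "BMD", "pending"] = "pending"
    age_exam: Optional[float] = None
    age_onset: Optional[float] = None
    age_loa: Optional[float] = None          # None = unknown or not lost
    ambulant: Optional[bool] = None
    scrn: Optional[float] = None             # serum creatinine, µmol/L
    ck: Optional[float] = None               # creatine kinase, U/L
    dystrophin_staining: Literal["absent", "patchy", "unknown"] = "unknown"
    mother_carrier: Literal["carrier", "non_carrier", "unknown"] = "unknown"
    pathogenicity_ok: bool = True

    def __post_init__(self) -> None:
        for name in ("age_exam", "age_onset", "age_loa"):
            val = getattr(self, name)
            if val is not None and val < 0:
                raise ValidationError(f"{name} must be non-negative")
        for name in ("scrn", "ck"):
            val = getattr(self, name)
            if val is not None and val <= 0:
                raise ValidationError(f"{name} must be positive when present")


def phenotype_classify(
    age_loa: Optional[float] = None,
    ambulant: Optional[bool] = None,
    age_onset: Optional[float] = None,
    motor_status: Optional[Literal["mild", "intermediate", "severe"]] = None,
    age_exam: Optional[float] = None,
) -> str:
    """Phenotype from clinical fields (see module docstring for the rules)."""
    if age_loa is not None and ambulant:
        raise ValidationError("contradictory fields: age_loa given but still ambulant")
    if age_loa is not None:
        if age_loa < 13:
            return "DMD"
        if age_loa < 16:
            return "IMD"
        return "BMD"
    if ambulant:
        if age_onset is not None and age_onset <= 5 and motor_status == "severe":
            return "DMD"
        if motor_status == "mild" and age_exam is not None and age_exam > 5:
            return "BMD"
        if motor_status == "intermediate":
            return "IMD"
        if motor_status == "severe" and age_onset is not None and age_onset <= 5:
            return "DMD"
    return "pending"


# -- contingency machinery ---------------------------------------------------


def expected_counts(observed: np.ndarray) -> np.ndarray:
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValidationError("observed must be a 2-D non-negative count table")
    total = obs.sum()
    if total == 0:
        raise ValidationError("empty table")
    return np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total


def select_test(observed: np.ndarray) -> str:
    """Dispatch rule: Fisher when any expected cell < 1 or n < 40; the
    continuity-corrected chi-square when any expected cell < 5; else the
    plain chi-square."""
    obs = np.asarray(observed, dtype=float)
    exp = expected_counts(obs)
    n = obs.sum()
    if (exp < 1).any() or n < 40:
        return "fisher"
    if (exp < 5).any():
        return "chi_square_continuity"
    return "chi_square"


@dataclass(frozen=True)
class OddsRatioResult:
    or_value: float
    ci_low: float
    ci_high: float
    log_se: float


def odds_ratio_ci(
    table: Sequence[Sequence[float]], zero_correction: bool = False
) -> OddsRatioResult:
    """Odds ratio with the Woolf (log-normal) 95% interval.

    OR = ad/bc for [[a, b], [c, d]]; CI = exp(ln OR +/- 1.96 * sqrt(1/a +
    1/b + 1/c + 1/d)).  ``zero_correction`` adds 0.5 to every cell
    (Haldane-Anscombe) before computing; otherwise a zero cell is an error.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ContractError("odds ratio requires a 2x2 table")
    if (t == 0).any():
        if not zero_correction:
            raise ValidationError("zero cell: odds ratio undefined without correction")
        t = t + 0.5
    a, b, c, d = t.ravel()
    or_value = (a * d) / (b * c)
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    half = 1.959963984540054 * se
    return OddsRatioResult(
        float(or_value),
        float(or_value * np.exp(-half)),
        float(or_value * np.exp(half)),
        se,
    )


@dataclass
class ContingencyResult:
    observed: np.ndarray
    expected: np.ndarray
    test: str
    statistic: Optional[float]
    p_value: float
    or_result: Optional[OddsRatioResult] = None
    row_labels: tuple = ()
    col_labels: tuple = ()

    @property
    def or_value(self) -> Optional[float]:
        return self.or_result.or_value if self.or_result else None


def contingency_test(
    observed: np.ndarray, zero_correction: bool = False
) -> ContingencyResult:
    """Run the dispatched test on a count table and attach OR/CI when 2x2."""
    obs = np.asarray(observed, dtype=float)
    test = select_test(obs)
    exp = expected_counts(obs)
    if test == "fisher":
        if obs.shape != (2, 2):
            raise ValidationError(
                "Fisher dispatch on a table larger than 2x2 is not supported; "
                "collapse categories or use a larger sample"
            )
        _, p = sps.fisher_exact(obs)
        stat = None
    else:
        correction = test == "chi_square_continuity"
        res = sps.chi2_contingency(obs, correction=correction)
        stat, p = float(res[0]), float(res[1])
    orr = None
    if obs.shape == (2, 2):
        try:
            orr = odds_ratio_ci(obs, zero_correction=zero_correction)
        except ValidationError:
            orr = None
    return ContingencyResult(obs, exp, test, stat, float(p), orr)


def run_association(
    cohort: pd.DataFrame,
    row_factor: str,
    col_factor: str,
    filters: Optional[dict] = None,
    include_pending: bool = False,
    zero_correction: bool = False,
) -> ContingencyResult:
    """Cross-tabulate two categorical columns and run the dispatched test.

    Pending patients are excluded whenever either factor is the phenotype
    (or the severe/mild grouping derived from it), unless requested.
    """
    df = cohort
    if filters:
        for col, val in filters.items():
            df = df[df[col].isin(val if isinstance(val, (list, tuple, set)) else [val])]
    for factor in (row_factor, col_factor):
        if factor not in df.columns:
            raise ValidationError(f"missing column {factor!r}")
    if not include_pending and "phenotype" in df.columns:
        if row_factor in ("phenotype", "severity") or col_factor in ("phenotype", "severity"):
            df = df[df["phenotype"] != "pending"]
    df = df.dropna(subset=[row_factor, col_factor])
    table = pd.crosstab(df[row_factor], df[col_factor])
    # canonical orientation: severe group first, phenotype order fixed, so a
    # 2x2 odds ratio always reads "first row -> severe"
    _orders = {
        "severity": ["DMD/IMD", "BMD"],
        "phenotype": ["DMD", "IMD", "BMD"],
        "truncating": [True, False],
    }
    for axis, factor in ((0, row_factor), (1, col_factor)):
        if factor in _orders:
            want = [x for x in _orders[factor] if x in (table.index if axis == 0 else table.columns)]
            table = table.reindex(want, axis=axis)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValidationError(
            f"degenerate table: {row_factor} x {col_factor} has a single level after filtering"
        )
    res = contingency_test(table.to_numpy(), zero_correction=zero_correction)
    res.row_labels = tuple(table.index)
    res.col_labels = tuple(table.columns)
    return res


def severity(phenotype: str) -> Optional[str]:
    if phenotype in SEVERE:
        return "DMD/IMD"
    if phenotype == "BMD":
        return "BMD"
    return None


def add_severity(cohort: pd.DataFrame) -> pd.DataFrame:
    out = cohort.copy()
    out["severity"] = out["phenotype"].map(severity)
    return out


# -- logistic stage ----------------------------------------------------------


@dataclass
class LogisticStageResult:
    status: Literal["ok", "separation", "no_convergence"]
    coef_table: Optional[pd.DataFrame]
    n_used: int
    n_dropped_missing: int
    model: object = field(default=None, repr=False)


def scrn_logistic(
    cohort: pd.DataFrame,
    predictor: Literal["scrn", "ck"] = "scrn",
    max_age: float = 16.0,
) -> LogisticStageResult:
    """Logistic regression of severe phenotype on age, mutation type and a
    serum biomarker.

    Patients older than ``max_age`` at examination are excluded (above that
    age the mild phenotype dominates by definition and the contrast is
    uninformative); rows with a missing predictor are dropped and counted.
    Outcome: DMD/IMD = 1 vs BMD = 0 (pending excluded).  Per-covariate OR =
    exp(coefficient) with Wald 95% CI.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    needed = {"phenotype", "age_exam", "mutation_class", predictor}
    missing = needed - set(cohort.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")
    df = cohort[cohort["phenotype"] != "pending"].copy()
    df = df[df["age_exam"] <= max_age]
    n_before = len(df)
    df = df.dropna(subset=[predictor, "age_exam"])
    n_dropped = n_before - len(df)
    y = df["phenotype"].isin(SEVERE).astype(int)
    design = df[["age_exam", predictor, "mutation_class"]].copy()
    # mutation type enters as 4 levels: the three largest classes plus a
    # pooled remainder — a dummy carried by a handful of rows with a single
    # outcome level would quasi-separate the ML fit
    keep = design["mutation_class"].value_counts().index[:3]
    design["mutation_class"] = design["mutation_class"].where(
        design["mutation_class"].isin(keep), "other"
    )
    X = pd.get_dummies(
        design,
        columns=["mutation_class"],
        drop_first=True,
        dtype=float,
    )
    X = sm.add_constant(X, has_constant="add")
    if y.nunique() < 2 or df[predictor].nunique() < 2:
        return LogisticStageResult("separation", None, len(df), n_dropped)
    try:
        import warnings as _warnings

        from statsmodels.tools.sm_exceptions import ConvergenceWarning

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", ConvergenceWarning)
            _warnings.simplefilter("ignore", RuntimeWarning)
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return LogisticStageResult("separation", None, len(df), n_dropped)
    if not fit.mle_retvals.get("converged", False):
        return LogisticStageResult("no_convergence", None, len(df), n_dropped)
    if np.abs(fit.params).max() > 50:
        return LogisticStageResult("separation", None, len(df), n_dropped)
    ci = fit.conf_int()
    table = pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
            "p_value": fit.pvalues,
            "or": np.exp(fit.params),
            "or_ci_low": np.exp(ci[0]),
            "or_ci_high": np.exp(ci[1]),
        }
    )
    return LogisticStageResult("ok", table, len(df), n_dropped, model=fit)
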