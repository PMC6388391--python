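import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dmdkit.errors import ContractError, ValidationError
from dmdkit.stats import (
    PatientRecord,
    add_severity,
    contingency_test,
    expected_counts,
    odds_ratio_ci,
    phenotype_classify,
    run_association,
    scrn_logistic,
    select_test,
)
from dmdkit.summaries import summarize_cohort


class TestPhenotypeClassify:
    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            (dict(age_loa=10), "DMD"),
            (dict(age_loa=12.9), "DMD"),
            (dict(age_loa=13), "IMD"),
            (dict(age_loa=14), "IMD"),
            (dict(age_loa=16), "BMD"),
            (dict(age_loa=20), "BMD"),
            (dict(ambulant=True, age_onset=4, motor_status="severe"), "DMD"),
            (dict(ambulant=True, age_exam=20, motor_status="mild"), "BMD"),
            (dict(ambulant=True, motor_status="intermediate"), "IMD"),
            (dict(), "pending"),
            (dict(ambulant=True), "pending"),
        ],
    )
    def test_rules(self, kwargs, expected):
        assert phenotype_classify(**kwargs) == expected

    def test_contradictory_fields_rejected(self):
        with pytest.raises(ValidationError):
            phenotype_classify(age_loa=9, ambulant=True)


class TestPatientRecord:
    def test_negative_age_rejected(self):
        with pytest.raises(ValidationError):
            PatientRecord(id="p", hgvs_c="c.1A>G", age_exam=-1)

    def test_nonpositive_scrn_rejected(self):
        with pytest.raises(ValidationError):
            PatientRecord(id="p", hgvs_c="c.1A>G", scrn=0)


def independent_dispatch(table):
    """Separate restatement of the dispatch rule for cross-checking."""
    t = np.asarray(table, dtype=float)
    n = t.sum()
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    min_expected = min(
        rows[i] * cols[j] / n for i in range(t.shape[0]) for j in range(t.shape[1])
    )
    if min_expected < 1 or n < 40:
        return "fisher"
    if min_expected < 5:
        return "chi_square_continuity"
    return "chi_square"


class TestSelectTest:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[30, 20], [25, 25]], "chi_square"),
            ([[20, 3], [22, 5]], "chi_square_continuity"),
            ([[10, 5], [8, 7]], "fisher"),  # n = 30 < 40
            ([[50, 1], [49, 0]], "fisher"),  # expected < 1
        ],
    )
    def test_examples(self, table, expected):
        assert select_test(table) == expected

    def test_rule_on_grid(self):
        # moderate grid here; the exhaustive n <= 60 sweep runs in the
        # acceptance suite
        for a, b, c, d in itertools.product(range(0, 14, 2), repeat=4):
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            table = [[a, b], [c, d]]
            assert select_test(table) == independent_dispatch(table)


class TestOddsRatio:
    def test_published_style_tables(self):
        r = odds_ratio_ci([[26, 2], [13, 12]])
        assert r.or_value == pytest.approx(12.0)
        assert (round(r.ci_low, 3), round(r.ci_high, 3)) == (2.332, 61.758)
        r = odds_ratio_ci([[15, 2], [12, 12]])
        assert r.or_value == pytest.approx(7.5)
        assert (round(r.ci_low, 3), round(r.ci_high, 3)) == (1.400, 40.178)

    def test_row_swap_inverts(self):
        a = odds_ratio_ci([[7, 3], [4, 9]])
        b = odds_ratio_ci([[4, 9], [7, 3]])
        assert a.or_value == pytest.approx(1 / b.or_value)
        assert a.ci_low == pytest.approx(1 / b.ci_high)
        assert a.ci_high == pytest.approx(1 / b.ci_low)

    def test_balanced_table_symmetric(self):
        r = odds_ratio_ci([[5, 5], [5, 5]])
        assert r.or_value == pytest.approx(1.0)
        assert math.log(r.ci_low) == pytest.approx(-math.log(r.ci_high))

    def test_zero_cell_handling(self):
        with pytest.raises(ValidationError):
            odds_ratio_ci([[5, 0], [5, 5]])
        r = odds_ratio_ci([[5, 0], [5, 5]], zero_correction=True)
        assert r.or_value == pytest.approx((5.5 * 5.5) / (0.5 * 5.5))

    def test_non_2x2_rejected(self):
        with pytest.raises(ContractError):
            odds_ratio_ci([[1, 2, 3], [4, 5, 6]])


class TestContingency:
    def test_expected_preserves_margins(self):
        obs = np.array([[12, 7, 9], [4, 16, 2]])
        exp = expected_counts(obs)
        assert np.allclose(exp.sum(axis=1), obs.sum(axis=1))
        assert np.allclose(exp.sum(axis=0), obs.sum(axis=0))

    def test_fisher_p_matches_hypergeometric_enumeration(self):
        """Two-sided Fisher p equals summed hypergeometric probabilities of
        tables at least as extreme, for all margins with n <= 40."""
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(80):
            n = int(rng.integers(5, 41))
            r1 = int(rng.integers(1, n))
            c1 = int(rng.integers(1, n))
            a_lo, a_hi = max(0, r1 + c1 - n), min(r1, c1)
            a = int(rng.integers(a_lo, a_hi + 1))
            table = [[a, r1 - a], [c1 - a, n - r1 - c1 + a]]
            _, p = sps.fisher_exact(table)
            probs = [
                sps.hypergeom.pmf(k, n, r1, c1) for k in range(a_lo, a_hi + 1)
            ]
            p_obs = sps.hypergeom.pmf(a, n, r1, c1)
            p_enum = sum(q for q in probs if q <= p_obs * (1 + 1e-9))
            assert p == pytest.approx(p_enum, rel=1e-6, abs=1e-12)
            checked += 1
        assert checked == 80

    def test_contingency_dispatches_and_attaches_or(self):
        res = contingency_test([[30, 20], [25, 25]])
        assert res.test == "chi_square" and res.statistic is not None
        assert res.or_result is not None
        res = contingency_test([[10, 5], [8, 7]])
        assert res.test == "fisher" and res.statistic is None


class TestRunAssociation:
    @pytest.fixture()
    def cohort(self):
        rng = np.random.default_rng(0)
        n = 120
        truncating = rng.random(n) < 0.6
        severe = rng.random(n) < np.where(truncating, 0.8, 0.4)
        return pd.DataFrame(
            {
                "truncating": truncating,
                "phenotype": np.where(severe, "DMD", "BMD"),
            }
        )

    def test_association_runs(self, cohort):
        df = add_severity(cohort)
        res = run_association(df, "truncating", "severity")
        assert res.p_value < 0.05
        assert res.row_labels == (True, False)
        assert res.col_labels == ("DMD/IMD", "BMD")

    def test_pending_excluded(self, cohort):
        df = add_severity(cohort)
        df.loc[:10, "phenotype"] = "pending"
        df = add_severity(df)
        res = run_association(df, "truncating", "severity")
        assert res.observed.sum() == (df["phenotype"] != "pending").sum()

    def test_degenerate_factor_rejected(self, cohort):
        df = add_severity(cohort)
        df["constant"] = "x"
        with pytest.raises(ValidationError, match="single level"):
            run_association(df, "constant", "severity")


class TestScrnLogistic:
    def test_constant_predictor_flagged(self):
        df = pd.DataFrame(
            {
                "phenotype": ["DMD", "BMD"] * 20,
                "age_exam": np.linspace(2, 15, 40),
                "mutation_class": ["nonsense"] * 40,
                "scrn": [20.0] * 40,
            }
        )
        res = scrn_logistic(df, "scrn")
        assert res.status == "separation"

    def test_missing_predictor_rows_counted(self):
        rng = np.random.default_rng(1)
        n = 80
        severe = rng.random(n) < 0.5
        scrn = 20 + 2.0 * severe + rng.normal(0, 1.5, n)
        scrn[:10] = np.nan
        df = pd.DataFrame(
            {
                "phenotype": np.where(severe, "DMD", "BMD"),
                "age_exam": rng.uniform(2, 15, n),
                "mutation_class": rng.choice(["nonsense", "splicing"], n),
                "scrn": scrn,
            }
        )
        res = scrn_logistic(df, "scrn")
        assert res.n_dropped_missing == 10
        assert res.status == "ok"
        assert "scrn" in res.coef_table.index


class TestSummaries:
    def test_fractions_sum_to_one(self):
        from dmdkit.reference import reference_cohort

        out = summarize_cohort(reference_cohort())
        assert out["class_distribution"].query("group == 'all'")["pct"].sum() == pytest.approx(100.0, abs=0.05)
        assert out["cpg"]["pct"].sum() == pytest.approx(100.0, abs=0.05)
        ptc = out["ptc"]
        for grp in ("truncating", "nonsense", "frameshift"):
            assert ptc.query("group == @grp")["pct"].sum() == pytest.approx(100.0, abs=0.05)

    def test_missing_columns_reported(self):
        with pytest.raises(ValidationError, match="cpg"):
            summarize_cohort(pd.DataFrame({"mutation_class": ["nonsense"]}), which=["cpg"])
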