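"""Logistic models, sparse-level grouping, chi-squared and Mann–Whitney tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fevscore.fixtures import HIV_OUTCOME_TABLE, QSOFA_COUNTS
from fevscore.models import (
    RankDeficiencyError,
    adjusted_model,
    age_group,
    chi_squared_test,
    fit_logistic,
    group_sparse_levels,
    mann_whitney_test,
)
from fevscore.roc import ScoreCounts, auc_tie_corrected

from conftest import counts_to_scores


# --- fit_logistic ----------------------------------------------------------

def test_intercept_only_fit_equals_log_odds():
    n_dead, n_alive = 185, 2612
    y = np.array([1] * n_dead + [0] * n_alive)
    X = pd.DataFrame({"intercept": np.ones(len(y))})
    fit = fit_logistic(X, y)
    assert fit.converged
    assert fit.coefficients["intercept"] == pytest.approx(
        math.log(n_dead / n_alive), abs=1e-8
    )


def test_two_by_two_fit_matches_cross_product_odds_ratio():
    # HIV-positive vs negative mortality contingency from the study
    a = HIV_OUTCOME_TABLE["positive"]["dead"]      # 112
    b = HIV_OUTCOME_TABLE["positive"]["alive"]     # 573
    c = HIV_OUTCOME_TABLE["negative"]["dead"]      # 73
    d = HIV_OUTCOME_TABLE["negative"]["alive"]     # 2039
    y = np.array([1] * a + [0] * b + [1] * c + [0] * d)
    x = np.array([1.0] * (a + b) + [0.0] * (c + d))
    fit = fit_logistic(pd.DataFrame({"intercept": 1.0, "hiv": x}), y)
    or_closed_form = (a * d) / (b * c)
    assert fit.odds_ratio("hiv") == pytest.approx(or_closed_form, abs=1e-8)
    se_closed_form = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    assert fit.standard_errors["hiv"] == pytest.approx(se_closed_form,
                                                       abs=1e-8)


def test_parameter_recovery_on_simulated_predictors():
    rng = np.random.default_rng(99)
    n = 5000
    x1 = rng.standard_normal(n)
    x2 = (rng.random(n) < 0.3).astype(float)
    truth = {"intercept": -2.0, "x1": 0.8, "x2": 1.2}
    logit = truth["intercept"] + truth["x1"] * x1 + truth["x2"] * x2
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    fit = fit_logistic(pd.DataFrame({"intercept": 1.0, "x1": x1, "x2": x2}), y)
    assert fit.converged
    for name, beta in truth.items():
        assert abs(fit.coefficients[name] - beta) < 3 * fit.standard_errors[name]


def test_perfect_separation_is_flagged_not_silent():
    x = np.array([0.0] * 10 + [1.0] * 10)
    y = np.array([0] * 10 + [1] * 10)
    fit = fit_logistic(pd.DataFrame({"intercept": 1.0, "x": x}), y)
    assert not fit.converged
    assert "separation" in fit.diagnostic


def test_rank_deficiency_names_collinear_columns():
    rng = np.random.default_rng(5)
    x = rng.standard_normal(40)
    y = (rng.random(40) < 0.5).astype(int)
    # either member of the collinear pair may be reported
    with pytest.raises(RankDeficiencyError, match=r"collinear columns: \['x(_copy)?'\]"):
        fit_logistic(
            pd.DataFrame({"intercept": 1.0, "x": x, "x_copy": 2 * x}), y
        )


# --- sparse-level grouping -------------------------------------------------

def test_grouping_identity_when_all_levels_dense():
    counts = ScoreCounts((0, 1, 2), (10, 10, 10), (5, 5, 5))
    grouped, mapping = group_sparse_levels(counts, min_count=5)
    assert grouped == counts
    assert mapping == {0: 0, 1: 1, 2: 2}


def test_grouping_merges_sparse_top_levels():
    counts = ScoreCounts((1, 2, 3), (8, 2, 1), (2, 1, 1))
    grouped, mapping = group_sparse_levels(counts, min_count=5)
    assert grouped.levels == (1, 2)
    assert grouped.alive == (8, 3)
    assert grouped.dead == (2, 2)
    assert mapping == {1: 1, 2: 2, 3: 2}


def test_grouping_is_idempotent_and_preserves_totals(rng):
    for _ in range(20):
        k = int(rng.integers(2, 10))
        counts = ScoreCounts(
            tuple(range(k)),
            tuple(int(x) for x in rng.integers(0, 30, k)),
            tuple(int(x) for x in rng.integers(0, 8, k)),
        )
        if counts.n_dead == 0 or counts.n_alive == 0:
            continue
        grouped, _ = group_sparse_levels(counts, min_count=5)
        assert grouped.n == counts.n
        again, _ = group_sparse_levels(grouped, min_count=5)
        assert again == grouped


def test_grouping_by_outcome_criterion():
    # alternative reading: fewer than five *deaths* at a level
    counts = ScoreCounts((0, 1, 2), (100, 100, 100), (20, 4, 4))
    grouped, _ = group_sparse_levels(counts, min_count=5, criterion="dead")
    assert grouped.dead == (20, 8)


def test_grouping_collapses_tiny_tables_to_one_group():
    counts = ScoreCounts((0, 1), (1, 1), (1, 0))
    grouped, _ = group_sparse_levels(counts, min_count=5)
    assert len(grouped.levels) == 1
    assert grouped.n == counts.n


# --- OR tables -------------------------------------------------------------

def _scored_cohort(n=3000, seed=11):
    rng = np.random.default_rng(seed)
    age = rng.integers(15, 85, n)
    sex = np.where(rng.random(n) < 0.6, "female", "male")
    hiv = np.where(rng.random(n) < 0.24, "positive", "negative")
    score = rng.integers(0, 5, n).astype(float)
    logit = -3.5 + 0.6 * score + math.log(5) * (hiv == "positive")
    y = rng.random(n) < 1 / (1 + np.exp(-logit))
    return pd.DataFrame({
        "age_years": age, "sex": sex, "hiv_status": hiv,
        "outcome": np.where(y, "dead", "alive"),
        "mews": score, "qsofa": np.minimum(score, 3), "uva": score,
    })


def test_uva_model_refuses_hiv_covariate():
    df = _scored_cohort()
    with pytest.raises(ValueError, match="component of the UVA score"):
        adjusted_model(df, "uva", covariates=["age_group", "sex", "hiv"])


def test_mews_reference_level_is_one():
    df = _scored_cohort()
    table = adjusted_model(df, "mews", covariates=[])
    ref = [r for r in table.rows if r.reference and r.predictor == "mews"]
    assert len(ref) == 1 and ref[0].level == "1"


def test_qsofa_reference_level_is_zero():
    df = _scored_cohort()
    table = adjusted_model(df, "qsofa", covariates=[])
    ref = [r for r in table.rows if r.reference and r.predictor == "qsofa"]
    assert ref[0].level == "0"


def test_adjusted_model_recovers_built_in_hiv_effect():
    df = _scored_cohort(n=8000, seed=21)
    table = adjusted_model(df, "mews", covariates=["age_group", "sex", "hiv"])
    hiv_rows = [r for r in table.rows
                if r.predictor == "hiv" and not r.reference]
    assert len(hiv_rows) == 1
    row = hiv_rows[0]
    assert row.ci_low < 5.0 < row.ci_high  # truth aOR = 5 built in
    assert row.ci_low <= row.odds_ratio <= row.ci_high


def test_or_table_reference_rows_have_no_ci():
    df = _scored_cohort()
    table = adjusted_model(df, "mews", covariates=["sex"])
    frame = table.to_frame()
    refs = frame[frame.reference]
    assert (refs.odds_ratio == 1.0).all()
    assert refs.ci_low.isna().all()


# --- descriptive tests -----------------------------------------------------

def test_chi_squared_proportional_table_is_null():
    stat, p = chi_squared_test([[10, 10], [10, 10]])
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)
    stat, _ = chi_squared_test([[20, 40], [10, 20]])
    assert stat == pytest.approx(0.0, abs=1e-12)


def test_chi_squared_matches_closed_form_2x2():
    a, b, c, d = 20, 10, 10, 20
    n = a + b + c + d
    expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    stat, _ = chi_squared_test([[a, b], [c, d]])
    assert stat == pytest.approx(expected, abs=1e-10)


def test_chi_squared_rejects_zero_marginal():
    with pytest.raises(ValueError):
        chi_squared_test([[0, 0], [5, 5]])


def test_mann_whitney_extremes():
    u, _ = mann_whitney_test([1, 1, 1], [1, 1, 1, 1])
    assert u == 3 * 4 / 2
    u, p = mann_whitney_test([5, 6, 7], [1, 2, 3])
    assert u == 9
    assert p < 0.1


def test_mann_whitney_u_is_auc_kernel(qsofa_counts):
    scores, outcomes = counts_to_scores(qsofa_counts)
    dead_scores = scores[outcomes == 1]
    alive_scores = scores[outcomes == 0]
    u, _ = mann_whitney_test(dead_scores, alive_scores)
    auc = u / (len(dead_scores) * len(alive_scores))
    assert round(auc, 2) == 0.68
    assert auc == pytest.approx(auc_tie_corrected(qsofa_counts), abs=1e-12)


def test_mann_whitney_agrees_with_scipy(rng):
    # independent cross-check of U and the tie-corrected normal p
    for _ in range(10):
        x = rng.integers(0, 6, size=40).astype(float)
        y = rng.integers(0, 6, size=55).astype(float)
        u, p = mann_whitney_test(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        assert u == pytest.approx(ref.statistic, abs=1e-9)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)


def test_age_grouping_bands():
    assert age_group(15) == "15-<25"
    assert age_group(24.9) == "15-<25"
    assert age_group(25) == "25-<35"
    assert age_group(64) == "55-<65"
    assert age_group(80) == "65+"
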