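"""ROC engine: published-table reproduction and brute-force oracle checks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fevscore.fixtures import MEWS_LADDER, N_ALIVE, N_DEAD, counts_from_ladder
from fevscore.roc import (
    DegenerateVarianceError,
    ScoreCounts,
    UndefinedAUCError,
    auc_tie_corrected,
    delong_paired_test,
    delong_variance,
    reconstruct_counts_from_ladder,
    roc_points,
    threshold_ladder,
    threshold_metrics,
    trapezoid_area,
)

from conftest import counts_to_scores, random_counts


# --- independent oracles ---------------------------------------------------

def auc_by_pair_enumeration(scores, outcomes):
    """Concordant + half-tied case-control pairs, enumerated directly."""
    cases = [s for s, y in zip(scores, outcomes) if y == 1]
    controls = [s for s, y in zip(scores, outcomes) if y == 0]
    total = 0.0
    for c in cases:
        for k in controls:
            total += 1.0 if c > k else (0.5 if c == k else 0.0)
    return total / (len(cases) * len(controls))


def delong_by_pair_enumeration(scores, outcomes):
    """V10/V01 structural components built by explicit pair enumeration."""
    cases = [s for s, y in zip(scores, outcomes) if y == 1]
    controls = [s for s, y in zip(scores, outcomes) if y == 0]
    m, n = len(cases), len(controls)
    v10 = np.array([
        sum(1.0 if c > k else (0.5 if c == k else 0.0) for k in controls) / n
        for c in cases
    ])
    v01 = np.array([
        sum(1.0 if c > k else (0.5 if c == k else 0.0) for c in cases) / m
        for k in controls
    ])
    auc = v10.mean()
    return auc, np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n, v10, v01


# --- tie-corrected AUC -----------------------------------------------------

def test_qsofa_contingency_reproduces_published_auc(qsofa_counts):
    assert round(auc_tie_corrected(qsofa_counts), 2) == 0.68


def test_auc_extremes():
    separated = ScoreCounts((0, 1), (10, 0), (0, 10))
    assert auc_tie_corrected(separated) == 1.0
    all_tied = ScoreCounts((0,), (10,), (10,))
    assert auc_tie_corrected(all_tied) == 0.5


def test_auc_requires_both_outcome_classes():
    with pytest.raises(UndefinedAUCError):
        auc_tie_corrected(ScoreCounts((0, 1), (5, 5), (0, 0)))


def test_auc_matches_pair_enumeration_on_random_cohorts(rng):
    for _ in range(25):
        counts = random_counts(rng)
        scores, outcomes = counts_to_scores(counts)
        assert auc_tie_corrected(counts) == pytest.approx(
            auc_by_pair_enumeration(scores, outcomes), abs=1e-12
        )


# --- DeLong variance -------------------------------------------------------

def test_qsofa_contingency_reproduces_published_ci(qsofa_counts):
    est = delong_variance(qsofa_counts)
    assert round(est.ci_low, 2) == 0.64
    assert round(est.ci_high, 2) == 0.72


def test_delong_variance_zero_for_perfect_separation():
    est = delong_variance(ScoreCounts((0, 1), (10, 0), (0, 10)))
    assert est.variance == 0.0
    assert (est.ci_low, est.ci_high) == (1.0, 1.0)


def test_delong_variance_matches_jackknife_oracle(rng):
    toy = ScoreCounts((0, 1), (5, 5), (5, 5))
    scores, outcomes = counts_to_scores(toy)
    _, var_oracle, _, _ = delong_by_pair_enumeration(scores, outcomes)
    assert delong_variance(toy).variance == pytest.approx(var_oracle, abs=1e-12)
    for _ in range(10):
        counts = random_counts(rng, max_subjects=60)
        scores, outcomes = counts_to_scores(counts)
        _, var_oracle, _, _ = delong_by_pair_enumeration(scores, outcomes)
        assert delong_variance(counts).variance == pytest.approx(
            var_oracle, abs=1e-12
        )


def test_delong_variance_requires_two_per_class():
    with pytest.raises(DegenerateVarianceError):
        delong_variance(ScoreCounts((0, 1), (5, 5), (1, 0)))


# --- paired DeLong test ----------------------------------------------------

def test_identical_scores_give_null_comparison(rng):
    scores = rng.integers(0, 5, size=50).astype(float)
    outcomes = (rng.random(50) < 0.3).astype(int)
    outcomes[:2] = [0, 1]  # both classes present
    cmp = delong_paired_test(scores, scores.copy(), outcomes)
    assert cmp.delta == 0.0
    assert cmp.z == 0.0
    assert cmp.p_value == 1.0


def test_paired_test_is_antisymmetric(rng):
    a = rng.integers(0, 6, size=80).astype(float)
    b = rng.integers(0, 6, size=80).astype(float)
    y = (rng.random(80) < 0.4).astype(int)
    y[:2] = [0, 1]
    fwd = delong_paired_test(a, b, y)
    rev = delong_paired_test(b, a, y)
    assert fwd.z == pytest.approx(-rev.z, abs=1e-12)
    assert fwd.delta == pytest.approx(-rev.delta, abs=1e-12)
    assert fwd.p_value == pytest.approx(rev.p_value, abs=1e-12)


def test_paired_z_matches_component_enumeration_on_small_cohort(rng):
    # 20-subject toy: components built by explicit O(m*n) enumeration
    for _ in range(10):
        a = rng.integers(0, 4, size=20).astype(float)
        b = rng.integers(0, 4, size=20).astype(float)
        y = np.array([1] * 6 + [0] * 14)
        auc_a, _, v10a, v01a = delong_by_pair_enumeration(a, y)
        auc_b, _, v10b, v01b = delong_by_pair_enumeration(b, y)
        var = (np.var(v10a - v10b, ddof=1) / 6
               + np.var(v01a - v01b, ddof=1) / 14)
        cmp = delong_paired_test(a, b, y)
        assert cmp.delta == pytest.approx(auc_a - auc_b, abs=1e-12)
        assert cmp.variance_delta == pytest.approx(var, abs=1e-12)
        if var > 0:
            assert cmp.z == pytest.approx((auc_a - auc_b) / math.sqrt(var),
                                          abs=1e-10)


def test_paired_test_rejects_length_mismatch_and_single_class():
    with pytest.raises(ValueError):
        delong_paired_test([1, 2], [1, 2, 3], [0, 1])
    with pytest.raises(UndefinedAUCError):
        delong_paired_test([1, 2], [2, 1], [0, 0])


def test_paired_test_type_one_error_within_binomial_envelope():
    """Null rejection rate at alpha=0.05 over 2000 simulated cohorts.

    Two equally informative discretised scores of the same latent severity;
    the 99% binomial envelope for 2000 replicates at p=0.05 is
    0.05 +/- 2.576*sqrt(0.05*0.95/2000).
    """
    rng = np.random.default_rng(1729)
    n, reps = 500, 2000
    rejections = 0
    for _ in range(reps):
        u = rng.standard_normal(n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(u - 2.0)))).astype(int)
        if y.sum() < 2 or y.sum() > n - 2:
            continue
        a = np.round(u + rng.standard_normal(n))
        b = np.round(u + rng.standard_normal(n))
        if delong_paired_test(a, b, y).p_value < 0.05:
            rejections += 1
    rate = rejections / reps
    half_width = 2.576 * math.sqrt(0.05 * 0.95 / reps)
    assert abs(rate - 0.05) < half_width


# --- threshold metrics -----------------------------------------------------

def test_qsofa_threshold_two_reproduces_published_row(qsofa_counts):
    t = threshold_metrics(qsofa_counts, 2)
    assert round(t.sensitivity, 2) == 30.81
    assert round(t.specificity, 2) == 93.19
    assert round(t.ppv, 2) == 24.26
    assert round(t.npv, 2) == 95.00


def test_threshold_extremes(qsofa_counts):
    low = threshold_metrics(qsofa_counts, 0)
    assert (low.sensitivity, low.specificity) == (100.0, 0.0)
    assert low.npv is None  # no predicted negatives
    assert round(low.ppv, 2) == 6.61  # prevalence
    high = threshold_metrics(qsofa_counts, 99)
    assert (high.sensitivity, high.specificity) == (0.0, 100.0)
    assert high.ppv is None


def test_ladder_is_monotone(qsofa_counts):
    ladder = threshold_ladder(qsofa_counts)
    se = [t.sensitivity for t in ladder]
    sp = [t.specificity for t in ladder]
    assert se == sorted(se, reverse=True)
    assert sp == sorted(sp)


# --- ladder inversion ------------------------------------------------------

def test_uva_ladder_inverts_to_expected_dead_counts():
    counts = counts_from_ladder("uva")
    assert counts.dead[:11] == (23, 11, 49, 35, 25, 17, 16, 5, 2, 1, 1)
    assert counts.n_dead == N_DEAD
    assert counts.n_alive == N_ALIVE


def test_mews_ladder_level_zero_alive_count():
    counts = counts_from_ladder("mews")
    assert counts.alive[0] == 583  # 2612 x 22.32% rounded
    assert counts.n_alive == N_ALIVE
    assert counts.n_dead == N_DEAD


def test_trivial_ladder_puts_all_mass_at_one_level():
    counts = reconstruct_counts_from_ladder(
        [100.0, 0.0], [0.0, 100.0], n_dead=7, n_alive=9
    )
    # Se drops to 0 and Sp jumps to 100 at threshold 1: every subject of
    # both classes sits at level 0
    assert counts.dead == (7, 0)
    assert counts.alive == (9, 0)


def test_non_monotone_ladder_rejected():
    with pytest.raises(ValueError):
        reconstruct_counts_from_ladder([100.0, 50.0, 60.0], [0.0, 10.0, 20.0],
                                       10, 10)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_ladder_roundtrip_is_identity_on_integer_counts(seed):
    """threshold ladder -> reconstruction recovers the original counts.

    Holds whenever the ladder percentages are carried at full precision.
    """
    counts = random_counts(np.random.default_rng(seed))
    ladder = threshold_ladder(counts)
    rebuilt = reconstruct_counts_from_ladder(
        [t.sensitivity for t in ladder],
        [t.specificity for t in ladder],
        n_dead=counts.n_dead,
        n_alive=counts.n_alive,
        levels=counts.levels,
    )
    assert rebuilt.alive == counts.alive
    assert rebuilt.dead == counts.dead


# --- ROC curve -------------------------------------------------------------

def test_roc_points_trapezoid_equals_mann_whitney_auc(qsofa_counts, rng):
    pts = roc_points(qsofa_counts)
    assert len(pts) == 5
    assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)
    assert trapezoid_area(pts) == pytest.approx(
        auc_tie_corrected(qsofa_counts), abs=1e-12
    )
    for _ in range(20):
        counts = random_counts(rng)
        assert trapezoid_area(roc_points(counts)) == pytest.approx(
            auc_tie_corrected(counts), abs=1e-12
        )


def test_roc_degenerate_curves():
    single = ScoreCounts((0,), (10,), (5,))
    assert roc_points(single) == [(0.0, 0.0), (1.0, 1.0)]
    assert trapezoid_area(roc_points(single)) == 0.5
    separated = ScoreCounts((0, 1), (10, 0), (0, 10))
    assert (0.0, 1.0) in roc_points(separated)
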