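"""ROC machinery for ordinal severity scores.

Everything here works either from per-subject score vectors or from the
sufficient statistic for an ordinal score: the per-level alive/dead counts
(:class:`ScoreCounts`).  The pieces are

* tie-corrected Mann–Whitney AUC — the probability that a randomly chosen
  case (death) outranks a randomly chosen control, counting ties as 1/2;
  identical to the trapezoidal area under the ROC step curve,
* DeLong structural-component variance for a single AUC, with a Wald
  confidence interval,
* the paired DeLong test for the difference of two correlated AUCs measured
  on the same subjects,
* operating characteristics (Se/Sp/PPV/NPV) at a threshold, with the
  positivity convention *score >= threshold*,
* inversion of a published sensitivity/specificity ladder back to per-level
  counts, which lets printed threshold tables be re-analysed exactly.

The DeLong machinery follows the structural-component construction: for case
i, V10_i is the fraction of controls it outranks (ties 1/2); for control j,
V01_j is the fraction of cases outranking it.  Then
``Var(AUC) = S10/m + S01/n`` with S10, S01 the sample variances of the
components and m, n the case/control counts.  For paired scores the 2x2
component covariance matrices yield
``Var(dAUC) = (S10_aa + S10_bb - 2 S10_ab)/m + (S01_aa + S01_bb - 2 S01_ab)/n``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


class UndefinedAUCError(ValueError):
    """AUC is undefined: one outcome class is empty."""


class DegenerateVarianceError(ValueError):
    """DeLong variance needs at least two subjects per outcome class."""


@dataclass(frozen=True)
class ScoreCounts:
    """Per-score-level alive/dead counts at strictly increasing levels."""

    levels: tuple[float, ...]
    alive: tuple[int, ...]
    dead: tuple[int, ...]

    def __post_init__(self):
        levels = tuple(float(x) for x in self.levels)
        alive = tuple(int(x) for x in self.alive)
        dead = tuple(int(x) for x in self.dead)
        if not (len(levels) == len(alive) == len(dead)):
            raise ValueError("levels, alive and dead must have equal length")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("levels must be strictly increasing")
        if any(c < 0 for c in alive + dead):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "alive", alive)
        object.__setattr__(self, "dead", dead)

    @property
    def n_alive(self) -> int:
        return sum(self.alive)

    @property
    def n_dead(self) -> int:
        return sum(self.dead)

    @property
    def n(self) -> int:
        return self.n_alive + self.n_dead

    @classmethod
    def from_scores(
        cls, scores: Sequence[float], outcomes: Sequence[int]
    ) -> "ScoreCounts":
        """Tabulate per-subject scores against a binary outcome (1 = dead)."""
        s = np.asarray(scores, dtype=float)
        y = np.asarray(outcomes, dtype=int)
        if s.shape != y.shape:
            raise ValueError("scores and outcomes must have equal length")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("outcomes must be binary 0/1")
        levels = np.unique(s)
        alive = [int(np.sum((s == lv) & (y == 0))) for lv in levels]
        dead = [int(np.sum((s == lv) & (y == 1))) for lv in levels]
        return cls(tuple(levels), tuple(alive), tuple(dead))

    # -- plain-text round-trips -------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"level": self.levels, "alive": self.alive, "dead": self.dead}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ScoreCounts":
        df = pd.read_csv(path)
        return cls(tuple(df["level"]), tuple(df["alive"]), tuple(df["dead"]))

    def to_json(self) -> str:
        return json.dumps(
            {"levels": list(self.levels), "alive": list(self.alive),
             "dead": list(self.dead)}
        )

    @classmethod
    def from_json(cls, text: str) -> "ScoreCounts":
        obj = json.loads(text)
        return cls(tuple(obj["levels"]), tuple(obj["alive"]), tuple(obj["dead"]))


@dataclass(frozen=True)
class AUCEstimate:
    """AUC with DeLong variance and a Wald confidence interval."""

    auc: float
    variance: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    n_dead: int = 0
    n_alive: int = 0

    def __post_init__(self):
        if not (self.ci_low - 1e-12 <= self.auc <= self.ci_high + 1e-12):
            raise ValueError("CI must bracket the AUC")


@dataclass(frozen=True)
class DeLongComparison:
    """Paired DeLong test for the difference of two correlated AUCs."""

    auc_a: float
    auc_b: float
    delta: float
    variance_delta: float
    z: float
    p_value: float


def _check_classes(counts: ScoreCounts) -> None:
    if counts.n_dead == 0 or counts.n_alive == 0:
        raise UndefinedAUCError(
            "AUC undefined: need at least one subject in each outcome class "
            f"(alive={counts.n_alive}, dead={counts.n_dead})"
        )


def auc_tie_corrected(counts: ScoreCounts) -> float:
    """Tie-corrected Mann–Whitney AUC from per-level counts.

    ``AUC = [sum_{i<j} alive_i * dead_j + 1/2 sum_i alive_i * dead_i] / (N_alive * N_dead)``
    """
    _check_classes(counts)
    alive = np.asarray(counts.alive, dtype=float)
    dead = np.asarray(counts.dead, dtype=float)
    alive_below = np.concatenate(([0.0], np.cumsum(alive)[:-1]))
    concordant = float(np.sum(dead * alive_below))
    ties = float(np.sum(dead * alive))
    return (concordant + 0.5 * ties) / (counts.n_alive * counts.n_dead)


def _structural_components(counts: ScoreCounts):
    """Per-level V10 (cases) and V01 (controls) from cumulative counts."""
    alive = np.asarray(counts.alive, dtype=float)
    dead = np.asarray(counts.dead, dtype=float)
    n, m = counts.n_alive, counts.n_dead
    alive_below = np.concatenate(([0.0], np.cumsum(alive)[:-1]))
    dead_above = np.concatenate((np.cumsum(dead[::-1])[::-1][1:], [0.0]))
    v10 = (alive_below + 0.5 * alive) / n  # for a case at each level
    v01 = (dead_above + 0.5 * dead) / m  # for a control at each level
    return v10, v01


def delong_variance(counts: ScoreCounts, alpha: float = 0.05) -> AUCEstimate:
    """DeLong variance and Wald CI for a single AUC from per-level counts."""
    _check_classes(counts)
    m, n = counts.n_dead, counts.n_alive
    if m < 2 or n < 2:
        raise DegenerateVarianceError(
            f"DeLong variance needs >= 2 subjects per class (dead={m}, alive={n})"
        )
    auc = auc_tie_corrected(counts)
    v10, v01 = _structural_components(counts)
    dead = np.asarray(counts.dead, dtype=float)
    alive = np.asarray(counts.alive, dtype=float)
    s10 = float(np.sum(dead * (v10 - auc) ** 2)) / (m - 1)
    s01 = float(np.sum(alive * (v01 - auc) ** 2)) / (n - 1)
    variance = s10 / m + s01 / n
    zcrit = stats.norm.ppf(1 - alpha / 2)
    se = math.sqrt(variance)
    return AUCEstimate(
        auc=auc,
        variance=variance,
        ci_low=max(0.0, auc - zcrit * se),
        ci_high=min(1.0, auc + zcrit * se),
        alpha=alpha,
        n_dead=m,
        n_alive=n,
    )


def _components_per_subject(scores, outcomes):
    """Per-subject V10 (cases) and V01 (controls) via midranks, O(N log N)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    cases = s[y == 1]
    controls = s[y == 0]
    m, n = len(cases), len(controls)
    tx = stats.rankdata(np.concatenate([cases, controls]))  # combined midranks
    txx = stats.rankdata(cases)  # within-case midranks
    tyy = stats.rankdata(controls)
    v10 = (tx[:m] - txx) / n
    v01 = 1.0 - (tx[m:] - tyy) / m
    return v10, v01


def delong_paired_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    outcomes: Sequence[int],
) -> DeLongComparison:
    """Paired DeLong test comparing two scores measured on the same subjects.

    Returns the AUC difference ``delta = AUC_a - AUC_b``, its
    structural-component variance, the normal deviate z and the two-sided
    p-value.  Identical score orderings give z = 0, p = 1 exactly.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("scores_a, scores_b and outcomes must have equal length")
    classes = set(np.unique(y))
    if not classes <= {0, 1} or len(classes) < 2:
        raise UndefinedAUCError("outcomes must contain both classes (0 and 1)")
    m = int(np.sum(y == 1))
    n = int(np.sum(y == 0))
    if m < 2 or n < 2:
        raise DegenerateVarianceError(
            f"paired DeLong test needs >= 2 subjects per class (dead={m}, alive={n})"
        )

    v10a, v01a = _components_per_subject(a, y)
    v10b, v01b = _components_per_subject(b, y)
    auc_a = float(np.mean(v10a))
    auc_b = float(np.mean(v10b))
    delta = auc_a - auc_b
    d10 = v10a - v10b
    d01 = v01a - v01b
    # Var(delta) from the component covariance matrices collapses to the
    # sample variances of the per-subject component differences.
    var_delta = 0.0
    if m > 1:
        var_delta += float(np.var(d10, ddof=1)) / m
    if n > 1:
        var_delta += float(np.var(d01, ddof=1)) / n

    if var_delta <= 0.0:
        z = 0.0
        p = 1.0
        if delta != 0.0:  # degenerate: differing AUCs with zero variance
            z = math.inf if delta > 0 else -math.inf
            p = 0.0
    else:
        z = delta / math.sqrt(var_delta)
        p = 2.0 * stats.norm.sf(abs(z))
    return DeLongComparison(
        auc_a=auc_a, auc_b=auc_b, delta=delta,
        variance_delta=var_delta, z=z, p_value=min(p, 1.0),
    )


@dataclass(frozen=True)
class ThresholdMetrics:
    """Operating characteristics at one positivity threshold (score >= t).

    Percentages in [0, 100] at full precision; PPV/NPV are ``None`` when
    their denominator (predicted-positive / predicted-negative set) is empty.
    """

    threshold: float
    sensitivity: float
    specificity: float
    ppv: float | None
    npv: float | None


def threshold_metrics(counts: ScoreCounts, threshold: float) -> ThresholdMetrics:
    """Se/Sp/PPV/NPV of the rule *score >= threshold* against death.

    sensitivity = % dead with score >= t; specificity = % alive with
    score < t; PPV = % dead among predicted positive; NPV = % alive among
    predicted negative.
    """
    _check_classes(counts)
    levels = np.asarray(counts.levels, dtype=float)
    alive = np.asarray(counts.alive, dtype=float)
    dead = np.asarray(counts.dead, dtype=float)
    pos = levels >= threshold
    tp = float(dead[pos].sum())
    fp = float(alive[pos].sum())
    fn = float(dead[~pos].sum())
    tn = float(alive[~pos].sum())
    se = 100.0 * tp / (tp + fn)
    sp = 100.0 * tn / (tn + fp)
    ppv = 100.0 * tp / (tp + fp) if (tp + fp) > 0 else None
    npv = 100.0 * tn / (tn + fn) if (tn + fn) > 0 else None
    return ThresholdMetrics(threshold, se, sp, ppv, npv)


def threshold_ladder(counts: ScoreCounts) -> list[ThresholdMetrics]:
    """Operating characteristics at every observed level, ascending."""
    return [threshold_metrics(counts, t) for t in counts.levels]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def reconstruct_counts_from_ladder(
    sens_by_threshold: Sequence[float],
    spec_by_threshold: Sequence[float],
    n_dead: int,
    n_alive: int,
    levels: Sequence[float] | None = None,
) -> ScoreCounts:
    """Invert a printed Se/Sp ladder back to per-level alive/dead counts.

    The ladders list, for ascending thresholds t, the sensitivity (% dead
    with score >= t) and specificity (% alive with score < t).  Cumulative
    counts are recovered by rounding ``n_dead * Se/100`` and
    ``n_alive * Sp/100`` to the nearest integer and differencing; the
    reconstructed counts sum exactly to ``n_dead`` and ``n_alive``.
    """
    se = np.asarray(sens_by_threshold, dtype=float)
    sp = np.asarray(spec_by_threshold, dtype=float)
    if se.shape != sp.shape:
        raise ValueError("ladders must have equal length")
    if np.any(np.diff(se) > 1e-9):
        raise ValueError("sensitivity must be non-increasing in threshold")
    if np.any(np.diff(sp) < -1e-9):
        raise ValueError("specificity must be non-decreasing in threshold")
    k = len(se)
    if levels is None:
        levels = tuple(float(i) for i in range(k))
    if se[0] != 100.0 or sp[0] != 0.0:
        raise ValueError("ladder must start at the all-positive threshold "
                         "(Se 100, Sp 0)")

    dead_ge = np.array([_round_half_up(n_dead * s / 100.0) for s in se])
    alive_lt = np.array([_round_half_up(n_alive * s / 100.0) for s in sp])
    dead = dead_ge - np.concatenate([dead_ge[1:], [0]])
    alive = np.concatenate([alive_lt[1:], [n_alive]]) - alive_lt
    if np.any(dead < 0) or np.any(alive < 0):
        raise ValueError("negative differenced count after rounding; "
                         "ladder inconsistent with the stated totals")
    return ScoreCounts(tuple(levels), tuple(int(x) for x in alive),
                       tuple(int(x) for x in dead))


def roc_points(counts: ScoreCounts) -> list[tuple[float, float]]:
    """ROC step-curve vertices: ordered (1 - Sp, Se) pairs as proportions.

    One point per threshold, from (0, 0) (threshold above the maximum) to
    (1, 1) (all positive); the trapezoidal area over these points equals the
    tie-corrected Mann–Whitney AUC.
    """
    _check_classes(counts)
    alive = np.asarray(counts.alive, dtype=float)
    dead = np.asarray(counts.dead, dtype=float)
    # descending thresholds: cumulative sums from the top of the scale
    fpr = np.concatenate(([0.0], np.cumsum(alive[::-1]))) / counts.n_alive
    tpr = np.concatenate(([0.0], np.cumsum(dead[::-1]))) / counts.n_dead
    return list(zip(fpr.tolist(), tpr.tolist()))


def trapezoid_area(points: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal area under a piecewise-linear ROC curve."""
    pts = sorted(points)
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    return float(np.trapezoid(ys, xs))
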