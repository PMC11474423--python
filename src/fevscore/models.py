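"""Regression and descriptive statistics for the severity-score validation.

Logistic models quantify the association between each severity score and
death by follow-up, unadjusted and after an a-priori adjustment for age
group, sex and HIV status.  HIV is never entered as a covariate alongside
UVA, because HIV serostatus is a component of the UVA score itself.

Score scales are entered as categorical factors after sparse levels are
merged (fewer than a minimum number of subjects — or, optionally, of deaths —
at a level), with reference level 0 for qSOFA and UVA and level 1 for MEWS.

Model fitting is ordinary maximum likelihood by iteratively reweighted least
squares (via statsmodels' binomial GLM); Wald standard errors come from the
inverse observed information.  Perfect separation is reported, never
silently "fixed".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .roc import ScoreCounts


class SeparationError(RuntimeError):
    """The likelihood is unbounded: a predictor perfectly separates outcomes."""


class RankDeficiencyError(ValueError):
    """The design matrix is rank deficient (collinear columns)."""


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit on the log-odds scale."""

    coefficients: Mapping[str, float]
    standard_errors: Mapping[str, float]
    converged: bool
    iterations: int
    log_likelihood: float
    diagnostic: str = ""

    def odds_ratio(self, name: str) -> float:
        return math.exp(self.coefficients[name])

    def or_ci(self, name: str, alpha: float = 0.05) -> tuple[float, float]:
        z = stats.norm.ppf(1 - alpha / 2)
        beta = self.coefficients[name]
        se = self.standard_errors[name]

        def safe_exp(x: float) -> float:
            try:
                return math.exp(x)
            except OverflowError:  # quasi-separated level: unbounded CI
                return math.inf

        return safe_exp(beta - z * se), safe_exp(beta + z * se)


@dataclass(frozen=True)
class ORRow:
    predictor: str
    level: str
    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    reference: bool = False


@dataclass(frozen=True)
class ORTable:
    """Per-predictor odds ratios with 95% Wald CIs; reference rows have OR 1."""

    rows: tuple[ORRow, ...]
    adjusted: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "predictor": r.predictor,
                    "level": r.level,
                    "odds_ratio": 1.0 if r.reference else r.odds_ratio,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "reference": r.reference,
                }
                for r in self.rows
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < X.shape[1]:
        # name the offending columns via pivoted QR
        _, r_mat, piv = _qr_pivot(arr)
        keep = piv[:rank]
        dropped = [X.columns[i] for i in range(X.shape[1]) if i not in keep]
        raise RankDeficiencyError(
            f"design matrix rank {rank} < {X.shape[1]}; "
            f"collinear columns: {dropped}"
        )


def _qr_pivot(arr: np.ndarray):
    from scipy.linalg import qr

    return qr(arr, mode="economic", pivoting=True)


def fit_logistic(
    design: pd.DataFrame,
    outcome: Sequence[int],
    tolerance: float = 1e-13,
    max_iter: int = 100,
) -> LogisticFit:
    """Fit a logistic model by IRLS; Wald SEs from the inverse information.

    ``design`` must already contain an intercept column if one is wanted
    (conventionally named ``"intercept"``).  Perfect separation is flagged as
    a non-converged fit with a diagnostic message rather than raised, unless
    the optimiser itself fails.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("outcome must contain both classes coded 0/1")
    X = design.astype(float)
    if len(X) != len(y):
        raise ValueError("design and outcome lengths differ")
    for col in X.columns:
        if col != "intercept" and X[col].nunique() == 1:
            raise ValueError(f"predictor column {col!r} is constant")
    _check_rank(X)

    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(maxiter=max_iter, tol=tolerance)
    params = dict(zip(X.columns, res.params))
    bse = dict(zip(X.columns, res.bse))
    iterations = len(res.fit_history.get("deviance", [])) if res.fit_history else max_iter

    diagnostic = ""
    converged = bool(getattr(res, "converged", True))
    mu = np.asarray(res.fittedvalues)
    eps = 1e-8
    separated = (mu[y == 1].min(initial=1.0) > 1 - eps) and (
        mu[y == 0].max(initial=0.0) < eps
    )
    if separated or max(abs(v) for v in params.values()) > 50:
        converged = False
        diagnostic = (
            "perfect (or quasi-complete) separation detected: fitted "
            "probabilities are 0/1 and coefficients diverge; estimates and "
            "standard errors are not interpretable"
        )
    return LogisticFit(
        coefficients=params,
        standard_errors=bse,
        converged=converged,
        iterations=iterations,
        log_likelihood=float(res.llf),
        diagnostic=diagnostic,
    )


# ---------------------------------------------------------------------------
# Sparse-level grouping

def group_sparse_levels(
    counts: ScoreCounts, min_count: int = 5, criterion: str = "total"
) -> tuple[ScoreCounts, dict[float, float]]:
    """Merge sparse score levels, working from the top of the scale downward.

    A level is sparse when its criterion cell — ``"total"`` participants
    (default), ``"dead"`` or ``"alive"`` — holds fewer than ``min_count``
    subjects.  The highest sparse level is repeatedly merged into its lower
    neighbour (the lowest level merges upward), so the mapping is surjective
    and order-preserving.  Each merged group is labelled by its lowest
    original level.

    Returns the grouped counts and the original-level -> grouped-level map.
    If the whole table holds fewer than ``min_count`` subjects the result is
    a single group.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    cell = {"total": lambda a, d: a + d,
            "dead": lambda a, d: d,
            "alive": lambda a, d: a}.get(criterion)
    if cell is None:
        raise ValueError(f"unknown criterion {criterion!r}")

    # groups: list of (member levels, alive, dead), ascending
    groups = [([lv], a, d) for lv, a, d in
              zip(counts.levels, counts.alive, counts.dead)]
    while len(groups) > 1:
        sparse = [i for i, (_, a, d) in enumerate(groups) if cell(a, d) < min_count]
        if not sparse:
            break
        i = max(sparse)
        j = i - 1 if i > 0 else 1  # lowest level merges upward
        lo, hi = min(i, j), max(i, j)
        merged = (
            groups[lo][0] + groups[hi][0],
            groups[lo][1] + groups[hi][1],
            groups[lo][2] + groups[hi][2],
        )
        groups[lo:hi + 1] = [merged]

    mapping: dict[float, float] = {}
    for members, _, _ in groups:
        rep = min(members)
        for lv in members:
            mapping[lv] = rep
    grouped = ScoreCounts(
        tuple(min(m) for m, _, _ in groups),
        tuple(a for _, a, _ in groups),
        tuple(d for _, _, d in groups),
    )
    return grouped, mapping


# ---------------------------------------------------------------------------
# Adjusted / unadjusted OR tables

AGE_BINS = (15, 25, 35, 45, 55, 65)
AGE_LABELS = ("15-<25", "25-<35", "35-<45", "45-<55", "55-<65", "65+")


def age_group(age_years: float) -> str:
    """Six-level age grouping used throughout the analysis (reference 15-<25)."""
    for lo, label in zip(reversed(AGE_BINS), reversed(AGE_LABELS)):
        if age_years >= lo:
            return label
    return AGE_LABELS[0]


def _score_reference(score_name: str, levels: Sequence[float]) -> float:
    # MEWS models are referenced to a score of 1; qSOFA/UVA to 0.
    if score_name.lower() == "mews" and 1 in levels:
        return 1
    return min(levels)


def adjusted_model(
    cohort: pd.DataFrame,
    score_name: str,
    covariates: Sequence[str] = ("age_group", "sex", "hiv"),
    min_count: int = 5,
    criterion: str = "total",
    alpha: float = 0.05,
) -> ORTable:
    """Odds-ratio table for a severity score entered as a grouped factor.

    ``cohort`` must carry a column named after the score (``mews``/``qsofa``/
    ``uva``), an ``outcome`` column coded alive/dead, and the covariate
    columns (``age_years`` or ``age_group``, ``sex``, ``hiv_status``).
    Passing an empty covariate list gives the unadjusted model.

    Requesting HIV adjustment together with UVA is refused: HIV status is a
    component of the UVA score, so the study's models never adjusted UVA for
    HIV.
    """
    score_col = score_name.lower()
    if score_col not in cohort.columns:
        raise KeyError(f"cohort has no {score_col!r} column; score it first")
    covariates = list(covariates)
    if score_col == "uva" and "hiv" in covariates:
        raise ValueError(
            "HIV status cannot be a covariate in UVA models: it is a "
            "component of the UVA score"
        )

    df = cohort.copy()
    y = (df["outcome"].astype(str) == "dead").astype(int).to_numpy()
    counts = ScoreCounts.from_scores(df[score_col].to_numpy(float), y)
    _, mapping = group_sparse_levels(counts, min_count=min_count,
                                     criterion=criterion)
    grouped = df[score_col].map(mapping)
    levels = sorted(grouped.unique())
    ref = _score_reference(score_col, levels)

    X = pd.DataFrame({"intercept": np.ones(len(df))}, index=df.index)
    rows: list[ORRow] = []

    def level_label(lv: float) -> str:
        members = sorted(k for k, v in mapping.items() if v == lv)
        if len(members) == 1:
            return f"{members[0]:g}"
        return f"{members[0]:g}+"

    score_cols = []
    for lv in levels:
        if lv == ref:
            continue
        col = f"{score_col}[{level_label(lv)}]"
        X[col] = (grouped == lv).astype(float)
        score_cols.append((col, lv))

    cov_cols: list[tuple[str, str, str]] = []  # (column, predictor, level)
    for cov in covariates:
        if cov == "age_group":
            ag = (df["age_group"] if "age_group" in df
                  else df["age_years"].map(age_group))
            for label in AGE_LABELS[1:]:
                col = f"age[{label}]"
                X[col] = (ag == label).astype(float)
                cov_cols.append((col, "age_group", label))
        elif cov == "sex":
            col = "sex[male]"
            X[col] = (df["sex"].astype(str) == "male").astype(float)
            cov_cols.append((col, "sex", "male"))
        elif cov == "hiv":
            col = "hiv[positive]"
            X[col] = (df["hiv_status"].astype(str) == "positive").astype(float)
            cov_cols.append((col, "hiv", "positive"))
        else:
            raise ValueError(f"unknown covariate {cov!r}")

    # age levels absent from the data would be constant-zero columns
    X = X.loc[:, [c for c in X.columns if c == "intercept" or X[c].nunique() > 1]]
    fit = fit_logistic(X, y)

    rows.append(ORRow(score_col, level_label(ref), None, None, None,
                      reference=True))
    for col, lv in score_cols:
        if col not in fit.coefficients:
            continue
        lo, hi = fit.or_ci(col, alpha)
        rows.append(ORRow(score_col, level_label(lv), fit.odds_ratio(col),
                          lo, hi))
    seen_ref = set()
    for col, pred, label in cov_cols:
        if pred not in seen_ref:
            ref_label = {"age_group": AGE_LABELS[0], "sex": "female",
                         "hiv": "negative"}[pred]
            rows.append(ORRow(pred, ref_label, None, None, None,
                              reference=True))
            seen_ref.add(pred)
        if col not in fit.coefficients:
            continue
        lo, hi = fit.or_ci(col, alpha)
        rows.append(ORRow(pred, label, fit.odds_ratio(col), lo, hi))
    return ORTable(tuple(rows), adjusted=bool(covariates))


# ---------------------------------------------------------------------------
# Descriptive tests

def chi_squared_test(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-squared test of association on an r x k count table."""
    arr = np.asarray(table, dtype=float)
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero marginal: expected counts are undefined")
    stat, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), float(p)


def mann_whitney_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Tie-corrected Mann–Whitney U test (normal approximation, two-sided).

    U counts pairs where x outranks y (ties 1/2), so ``U / (n_x * n_y)`` is
    exactly the tie-corrected AUC with ``x`` as the case sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)

    n = nx + ny
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    if n > 1:
        sigma_sq = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    else:
        sigma_sq = 0.0
    if sigma_sq <= 0:
        return u, 1.0
    z = (u - nx * ny / 2.0) / math.sqrt(sigma_sq)
    p = 2.0 * stats.norm.sf(abs(z))
    return u, min(p, 1.0)
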