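"""End-to-end validation pipeline.

Takes a canonical cohort table (real or simulated), computes the three
severity scores per participant, applies complete-case filtering, and
produces a structured :class:`AnalysisReport`: per-score AUCs with DeLong
CIs, all pairwise DeLong comparisons, full threshold ladders, subgroup AUCs
(site, patient group), missing-outcome sensitivity analyses (all lost to
follow-up assumed alive; all assumed dead), and unadjusted/adjusted
odds-ratio tables.

Undefined statistics (e.g. a subgroup with a single outcome class) are
emitted as explicit nulls with a reason, never as zeros.  Reports are
deterministic functions of their input.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import models, roc, scoring
from .cohort_sim import COHORT_COLUMNS

logger = logging.getLogger("fevscore")

SCORE_NAMES = ("mews", "qsofa", "uva")

_COMPONENT_FIELDS = (
    "temperature_c", "heart_rate", "resp_rate", "sbp_mmhg", "spo2_pct",
    "gcs_eye", "gcs_verbal", "motor_category", "hiv_status",
)


def _is_missing(series: pd.Series) -> pd.Series:
    return series.isna() | (series.astype(str).str.strip() == "")


def validate_schema(cohort: pd.DataFrame) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")


def add_score_columns(
    cohort: pd.DataFrame,
    plus_hiv: bool = False,
    hiv_points: int = 2,
) -> pd.DataFrame:
    """Append mews/qsofa/uva (and gcs) columns; incomplete rows score NA.

    With ``plus_hiv=True`` the exploratory ``mews_hiv``/``qsofa_hiv``
    variants (base score + ``hiv_points`` if HIV-positive) are added too.
    """
    validate_schema(cohort)
    df = cohort.copy()
    n = len(df)
    out = {name: np.full(n, np.nan) for name in
           ("gcs", "mews", "qsofa", "uva")}
    complete = ~np.logical_or.reduce(
        [_is_missing(df[c]).to_numpy() for c in _COMPONENT_FIELDS]
    )
    for i in np.nonzero(complete)[0]:
        row = df.iloc[i]
        try:
            v = scoring.VitalSigns(
                temperature=float(row["temperature_c"]),
                heart_rate=int(row["heart_rate"]),
                resp_rate=int(row["resp_rate"]),
                sbp=int(row["sbp_mmhg"]),
                spo2=int(row["spo2_pct"]),
            )
            c = scoring.ConsciousnessAssessment(
                eye_response=int(row["gcs_eye"]),
                verbal_response=int(row["gcs_verbal"]),
                motor_category=scoring.MotorCategory(row["motor_category"]),
            )
            hiv = scoring.HIVStatus(row["hiv_status"])
        except (scoring.ValidationError, ValueError) as exc:
            raise ValueError(
                f"row {df.index[i]} (participant "
                f"{row['participant_id']}): {exc}"
            ) from exc
        gcs = scoring.modified_gcs(c)
        out["gcs"][i] = gcs
        out["mews"][i] = scoring.score_mews(v, scoring.avpu_from_gcs(gcs))
        out["qsofa"][i] = scoring.score_qsofa(v, gcs)
        out["uva"][i] = scoring.score_uva(v, gcs, hiv)
    for name, vals in out.items():
        df[name] = vals
    if plus_hiv:
        pos = (df["hiv_status"].astype(str) == "positive").to_numpy()
        df["mews_hiv"] = df["mews"] + np.where(pos, hiv_points, 0)
        df["qsofa_hiv"] = df["qsofa"] + np.where(pos, hiv_points, 0)
    return df


@dataclass(frozen=True)
class FlowCounts:
    """Cohort flow: enrolled -> lost to follow-up -> incomplete -> analysed."""

    enrolled: int
    lost_to_followup: int
    incomplete: int
    analysed: int

    def __post_init__(self):
        if self.analysed != self.enrolled - self.lost_to_followup - self.incomplete:
            raise ValueError("flow counts are inconsistent")


def complete_case_filter(cohort: pd.DataFrame) -> tuple[pd.DataFrame, FlowCounts]:
    """Retain records with all score components, HIV status and outcome.

    Removal reasons are counted in enrolment-flow order: loss to follow-up
    (missing outcome) first, then incomplete score components among those
    followed up.
    """
    validate_schema(cohort)
    n = len(cohort)
    lost_mask = _is_missing(cohort["outcome"])
    followed = cohort.loc[~lost_mask]
    incomplete_mask = np.logical_or.reduce(
        [_is_missing(followed[c]).to_numpy() for c in _COMPONENT_FIELDS]
    )
    analysed = followed.loc[~incomplete_mask]
    flow = FlowCounts(
        enrolled=n,
        lost_to_followup=int(lost_mask.sum()),
        incomplete=int(incomplete_mask.sum()),
        analysed=len(analysed),
    )
    logger.info(
        "complete-case filter: %d enrolled, %d lost to follow-up, "
        "%d missing components, %d analysed",
        flow.enrolled, flow.lost_to_followup, flow.incomplete, flow.analysed,
    )
    return analysed.copy(), flow


def sensitivity_impute_outcome(cohort: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Replace missing follow-up outcomes by ``"alive"`` or ``"dead"``.

    Records with incomplete score components remain excluded downstream;
    only the outcome is imputed.
    """
    if mode not in ("alive", "dead"):
        raise ValueError(f"unknown imputation mode {mode!r}")
    validate_schema(cohort)
    df = cohort.copy()
    df.loc[_is_missing(df["outcome"]), "outcome"] = mode
    return df


# ---------------------------------------------------------------------------
# Report structure


def _auc_entry(scores: np.ndarray, outcomes: np.ndarray,
               alpha: float = 0.05) -> dict[str, Any]:
    """AUC + DeLong CI as a JSON-ready dict, or an explicit null with reason."""
    n = len(outcomes)
    n_dead = int(outcomes.sum())
    n_alive = n - n_dead
    if n_dead < 2 or n_alive < 2:
        return {"auc": None, "ci_low": None, "ci_high": None,
                "variance": None, "n": n, "n_dead": n_dead,
                "reason": "fewer than 2 subjects in one outcome class"}
    counts = roc.ScoreCounts.from_scores(scores, outcomes)
    est = roc.delong_variance(counts, alpha=alpha)
    return {"auc": est.auc, "ci_low": est.ci_low, "ci_high": est.ci_high,
            "variance": est.variance, "n": n, "n_dead": n_dead}


def _pairwise_entry(a: np.ndarray, b: np.ndarray,
                    outcomes: np.ndarray) -> dict[str, Any]:
    cmp = roc.delong_paired_test(a, b, outcomes)
    return {"auc_a": cmp.auc_a, "auc_b": cmp.auc_b, "delta": cmp.delta,
            "variance_delta": cmp.variance_delta, "z": cmp.z,
            "p_value": cmp.p_value}


def _ladder_entry(counts: roc.ScoreCounts) -> list[dict[str, Any]]:
    return [
        {"threshold": t.threshold, "sensitivity": t.sensitivity,
         "specificity": t.specificity, "ppv": t.ppv, "npv": t.npv}
        for t in roc.threshold_ladder(counts)
    ]


@dataclass(frozen=True)
class AnalysisReport:
    """Structured results of the full validation run (JSON-serialisable)."""

    flow: FlowCounts
    descriptives: Mapping[str, Any]
    aucs: Mapping[str, Any]
    pairwise: Mapping[str, Any]
    ladders: Mapping[str, Any]
    subgroups: Mapping[str, Any]
    sensitivity: Mapping[str, Any]
    or_tables: Mapping[str, Any]
    options: Mapping[str, Any]

    def to_dict(self) -> dict[str, Any]:
        return {
            "flow": {
                "enrolled": self.flow.enrolled,
                "lost_to_followup": self.flow.lost_to_followup,
                "incomplete": self.flow.incomplete,
                "analysed": self.flow.analysed,
            },
            "descriptives": self.descriptives,
            "aucs": self.aucs,
            "pairwise": self.pairwise,
            "ladders": self.ladders,
            "subgroups": self.subgroups,
            "sensitivity": self.sensitivity,
            "or_tables": self.or_tables,
            "options": self.options,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        obj = json.loads(text)
        return cls(
            flow=FlowCounts(**obj["flow"]),
            descriptives=obj["descriptives"],
            aucs=obj["aucs"],
            pairwise=obj["pairwise"],
            ladders=obj["ladders"],
            subgroups=obj["subgroups"],
            sensitivity=obj["sensitivity"],
            or_tables=obj["or_tables"],
            options=obj["options"],
        )


def _score_block(df: pd.DataFrame, score_names: Sequence[str],
                 alpha: float) -> tuple[dict, dict, dict]:
    """AUCs, pairwise tests and ladders for an analysed (scored) table."""
    y = (df["outcome"].astype(str) == "dead").astype(int).to_numpy()
    aucs, ladders = {}, {}
    for name in score_names:
        s = df[name].to_numpy(float)
        aucs[name] = _auc_entry(s, y, alpha)
        if aucs[name]["auc"] is not None:
            ladders[name] = _ladder_entry(roc.ScoreCounts.from_scores(s, y))
    pairwise = {}
    for i, a in enumerate(score_names):
        for b in score_names[i + 1:]:
            if aucs[a]["auc"] is None or aucs[b]["auc"] is None:
                pairwise[f"{a}_vs_{b}"] = {
                    "p_value": None,
                    "reason": "AUC undefined in at least one arm",
                }
                continue
            pairwise[f"{a}_vs_{b}"] = _pairwise_entry(
                df[a].to_numpy(float), df[b].to_numpy(float), y
            )
    return aucs, pairwise, ladders


def run_validation(
    cohort: pd.DataFrame,
    plus_hiv: bool = False,
    hiv_points: int = 2,
    subgroup_by: Sequence[str] = ("site", "patient_group"),
    min_count: int = 5,
    grouping_criterion: str = "total",
    alpha: float = 0.05,
    fit_or_tables: bool = True,
) -> AnalysisReport:
    """Run the full severity-score validation on a canonical cohort table."""
    validate_schema(cohort)
    scored = add_score_columns(cohort, plus_hiv=plus_hiv,
                               hiv_points=hiv_points)
    analysed, flow = complete_case_filter(scored)
    y = (analysed["outcome"].astype(str) == "dead").astype(int).to_numpy()

    score_names = list(SCORE_NAMES) + (
        ["mews_hiv", "qsofa_hiv"] if plus_hiv else []
    )
    aucs, pairwise, ladders = _score_block(analysed, score_names, alpha)

    descriptives = {
        "n_analysed": int(len(analysed)),
        "n_dead": int(y.sum()),
        "mortality_pct": 100.0 * float(y.mean()) if len(y) else None,
        "median_age": float(analysed["age_years"].astype(float).median()),
        "pct_female": 100.0 * float(
            (analysed["sex"].astype(str) == "female").mean()
        ),
        "pct_inpatient": 100.0 * float(
            (analysed["patient_group"].astype(str) == "inpatient").mean()
        ),
        "pct_hiv_positive": 100.0 * float(
            (analysed["hiv_status"].astype(str) == "positive").mean()
        ),
    }

    subgroups: dict[str, Any] = {}
    for col in subgroup_by:
        subgroups[col] = {}
        for value, sub in analysed.groupby(analysed[col].astype(str)):
            sub_aucs, sub_pairwise, _ = _score_block(sub, list(SCORE_NAMES),
                                                     alpha)
            subgroups[col][value] = {"aucs": sub_aucs,
                                     "pairwise": sub_pairwise}

    sensitivity: dict[str, Any] = {}
    for mode in ("alive", "dead"):
        imputed = sensitivity_impute_outcome(scored, mode)
        sub_analysed, _ = complete_case_filter(imputed)
        s_aucs, s_pairwise, _ = _score_block(sub_analysed, list(SCORE_NAMES),
                                             alpha)
        sensitivity[f"missing_outcome_set_to_{mode}"] = {
            "n": int(len(sub_analysed)), "aucs": s_aucs,
            "pairwise": s_pairwise,
        }

    or_tables: dict[str, Any] = {}
    if fit_or_tables:
        for name in SCORE_NAMES:
            covs = ["age_group", "sex"] + ([] if name == "uva" else ["hiv"])
            entry = {}
            for label, cov_list in (("unadjusted", []), ("adjusted", covs)):
                try:
                    table = models.adjusted_model(
                        analysed, name, covariates=cov_list,
                        min_count=min_count, criterion=grouping_criterion,
                        alpha=alpha,
                    )
                    frame = table.to_frame()
                    # NaN is not JSON-representable; emit explicit nulls
                    frame = frame.astype(object).where(frame.notna(), None)
                    entry[label] = frame.to_dict(orient="records")
                except (models.SeparationError, ValueError) as exc:
                    entry[label] = {"error": str(exc)}
            or_tables[name] = entry

    options = {
        "plus_hiv": plus_hiv, "hiv_points": hiv_points,
        "subgroup_by": list(subgroup_by), "min_count": min_count,
        "grouping_criterion": grouping_criterion, "alpha": alpha,
        "auc_ci_method": "DeLong structural components, Wald interval",
    }
    return AnalysisReport(
        flow=flow, descriptives=descriptives, aucs=aucs, pairwise=pairwise,
        ladders=ladders, subgroups=subgroups, sensitivity=sensitivity,
        or_tables=or_tables, options=options,
    )


# ---------------------------------------------------------------------------
# Rendering


def _fmt_pct(x: float | None) -> str:
    if x is None:
        return ""
    return f"{math.floor(x * 100 + 0.5) / 100:.2f}"  # half-up at 2 dp


def _fmt_auc(entry: Mapping[str, Any]) -> str:
    if entry.get("auc") is None:
        return "undefined"
    return (f"{entry['auc']:.2f} "
            f"({entry['ci_low']:.2f}-{entry['ci_high']:.2f})")


def _fmt_p(p: float | None) -> str:
    if p is None:
        return "undefined"
    return "p < 0.001" if p < 0.001 else f"p = {p:.3f}"


def render_report(report: AnalysisReport, outdir: str | Path) -> list[Path]:
    """Write the report as JSON (full precision), Markdown and ROC CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    json_path = outdir / "report.json"
    json_path.write_text(report.to_json())
    written.append(json_path)

    lines = ["# Severity-score validation report", ""]
    f = report.flow
    lines += [
        "## Cohort flow",
        "",
        f"- enrolled: {f.enrolled}",
        f"- lost to follow-up: {f.lost_to_followup}",
        f"- missing score components: {f.incomplete}",
        f"- analysed (complete case): {f.analysed}",
        "",
        "## AUCs and pairwise comparisons",
        "",
    ]
    score_cols = [s for s in report.aucs]
    header = "| Analysis | " + " | ".join(s.upper() for s in score_cols) + \
        " | UVA vs MEWS | UVA vs qSOFA | MEWS vs qSOFA |"
    sep = "|" + "---|" * (len(score_cols) + 4)

    def pairwise_cells(pw: Mapping[str, Any]) -> list[str]:
        cells = []
        for key in ("mews_vs_uva", "qsofa_vs_uva", "mews_vs_qsofa"):
            entry = pw.get(key)
            cells.append(_fmt_p(entry.get("p_value")) if entry else "")
        return cells

    lines.append(header)
    lines.append(sep)
    row = ["Complete case"] + [_fmt_auc(report.aucs[s]) for s in score_cols]
    row += pairwise_cells(report.pairwise)
    lines.append("| " + " | ".join(row) + " |")
    for label, block in report.sensitivity.items():
        row = [label.replace("_", " ")] + [
            _fmt_auc(block["aucs"].get(s, {})) for s in score_cols
        ]
        row += pairwise_cells(block["pairwise"])
        lines.append("| " + " | ".join(row) + " |")
    for col, groups in report.subgroups.items():
        for value, block in sorted(groups.items()):
            row = [f"{col}: {value}"] + [
                _fmt_auc(block["aucs"].get(s, {})) for s in score_cols
            ]
            row += pairwise_cells(block["pairwise"])
            lines.append("| " + " | ".join(row) + " |")

    lines += ["", "## Operating characteristics", ""]
    for name, ladder in report.ladders.items():
        lines += [f"### {name.upper()}", "",
                  "| Threshold | Specificity | Sensitivity | NPV | PPV |",
                  "|---|---|---|---|---|"]
        for rowd in ladder:
            lines.append(
                "| {t:g} | {sp} | {se} | {npv} | {ppv} |".format(
                    t=rowd["threshold"], sp=_fmt_pct(rowd["specificity"]),
                    se=_fmt_pct(rowd["sensitivity"]),
                    npv=_fmt_pct(rowd["npv"]), ppv=_fmt_pct(rowd["ppv"]),
                )
            )
        lines.append("")

    md_path = outdir / "report.md"
    md_path.write_text("\n".join(lines))
    written.append(md_path)

    for name, ladder in report.ladders.items():
        counts_levels = [rowd["threshold"] for rowd in ladder]
        se = [rowd["sensitivity"] / 100.0 for rowd in ladder]
        sp = [rowd["specificity"] / 100.0 for rowd in ladder]
        pts = pd.DataFrame({
            "threshold": counts_levels,
            "fpr": [1.0 - s for s in sp],
            "tpr": se,
        })
        p = outdir / f"roc_{name}.csv"
        pts.to_csv(p, index=False)
        written.append(p)
    return written
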