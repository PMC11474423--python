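"""Published summary tables from the multicentre febrile-cohort validation.

These are the printed, de-identified summary statistics of the study the
package validates against: the qSOFA score-by-outcome contingency, the full
sensitivity/specificity ladders of all three scores, and the HIV-by-outcome
two-by-two table.  They are sufficient statistics — per-level counts and
operating-characteristic ladders — not individual-level data, and they let
the ROC engine reproduce the study's headline numbers exactly.

Totals: 2797 participants analysed, of whom 185 (7%) had died by follow-up
and 2612 were alive.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .roc import ScoreCounts, reconstruct_counts_from_ladder

#: Participants analysed / dead / alive by the time of follow-up.
N_TOTAL = 2797
N_DEAD = 185
N_ALIVE = 2612

#: qSOFA score-by-outcome contingency (scores 0-3).
QSOFA_COUNTS = ScoreCounts(
    levels=(0, 1, 2, 3),
    alive=(1387, 1047, 176, 2),
    dead=(49, 79, 50, 7),
)

#: HIV status by outcome.  ``total`` is the printed subgroup denominator,
#: which in the source table disagrees with dead+alive by 10 (685 vs 675 for
#: HIV-positive); the printed mortality percentages (17% / 3%) use ``total``.
HIV_OUTCOME_TABLE = {
    "positive": {"dead": 112, "alive": 573, "total": 675},
    "negative": {"dead": 73, "alive": 2039, "total": 2104},
}

# Printed operating-characteristic ladders: for ascending thresholds t,
# specificity (% alive with score < t) and sensitivity (% dead >= t).
MEWS_LADDER = {
    "thresholds": tuple(range(12)),
    "specificity": (0.00, 22.32, 42.84, 63.09, 77.34, 87.17,
                    94.87, 98.47, 99.73, 99.96, 100.00, 100.00),
    "sensitivity": (100.00, 91.35, 77.30, 63.24, 45.41, 29.19,
                    20.00, 8.11, 4.86, 1.62, 1.08, 0.00),
}

QSOFA_LADDER = {
    "thresholds": tuple(range(5)),
    "specificity": (0.00, 53.10, 93.19, 99.92, 100.00),
    "sensitivity": (100.00, 73.51, 30.81, 3.78, 0.00),
}

UVA_LADDER = {
    "thresholds": tuple(range(12)),
    "specificity": (0.00, 56.97, 72.47, 89.78, 95.21, 97.78,
                    98.85, 99.58, 99.85, 99.92, 100.00, 100.00),
    "sensitivity": (100.00, 87.57, 81.62, 55.14, 36.22, 22.70,
                    13.51, 4.86, 2.16, 1.08, 0.54, 0.00),
}

LADDERS = {"mews": MEWS_LADDER, "qsofa": QSOFA_LADDER, "uva": UVA_LADDER}


def counts_from_ladder(score: str) -> ScoreCounts:
    """Per-level alive/dead counts recovered from a printed ladder.

    ``score`` is one of ``"mews"``, ``"qsofa"``, ``"uva"``.
    """
    ladder = LADDERS[score.lower()]
    return reconstruct_counts_from_ladder(
        ladder["sensitivity"], ladder["specificity"],
        n_dead=N_DEAD, n_alive=N_ALIVE,
        levels=ladder["thresholds"],
    )


def write_fixture_csvs(outdir: str | Path) -> list[Path]:
    """Write the contingency and ladder fixtures as CSV files; return paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    p = outdir / "qsofa_by_outcome.csv"
    QSOFA_COUNTS.to_csv(p)
    written.append(p)
    for name, ladder in LADDERS.items():
        p = outdir / f"{name}_ladder.csv"
        pd.DataFrame(
            {
                "threshold": ladder["thresholds"],
                "specificity": ladder["specificity"],
                "sensitivity": ladder["sensitivity"],
            }
        ).to_csv(p, index=False)
        written.append(p)
    return written
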