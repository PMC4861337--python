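"""Published summary data bundled for demonstrations and cross-checks.

The raw per-expert responses of the wasting/stunting priority-setting
exercise this package models were never deposited, but its ranked table of
top-ten questions — per-criterion percentage scores (answerability,
usefulness, impact), the overall research priority score and the average
expert agreement, all at printed precision — is public. Those rows are
bundled here so the scoring and ranking layers can be exercised against real
published numbers.

Note one quirk of the printed table: the question ranked 9th (Q11) prints an
RPS of 82.8, while the mean of its printed criterion scores is 82.87 -> 82.9;
the published RPS column was evidently computed before the criterion scores
were rounded for print. Recomputation from the printed triples therefore
reproduces every row except that one to one decimal, and reproduces the full
rank order exactly (82.9 for Q23 stays above 82.87 for Q11 at full precision).
"""

from __future__ import annotations

import pandas as pd

from .survey_model import Criterion, Question, ScoreTable, SurveyDesign

__all__ = ["wasting_stunting_top10", "top10_design", "top10_score_table", "CRITERIA"]

CRITERIA = ("answerability", "usefulness", "impact")

# rank, question_no, label, answerability, usefulness, impact, rps_printed, aea_printed
_TOP10 = [
    (1, 24, "Interventions outside the 1000 days leading to catch-up in height",
     93.8, 93.8, 85.7, 91.1, 0.84),
    (2, 27, "Timely interventions to mitigate seasonal peaks in undernutrition",
     93.3, 86.7, 86.7, 88.9, 0.80),
    (3, 20, "Optimal RUTF formulation for ponderal and linear growth",
     84.4, 93.8, 83.3, 87.2, 0.85),
    (4, 7, "Role of pre-pregnancy nutritional status in wasting/stunting risk at birth",
     88.2, 86.7, 85.7, 86.9, 0.82),
    (5, 28, "Effective intervention packages for maternal nutrition and newborn outcomes",
     93.3, 90.6, 75.0, 86.3, 0.79),
    (6, 21, "Nutrition convalescent support to prevent both wasting and stunting",
     89.3, 90.6, 73.3, 84.4, 0.79),
    (7, 30, "Practical linkages between treatment and prevention interventions",
     78.1, 90.6, 83.3, 84.0, 0.74),
    (8, 23, "New interventions for treating severe stunting to prevent mortality",
     71.9, 87.5, 89.3, 82.9, 0.74),
    (9, 11, "Role of gut health/inflammation in wasting",
     81.3, 90.6, 76.7, 82.8, 0.72),
    (10, 5, "Does treatment of wasting support catch-up in linear growth",
     86.1, 78.1, 80.0, 81.4, 0.77),
]


def wasting_stunting_top10() -> pd.DataFrame:
    """Printed top-ten rows: ranks, question numbers, criterion scores, RPS, AEA."""
    return pd.DataFrame(
        _TOP10,
        columns=[
            "rank", "question_no", "label",
            "answerability", "usefulness", "impact",
            "rps_printed", "aea_printed",
        ],
    )


def top10_design() -> SurveyDesign:
    """A 10-question design for the published top-ten, ordered by question
    number (not by rank, so ranking must be earned from the scores)."""
    rows = sorted(_TOP10, key=lambda r: r[1])
    return SurveyDesign(
        questions=[Question(f"Q{r[1]}", r[2]) for r in rows],
        criteria=[Criterion(c) for c in CRITERIA],
    )


def top10_score_table() -> ScoreTable:
    """ScoreTable built from the printed criterion-score triples (equal weights)."""
    design = top10_design()
    df = wasting_stunting_top10().assign(
        question_id=lambda d: "Q" + d["question_no"].astype(str)
    ).set_index("question_id")
    return ScoreTable.from_criterion_scores(
        design, df[list(CRITERIA)].astype(float)
    )
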