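"""Criterion scores, research priority scores and ranking.

Each question receives one score per judging criterion,

    S_qc = 100 * mean(point values of substantive answers to cell (q, c)),

where substantive means yes (1), no (0) or undecided (0.5); missing input and
unreached cells are excluded from numerator and denominator alike. The
research priority score is the weighted mean over the criteria with a defined
score,

    RPS_q = sum_c w_c * S_qc / sum_c w_c,

which with the default equal weights is the plain mean the classic CHNRI
write-ups report. All arithmetic is carried at full precision; one-decimal
rounding is a display concern only (see :func:`round_half_up`), so ranking can
never depend on printed precision.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .errors import ComputationError, ValidationError
from .survey_model import ResponseMatrix, ScoreTable, AgreementTable, SurveyDesign

__all__ = [
    "CriterionScore",
    "criterion_score",
    "research_priority_score",
    "score_all",
    "rank_questions",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (display convention).

    Python's built-in ``round`` is banker's rounding; priority tables are
    conventionally printed with 93.75 -> 93.8, so displays use this instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


class CriterionScore(NamedTuple):
    score: float | None  # percentage in [0, 100]; None when no responder
    n_responders: int


def _check_ids(design: SurveyDesign, question_id: str, criterion_id: str) -> None:
    if question_id not in set(design.question_ids):
        raise ValidationError(f"unknown question_id {question_id!r}")
    if criterion_id not in set(design.criterion_ids):
        raise ValidationError(f"unknown criterion_id {criterion_id!r}")


def criterion_score(
    matrix: ResponseMatrix, question_id: str, criterion_id: str
) -> CriterionScore:
    """Percentage score for one question under one criterion.

    Returns ``(score, n_responders)``; the score is undefined (``None``) when
    no expert gave a substantive answer. The single final division keeps the
    result the correctly-rounded double of the exact rational value.
    """
    _check_ids(matrix.design, question_id, criterion_id)
    total = 0.0
    n = 0
    for e in matrix.experts:
        cat = matrix.answers.get((e, question_id, criterion_id))
        if cat is None:
            continue
        pv = cat.point_value
        if pv is None:
            continue
        total += pv
        n += 1
    if n == 0:
        return CriterionScore(None, 0)
    return CriterionScore((100.0 * total) / n, n)


def research_priority_score(
    criterion_scores: Mapping[str, float | None],
    weights: Mapping[str, float] | None = None,
) -> float | None:
    """Weighted mean of the defined criterion scores; ``None`` if none defined.

    Weights are renormalised over the criteria that actually have a score, so
    a question with no responders under one criterion is averaged over the
    rest rather than silently penalised. Equal weights reproduce the
    unweighted mean.
    """
    defined = [(c, s) for c, s in criterion_scores.items() if s is not None]
    if not defined:
        return None
    if weights is None:
        total = 0.0
        for _, s in defined:
            total += s
        return total / len(defined)
    wsum = 0.0
    acc = 0.0
    for c, s in defined:
        w = float(weights.get(c, 0.0))
        if w < 0:
            raise ValidationError(f"negative weight for criterion {c!r}")
        acc += w * s
        wsum += w
    if wsum <= 0:
        raise ValidationError("weights over the defined criteria sum to zero")
    return acc / wsum


def score_all(
    matrix: ResponseMatrix, weights: Mapping[str, float] | None = None
) -> ScoreTable:
    """Score every question of the design; vectorised over the dense arrays."""
    design = matrix.design
    if weights is None:
        weights = design.weights
    _codes, points = matrix.to_arrays()
    n = np.sum(~np.isnan(points), axis=0)  # (Q, C) responder counts
    with np.errstate(invalid="ignore"):
        totals = np.nansum(points, axis=0)
        scores = np.where(n > 0, (100.0 * totals) / np.maximum(n, 1), np.nan)
    cs = pd.DataFrame(scores, index=design.question_ids, columns=design.criterion_ids)
    nr = pd.DataFrame(
        n.astype(int), index=design.question_ids, columns=design.criterion_ids
    )
    rps = pd.Series(
        {
            q: _rps_or_nan(cs.loc[q], weights)
            for q in design.question_ids
        },
        dtype=float,
    ).reindex(design.question_ids)
    return ScoreTable(
        design=design,
        criterion_scores=cs,
        n_responders=nr,
        rps=rps,
        weights=dict(weights) if weights is not None else None,
    )


def _rps_or_nan(row: pd.Series, weights: Mapping[str, float] | None) -> float:
    val = research_priority_score(
        {c: (None if pd.isna(v) else float(v)) for c, v in row.items()}, weights
    )
    return np.nan if val is None else val


def rank_order(
    rps: np.ndarray, aea: np.ndarray | None = None
) -> np.ndarray:
    """Dense 1-based ranks for an RPS vector (NaN RPS -> rank 0, excluded).

    Descending RPS on full-precision values; exact ties broken by higher AEA
    when supplied, then by position (design order). Returned as an int array
    aligned with the input.
    """
    rps = np.asarray(rps, dtype=float)
    q = rps.size
    defined = ~np.isnan(rps)
    if not defined.any():
        raise ComputationError("no question has a defined RPS; cannot rank")
    if aea is None:
        tiebreak = np.zeros(q)
    else:
        tiebreak = np.where(np.isnan(np.asarray(aea, dtype=float)), -np.inf,
                            np.asarray(aea, dtype=float))
    idx = np.arange(q)[defined]
    # lexsort: last key is primary
    order = idx[np.lexsort((idx, -tiebreak[defined], -rps[defined]))]
    ranks = np.zeros(q, dtype=int)
    ranks[order] = np.arange(1, order.size + 1)
    return ranks


def rank_questions(
    table: ScoreTable, agreement: AgreementTable | None = None
) -> ScoreTable:
    """Return a copy of the table with dense 1-based ranks attached.

    Questions are ordered by descending RPS (full precision). Exact RPS ties
    are broken by higher average expert agreement when an agreement table is
    supplied, then by design order; questions with undefined RPS are flagged
    by an NA rank and excluded from the permutation.
    """
    design = table.design
    rps = table.rps.reindex(design.question_ids).to_numpy(dtype=float)
    aea = (
        agreement.aea.reindex(design.question_ids).to_numpy(dtype=float)
        if agreement is not None
        else None
    )
    ranks = rank_order(rps, aea)
    rank_series = pd.Series(
        pd.array([r if r > 0 else pd.NA for r in ranks], dtype="Int64"),
        index=design.question_ids,
    )
    return ScoreTable(
        design=design,
        criterion_scores=table.criterion_scores,
        n_responders=table.n_responders,
        rps=table.rps,
        rank=rank_series,
        weights=table.weights,
    )
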