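"""Average expert agreement (AEA) and modal-response fractions.

For one question x criterion cell, the modal fraction is

    f_qc = N(most frequent substantive answer) / N(any substantive answer),

with the three substantive categories yes / no / undecided; "insufficiently
informed" and unreached cells enter neither count. The average expert
agreement of a question is the unweighted mean of the defined modal fractions
over its criterion queries (three in the classic survey):

    AEA_q = (1 / C) * sum_c f_qc.

AEA measures consensus versus controversy: 1 means every responding expert
gave the same answer everywhere; with three categories the modal fraction
cannot fall below 1/3 (attained only by a perfect three-way split). Ties in
the mode are harmless — only the maximal count enters the fraction.
"""

from __future__ import annotations

from collections import Counter
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ComputationError
from .survey_model import (
    AgreementTable,
    ResponseMatrix,
    SUBSTANTIVE_CODES,
)
from .scoring import _check_ids

__all__ = [
    "ModalFraction",
    "modal_fraction",
    "average_expert_agreement",
    "agreement_all",
]


class ModalFraction(NamedTuple):
    fraction: float | None  # None when no substantive responder
    modal_count: int
    responder_count: int


def modal_fraction(
    matrix: ResponseMatrix, question_id: str, criterion_id: str
) -> ModalFraction:
    """Modal substantive-answer fraction for one cell; undefined when empty."""
    _check_ids(matrix.design, question_id, criterion_id)
    counts: Counter = Counter()
    for e in matrix.experts:
        cat = matrix.answers.get((e, question_id, criterion_id))
        if cat is not None and cat.point_value is not None:
            counts[cat] += 1
    responders = sum(counts.values())
    if responders == 0:
        return ModalFraction(None, 0, 0)
    modal = max(counts.values())
    return ModalFraction(modal / responders, modal, responders)


def average_expert_agreement(matrix: ResponseMatrix, question_id: str) -> float | None:
    """Mean modal fraction over the question's criteria with >=1 responder."""
    fractions = []
    for c in matrix.design.criterion_ids:
        mf = modal_fraction(matrix, question_id, c)
        if mf.fraction is not None:
            fractions.append(mf.fraction)
    if not fractions:
        return None
    total = 0.0
    for f in fractions:
        total += f
    return total / len(fractions)


def agreement_all(matrix: ResponseMatrix) -> AgreementTable:
    """AEA for every question, with per-criterion modal details, vectorised."""
    design = matrix.design
    codes, _points = matrix.to_arrays()
    # counts per substantive category, shape (3, Q, C)
    cat_counts = np.stack([(codes == k).sum(axis=0) for k in SUBSTANTIVE_CODES])
    responder = cat_counts.sum(axis=0)
    modal = cat_counts.max(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = np.where(responder > 0, modal / np.maximum(responder, 1), np.nan)
    idx, cols = design.question_ids, design.criterion_ids
    mf = pd.DataFrame(fractions, index=idx, columns=cols)
    aea = pd.Series(
        {
            q: (np.nan if np.isnan(fractions[i]).all()
                else _seq_mean(fractions[i][~np.isnan(fractions[i])]))
            for i, q in enumerate(idx)
        },
        dtype=float,
    ).reindex(idx)
    if aea.isna().all():
        raise ComputationError("no question has any substantive responder")
    return AgreementTable(
        design=design,
        modal_counts=pd.DataFrame(modal, index=idx, columns=cols),
        responder_counts=pd.DataFrame(responder, index=idx, columns=cols),
        modal_fractions=mf,
        aea=aea,
    )


def _seq_mean(values: np.ndarray) -> float:
    # left-to-right summation, matching the scalar definition exactly
    total = 0.0
    for v in values:
        total += float(v)
    return total / values.size
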