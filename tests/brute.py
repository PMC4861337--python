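"""Independent brute-force oracle for criterion scores, RPS and AEA.

Deliberately naive: walks the answers mapping directly, counts with
``collections.Counter``, and does exact rational arithmetic with
``fractions.Fraction``, converting to float only at the very end (one
correctly-rounded conversion per statistic component). Shares no code with
the package implementation.
"""

from collections import Counter
from fractions import Fraction

from chnri.survey_model import ResponseCategory

_POINTS = {
    ResponseCategory.YES: Fraction(1),
    ResponseCategory.NO: Fraction(0),
    ResponseCategory.UNDECIDED: Fraction(1, 2),
}


def brute_criterion_score(matrix, question_id, criterion_id):
    """(score float | None, n_responders) by direct enumeration."""
    vals = []
    for (e, q, c), cat in matrix.answers.items():
        if q == question_id and c == criterion_id and cat in _POINTS:
            vals.append(_POINTS[cat])
    if not vals:
        return None, 0
    exact = Fraction(100) * sum(vals) / len(vals)
    return float(exact), len(vals)


def brute_rps(matrix, question_id):
    """Plain mean of the defined criterion scores, in design order."""
    scores = []
    for c in matrix.design.criterion_ids:
        s, _ = brute_criterion_score(matrix, question_id, c)
        if s is not None:
            scores.append(s)
    if not scores:
        return None
    total = 0.0
    for s in scores:
        total += s
    return total / len(scores)


def brute_modal_fraction(matrix, question_id, criterion_id):
    counts = Counter(
        cat
        for (e, q, c), cat in matrix.answers.items()
        if q == question_id and c == criterion_id and cat in _POINTS
    )
    n = sum(counts.values())
    if n == 0:
        return None
    return float(Fraction(max(counts.values()), n))


def brute_aea(matrix, question_id):
    fractions = []
    for c in matrix.design.criterion_ids:
        f = brute_modal_fraction(matrix, question_id, c)
        if f is not None:
            fractions.append(f)
    if not fractions:
        return None
    total = 0.0
    for f in fractions:
        total += f
    return total / len(fractions)
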