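"""Domain types, validation and delimited-text I/O for CHNRI-style surveys.

A CHNRI priority-setting exercise asks a panel of experts to judge each
candidate research question against a fixed set of criteria (here typically
answerability, usefulness and impact), one categorical answer per
expert x question x criterion cell:

* ``yes``        — worth 1 point,
* ``no``         — worth 0 points,
* ``undecided``  — worth 0.5 points,
* ``insufficiently informed`` — treated as missing input; carries no points
  and is excluded from every denominator.

The canonical interchange format is a long (tidy) CSV with one row per
(expert_id, question_id, criterion_id, response). A cell with no row at all
(an expert who stopped the survey early, or never took part) is distinct from
an explicit missing answer; both are "no score" for the statistics but the
distinction is preserved on round-trip.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import pandas as pd
import yaml

from .errors import ValidationError

__all__ = [
    "ResponseCategory",
    "Question",
    "Criterion",
    "SurveyDesign",
    "ResponseMatrix",
    "ScoreTable",
    "AgreementTable",
    "CompletionSummary",
    "read_responses",
    "write_responses",
    "completion_summary",
]

RESPONSE_COLUMNS = ("expert_id", "question_id", "criterion_id", "response")


class ResponseCategory(enum.Enum):
    """One expert's answer to one question under one criterion."""

    YES = "yes"
    NO = "no"
    UNDECIDED = "undecided"
    MISSING = "missing"

    @property
    def point_value(self) -> float | None:
        """Score points carried by the answer; ``None`` for MISSING."""
        return _POINTS[self]

    @classmethod
    def from_label(cls, label: str) -> "ResponseCategory":
        """Parse a survey-export label, case-insensitively after trimming.

        Both ``missing`` and ``insufficiently informed`` map to MISSING;
        any other label is rejected rather than coerced.
        """
        key = str(label).strip().lower()
        try:
            return _LABELS[key]
        except KeyError:
            raise ValidationError(f"unknown response label {label!r}") from None


_POINTS: dict[ResponseCategory, float | None] = {
    ResponseCategory.YES: 1.0,
    ResponseCategory.NO: 0.0,
    ResponseCategory.UNDECIDED: 0.5,
    ResponseCategory.MISSING: None,
}

_LABELS: dict[str, ResponseCategory] = {
    "yes": ResponseCategory.YES,
    "no": ResponseCategory.NO,
    "undecided": ResponseCategory.UNDECIDED,
    "missing": ResponseCategory.MISSING,
    "insufficiently informed": ResponseCategory.MISSING,
}

# integer codes used by the array representation; -1 marks an absent cell
_CODES = {
    ResponseCategory.YES: 0,
    ResponseCategory.NO: 1,
    ResponseCategory.UNDECIDED: 2,
    ResponseCategory.MISSING: 3,
}
_CATEGORY_BY_CODE = {v: k for k, v in _CODES.items()}
SUBSTANTIVE_CODES = (0, 1, 2)  # yes, no, undecided
POINTS_BY_CODE = (1.0, 0.0, 0.5)


@dataclass(frozen=True)
class Question:
    question_id: str
    text: str = ""
    theme: str | None = None


@dataclass(frozen=True)
class Criterion:
    criterion_id: str
    text: str = ""


@dataclass
class SurveyDesign:
    """Ordered questions and judging criteria, with optional criterion weights.

    Weights default to equal (the unweighted mean most CHNRI exercises use);
    when supplied they must be non-negative with positive sum and are used
    normalised as ``w_c / sum(w)``.
    """

    questions: list[Question]
    criteria: list[Criterion]
    weights: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.questions = [
            q if isinstance(q, Question) else Question(str(q)) for q in self.questions
        ]
        self.criteria = [
            c if isinstance(c, Criterion) else Criterion(str(c)) for c in self.criteria
        ]
        if not self.questions:
            raise ValidationError("design needs at least one question")
        if not self.criteria:
            raise ValidationError("design needs at least one criterion")
        qids = [q.question_id for q in self.questions]
        cids = [c.criterion_id for c in self.criteria]
        if len(set(qids)) != len(qids):
            raise ValidationError("question_ids are not unique")
        if len(set(cids)) != len(cids):
            raise ValidationError("criterion_ids are not unique")
        if self.weights is not None:
            if set(self.weights) != set(cids):
                raise ValidationError("weights must cover exactly the design criteria")
            vals = [float(self.weights[c]) for c in cids]
            if any(v < 0 for v in vals):
                raise ValidationError("criterion weights must be non-negative")
            if sum(vals) <= 0:
                raise ValidationError("criterion weights must have positive sum")
            self.weights = {c: float(self.weights[c]) for c in cids}

    @property
    def question_ids(self) -> list[str]:
        return [q.question_id for q in self.questions]

    @property
    def criterion_ids(self) -> list[str]:
        return [c.criterion_id for c in self.criteria]

    @property
    def n_questions(self) -> int:
        return len(self.questions)

    @property
    def n_criteria(self) -> int:
        return len(self.criteria)

    @classmethod
    def simple(
        cls,
        n_questions: int,
        criteria: Iterable[str] = ("answerability", "usefulness", "impact"),
    ) -> "SurveyDesign":
        """Convenience design with questions Q1..Qn and the classic criteria."""
        return cls(
            questions=[Question(f"Q{i + 1}") for i in range(n_questions)],
            criteria=[Criterion(c) for c in criteria],
        )

    @classmethod
    def from_yaml(cls, path) -> "SurveyDesign":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, Mapping):
            raise ValidationError(f"design file {path} is not a mapping")
        try:
            questions = [
                Question(str(q["id"]), str(q.get("text", "")), q.get("theme"))
                if isinstance(q, Mapping)
                else Question(str(q))
                for q in raw["questions"]
            ]
            criteria = [
                Criterion(str(c["id"]), str(c.get("text", "")))
                if isinstance(c, Mapping)
                else Criterion(str(c))
                for c in raw["criteria"]
            ]
        except KeyError as exc:
            raise ValidationError(f"design file missing key {exc}") from None
        weights = raw.get("weights")
        if weights is not None:
            weights = {str(k): float(v) for k, v in weights.items()}
        return cls(questions=questions, criteria=criteria, weights=weights)

    def to_yaml(self, path) -> None:
        doc: dict = {
            "questions": [
                {"id": q.question_id, "text": q.text, "theme": q.theme}
                for q in self.questions
            ],
            "criteria": [{"id": c.criterion_id, "text": c.text} for c in self.criteria],
        }
        if self.weights is not None:
            doc["weights"] = dict(self.weights)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class ResponseMatrix:
    """The expert x question x criterion categorical answers.

    ``answers`` maps (expert_id, question_id, criterion_id) to a
    :class:`ResponseCategory`. Keys absent from the map are cells the expert
    never reached (distinct from an explicit MISSING answer). Expert order is
    the order of ``experts``; question/criterion order comes from the design.
    """

    design: SurveyDesign
    experts: list[str]
    answers: dict[tuple[str, str, str], ResponseCategory] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.experts = [str(e) for e in self.experts]
        if len(set(self.experts)) != len(self.experts):
            raise ValidationError("expert_ids are not unique")
        eset = set(self.experts)
        qset = set(self.design.question_ids)
        cset = set(self.design.criterion_ids)
        for (e, q, c), cat in self.answers.items():
            if e not in eset:
                raise ValidationError(f"answer references unknown expert_id {e!r}")
            if q not in qset:
                raise ValidationError(f"answer references unknown question_id {q!r}")
            if c not in cset:
                raise ValidationError(f"answer references unknown criterion_id {c!r}")
            if not isinstance(cat, ResponseCategory):
                raise ValidationError(f"answer for {(e, q, c)} is not a ResponseCategory")

    @classmethod
    def from_records(
        cls,
        design: SurveyDesign,
        records: Iterable[tuple[str, str, str, ResponseCategory | str]],
        experts: list[str] | None = None,
    ) -> "ResponseMatrix":
        """Build a matrix from (expert, question, criterion, answer) tuples.

        Expert order defaults to first appearance; string answers are parsed
        as labels. Duplicate cells are an error.
        """
        answers: dict[tuple[str, str, str], ResponseCategory] = {}
        seen_experts: list[str] = []
        for e, q, c, a in records:
            key = (str(e), str(q), str(c))
            if key in answers:
                raise ValidationError(f"duplicate answer for {key}")
            answers[key] = (
                a if isinstance(a, ResponseCategory) else ResponseCategory.from_label(a)
            )
            if key[0] not in seen_experts:
                seen_experts.append(key[0])
        return cls(design=design, experts=experts or seen_experts, answers=answers)

    @property
    def n_experts(self) -> int:
        return len(self.experts)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long DataFrame (expert_id, question_id, criterion_id, response)
        in expert-major, design order; absent cells produce no row."""
        qorder = self.design.question_ids
        corder = self.design.criterion_ids
        rows = [
            (e, q, c, self.answers[(e, q, c)].value)
            for e in self.experts
            for q in qorder
            for c in corder
            if (e, q, c) in self.answers
        ]
        return pd.DataFrame(rows, columns=list(RESPONSE_COLUMNS))

    def to_arrays(self):
        """Dense integer codes, shape (n_experts, n_questions, n_criteria).

        Codes: 0=yes, 1=no, 2=undecided, 3=missing, -1=absent (no record).
        Returned alongside the matching float point array (NaN where the cell
        carries no points, i.e. missing or absent).
        """
        import numpy as np

        E, Q, C = self.n_experts, self.design.n_questions, self.design.n_criteria
        ei = {e: i for i, e in enumerate(self.experts)}
        qi = {q: i for i, q in enumerate(self.design.question_ids)}
        ci = {c: i for i, c in enumerate(self.design.criterion_ids)}
        codes = np.full((E, Q, C), -1, dtype=np.int8)
        for (e, q, c), cat in self.answers.items():
            codes[ei[e], qi[q], ci[c]] = _CODES[cat]
        points = np.full((E, Q, C), np.nan)
        for code, pt in zip(SUBSTANTIVE_CODES, POINTS_BY_CODE):
            points[codes == code] = pt
        return codes, points

    def subset_experts(self, experts: list[str]) -> "ResponseMatrix":
        keep = set(experts)
        answers = {k: v for k, v in self.answers.items() if k[0] in keep}
        return ResponseMatrix(design=self.design, experts=list(experts), answers=answers)


def category_from_code(code: int) -> ResponseCategory:
    return _CATEGORY_BY_CODE[int(code)]


def read_responses(path, design: SurveyDesign) -> ResponseMatrix:
    """Read a long-format response CSV and validate it against the design.

    Expects header columns ``expert_id, question_id, criterion_id, response``;
    response labels are matched case-insensitively and may use either
    ``missing`` or ``insufficiently informed`` for missing input. Duplicate
    (expert, question, criterion) rows and unknown identifiers are errors that
    name the offending row (1-based file line, header = line 1).
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"response file {path} is empty") from None
    missing_cols = set(RESPONSE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValidationError(
            f"response file {path} lacks required columns {sorted(missing_cols)}"
        )
    if df.empty:
        raise ValidationError(f"response file {path} has no data rows")

    qset = set(design.question_ids)
    cset = set(design.criterion_ids)
    answers: dict[tuple[str, str, str], ResponseCategory] = {}
    experts: list[str] = []
    seen_experts: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header occupies line 1
        e, q, c, r = (
            str(row.expert_id),
            str(row.question_id),
            str(row.criterion_id),
            row.response,
        )
        if q not in qset:
            raise ValidationError(f"line {line}: unknown question_id {q!r}")
        if c not in cset:
            raise ValidationError(f"line {line}: unknown criterion_id {c!r}")
        key = (e, q, c)
        if key in answers:
            raise ValidationError(f"line {line}: duplicate answer for {key}")
        try:
            answers[key] = ResponseCategory.from_label(r)
        except ValidationError as exc:
            raise ValidationError(f"line {line}: {exc}") from None
        if e not in seen_experts:
            seen_experts.add(e)
            experts.append(e)
    return ResponseMatrix(design=design, experts=experts, answers=answers)


def write_responses(matrix: ResponseMatrix, path) -> None:
    """Write the matrix as canonical long CSV; round-trips exactly.

    Explicit MISSING answers are written as rows (label ``missing``); absent
    cells produce no row, so the partial-completion structure survives I/O.
    """
    df = matrix.to_frame()
    if df.empty:
        raise ValidationError("refusing to write a matrix with no answers")
    df.to_csv(path, index=False)


class CompletionSummary(NamedTuple):
    n_took_part: int
    n_complete: int
    participation_pct: int


def completion_summary(matrix: ResponseMatrix, panel_size: int) -> CompletionSummary:
    """Participation bookkeeping against the invited panel size.

    An expert *took part* if they have at least one recorded answer (an
    explicit "insufficiently informed" counts as a record); they *completed*
    the survey if every question x criterion cell has a record. The
    participation percentage is reported to the nearest integer, as CHNRI
    write-ups print it (e.g. 18 of 25 -> 72%).
    """
    answered_by: dict[str, int] = {e: 0 for e in matrix.experts}
    for (e, _, _), _cat in matrix.answers.items():
        answered_by[e] += 1
    n_cells = matrix.design.n_questions * matrix.design.n_criteria
    n_took_part = sum(1 for n in answered_by.values() if n > 0)
    n_complete = sum(1 for n in answered_by.values() if n == n_cells)
    if panel_size < n_took_part:
        raise ValidationError(
            f"panel_size {panel_size} smaller than number of responders {n_took_part}"
        )
    pct = int(round(100.0 * n_took_part / panel_size)) if panel_size else 0
    return CompletionSummary(n_took_part, n_complete, pct)


@dataclass
class ScoreTable:
    """Per-question criterion scores (0-100%), RPS, responder counts, ranks.

    ``criterion_scores`` and ``n_responders`` are question x criterion frames
    (NaN / 0 where no expert gave a substantive answer); ``rps`` is the
    per-question research priority score and ``rank`` the 1-based dense rank
    (NA until ranking has been applied, and for questions with undefined RPS).
    """

    design: SurveyDesign
    criterion_scores: pd.DataFrame
    n_responders: pd.DataFrame
    rps: pd.Series
    rank: pd.Series | None = None
    weights: dict[str, float] | None = None

    @classmethod
    def from_criterion_scores(
        cls,
        design: SurveyDesign,
        criterion_scores: pd.DataFrame,
        n_responders: pd.DataFrame | None = None,
        weights: dict[str, float] | None = None,
    ) -> "ScoreTable":
        """Build a table from already-summarised criterion scores.

        Useful when only the published per-criterion percentages are available
        (as in a published ranked table) rather than raw responses. RPS is
        recomputed from the given scores with the given weights.
        """
        from .scoring import research_priority_score

        cs = criterion_scores.reindex(
            index=design.question_ids, columns=design.criterion_ids
        ).astype(float)
        if n_responders is None:
            n_responders = cs.notna().astype(int) * 0
        rps = pd.Series(
            {
                q: research_priority_score(
                    {c: (None if pd.isna(v) else float(v)) for c, v in cs.loc[q].items()},
                    weights=weights,
                )
                for q in design.question_ids
            },
            dtype=float,
        ).reindex(design.question_ids)
        return cls(
            design=design,
            criterion_scores=cs,
            n_responders=n_responders,
            rps=rps,
            weights=weights,
        )

    def rps_range(self) -> tuple[float, float]:
        defined = self.rps.dropna()
        return float(defined.min()), float(defined.max())

    def to_frame(self) -> pd.DataFrame:
        """Flat frame: question_id, rank, one column per criterion score,
        per-criterion responder counts, rps (full precision)."""
        out = pd.DataFrame({"question_id": self.design.question_ids})
        out["rank"] = (
            self.rank.reindex(self.design.question_ids).values
            if self.rank is not None
            else pd.array([pd.NA] * len(out), dtype="Int64")
        )
        for c in self.design.criterion_ids:
            out[c] = self.criterion_scores[c].reindex(self.design.question_ids).values
        for c in self.design.criterion_ids:
            out[f"n_{c}"] = self.n_responders[c].reindex(self.design.question_ids).values
        out["rps"] = self.rps.reindex(self.design.question_ids).values
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class AgreementTable:
    """Per-question AEA with the per-criterion modal-response details.

    For each question x criterion cell: ``modal_counts`` is the count of the
    most frequent substantive answer, ``responder_counts`` the count of all
    substantive answers, ``modal_fractions`` their ratio. ``aea`` is the
    unweighted mean of the defined modal fractions of each question.
    """

    design: SurveyDesign
    modal_counts: pd.DataFrame
    responder_counts: pd.DataFrame
    modal_fractions: pd.DataFrame
    aea: pd.Series

    def aea_range(self) -> tuple[float, float]:
        defined = self.aea.dropna()
        return float(defined.min()), float(defined.max())

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"question_id": self.design.question_ids})
        out["aea"] = self.aea.reindex(self.design.question_ids).values
        for c in self.design.criterion_ids:
            out[f"modal_count_{c}"] = self.modal_counts[c].values
            out[f"responder_count_{c}"] = self.responder_counts[c].values
            out[f"modal_fraction_{c}"] = self.modal_fractions[c].values
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
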