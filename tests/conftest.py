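import pytest

from chnri.survey_model import ResponseCategory, ResponseMatrix, SurveyDesign

Y = ResponseCategory.YES
N = ResponseCategory.NO
U = ResponseCategory.UNDECIDED
M = ResponseCategory.MISSING


def make_matrix(design, records, experts=None):
    """(expert, question, criterion, category) tuples -> validated matrix."""
    return ResponseMatrix.from_records(design, records, experts=experts)


@pytest.fixture
def design_2x2():
    return SurveyDesign.simple(2, criteria=("c1", "c2"))


@pytest.fixture
def toy_matrix(design_2x2):
    """Two questions, two criteria, three experts; e3 stopped after Q1.

    Hand-computed ground truth:
      Q1/c1: {Y, U, N}  -> 50.0, 3 responders, modal 1/3
      Q1/c2: {Y, Y, M}  -> 100.0, 2 responders, modal 1
      Q2/c1: {N, U}     -> 25.0, 2 responders, modal 1/2
      Q2/c2: {Y, N}     -> 50.0, 2 responders, modal 1/2
      RPS: Q1 = 75.0, Q2 = 37.5; AEA: Q1 = 2/3, Q2 = 1/2
    """
    return make_matrix(
        design_2x2,
        [
            ("e1", "Q1", "c1", Y), ("e1", "Q1", "c2", Y),
            ("e1", "Q2", "c1", N), ("e1", "Q2", "c2", Y),
            ("e2", "Q1", "c1", U), ("e2", "Q1", "c2", Y),
            ("e2", "Q2", "c1", U), ("e2", "Q2", "c2", N),
            ("e3", "Q1", "c1", N), ("e3", "Q1", "c2", M),
        ],
    )
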