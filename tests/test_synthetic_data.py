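import numpy as np
import pytest

from chnri.agreement import agreement_all
from chnri.errors import ValidationError
from chnri.scoring import score_all
from chnri.survey_model import Question, ResponseCategory, SurveyDesign
from chnri.synthetic_data import (
    PanelSpec,
    aea_reference,
    canonical_query_order,
    expected_criterion_scores,
    expected_rps,
    generate_panel,
    recovery_experiment,
)


@pytest.fixture
def small_design():
    return SurveyDesign.simple(4)


class TestPanelSpec:
    def test_invalid_probability_vectors_rejected(self, small_design):
        with pytest.raises(ValidationError):
            PanelSpec(design=small_design, cell_probs=(0.5, 0.5, 0.5, 0.5))
        with pytest.raises(ValidationError):
            PanelSpec(design=small_design, cell_probs=(0.9, 0.2, -0.1, 0.0))
        with pytest.raises(ValidationError):
            PanelSpec(design=small_design, cell_probs=(1.0, 0.0, 0.0))

    def test_experts_cannot_exceed_invited(self, small_design):
        with pytest.raises(ValidationError):
            PanelSpec(design=small_design, n_invited=10, n_experts=11)

    def test_cascading_probability_overrides(self):
        design = SurveyDesign(
            questions=[Question("Q1", theme="t1"), Question("Q2", theme="t2")],
            criteria=["c1", "c2"],
        )
        spec = PanelSpec(
            design=design,
            cell_probs={
                "default": (0.25, 0.25, 0.25, 0.25),
                "themes": {"t2": (0.7, 0.1, 0.1, 0.1)},
                "cells": {"Q1:c2": (1.0, 0.0, 0.0, 0.0)},
            },
        )
        probs = spec.resolve_probs()
        np.testing.assert_allclose(probs[0, 0], (0.25, 0.25, 0.25, 0.25))
        np.testing.assert_allclose(probs[0, 1], (1.0, 0.0, 0.0, 0.0))
        np.testing.assert_allclose(probs[1, 0], (0.7, 0.1, 0.1, 0.1))

    def test_consensus_sharpens_toward_mode(self, small_design):
        base = PanelSpec(design=small_design, cell_probs=(0.5, 0.3, 0.1, 0.1))
        sharp = PanelSpec(design=small_design, cell_probs=(0.5, 0.3, 0.1, 0.1),
                          consensus=0.5)
        p0, p1 = base.resolve_probs()[0, 0], sharp.resolve_probs()[0, 0]
        assert p1[0] > p0[0]            # modal category gains mass
        assert p1[3] == pytest.approx(p0[3])  # missing mass untouched
        assert p1.sum() == pytest.approx(1.0)
        full = PanelSpec(design=small_design, cell_probs=(0.5, 0.3, 0.1, 0.1),
                         consensus=1.0).resolve_probs()[0, 0]
        np.testing.assert_allclose(full, (0.9, 0.0, 0.0, 0.1))


class TestGeneratePanel:
    def test_deterministic_given_seed(self, small_design):
        spec = PanelSpec(design=small_design, seed=42)
        assert generate_panel(spec).answers == generate_panel(spec).answers

    def test_different_seed_differs(self, small_design):
        a = generate_panel(PanelSpec(design=small_design, seed=1))
        b = generate_panel(PanelSpec(design=small_design, seed=2))
        assert a.answers != b.answers

    def test_degenerate_yes_panel(self, small_design):
        spec = PanelSpec(design=small_design, cell_probs=(1.0, 0.0, 0.0, 0.0),
                         partial_completion_rate=0.0, seed=5)
        panel = generate_panel(spec)
        assert set(panel.answers.values()) == {ResponseCategory.YES}
        assert (score_all(panel).criterion_scores == 100.0).all().all()
        assert (agreement_all(panel).aea == 1.0).all()

    def test_partial_completers_answer_canonical_prefix(self, small_design):
        spec = PanelSpec(design=small_design, partial_completion_rate=1.0, seed=9)
        panel = generate_panel(spec)
        order = canonical_query_order(small_design)
        for e in panel.experts:
            answered = [k for k, (q, c) in enumerate(order)
                        if (e, q, c) in panel.answers]
            assert answered == list(range(len(answered)))  # a prefix
            assert 1 <= len(answered) < len(order)

    def test_sample_mean_matches_expectation(self):
        # p = (0.5, 0.3, 0.2, 0): expected score 100*(0.5 + 0.1) = 60
        design = SurveyDesign.simple(1, criteria=("c",))
        spec = PanelSpec(design=design, n_invited=500, n_experts=500,
                         cell_probs=(0.5, 0.3, 0.2, 0.0),
                         partial_completion_rate=0.0, seed=17)
        score = score_all(generate_panel(spec)).criterion_scores.iat[0, 0]
        # sd of point values = sqrt(0.55 - 0.36); 3 binomial-style SEs
        se = 100 * np.sqrt(0.19) / np.sqrt(500)
        assert abs(score - 60.0) < 3 * se

    def test_generated_panels_validate_and_roundtrip(self, small_design, tmp_path):
        from chnri.survey_model import read_responses, write_responses

        panel = generate_panel(PanelSpec(design=small_design, seed=23))
        path = tmp_path / "panel.csv"
        write_responses(panel, path)
        back = read_responses(path, small_design)
        assert back.answers == panel.answers


class TestExpectations:
    def test_closed_form_criterion_expectation(self, small_design):
        spec = PanelSpec(design=small_design, cell_probs=(0.5, 0.3, 0.2, 0.0))
        assert (expected_criterion_scores(spec) == 60.0).all().all()
        assert (expected_rps(spec) == 60.0).all()

    def test_missingness_rescales_denominator(self, small_design):
        spec = PanelSpec(design=small_design, cell_probs=(0.45, 0.27, 0.18, 0.10))
        np.testing.assert_allclose(
            expected_criterion_scores(spec).to_numpy(), 60.0, rtol=1e-12
        )

    def test_aea_reference_degenerate_case(self):
        assert aea_reference((1.0, 0.0, 0.0, 0.0), 18, 1000, seed=0) == 1.0

    def test_aea_reference_bounds_and_determinism(self):
        a = aea_reference((1 / 3, 1 / 3, 1 / 3, 0.0), 18, 5000, seed=4)
        b = aea_reference((1 / 3, 1 / 3, 1 / 3, 0.0), 18, 5000, seed=4)
        assert a == b
        assert 1 / 3 < a < 1.0


class TestConsensusMonotonicity:
    def test_mean_aea_nondecreasing_in_consensus(self):
        design = SurveyDesign.simple(5)
        means = []
        for consensus in (0.0, 0.3, 0.6, 0.9):
            vals = []
            for seed in range(25):
                spec = PanelSpec(design=design, cell_probs=(0.5, 0.3, 0.2, 0.0),
                                 consensus=consensus,
                                 partial_completion_rate=0.0, seed=seed)
                vals.append(agreement_all(generate_panel(spec)).aea.mean())
            means.append(np.mean(vals))
        assert all(b >= a - 1e-9 for a, b in zip(means, means[1:]))
        assert means[-1] > means[0]


class TestRecoveryExperiment:
    def test_degenerate_spec_zero_bias_zero_spread(self, small_design):
        spec = PanelSpec(design=small_design, cell_probs=(1.0, 0.0, 0.0, 0.0),
                         partial_completion_rate=0.0, seed=0)
        summary = recovery_experiment(spec, n_replicates=5, seed=1,
                                      aea_reference_replicates=1000)
        assert (summary.per_question["rps_bias"] == 0.0).all()
        assert (summary.per_question["rps_sd"] == 0.0).all()
        assert (summary.per_question["aea_bias"] == 0.0).all()

    def test_mixed_spec_small_bias(self):
        design = SurveyDesign.simple(3)
        spec = PanelSpec(design=design, cell_probs=(0.55, 0.2, 0.15, 0.1),
                         partial_completion_rate=0.0, seed=0)
        summary = recovery_experiment(spec, n_replicates=120, seed=7,
                                      aea_reference_replicates=20_000)
        se = summary.per_question["rps_sd"] / np.sqrt(summary.n_replicates)
        assert (summary.per_question["rps_bias"].abs() <= 4 * se).all()

    def test_spread_shrinks_with_panel_size(self):
        design = SurveyDesign.simple(2)
        kwargs = dict(cell_probs=(0.55, 0.2, 0.15, 0.1),
                      partial_completion_rate=0.0, seed=0)
        small = recovery_experiment(
            PanelSpec(design=design, n_experts=18, n_invited=25, **kwargs),
            n_replicates=150, seed=3, aea_reference_replicates=2000)
        large = recovery_experiment(
            PanelSpec(design=design, n_experts=180, n_invited=180, **kwargs),
            n_replicates=150, seed=3, aea_reference_replicates=2000)
        ratio = (large.per_question["rps_sd"] / small.per_question["rps_sd"]).mean()
        # binomial variance scaling predicts 1/sqrt(10) ~ 0.316
        assert ratio < 0.6

    def test_requires_at_least_two_replicates(self, small_design):
        with pytest.raises(ValidationError):
            recovery_experiment(PanelSpec(design=small_design), n_replicates=1)
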