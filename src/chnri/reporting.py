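"""Human-readable ranking tables and the end-to-end pipeline runner."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from .agreement import agreement_all
from .errors import ChnriError, StageError, ValidationError
from .scoring import rank_questions, round_half_up, score_all
from .stability import aea_rps_association, bootstrap_ranks
from .survey_model import (
    AgreementTable,
    ScoreTable,
    SurveyDesign,
    read_responses,
)

__all__ = ["render_ranking", "ranking_to_text", "run_pipeline", "plot_aea_rps"]

log = logging.getLogger("chnri")


def render_ranking(
    scores: ScoreTable,
    agreement: AgreementTable | None = None,
    top_k: int = 10,
) -> pd.DataFrame:
    """Ranked display table, truncated to the top ``top_k`` questions.

    Columns: question, rank, question_no (the question_id), one column per
    criterion (one decimal), rps (one decimal) and, when an agreement table is
    supplied, aea (two decimals). Display rounding happens here and only here.
    """
    if top_k < 1:
        raise ValidationError("top_k must be >= 1")
    if scores.rank is None:
        scores = rank_questions(scores, agreement)
    design = scores.design
    text_by_id = {q.question_id: q.text for q in design.questions}
    rows = []
    for qid in design.question_ids:
        rank = scores.rank.get(qid)
        if pd.isna(rank) or int(rank) > top_k:
            continue
        row: dict = {
            "question": text_by_id[qid] or qid,
            "rank": int(rank),
            "question_no": qid,
        }
        for c in design.criterion_ids:
            v = scores.criterion_scores.at[qid, c]
            row[c] = None if pd.isna(v) else round_half_up(float(v), 1)
        rps = scores.rps.get(qid)
        row["rps"] = None if pd.isna(rps) else round_half_up(float(rps), 1)
        if agreement is not None:
            aea = agreement.aea.get(qid)
            row["aea"] = None if pd.isna(aea) else round_half_up(float(aea), 2)
        rows.append(row)
    out = pd.DataFrame(rows).sort_values("rank").reset_index(drop=True)
    return out


def ranking_to_text(table: pd.DataFrame) -> str:
    return table.to_string(index=False) + "\n"


def plot_aea_rps(scores: ScoreTable, agreement: AgreementTable, path, top_k: int = 10):
    """Scatter of AEA against RPS with the top-k questions highlighted."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if scores.rank is None:
        scores = rank_questions(scores, agreement)
    qids = scores.design.question_ids
    rps = scores.rps.reindex(qids)
    aea = agreement.aea.reindex(qids)
    in_top = scores.rank.reindex(qids).astype("float").le(top_k).fillna(False)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(rps[~in_top], aea[~in_top], color="grey", label="other questions")
    ax.scatter(rps[in_top], aea[in_top], color="red", label=f"top {top_k} by RPS")
    ax.set_xlabel("Research priority score (RPS, %)")
    ax.set_ylabel("Average expert agreement (AEA)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, metadata={})
    plt.close(fig)


def run_pipeline(
    responses_path,
    design_path,
    out_dir,
    weights: Mapping[str, float] | None = None,
    top_k: int = 10,
    with_stability: bool = False,
    bootstrap_reps: int = 2000,
    n_permutations: int = 9999,
    seed: int = 0,
    fmt: str = "csv",
    plot: bool = False,
) -> dict[str, Path]:
    """read -> validate -> score -> rank -> agreement -> (stability) -> render.

    Writes every artifact into ``out_dir`` and returns the paths. Any stage
    failure is re-raised as :class:`StageError` naming the stage, which the
    CLI maps to a non-zero exit status.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def stage(name: str, fn):
        try:
            return fn()
        except ChnriError as exc:
            raise StageError(name, exc) from exc
        except OSError as exc:
            raise StageError(name, exc) from exc

    design = stage("read-design", lambda: SurveyDesign.from_yaml(design_path))
    matrix = stage("read-responses", lambda: read_responses(responses_path, design))
    scores = stage("score", lambda: score_all(matrix, weights))
    agreement = stage("agreement", lambda: agreement_all(matrix))
    scores = stage("rank", lambda: rank_questions(scores, agreement))

    n_answered = len({e for (e, _, _) in matrix.answers})
    log.info("experts with answers: %d of %d listed", n_answered, matrix.n_experts)
    log.info("RPS range: %.1f to %.1f", *scores.rps_range())
    log.info("AEA range: %.2f to %.2f", *agreement.aea_range())

    def write_outputs():
        scores.to_csv(out_dir / "scores.csv")
        paths["scores"] = out_dir / "scores.csv"
        agreement.to_csv(out_dir / "agreement.csv")
        paths["agreement"] = out_dir / "agreement.csv"
        table = render_ranking(scores, agreement, top_k=top_k)
        table.to_csv(out_dir / "ranking.csv", index=False)
        paths["ranking"] = out_dir / "ranking.csv"
        if fmt in ("txt", "text"):
            (out_dir / "ranking.txt").write_text(ranking_to_text(table))
            paths["ranking_txt"] = out_dir / "ranking.txt"
        elif fmt == "json":
            table.to_json(out_dir / "ranking.json", orient="records", indent=2)
            paths["ranking_json"] = out_dir / "ranking.json"

    stage("render", write_outputs)

    if with_stability:
        def run_stability():
            report = bootstrap_ranks(
                matrix, weights, n_replicates=bootstrap_reps, seed=seed, top_k=top_k
            )
            report.to_csv(out_dir / "stability.csv")
            report.to_json(out_dir / "stability.json")
            paths["stability"] = out_dir / "stability.csv"

        def run_association():
            assoc = aea_rps_association(
                scores, agreement, n_permutations=n_permutations, seed=seed
            )
            assoc.to_json(out_dir / "association.json")
            paths["association"] = out_dir / "association.json"

        stage("stability", run_stability)
        stage("association", run_association)

    if plot:
        stage(
            "plot",
            lambda: plot_aea_rps(scores, agreement, out_dir / "aea_rps.png", top_k),
        )
        paths["plot"] = out_dir / "aea_rps.png"
    return paths
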