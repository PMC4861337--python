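"""Rank stability under panel resampling, and the AEA-RPS association.

Priority-setting panels are small (typically ~18 scorers), so the published
ranking carries sampling noise. :func:`bootstrap_ranks` resamples experts —
the unit whose scarcity drives the concern — with replacement, recomputes the
full score/agreement/rank pipeline per replicate, and summarises each
question's rank distribution plus a global concordance (Kendall's W across
replicate rankings, reported together with the equivalent mean pairwise
Spearman correlation).

:func:`aea_rps_association` quantifies the familiar CHNRI pattern that
higher-scoring questions attract more agreement: an ordinary least-squares
fit of AEA on RPS with a two-sided permutation test for the slope (add-one
estimator, never exactly zero), alongside the classical t-based p-value for
reference.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ComputationError
from .scoring import rank_order
from .survey_model import (
    AgreementTable,
    ResponseMatrix,
    ScoreTable,
    SUBSTANTIVE_CODES,
    POINTS_BY_CODE,
)

__all__ = [
    "StabilityReport",
    "AssociationReport",
    "bootstrap_ranks",
    "aea_rps_association",
]


@dataclass
class StabilityReport:
    """Bootstrap rank-distribution summary.

    ``per_question`` columns: observed_rank, median_rank, rank_lo / rank_hi
    (central 95% interval), p_top_k. ``concordance_w`` is Kendall's W over the
    replicate rankings; ``mean_pairwise_spearman`` the equivalent
    (B*W - 1)/(B - 1) average pairwise rank correlation.
    """

    per_question: pd.DataFrame
    concordance_w: float
    mean_pairwise_spearman: float
    n_replicates: int
    seed: int
    top_k: int
    n_dropped_replicates: int = 0

    def to_json(self, path) -> None:
        doc = {
            "concordance_w": self.concordance_w,
            "mean_pairwise_spearman": self.mean_pairwise_spearman,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "top_k": self.top_k,
            "n_dropped_replicates": self.n_dropped_replicates,
            "per_question": self.per_question.reset_index()
            .rename(columns={"index": "question_id"})
            .to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    def to_csv(self, path) -> None:
        self.per_question.rename_axis("question_id").to_csv(path)


@dataclass
class AssociationReport:
    """OLS fit of AEA on RPS with permutation inference for the slope."""

    slope: float
    intercept: float
    p_permutation: float
    p_t: float  # classical two-sided t-based p, for reference
    r_squared: float
    n_questions: int
    n_permutations: int
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def _replicate_statistics(codes: np.ndarray, weights_vec: np.ndarray | None):
    """RPS and AEA vectors from a (E, Q, C) code array (codes as in to_arrays)."""
    counts = np.stack([(codes == k).sum(axis=0) for k in SUBSTANTIVE_CODES])  # (3,Q,C)
    n = counts.sum(axis=0)
    totals = sum(
        pt * counts[i] for i, pt in enumerate(POINTS_BY_CODE)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(n > 0, (100.0 * totals) / np.maximum(n, 1), np.nan)
        fractions = np.where(n > 0, counts.max(axis=0) / np.maximum(n, 1), np.nan)
    defined = ~np.isnan(scores)
    if weights_vec is None:
        w = np.ones(scores.shape[1])
    else:
        w = weights_vec
    wmask = defined * w[None, :]
    wsum = wmask.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rps = np.where(
            wsum > 0,
            np.nansum(np.where(defined, scores, 0.0) * wmask, axis=1) / np.maximum(wsum, 1e-300),
            np.nan,
        )
        n_def = (~np.isnan(fractions)).sum(axis=1)
        aea = np.where(
            n_def > 0,
            np.nansum(np.where(np.isnan(fractions), 0.0, fractions), axis=1)
            / np.maximum(n_def, 1),
            np.nan,
        )
    return rps, aea


def bootstrap_ranks(
    matrix: ResponseMatrix,
    weights=None,
    n_replicates: int = 2000,
    seed: int = 0,
    top_k: int = 10,
) -> StabilityReport:
    """Expert-resampling bootstrap of the priority ranking.

    Each replicate draws ``n_experts`` experts with replacement, recomputes
    criterion scores, RPS, AEA, and the dense ranking (AEA tie-break), and
    records every question's rank. Replicates in which some question loses
    all responders are dropped from the global concordance (counted in the
    report) but still contribute the ranks they define. Deterministic given
    ``seed``; invariant to expert relabeling by construction.
    """
    if n_replicates < 1:
        raise ComputationError("n_replicates must be >= 1")
    answered = {e for (e, _, _) in matrix.answers}
    if len(answered) < 2:
        raise ComputationError(
            "bootstrap needs >= 2 experts with answers; resampling is degenerate"
        )
    design = matrix.design
    if weights is None:
        weights = design.weights
    wvec = (
        np.array([float(weights[c]) for c in design.criterion_ids])
        if weights is not None
        else None
    )
    codes, _ = matrix.to_arrays()
    E, Q, _C = codes.shape
    rng = np.random.default_rng(seed)
    ranks = np.zeros((n_replicates, Q))
    for b in range(n_replicates):
        idx = rng.integers(0, E, size=E)
        rps, aea = _replicate_statistics(codes[idx], wvec)
        if np.isnan(rps).all():
            ranks[b] = np.nan
            continue
        r = rank_order(rps, aea).astype(float)
        r[r == 0] = np.nan
        ranks[b] = r

    obs_rps, obs_aea = _replicate_statistics(codes, wvec)
    obs_rank = rank_order(obs_rps, obs_aea).astype(float)
    obs_rank[obs_rank == 0] = np.nan

    per_question = pd.DataFrame(
        {
            "observed_rank": obs_rank,
            "median_rank": np.nanmedian(ranks, axis=0),
            "rank_lo": np.nanpercentile(ranks, 2.5, axis=0),
            "rank_hi": np.nanpercentile(ranks, 97.5, axis=0),
            "p_top_k": np.nanmean(ranks <= top_k, axis=0),
        },
        index=design.question_ids,
    )

    complete = ~np.isnan(ranks).any(axis=1)
    n_dropped = int((~complete).sum())
    W, mean_rho = _kendall_w(ranks[complete])
    return StabilityReport(
        per_question=per_question,
        concordance_w=W,
        mean_pairwise_spearman=mean_rho,
        n_replicates=n_replicates,
        seed=seed,
        top_k=top_k,
        n_dropped_replicates=n_dropped,
    )


def _kendall_w(ranks: np.ndarray) -> tuple[float, float]:
    """Kendall's coefficient of concordance over B complete rankings of Q items
    (tie-free: each ranking is a permutation), and the implied mean pairwise
    Spearman correlation (B*W - 1)/(B - 1)."""
    B, Q = ranks.shape
    if B < 2 or Q < 2:
        return float("nan"), float("nan")
    totals = ranks.sum(axis=0)
    S = float(((totals - totals.mean()) ** 2).sum())
    W = 12.0 * S / (B**2 * (Q**3 - Q))
    mean_rho = (B * W - 1.0) / (B - 1.0)
    return W, mean_rho


def aea_rps_association(
    scores: ScoreTable,
    agreement: AgreementTable,
    n_permutations: int = 9999,
    seed: int = 0,
) -> AssociationReport:
    """Least-squares slope of AEA on RPS with a permutation p-value.

    The null randomly relabels the AEA values across questions, preserving
    both marginals; p = (1 + #{|slope_perm| >= |slope_obs|}) / (1 + m), the
    add-one estimator. A classical t-based p-value from the same OLS fit is
    reported for reference. Deterministic given ``seed``.
    """
    qids = scores.design.question_ids
    x = scores.rps.reindex(qids).to_numpy(dtype=float)
    y = agreement.aea.reindex(qids).to_numpy(dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ComputationError("association needs >= 3 questions with defined RPS and AEA")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise ComputationError("zero variance in RPS; slope undefined")

    # closed-form OLS; the same expression scores the permutations, so the
    # observed and permuted slopes are exactly comparable
    slope = float(xc @ y / sxx)
    intercept = float(y.mean() - slope * x.mean())
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    p_t = float(fit.pvalues[1])

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(y, (n_permutations, 1)), axis=1)
    perm_slopes = perms @ xc / sxx
    p_perm = (1.0 + float(np.sum(np.abs(perm_slopes) >= abs(slope)))) / (
        1.0 + n_permutations
    )
    return AssociationReport(
        slope=slope,
        intercept=intercept,
        p_permutation=p_perm,
        p_t=p_t,
        r_squared=float(fit.rsquared),
        n_questions=n,
        n_permutations=n_permutations,
        seed=seed,
    )
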