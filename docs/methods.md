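# Methods

## The scoring model

The package implements the quantitative core of the CHNRI (Child Health and
Nutrition Research Initiative) research-priority-setting methodology as used
in expert surveys on child undernutrition: a panel of experts judges each of
Q candidate research questions against C criteria (canonically answerability,
usefulness and impact), answering each of the Q×C queries with one of

| answer | points |
|---|---|
| yes | 1 |
| no | 0 |
| undecided | 0.5 |
| insufficiently informed | — (missing input) |

For question *q* and criterion *c*, with substantive answers (yes / no /
undecided) from *n_qc* experts,

    S_qc = 100 · (Σ points) / n_qc          (criterion score, %)

The research priority score is the weighted mean over criteria with a defined
score,

    RPS_q = Σ_c w_c S_qc / Σ_c w_c ,

with equal weights by default (reproducing the unweighted mean used by the
exercise this package models, which deliberately omitted the
stakeholder-weighting stage). Weights are renormalised over *defined*
criterion scores, so a question with no responders under one criterion is
averaged over the rest rather than silently penalised.

The average expert agreement is the mean modal-response fraction,

    AEA_q = (1/C) Σ_c  N(most frequent substantive answer to (q,c))
                      / N(any substantive answer to (q,c)) .

With three substantive categories each modal fraction lies in [1/3, 1]; the
1/3 floor is attained only by a perfect three-way split (possible when n_qc
is divisible by 3), so the implementation and tests use the closed bound.
Modal ties need no tie-break: only the maximal count enters the fraction.

Questions are ranked by descending full-precision RPS. Exact ties are broken
by higher AEA when available, then by design order; ranks are dense (1..Q).
The published tables this methodology produces print RPS to one decimal and
AEA to two; the package keeps full precision everywhere and applies
round-half-up display rounding only in renderers. This matters: the bundled
published top-ten table contains one row whose printed RPS (82.8) disagrees
with the mean of its printed criterion scores (82.87 → 82.9), showing that
its RPS column was computed before rounding — ranking on displayed values
would be unstable exactly where scores are close.

## Missing data and partial completion

Two kinds of "no score" are distinguished and preserved through I/O:
an explicit *insufficiently informed* answer (a recorded row) and an *absent*
cell (the expert stopped the survey early or never took part). Both are
excluded from every numerator and denominator; participation bookkeeping
(`completion_summary`) counts an expert as having taken part if they have any
recorded answer, and as complete if every cell has a record. Partial
completers contribute to every cell they answered, which is consistent with
published per-criterion responder counts that vary across questions.

## Stability diagnostics

Because these panels are small (typically ~18 scorers), the ranking carries
sampling noise. `bootstrap_ranks` resamples **experts** with replacement —
the expert is the scarce sampling unit — and recomputes scores, AEA and the
full ranking per replicate. It reports each question's median rank, central
95% rank interval and probability of staying in the top-k, plus Kendall's W
across replicate rankings and the equivalent mean pairwise Spearman
correlation (B·W − 1)/(B − 1). Replicates in which a question loses all its
responders yield no complete ranking and are excluded from the concordance
(counted in the report).

`aea_rps_association` fits AEA on RPS by ordinary least squares and tests the
slope with a two-sided permutation test (random relabeling of AEA across
questions, add-one p-value (1 + #{|b*| ≥ |b|})/(1 + m), never exactly zero).
Permutation inference is the primary p-value because Q is small and scores
are bounded; the classical t-based p from the same fit is reported for
reference. The observed slope is computed with the same closed-form
covariance/variance expression that scores the permutations, so observed and
permuted statistics are exactly comparable even in degenerate cases
(constant AEA → slope 0, p ≈ 1).

Defaults: 2000 bootstrap replicates, 9999 permutations, seed 0; all
configurable, and every randomised stage is deterministic given its seed.

## The synthetic panel generator

No raw per-expert responses were published for the exercise this package
models, so validation runs on generated panels with known ground truth.
Each (expert, question, criterion) cell draws independently from a
categorical distribution (p_yes, p_no, p_und, p_miss); vectors can be set
globally, per question theme, or per cell (cells ▸ themes ▸ default
cascade). Generator defaults emulate the modelled survey:

* 25 invited, 18 responding experts (72% participation);
* partial-completion rate 2/18 ≈ 0.11 — matching 16 of 18 full completions —
  with early stoppers answering a uniform-random proper prefix of the
  criterion-major query order (all questions under one criterion, then the
  next), mirroring how the survey was presented;
* default cell probabilities (0.55, 0.20, 0.15, 0.10): a moderately
  enthusiastic panel with a realistic "insufficiently informed" rate, placing
  expected criterion scores (≈69%) mid-range of the published 46.7–91.1 RPS
  span.

A `consensus` parameter in [0, 1] sharpens each cell's substantive simplex
toward its mode by convex combination with the degenerate modal distribution
(missing mass untouched); mean AEA is non-decreasing in it (tested).

Under this model the expected criterion score has the closed form
100·(p_yes + 0.5·p_und)/(p_yes + p_no + p_und) — exact conditional on at
least one substantive responder, since each substantive answer's conditional
point expectation is independent of the responder count. The expected AEA
has no simple closed form (it is the expectation of a trinomial maximal
order statistic over a random denominator); a seeded Monte-Carlo reference
(`aea_reference`, default 10⁵ replicates per distinct probability vector)
stands in for it. The reference assumes full participation, so recovery
experiments that use it as ground truth set the partial-completion rate to 0.

What the generator does **not** emulate: correlated expert effects (shared
schools of thought), question-order or fatigue effects, informative
missingness (experts more likely to abstain on contested questions), and any
dependence between cells. Passing recovery tests therefore show the
estimators are correct under independence, not that real panels behave this
way; correlated-panel generation is a documented extension point.

## Numerical choices

* Each statistic is computed with a single final floating division (e.g.
  (100·Σpoints)/n), making the result the correctly rounded double of the
  exact rational value; the test suite asserts bit-exact agreement with a
  `fractions.Fraction` brute-force oracle over exhaustive small-panel grids
  and 1000 random panels.
* Point sums (multiples of 0.5) are exact in binary floating point, so
  results are independent of summation order; means over criteria are taken
  left-to-right in design order.
* Display rounding is decimal round-half-up (93.75 → 93.8), applied only in
  renderers.
* Replicate seeds are spawned from a single `numpy.random.SeedSequence` and
  kept below 2³¹.

## Problem sizes used in validation

Tests and the acceptance script exercise the method at the modelled survey's
scale — 30 questions × 3 criteria × 18 experts — with 500 replicate panels
for parameter recovery (300 in the acceptance script), 2000 bootstrap
replicates and 9999 permutations; exhaustive oracle checks enumerate all 4⁴
and 4⁶ category assignments of 2-expert 2-question and 3-expert 2-criterion
panels plus 1000 random partially-complete panels. Recovery tolerances are
3 Monte-Carlo standard errors of the replicate mean per question (plus the
reference's own simulation error for AEA).

## Known limitations

* The published AEA column, the full 30-question RPS minimum/maximum and the
  AEA range endpoints, and the published regression p-value depend on the
  unpublished raw responses and cannot be recomputed; the package instead
  validates those code paths on synthetic panels.
* AEA is not chance-corrected (no kappa/alpha); it is the methodology's own
  statistic and is reported as such.
* The tie-breaking rule for equal RPS (higher AEA, then design order) is this
  package's choice; the methodology literature does not specify one.
* Expert resampling treats experts as exchangeable; weighting by expertise or
  modelling rater effects is out of scope.
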