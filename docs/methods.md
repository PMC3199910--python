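# Methods

## Measurement model

Responses follow the partial credit model (PCM). An item with ordered
categories 0..m has m step thresholds δ₁..δ_m (logits) and category
probabilities

    P(X = k | θ) ∝ exp( Σ_{j=1..k} (θ − δ_j) ),   k = 0..m,

with the empty sum for k = 0. A dichotomous item (m = 1) reduces to the
one-parameter logistic Rasch model, so an item's severity is the θ at which
it is affirmed with probability ½. Probabilities are computed from
max-shifted cumulative log-weights, so they normalise to machine precision
over the whole |θ| ≤ 50 range used anywhere in the package.

The expected simple-sum score over a bank, E[S|θ] = Σᵢ Σ_k k·Pᵢ(k|θ), is the
test characteristic curve (TCC). It is strictly increasing in θ, which is
what makes the raw-score → logit table a function: row r of the table is
the θ solving E[S|θ] = r (Brent's method on [−60, 60], |residual| ≤ 1e−12).

**Extreme scores.** Raw scores 0 and max have no finite maximum-likelihood
θ, so they are replaced by `0 + a` and `max − a` before inversion, with
`a = 0.3` by default. The fractional-score correction is the standard
device for keeping conversion-table endpoints finite; 0.3 sits in the
conventional 0.25–0.5 range. The packaged reference conversion table is
treated strictly as input data, never as an estimation target, because the
correction behind its endpoints is not recorded.

## Estimation

`fit_item_bank` uses joint (unconditional) maximum likelihood — the
simplest estimator consistent with the zero-mean item constraint, which is
re-imposed after every cycle by shifting thresholds and person locations
together (the PCM likelihood is invariant under that joint shift).
Conditional ML and marginal ML are out of scope by design.

Each cycle alternates:

1. **Person step.** Given thresholds, the ML person estimate solves
   E[S|θ_p] = r_p over that person's observed items (sum-score
   sufficiency). Solved for all persons at once by damped Newton on the
   TCC, steps clipped to ±1 logit, inner tolerance 1e−10.
2. **Item step.** Given persons, each item's thresholds maximise its
   likelihood via BFGS with the analytic gradient
   ∂(−ℓ)/∂δ_j = Σ_p [1(x_p ≥ j) − P_p(X ≥ j)].

Convergence: maximum absolute threshold change < `tol` (default 1e−6),
capped at `max_iter = 200` cycles with a warning flag on the result when
the cap is hit. Category counts per item are inferred from the largest
observed code.

**Degenerate data.** Persons whose observed responses are all-minimum or
all-maximum, and items with a single observed category, have infinite ML
estimates; they are excluded before estimation (iterating, since excluding
persons can degenerate items and vice versa) and reported on the result,
never imputed. A perfectly deterministic Guttman matrix collapses entirely
under this cascade — after removing perfect patterns no information
remains — and is reported as an estimation error. As a backstop against
quasi-separation, any parameter passing |15| logits during iteration also
raises. Missing responses simply drop out of the per-person and per-item
sums.

**Joint-ML bias.** With a fixed, small number of items (K = 8 here), joint
ML estimates item dispersion inconsistently, inflating thresholds by
roughly K/(K−1). The classical (K−1)/K shrinkage is available as
`bias_correction`; it is off by default (the raw likelihood optimum is
reported unless asked otherwise) and switched on wherever the goal is to
recover generating thresholds — recovery runs at n = 1000 respondents
achieve threshold RMSE ≈ 0.10–0.16 logits with the correction, versus
0.20–0.32 without it, which is the inconsistency showing, not noise.

## Crosswalk

A band covering raw scores lo..hi maps to the logit window
`(logit(lo − 1), logit(hi)]` — lower-exclusive, upper-inclusive. This is
the unique simple convention consistent with every one of the 55 reference
assignments (an item at −1.05 falls in the Low band whose upper edge is
score 10's −1.03; an item at 0.15 falls in High whose lower edge is score
20's 0.07), and the package regression-tests exactly that: 0/55
mismatches. An exact boundary tie goes to the lower-severity band; the
reference data contain no ties, so the choice is purely for determinism.
A score of 0 lies below the lowest band by the band definitions themselves;
severities at or below logit(0), or above logit(max), receive explicit
below-/above-range markers rather than being dropped.

Non-tabulated scores are piecewise-linearly interpolated in (score, logit).
The packaged abbreviated table tabulates every multiple of 5, which covers
all band boundaries actually used; interpolation exists for callers who
need intermediate scores.

## Scenarios and the ladder

Scenarios are the band partition verbatim: each band's items sorted
ascending by severity (ties by label), with per-band counts and a separate
out-of-range list. No prose smoothing is applied.

The ladder takes each `step`-point score (default 5) from the top of the
scale downwards, converts it to a logit, and selects the `k` (default 3)
remaining items nearest by |Δlogit|, ties toward the more severe item,
each item usable once across the whole ladder. The published ladder was
hand-picked ("representative" items), so exact reproduction is a non-goal;
this documented deterministic rule replaces editorial judgement, and the
published version ships only for qualitative comparison. Descending fill
order gives the severe end — where items are sparse — first pick.

## Agreement

adjCAT = 2.5 × CAT maps the 0–40 total onto the SGRQ's 0–100 range;
`adjcat_to_cat` is its exact inverse. Bland–Altman differences are fixed as
SGRQ − adjCAT; the summary reports the mean difference (bias), SD,
bias ± 1.96 SD limits of agreement, the Pearson correlation of difference
against mean with its two-sided p-value (undefined and flagged below n = 3
or under zero variance), and for each threshold t the proportion of pairs
with |difference| strictly below t. Endpoint behaviour — what one scale
reads when the other is at 0 or 100 — is estimated by OLS of adjCAT on
SGRQ, clamped to [0, 100] to prevent nonsense extrapolation; how the
original endpoint readings were obtained is not recorded, so OLS is this
package's documented choice.

## Synthetic data

`make_paired_instruments` emulates one cohort answering both instruments:
θ ~ Normal(0, 1) (severities in logits; SD 1 is the conventional
calibration-sample spread), n = 1000 respondents, a CAT-like bank of
8 items × 5 thresholds drawn uniformly in [−2, 2] and centred, and an
SGRQ-C-like bank of 34 dichotomous plus 6 three-category items drawn in
[−3, 3] (≈15% polytomous, matching the instrument's stated composition;
the wider range matches the reference severities, which span −3.86 to
3.40). Responses are inverse-CDF draws from the PCM category
distributions. One master seed feeds four `SeedSequence` substreams (two
bank draws, the trait draw, response sampling), so stages are independently
reproducible; all derived seeds stay below 2³¹.

The synthetic SGRQ-like total is percent-of-maximum simple sum. The real
instrument applies empirically derived item weights, which are external
data this package does not carry; the agreement machinery only needs two
0–100 scales estimating one construct. Consequently the synthetic scales
agree far better than real instruments do (total-score correlation ≈ 0.88,
|bias| < 1 point, difference-vs-mean correlation strongly negative because
both totals are bounded coarse sums). Passing tests therefore demonstrate
that the machinery is correct and well calibrated under the model, not
that any particular empirical agreement level will be observed in
patients; empirical quantities that require the original cohort are out of
scope throughout. Exacerbation states, country effects and missing-data
mechanisms are not simulated.

## Problem sizes and numerical choices

Simulation-backed checks run at n = 1000 respondents (recovery over five
seeds, agreement under one fixed seed) and the end-to-end pipeline
rehearsal at n = 150–200 — sizes at which sampling noise is comfortably
inside the tolerances asserted (recovery RMSE ≤ 0.2 logits, |bias| ≤ 2
points, correlation ≥ 0.7) while keeping a full run inexpensive. TCC
inversion uses Brent on [−60, 60]; person Newton steps are clipped to ±1
logit; all tolerances are stated inline above. CSV writers emit full-
precision `repr` floats so write→read is an identity; run manifests record
parameters, seeds and SHA-256 digests, and carry a timestamp (they are the
one output excluded from bit-reproducibility comparisons).

## Known limitations

- Joint ML only; no conditional/marginal ML, no infit/outfit statistics,
  no differential item functioning.
- The extreme-score adjustment is a convention (0.3), not a recovered
  constant; conversion-table endpoints depend on it.
- The ladder rule is deliberately algorithmic and will not reproduce a
  hand-curated selection.
- Band cut-points are taken as given; validating them is out of scope.
- Synthetic SGRQ scoring ignores empirical item weights (see above).
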