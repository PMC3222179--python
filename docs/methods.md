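# Methods

## Measurement model

`rsmcat` measures a single latent trait (here: a patient's perception of
their hospitalization) from polytomous questionnaire responses scored
0..m, using the Rasch rating scale model (RSM). Item *i* is characterized by
one overall difficulty δᵢ; all items share one vector of category threshold
offsets τ₁ < … < τ_m (m = 4 thresholds, 5 categories for the packaged
IPQ-18 bank). The category probability is

    P(Xᵢ = k | θ) ∝ exp( k(θ − δᵢ) − Σ_{j≤k} τⱼ ),   k = 0..m,

with the empty sum zero. Consequences used throughout:

* adjacent categories k−1, k are equiprobable exactly at the step difficulty
  δᵢ + τ_k — this is how the bank's printed per-item step table is validated
  (every step must equal δᵢ + τⱼ within tolerance, 0.01 logits for the
  packaged fixture, 0.02 on CSV ingest);
* the expected score Eᵢ(θ) is strictly increasing in θ with limits 0 and m;
* item information equals the category-score variance
  Wᵢ(θ) = Σk²Pₖ − Eᵢ², test information I(θ) = ΣWᵢ is additive, and the
  maximum-likelihood measure's standard error is 1/√I(θ̂);
* the total raw score is sufficient for θ, so the ML estimate solves the
  score equation Σxᵢ = ΣEᵢ(θ) and the log-likelihood is concave.

All category probabilities are computed with max-shifted exponentials, so the
model is numerically exact over |θ| ≤ 30 even though the engine never leaves
[−6, 6].

Banks are *anchored*: δ and τ are inputs calibrated elsewhere; nothing here
re-estimates item parameters. The IPQ-18 fixture preserves the printed
parameter values verbatim — the four threshold offsets sum to 0.01 rather
than exactly zero, and we keep them as printed rather than re-centring,
since the original calibration's normalization convention is unknown.

## Person estimation

`mle_estimate` iterates Newton–Raphson on the score equation,
θ ← θ + (Σx − ΣE)/ΣW, with defaults: start 0, convergence tolerance 0.001
logits on the proposed update, 50 iterations maximum, per-iteration step
capped at 1.0 logit, estimates clamped to [−6, 6]. The cap plus concavity
make divergence impossible; the clamp bounds reportable measures at roughly
±6 logits (≈ 99.8% probability of the extreme category on every item), where
differences are no longer interpretable. A 0.001-step grid maximizer of the
log-likelihood (`grid_oracle`) is shipped as an audit tool; Newton–Raphson
agrees with it to ≤ 0.01 logits on randomized patterns in the test suite.

**Extreme patterns.** An all-minimum or all-maximum response vector has no
finite ML measure. Following the convention of commercial Rasch software,
the raw total is replaced by 0.3 (or N·m − 0.3) score points and the adjusted
score equation is solved exactly by bracketing. These estimates are flagged
`extreme` and are *not* clamped: the root of the adjusted equation (e.g.
θ ≈ −8.6 for all-0 on the full IPQ-18) is reported as-is so that extreme
measures remain strictly ordered below/above all near-extreme clamped ones.
The clamp applies to the Newton–Raphson path only.

## The adaptive engine

A session starts at θ₀ = 0, or at a coarse measure mapped from an optional
overall-satisfaction rating ({0→−2, 1→−1, 2→0, 3→+1, 4→+2} logits — a
declared convention; only the monotone direction matters, as the start value
influences nothing but the first item choices). Each step administers the
unanswered item with the highest information at the provisional measure;
exact ties break toward the difficulty closest to θ, then the smallest item
id, so sessions are fully reproducible. Note that RSM information with
widely spaced thresholds (the IPQ-18's span 7.9 logits) peaks near the
extreme step difficulties rather than at δ, so the most informative item at
a given θ is not necessarily the one with the nearest difficulty — selection
is always by explicit information evaluation, never by difficulty matching.

The provisional measure is re-estimated by ML after every response once at
least three responses are in and the pattern is not all-0/all-4. Before
that, a warm-up heuristic keeps selection adaptive: +0.7 logits after an
above-midpoint response, −0.7 below, unchanged at the midpoint.

**Stop rules.** A session stops when all of: (a) at least `min_items` = 10
items answered, (b) estimation active, and (c) the stopping standard error
is ≤ 0.51 logits (inclusive); or unconditionally at `max_items` (default:
the full bank, 18).

**The stopping standard error includes the calibration prior.** The 0.51
threshold is derived from the instrument's calibration as SD·√(1−R) =
2.09·√(1−0.94), the root-mean-square measurement error of a population with
person SD 2.09 and person separation reliability R = 0.94. We pair it with

    se_stop(θ) = 1 / √( I(θ) + 1/SD² ),

the posterior standard deviation under the calibration-population prior.
The pair is self-consistent: se_stop ≤ SD·√(1−R) holds exactly when the
marginal reliability 1 − se_stop²/SD² of the adaptive measure reaches R —
"stop when the short test is as reliable as the calibrated full instrument".
The pure-ML pairing (1/√I ≤ 0.51) is *arithmetically incompatible with the
instrument's documented behaviour*: summing the ten largest IPQ-18 item
informations anywhere in θ ∈ [−2.7, 3.0] gives less than 1/0.51² = 3.84, so
no 10-item session could ever stop at the threshold in the region where
essentially all respondents lie, yet observed administrations of this
instrument stop at the 10-item minimum most of the time. With the prior
term (precision 1/2.09² = 0.23) the 10-item stop is reachable across the
central region, and simulated test lengths (mean ≈ 10.8, most sessions 10–11
items) match the instrument's field behaviour. The prior SD is read from
the bank's `pop_sd` metadata (override with `StopRules.prior_sd`; set it to
`math.inf` for the pure-ML convention). The reported *measure* and its
standard error remain plain maximum likelihood throughout — the prior enters
the stopping decision only.

Per-session invariants, enforced in tests: termination within bank size, no
repeated administrations, stop reason recorded, and at an `se_met` stop both
the length and SE conditions hold.

## Person fit

Standardized residual z = (x − E)/√W at the estimated measure; outfit MNSQ
is the unweighted mean of z², infit MNSQ the information-weighted form
Σ(x−E)²/ΣW. Both have expectation ≈ 1 under model-consistent responding
(verified by simulation to within [0.9, 1.1]); outfit ≥ 2.0 flags a possibly
aberrant pattern. Fit is computed post hoc on a completed response vector at
the person's estimated measure, as in routine Rasch practice. No ZSTD
transformation is applied.

## Simulation study

`run_study` replicates a two-arm design comparing adaptive (CAT) against
full-length (NAT) administration:

1. draw `n_persons` true measures from Normal(person_mean, person_sd²) —
   defaults 200 persons from Normal(0.71, 1.62²), the published cohort's
   person distribution (normality of that cohort was not rejected);
2. run the adaptive engine per person with responses generated from the
   model at the true measure (inverse-CDF sampling of the category
   distribution, so simulated marginals match the model exactly);
3. generate a full 18-item response vector per person **at the CAT-estimated
   measure** and re-estimate it with the anchored bank — this mirrors the
   original two-step study design, in which full-length vectors were
   generated from the CAT-derived measures rather than from unknowable true
   measures (a `nat_at_true_theta` flag enables the alternative for
   methodological comparison);
4. keep extreme NAT vectors, estimating them via the 0.3-point adjustment,
   so the cohort size is preserved;
5. summarize: efficiency gain 1 − (CAT responses)/(NAT responses), Pearson
   correlation and paired t between the two measure sets, paired t on test
   lengths, descriptives of the CAT measures, and person-fit columns
   computed on the administered (CAT) responses.

Randomness flows from a single master seed through `SeedSequence` spawning
(one child stream per replicate, one grandchild per person), so studies are
reproducible and independent of execution order.

Under the defaults, five independent cohorts give mean test length ≈ 10.8 of
18 (efficiency gain ≈ 40%), CAT–NAT correlation ≈ 0.97, and no systematic
CAT–NAT measure difference — consistent with the published field results
(mean length 10.42, gain 42%, r = 0.98) at simulation precision. The
simulated tail is honest where the field data were truncated: a cohort drawn
from an unbounded normal contains persons beyond ±4 logits for whom even 18
items cannot reach the SE target, so a few sessions run the full bank
(observed field maximum was 12 items on a cohort whose measures spanned only
−2.6 to 4.0).

**What the generator does not emulate:** real respondents are not perfectly
model-consistent (no misfit, no careless or acquiescent responding is
injected), the person distribution is exactly normal, and proxy-versus-self
response differences, demographics, and answering time are outside the
response model. Passing simulations therefore demonstrate the engine's
internal correctness and the efficiency/precision trade-off under the model,
not robustness to misfitting humans.

## Statistical reporting

Paired t (df = n−1; a zero-variance nonzero-mean difference is reported as
signed infinity with a `degenerate` flag rather than an exception), Pearson
correlation, one-way ANOVA across groups, and descriptives (sample SD,
bias-corrected skewness and excess kurtosis; undefined shape moments of a
constant sample are NaN). Chi-square tests of independence on demographic
count tables use the uncorrected Pearson statistic — the form that
reproduces the published demographic tables from their printed counts
(department 3.9, age 0.9, participant/proxy 1.1 at one decimal); the
published respondent-willingness row is internally inconsistent (its counts
recompute to 0.70 uncorrected, 0.41 corrected, against a printed 0.6) and is
excluded from reproduction checks. Where published totals are quoted, the
arithmetically self-consistent value 2084 (= 200 × 10.42) is used for the
adaptive response total, and efficiency is the *gain* 1 − 2084/3600 ≈ 0.42.

## Known limitations

* Rating scale model only: no partial-credit (item-specific thresholds),
  graded-response, or non-Rasch models; no re-scoring of categories.
* Maximum-likelihood person estimation only (no EAP/MAP/weighted
  likelihood); the calibration prior appears solely in the stop rule.
* No exposure control or content balancing in item selection.
* Item-level fit and differential item functioning are out of scope; the
  bank is taken as validly calibrated.
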