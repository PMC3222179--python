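# rsmcat

Computerized adaptive testing (CAT) for polytomous questionnaires scored with
the Rasch rating scale model, built around the 18-item inpatient perception
questionnaire (IPQ-18) used to survey patients on discharge from hospital.

Surveying every patient with all 18 questions (nonadaptive testing, NAT) is a
burden precisely for the people least able to bear it. An adaptive test asks
only the questions that are informative about the individual respondent and
stops as soon as the measure is precise enough. `rsmcat` provides the full
tool chain for survey methodologists and health-services researchers: the
anchored item bank, the measurement model, the adaptive engine, person-fit
diagnostics, and a simulation framework that quantifies what adaptive
administration saves and what it costs in precision.

## The model

Responses are integer category scores x ∈ {0, …, m} (m = 4 for the IPQ-18).
Under the rating scale model, the probability that a person with measure θ
(logits) scores k on item i with difficulty δᵢ is

    P(Xᵢ = k | θ) = exp( k(θ − δᵢ) − Σ_{j≤k} τⱼ ) / Σ_c exp( c(θ − δᵢ) − Σ_{j≤c} τⱼ )

with one set of threshold offsets τ₁ < … < τ_m shared by all items (the empty
sum is 0). Adjacent categories k−1 and k are equally probable exactly at the
step difficulty δᵢ + τ_k. Item information at θ is the category-score
variance Wᵢ(θ); test information is ΣWᵢ, and the measure's standard error is
its reciprocal square root.

The adaptive loop administers the unanswered item with the highest
information at the provisional measure, re-estimates θ by Newton–Raphson
maximum likelihood after every response (once ≥ 3 responses are in and the
pattern is not all-0/all-4), and stops once at least 10 items are answered
and the reliability-consistent standard error 1/√(I(θ) + 1/SD²) falls to
SD·√(1−R) = 2.09·√(1−0.94) ≈ 0.51 logits — i.e. when the measure's marginal
reliability reaches the instrument's calibrated person separation reliability
(see `docs/methods.md` for why the stopping SE includes the calibration
prior). Person fit is monitored with infit/outfit mean squares; outfit ≥ 2.0
flags an aberrant pattern.

## Worked example

```python
from rsmcat import builtin_ipq18, run_scripted_session, person_fit

bank = builtin_ipq18()          # 18 anchored items, taus (−3.76, −1.91, 1.57, 4.11)
answers = {"39": 1, "11": 2, "27": 1, "41": 2, "24": 3, "30": 2, "42": 3,
           "9": 2, "44": 2, "2": 3, "5": 2, "17": 2, "12": 2, "23": 3,
           "38": 2, "18": 2, "19": 3, "34": 2}
result = run_scripted_session(bank, lambda item_id: answers[item_id])
print(result.n_items, result.stop_reason)
print(f"theta {result.estimate.theta:.3f}  se {result.estimate.se:.3f}")
fit = person_fit(result.responses, result.estimate.theta, bank)
print(f"infit {fit.infit_mnsq:.2f}  outfit {fit.outfit_mnsq:.2f}")
```

prints

```
10 se_met
theta 0.346  se 0.519
infit 0.67  outfit 0.66
```

The session needed only 10 of the 18 questions: the respondent's perception
measure is 0.35 logits (a touch above the average patient), the stop rule was
met (stopping SE 0.503 ≤ 0.51), and both fit statistics are well below the
2.0 aberrance cutoff.

The same engine drives the simulation study from the command line:

```sh
$ rsmcat simulate --n 200 --seed 42
CAT versus NAT comparison
=========================================
persons:                 200
total responses (CAT):   2196
total responses (NAT):   3600
mean CAT test length:    10.98 / 18
efficiency gain:         0.39 (39.0%)
Pearson r (CAT, NAT):    0.976
paired t, test length:   t(199) = -73.62, p = 2.57e-146
paired t, measures:      t(199) = -0.79, p = 0.433
CAT measures:            mean 0.88, SD 1.80, median 0.88, skew 0.159, kurtosis -0.13
```

200 simulated respondents drawn from Normal(0.71, 1.62²) answered on average
11.0 of 18 questions — roughly 40% fewer item administrations — while the
adaptive measures track the full-length measures at r ≈ 0.98 with no
systematic difference (paired t on measures, p = 0.43).

Other subcommands: `rsmcat validate` (check a bank's rating-scale
constraints), `rsmcat run` (interactive administration on the terminal),
`rsmcat report study.csv [--demographics demo.csv]`.

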