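# Methods

## The problem and the model

Administrative claims record each inpatient stay's diagnoses as ICD-10-CM
codes. A diagnosis is *specified* when it is coded to the most granular
clinically supported code, and *unspecified* when a catch-all code (for
depression: F32.9, F33.9, F32.A) is used instead. Facilities differ in how
often they specify, but raw rates confound coding practice with patient
mix. `codespec` separates the two with a two-stage procedure.

**Stage 1 — hospitalization-level risk model.** The binary outcome
S(p,f) ∈ {0,1} (stay *p* in facility *f* coded specified) is modeled as

    logit π(p,f) = α + βᵀ X(p,f)

where X collects patient covariates (demographic bands, payor, log length
of stay, ...) and facility covariates entered as plain fixed effects.
Stays are assumed independent given X, with unequal probabilities — the
key departure from a binomial model. The fit is by iteratively reweighted
least squares (IRLS); the fitted π̂(p,f) are the *risk-adjusted*
specificity probabilities: what peer-standard practice would predict for
that patient in that facility's case mix.

**Stage 2 — facility-level Poisson Binomial test.** Within facility *f*
the observed specified count Σ_{p⊂f} S(p,f) is, under stage 1, a sum of
independent non-identical Bernoulli trials — a Poisson Binomial (PB) law
with vector {π̂(p,f)}. Its pmf is computed exactly by adding one trial at
a time (O(n·k) dynamic-programming convolution in double precision, with
a renormalization guard at 1e-9 drift). At a per-side threshold *t*
(default 0.025, i.e. a two-sided 95% peer band) the discrete bounds are

    Q_L = min { q : P(X ≤ q) ≥ t },   Q_U = max { q : P(X ≥ q) ≥ t }

and a facility is classified *under* when P(X ≤ obs) < t, *over* when
P(X ≥ obs) < t, otherwise *in line*.

### The discrete-tail convention

A discrete law cannot put exactly mass *t* in a tail, so "the 2.5th
percentile" is ambiguous. We adopt the conservative convention above:
inclusive-tail p-values, with flagging equivalent to obs < Q_L or
obs > Q_U. Consequences, verified by the test suite:

- the per-side false-flag rate under the null equals P(X < Q_L) ≤ t
  (respectively P(X > Q_U) ≤ t) — the *exact conservative level*, which
  the calibration experiment reports next to the empirical rate;
- the attained level approaches *t* from below as facility size grows;
- a mid-p variant (half the point mass at the observed count in each
  tail) is available behind an explicit flag but is never the default,
  since classification uses the plain cdf.

For facilities so small that Q_L = 0 and Q_U = n, no flag is possible at
the chosen *t*; results carry a `low_information` marker rather than
being suppressed. No minimum facility size is imposed.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `t` (threshold) | 0.025 | per-side flagging level; peer band is the discrete 95% interval |
| IRLS `tol` | 1e-8 | absolute deviance-change convergence criterion |
| IRLS `max_iter` | 100 | iteration cap; non-convergence is reported, not raised |
| `instability_bound` | ln 100 | coefficients beyond it are flagged as quasi-separated and rendered ">100" / "0.000-Inf" in OR tables |
| `ridge` | 0 | optional L2 penalty for degenerate fixtures; off so estimates are plain ML |
| confidence | 0.95 | Wald intervals, z = 1.959964; p-values are two-sided Wald |
| `unspecified_map` | {F32.9, F33.9, F32.A} | codes counted as unspecified; configuration, with `*` prefix patterns allowed |

Numerical choices: linear predictors are clipped at ±30 inside IRLS (the
Bernoulli likelihood is flat beyond that); IRLS weights are floored at
1e-10; a near-singular information matrix under separation receives a
1e-10 jitter solely to keep the solve defined, with the offending columns
flagged. Rank deficiency is detected by pivoted QR and reported by column
name rather than silently dropped. First-stay ties (same patient, same
earliest discharge date) keep the first record in file order with a
logged warning. Same-day stays (length of stay 0) are clamped to 1 day
before the natural log; negative stays are rejected.

## The synthetic generator

Real national claims databases are proprietary, so the generator emulates
the *structure* of such an extract with a reduced covariate set whose
marginals match a large US depression inpatient cohort:

- sex: Female 65% (reference) / Male 35%;
- age band: 18–64 51% (reference), 65–84 41%, 85+ 8%;
- primary payor: Medicare traditional 62% (reference), Commercial 38%;
- length of stay: lognormal, median 4 days, log-scale SD 0.87
  (log-transformed at encoding).

True log-odds coefficients are set at field-realistic odds ratios —
Male 0.76, age 65–84 0.90, age 85+ 0.69, Commercial 1.22, log-LOS 1.82 —
with intercept 0.15, giving an overall specified rate near 0.70 and an
encoded design of exactly five non-intercept columns. Facilities receive
sizes from a log-uniform law (50–500 stays by default, or explicit
sizes), and non-conforming facilities are planted by adding a log-odds
shift to every stay's probability before the Bernoulli draw. One root
seed drives everything; experiment replicates derive child seeds through
`numpy.random.SeedSequence`, so runs are bit-reproducible.

What the generator does **not** emulate: covariate correlation and
multicollinearity (covariates are drawn independently), repeat stays or
any longitudinal structure, facility-level clustering beyond the injected
shift, and the full covariate breadth of a real extract. Passing tests
therefore demonstrate the pipeline contract — exact PB computation,
consistent estimation, calibrated and powerful flagging *when the risk
model is correctly specified* — not robustness to model misspecification
on real data.

## Experiments

- **Calibration** (`calibration_experiment`): all shifts zero; per
  replicate the cohort is regenerated, the model refitted, every facility
  classified. Reported: empirical per-side flag rates with binomial
  Monte-Carlo SEs and the mean exact conservative level of the fitted PB
  laws. The acceptance suite runs 20 replicates of 500 facilities × 200
  stays; the acceptance script runs 10 replicates of 200 facilities × 200
  stays — sizes chosen to make Monte-Carlo error small relative to *t*
  while the whole suite stays desk-scale.
- **Power** (`power_experiment`): planted facilities of fixed size and
  shift inside a conforming background; detection is a correct-direction
  flag. At +3 log-odds and 500 stays detection is essentially 1; shift-0
  cells reproduce the null rates.
- **Recovery** (`recovery_experiment`): per-coefficient bias, empirical
  SE and Wald CI coverage across replicated fits (n = 50,000 per
  replicate in the acceptance suite).

## Open design choices, resolved

- Principal and secondary diagnoses are treated as two separate cohorts
  keyed by (patient, role); how a stay with both roles contributes is not
  determined by the data model and is left to cohort construction.
- p-values and CIs are Wald (not likelihood-ratio); with the cohort sizes
  this method targets the difference is negligible, and Wald quantities
  come directly from the IRLS information matrix.
- State enters the multivariate model as ordinary fixed-effect dummies;
  the state-OR export assigns the reference state OR 1 by definition and
  bins the rest (under / non-significant / three over ranges with
  configurable cut points 2 and 4, since legend ranges are a display
  choice).
- The univariate and multivariate analyses share one encoding path; a
  univariate "fit" is the same IRLS on a single-variable design.
- AUC is computed in-sample over all distinct predicted values, with
  trapezoidal integration; it equals Mann–Whitney concordance with ties
  counted one half.

## Limitations

Independence across stays and facilities is assumed; shared coders,
health-system ownership or state-level clustering would make the PB band
anti-conservative. No random effects are offered. The exact pmf is
O(n²) per facility — fine at claims scale (a 10⁴-stay facility takes
well under a second); a continuity-corrected normal approximation to the
cdf is provided for very large groups but is never used for
classification unless explicitly requested. The flagging rate is
conservative (below *t*) for small facilities, markedly so below ~50
stays.
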