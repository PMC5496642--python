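# Methods

## Data model

A trial is a collection of per-subject episodes in counting-process
(start, stop] format. Time is measured in years since the subject's own
randomization; calendar staggering enters only through the censoring time.
Events occur at `stop`; a subject is at risk at time t on an interval iff
`start < t <= stop`. Censoring is the final record with `event=0`, never a
third event type. A fatal event is terminal; `prior_nonfatal_count`
increments only across a boundary created by a non-fatal event. Because no
other time-varying covariates exist, every record either ends in an event
or is the subject's last, so records are uniquely indexed by
(subject, prior_nonfatal_count) — the PWP strata fall directly out of the
data model. A dataset restricted to first events may legitimately end a
subject's sequence with a non-fatal event record (follow-up is truncated at
that event), which is why validation does not force the last record to be
fatal-or-censored.

The delimited format is UTF-8 CSV with columns
`subject_id, treatment, start, stop, event, event_type,
prior_nonfatal_count`, times in decimal years. Floats are written with
`%.17g` and read back with round-trip precision, so I/O is an exact
identity on records.

## Generative model

Conditionally on treatment X ∈ {0,1}, frailty Z and prior non-fatal count
k, the cause-specific hazards are constant in time:

    h_fatal    = λ1 · Z · exp(β1 X) · ρ^k
    h_nonfatal = λ2 · Z · exp(β2 X) · ρ^k

Z is gamma with mean 1 and variance θ (shape 1/θ, scale θ; exactly 1 when
θ=0) and is shared by both hazards, inducing positive correlation between
the fatal and non-fatal processes. ρ ≥ 1 multiplies *both* hazards once per
prior non-fatal event (the event-dependence, i.e. the indirect-effect
channel). Because the conditional hazards are piecewise constant, subject
paths are simulated exactly as competing exponentials: gap ~
Exp(h_fatal + h_nonfatal), the event is fatal with probability
h_fatal/(h_fatal+h_nonfatal), and after a non-fatal event k increments. No
inversion of a cumulative hazard is needed; the construction is exact, not
a discretization.

Trial design defaults: N=380 subjects, exactly ⌊N/2⌋ treated (exact
balance, not Bernoulli — "balanced randomized" and lower Monte Carlo
noise), recruitment R ~ U(0, 1) year, administrative censoring at the
common calendar close-out of a 2-year study, so individual follow-up is
C = 2 − R ∈ [1, 2] years. This staggered-censoring choice (rather than a
fixed 2 years of follow-up for everyone) matters: it sets the expected
event counts and hence the empirical standard errors of the replicate
estimates. Rates default to λ1=0.14 (death) and λ2=1.17 (admission) per
year, the planning values of a heart-failure trial with composite rate
1.31; the equal-rate variant λ1=λ2=0.655 keeps the same total. An event
falling exactly on the censoring time (a measure-zero case) counts as
observed.

With θ>0 and ρ>1 combined, Z·ρ^k compounds: high-frailty subjects can
accumulate dozens of events within follow-up (the per-event death
probability λ1/(λ1+λ2) is what terminates such runs). This is a property
of the stated model, not a numerical artifact; see Limitations.

## Estimation

All five analyses maximize a Cox-type partial likelihood in the single
binary treatment covariate; the baseline hazards are profiled out and never
estimated. The regimes differ only in the risk sets and qualifying events:

| regime | events | at risk at t |
|---|---|---|
| first-event Cox | first composite events | event-free and alive: t ≤ first stop |
| Andersen–Gill | all events (composite) | alive and uncensored: t ≤ last stop |
| multi-state | all events of one component | alive and uncensored |
| PWP | events within stratum k = prior count | subjects in their own k-th episode |
| cause-specific first | first events of one component | event-free and alive (other-type first events censor) |

The multi-state partial likelihood factorizes over components, so the joint
fit *is* the two per-component fits and the joint log-likelihood is their
sum; with a common β the model collapses to Andersen–Gill, and on
first-event-restricted data Andersen–Gill collapses to the first-event Cox
model. These identities are asserted in the tests rather than assumed.

With one binary covariate the likelihood reduces, per event, to the failing
arm and the per-arm risk-set counts (n0, n1), which do not depend on β.
The engine tabulates the counts once per fit via sorted interval bounds
(O((E+N) log N)) and then evaluates log-likelihood, score and observed
information in closed form, making Newton–Raphson iterations essentially
free. Ties are handled by the Breslow convention (the continuous-time
simulator makes ties measure-zero, and Breslow matches the brute-force
oracle used in the tests).

Numerical details: start at β=0; step-halving whenever a step would lower
the log-likelihood, with a relative slack of 1e-10·(|ll|+1) so float
rounding near the optimum cannot trigger spurious halving; convergence on
|score| < 1e-8 within 25 iterations; |Δβ| < 1e-10 stalls are reported as
non-converged. Monotone likelihoods are flagged, never silently estimated:
fits with all qualifying events in one arm are refused up front, and a
runaway |β| > 10 (an infinite MLE with score → 0 along the path, which a
score tolerance alone cannot detect) is reported as non-identifiable.
Standard errors are model-based (inverse observed information); sandwich
SEs are not provided because the replicate studies report *empirical* SEs —
the standard deviation of β̂ across simulated trials.

The Wald test is z = β̂/SE against the standard normal, two-sided.

## Replicate studies

`run_scenario` simulates `n_replicates` trials, analyses each with (up to)
six analyses — first-event Cox composite, cause-specific fatal/non-fatal,
AG composite, MS fatal/non-fatal — and aggregates on the log scale,
reporting exp(mean β̂) and the empirical SE (SD of β̂, denominator n−1).
Aggregating log estimates rather than hazard ratios matches how mean
regression coefficients are conventionally tabulated; the Jensen gap
between the two conventions is far below the 0.02 tolerance used in the
acceptance checks. Replicate r draws from the independent seed stream
(base_seed, r), so results are bit-reproducible and invariant to which
analyses are requested or in what order replicates run. Non-converged or
non-identifiable fits are excluded from the aggregates and counted; under
the default parameters (≈30+ deaths per trial) exclusions are rare and
cannot move the means at the stated tolerances.

Replicate counts: the packaged checks use 1000 replicates per grid cell
(2000 for the single power proportion). The Monte Carlo standard error of a
mean log-HR at 1000 replicates is ≈0.12/√1000 ≈ 0.004 — an order of
magnitude below the 0.02 comparison tolerance — so larger counts only
slow the suite without changing any verdict.

`empirical_power` simulates first-event composite trials as a single
exponential process per subject (rate λ under control, λ·HR under
treatment, same accrual/censoring design), fits the first-event Cox model
and counts two-sided Wald rejections. Internal design cross-checks:
Schoenfeld's required-events formula 4(z_{1−α/2}+z_{power})²/ln²(HR) gives
380 events for HR 0.75 at 80% power, and the closed-form first-event
probability under staggered accrual,
1 − e^{−λS}(e^{λa}−1)/(λa), applied to both arms at N=465 and λ=1.31,
yields ≈375 expected events — consistent with the measured power of ≈0.797.

## Discrete worked examples

Expected counts are kept as exact reals throughout; nothing is rounded
internally (the canonical examples choose arm sizes that make the counts
integers, but the construction does not require it). The selection-bias
builder derives the treated risk from the control risk and the
within-stratum odds ratio (odds_t = OR·odds_c), so recovering the input OR
within each stratum is exact by construction; the marginal OR of the
collapsed table then exhibits pure non-collapsibility/selection attenuation
(0.5758 vs 0.5 at the default parameters). The direct-effect builder makes
mortality depend only on the prior-event stratum, so within-stratum ORs are
exactly 1 and the marginal OR (8/11 ≈ 0.7273) is purely the mediated
effect. Comparisons against two-decimal renderings of these quantities use
a 0.01 tolerance since 0.5758 is conventionally displayed truncated as
0.57.

## What the simulator does and does not emulate

It emulates the designed trial: exact balance, uniform accrual,
administrative censoring only, exponential baseline hazards, a single
binary covariate, gamma frailty, geometric event dependence. It does not
model dropout or loss to follow-up, non-exponential baselines, covariates
beyond treatment, negative dependence (ρ<1 is accepted by validation but
makes the "hazards increase" interpretation vacuous), or enrollment
dynamics. Consequently, passing checks demonstrate correctness of the
estimation machinery and the bias mechanisms *under this generative model*;
they do not certify behavior under informative censoring or
non-proportional hazards in real data.

## Known limitations

- Only a single binary covariate is supported by the fitting engine; the
  closed-form per-event reduction relies on it.
- No baseline-hazard (Breslow) estimator and no joint frailty fitting: the
  package deliberately stays with marginal models, whose biases are the
  object of study.
- In the combined θ=0.6, ρ≥1.2 corner of the grid with rates
  (0.14, 1.17), the compounding Z·ρ^k makes per-subject event counts
  explode and the all-events estimates continue to fall with ρ (total
  effect ≈0.69 at ρ=1.3). A structural symmetry of the model — both
  components share the multiplier Z·ρ^k·e^{βX}, so the fatal and non-fatal
  all-events estimates have identical expectations — is confirmed
  numerically here (0.681 vs 0.685 at 3000 replicates). Conventionally
  tabulated reference values for this corner that *break* this symmetry
  should therefore be treated with caution when comparing.
- The acceptance checks are Monte Carlo; at 1000 replicates the verdicts
  have ≈0.004 log-scale resolution, adequate for the 0.02 tolerances but
  not for finer comparisons.
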