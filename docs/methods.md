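# Methods

## Task model

A session has 180 trials, 60 in each of three pseudorandomly interleaved
conditions (a seeded shuffle of a balanced list; no run-length
constraints are imposed). Each trial presents three options with
displayed reward magnitudes drawn i.i.d. uniform on {1, …, 100} and
hidden reward probabilities. Condition 1 has a single decision followed
by the chosen outcome and then the two foregone outcomes; conditions 2
and 3 add a second decision between the two initially unchosen options,
with magnitudes carried over (condition 2) or both reset to 50
(condition 3), followed by feedback for both remaining options. Event
onsets accumulate with one uniform 2.5–5.5 s jitter per event and there
is no inter-trial interval. Only chosen outcomes would pay; the payment
bookkeeping itself is not modelled, and stimulus identity/screen
position carry no computational content here, so options are abstract
ids 1–3.

Each option's true reward probability follows a beta random walk: the
value on trial *i+1* is a beta draw with mean equal to the value on
trial *i* and fixed variance (the volatility). Defaults: volatility
1e-3 (per-trial step s.d. ≈ 0.03, which sweeps much of the unit interval
over 180 trials while remaining trackable) and a uniform [0.2, 0.8]
first-trial draw to avoid starting pinned at a boundary. Neither value
is dictated by the task description, so both are exposed as parameters.
Near the boundaries the requested variance can exceed the feasible
beta variance `m(1−m)`; it is then clipped to 90% of the feasible
maximum and the event is logged. Options use independent random
streams.

Schedule pre-selection (`select_decorrelated_schedule`) draws candidate
walks, runs the optimal learner on full feedback sampled from each, and
keeps the candidate minimising the maximum absolute pairwise correlation
between the three estimate series — the same logic a designer uses to
decorrelate the regressors of interest before collecting data. It fails
loudly, reporting the best value achieved, if no candidate beats the
threshold.

## Bayesian volatility learner

Each option carries an independent joint posterior over a grid of

- *r* — current reward probability,
- *v* — log step-variance of the probability walk,
- *k* — standard deviation of the random walk followed by *v* in log
  space (how quickly volatility itself drifts).

One filter step diffuses the density through the transition kernels
(beta kernel in *r* with variance `exp(v)`; Gaussian kernel in *v* with
scale *k*; *k* static), multiplies in the Bernoulli likelihood of the
observed outcome, and renormalises. The kernel family is pinned here
explicitly for reproducibility: grid-based filters of this type are
conventionally described by citation, and the log-space Gaussian
volatility transition is the standard choice for this predictor family.

Estimates attributed to trial *i* are computed **before** any of trial
*i*'s outcomes (pre-outcome convention); this is what makes prediction
errors well defined. Within a trial, each option receives exactly one
diffusion step and (if its outcome is used) one likelihood update;
because options are independent, the order in which options are
processed within a trial cannot affect the estimates, and first- versus
second-phase feedback batching is immaterial for the pre-outcome
quantities.

The *optimal* variant feeds every option's revealed outcome to the
filter; the *experiential* variant updates only options the agent chose
(first choice always; second choice in conditions 2–3) while unchosen
options' beliefs diffuse without observation, so their uncertainty still
grows between visits.

Numerical choices:

- Default grid 50 (*r*) × 30 (*v*) × 15 (*k*). The *r* points are bin
  midpoints of an even partition of the fixed interior support
  [0.01, 0.99]; anchoring the support (rather than letting boundary
  bins approach 0/1 as the grid refines) is what makes the quadrature
  stable — doubling all grid dimensions changes no estimate by more
  than 0.02 on test sessions, and the suite checks this.
- *v* grid uniform in log variance on [log 5e-5, log 5e-2]; *k* grid
  log-spaced on [0.02, 2]. These brackets comfortably contain the
  default generating volatility of 1e-3.
- Transition columns are normalised on the grid, and the posterior is
  renormalised after every step (mass conservation is asserted to
  1e-10 in tests).
- One-point *v*/*k* grids are supported as a degenerate
  fixed-volatility mode; the test suite uses this reduction to check
  the filter against an independently coded brute-force
  transition-matrix filter to 1e-8.

## Choice model

Subjective value of an option with estimated probability *p* and
magnitude *m*:

    V = β·p + λ·(m/100) + γ·p·(m/100)

and choices follow a softmax over the available options' values (three
at first decisions, two at second decisions; condition-3 second
decisions use magnitude 50 for both options). Magnitude is rescaled by
100 purely for fitting conditioning — it is a reparameterisation of λ
and γ. There is no separate inverse-temperature parameter: scaling all
three weights jointly sharpens choices, so temperature is absorbed and
the parameter count is exactly three. The functional form is
reconstructed from the verbal description of weights on probability,
magnitude and their product (the participant-exclusion logic — "did not
use probability" ⟺ β and γ both near 0 — is only consistent with β on
*p* and γ on the product), and should be read as pinned here rather
than transcribed.

The session log-likelihood sums the log softmax probability of every
recorded choice: 180 first decisions and 120 second decisions by
default. Whether second decisions enter the likelihood is a flag
(`include_second`); they do by default, because the fitted estimates
should explain all recorded choices. BIC, however, always uses
n = 180: the three published table rows are mutually consistent with
`−2·logL + k·ln(180)` and inconsistent with n = 300, so the
first-decision trial count is the sample size the comparison uses.

## Fitting and model comparison

Four models: optimal Bayesian (k = 3: β, λ, γ), experiential Bayesian
(k = 3), single-rate delta rule (k = 4: + α) and dual-rate delta rule
(k = 5: separate α for options chosen at a phase of that trial versus
unchosen options). Delta-rule estimates apply
`p ← p + α·(outcome − p)` to every revealed outcome, with the same
pre-outcome convention as the filter; the recursion is solved in closed
form via cumulative retention products, falling back to direct
iteration when rates approach 1 and the products would underflow.

Maximum likelihood uses derivative-free Nelder–Mead from 10 seeded
random restarts (weights start uniform on [−8, 8], rates on
[0.05, 0.95]) inside boxes [−50, 50] for weights and [0, 1] for rates —
robust to the flat/sharp regions a softmax likelihood develops at large
weights, and exactly reproducible under a fixed seed. Standard errors
come from the inverse numerical Hessian at the optimum and are reported
as NaN when the Hessian is not positive definite (e.g. on a bound).
Group comparison sums log-likelihood and BIC over participants, adds a
k = 0 chance baseline, ranks by group BIC, and reports the
per-participant counterfactual learning index
`logL(optimal) − logL(experiential)`.

## Behavioural analyses

All group statistics are random effects: per-participant summaries
tested across participants with df = N − 1. Two-sided p-values are
reported everywhere, alongside one-sided values for directional
predictions.

- *Optimal-choice regression*: the indicator "chose the EV-best option
  at the first decision" is regressed on the probability and magnitude
  of the EV-ranked best/mid/worst options (ties broken toward the lower
  option id and flagged). Regressors are z-scored per participant so
  coefficients are comparable in the group test; this standardisation
  is a package choice. Optionally the previous trial's three
  magnitudes (under the previous trial's ranking) are added as a
  history control — agents here have no magnitude memory, so these
  serve as built-in null regressors. Perfect or quasi-separation is
  caught and refit with a small L2 penalty (α = 1e-3), flagged per
  participant.
- *Cross-correlation matrix*: probability, EV and magnitude of the
  chosen option and of the two unchosen options ranked by estimated
  probability, correlated over trials per participant and averaged.
  Zero-variance series yield missing entries rather than fabricated
  correlations.
- *Switch adaptation*: trials where the option previously ranked best
  (resp. worst) among the unchosen becomes EV-optimal on the next
  trial; adaptation is choosing it. The two trial sets are matched on
  the next trial's EV margin by 10 equal-width bins with seeded
  subsampling of the larger set per bin — the matching procedure is a
  package choice, audited by a KS test on the matched margins — and
  the matched frequencies are compared by paired t-test.

## fMRI regressors and design matrix

Prediction errors are outcome minus the same trial's pre-outcome
estimate, so every PE lies in [−1, 1]; counterfactual PEs use the
unchosen option's outcome and its own expectation. The regret signal
is purely outcome-based: delivered magnitude of the foregone second-
decision option (0 if unrewarded) minus delivered magnitude of the
chosen one. On simulated sessions the counterfactual PE and regret
correlate well below |r| = 0.8, so the two accounts are statistically
separable in the design.

The design matrix uses stick (zero-duration) events at phase onsets —
durations are a package choice, as is the canonical double-gamma HRF
(peak 6 s, undershoot 16 s, ratio 1:6) — convolved at 0.1 s resolution
and sampled at TR = 3 s, volumes indexed from 0. Parametric modulators
are mean-centred within their event set before convolution; no further
orthogonalisation is applied. Probability modulators are split by
ranking source: model-based ranking of the unchosen options in
conditions 1–2, participant-choice-based (the option taken at the
second decision is the best unchosen) in condition 3. The full request
is 24 columns: 5 phase main effects, 2 chosen-probability interactions,
8 best/worst-unchosen-probability interactions (2 phases × 2 ranking
sources × best/worst), 3 outcome modulators (one per feedback-bearing
phase; the foregone phase uses the mean of the two foregone outcomes),
and 6 zero motion placeholders. The inventory is a reconstruction of
the published 24-regressor description, which enumerates 23 regressors
plus motion explicitly; the foregone-phase outcome modulator is the
natural symmetric completion and is the package's choice.
`synthetic_bold_recovery` validates any assembled matrix by simulating
`y = Xβ + noise` and re-estimating β by OLS on the non-placeholder
columns.

## Synthetic validation: scope and limitations

The synthetic cohorts are the package's test bed, not a stand-in for
human data. Simulated agents use the generating defaults
(β, λ, γ) = (6, 3, 4) and, for delta-rule agents, α = 0.3 — weights
chosen so that per-participant fitted log-likelihoods land in the same
range as published per-participant fits (≈ −110 per participant for
≈ 300 decisions), i.e. realistically deterministic but noisy choice.
Against these conditions the suite establishes: filter correctness to
1e-8 against a brute-force oracle; cohort-mean parameter recovery
within 15% for 19 agents × 180 trials; correct model ranking by group
BIC in ≥ 8/10 replicate cohorts in both directions (10-agent cohorts —
discrimination is already decisive at this size, and the problem size
keeps the default suite fast); the (+, −, −) behavioural sign pattern
with null lagged-magnitude controls; and exact noiseless beta recovery
from the design matrix.

What passing these tests does **not** show: that human participants
follow the softmax/Bayesian model (real choice data include history
effects, lapses and response-time structure the generator omits); that
the published group t-statistics or brain–behaviour correlations are
reproduced (they require the original participants' and scanner data);
or that the HRF/event-duration conventions match the original analysis
pipeline beyond the documented reconstruction. Degenerate inputs are
handled explicitly: zero volatility yields a frozen walk, zero learning
rates never learn, separation in the logistic step is ridge-flagged,
and empty matched sets in the switch analysis skip the participant with
a report rather than failing silently.
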