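# Methods

## The reward engine

The engine is a per-participant deterministic state machine over scheduled
sample slots.  Each slot is classified with a strict precedence:

1. `missed` — no submission;
2. `out_of_window` — submitted outside the acceptance window;
3. `unverified` — identity not confirmed (the staff decision is the gold
   standard and overrides the automated match score whenever present;
   otherwise the score is compared against the cut-off, ties confirming);
4. `positive` — BrAC > 0.00 g/dL;
5. `negative_verified` — otherwise.

Identity precedes the alcohol result on purpose: an unverified sample
cannot count as verified abstinence regardless of its BrAC.

**Window semantics.** "Within a half-hour window" of a scheduled prompt is
ambiguous (± 30 min vs 30 min after).  We accept submissions in
`[scheduled_time, scheduled_time + window_minutes]`: the app prompts at
the scheduled time, so a sample cannot sensibly precede the prompt.
`window_minutes` is configurable (default 30; 60 is a common relaxation).
Out-of-window submissions are kept in the log but treated as missed for
reward purposes (and as reset triggers under CM); they enter feasibility
denominators only when `count_late_as_submitted` is set (default false).

**Escalation state.** The consecutive-verified-negative counter persists
overnight within a phase ("consecutive" carries no day qualifier), is
cleared by exactly the configured reset triggers (default missed /
positive / unverified), and is reinitialised to 0 at every phase boundary
— each phase is a distinct condition, so no credit is carried from a
control phase into CM or across CM blocks.  Under the default escalating
schedule the amount at level *k* is `min($2.00 + 0.25k, $3.50)`.

**Control-phase payment.** Control phases pay the base amount for any
in-window submission "independent of sample results".  An identity
failure is not a sample result, so unverified in-window submissions pay by
default; `control_pays_unverified=False` is available as a sensitivity
switch.

**Money.** All amounts are held as integer cents internally (no binary
floating-point drift over 168 accumulating transactions) and surfaced as
2-decimal USD.  The ledger enforces conservation
(`earned = available + banked + redeemed`, nothing negative) after every
transaction; redemption drains the available balance before the bank.
The 24-hour staff-confirmation delay present in a live deployment is
metadata, not engine logic: decisions are attached to the slot they pay
for.

**Maximum earnings.** The closed form sums flat phases as
`days x slots x base` and an escalating phase with `s` slots as the ramp
`m·base + increment·m(m−1)/2` with `m = min(s, ceil((cap−base)/increment))`
uncapped levels plus `(s−m)·cap`.  For the default plan this is
2 × $84 + ($15.75 + 78 × $3.50) = $456.75.  The closed form is tested
against the engine run on a perfect participant over randomized plans, so
either path can serve as the oracle for the other.

## Identity-verification metrics

Automated confirmation is `score >= cutoff` (ties confirm, matching the
"at least an 80% match" reading).  Sensitivity and specificity are
computed against the staff gold standard; empty denominators return an
explicit undefined marker rather than raising, since specificity is
undefined on cohorts with no staff-rejected image.  Exact
Clopper–Pearson 95% intervals accompany the point estimates: with true
negatives typically in the low teens, a normal approximation would be
badly misleading.

## The behavior simulator

Each participant is a draw from population priors:

| parameter | default prior | role |
| --- | --- | --- |
| `p_submit[phase]` | Beta, means 0.83 / 0.71 / 0.50 (A1/B/A2), κ=40 | per-slot attempt probability |
| `p_positive` | Beta(mean 0.158, κ=60) | P(BrAC > 0) per submission, control phases |
| `cm_effect` | TruncNormal(0.04, 0.02) on [0, 0.5] | subtracted from `p_positive` under CM (clamped at 0) |
| `p_lowquality` | Beta(mean 0.06, κ=80) | genuine image scoring below the cut-off |
| `p_impostor` | Beta(mean 0.01, κ=200) | submission not by the participant |
| `p_techfail` | Beta(mean 0.02, κ=100) | attempted submission lost to an app failure |
| `p_late` | 0.02 (fixed) | submission beyond the window |

Positive BrAC values are Uniform(0.01, 0.21) rounded to 2 decimals; match
scores come from a three-part mixture — genuine-good
TruncNormal(95, 3) on [80, 100], genuine-low-quality Uniform(40, 80),
impostor Uniform(0, 60) — whose components deliberately straddle the 80%
cut-off so both automated error types occur; `staff_confirmed` is "not
impostor" (staff are the gold standard).  The means above are calibrated
so a default 12-participant cohort reproduces, in expectation, the
aggregate behavior of a small feasibility trial: per-phase submission
fractions near 0.815/0.694/0.494 (overall ≈ 0.675 = 1360/2016) and ≈ 14%
of submitted samples alcohol-positive.  The Beta concentrations are a
judgment call (moderate, plausible between-participant heterogeneity);
only cohort-level aggregates are calibrated — real per-participant
heterogeneity (e.g. a couple of near-dropouts) is not identifiable from
aggregates and is not targeted.

Randomness: one root seed; participant *i* uses substreams
`SeedSequence((seed, i, 0))` for the profile and `((seed, i, 1))` for
events, so cohorts are reproducible, order-independent, and participant
*i*'s log does not change when the cohort grows.  All per-slot draws are
made up-front as fixed-order arrays, giving common random numbers across
parameter values (used by the monotonicity test: raising `cm_effect` can
only remove CM-phase positives).

What the simulator does **not** emulate: pharmacokinetic BrAC decay or
within-day drinking dynamics (positives are i.i.d. per slot given the
profile), behavioral reactivity of adherence to earned rewards, and
structured dropout beyond what low per-phase adherence produces.  Tests
passing on simulated cohorts therefore validate the *pipeline mechanics
and estimator calibration*, not behavioral realism.

## Feasibility and efficacy measures

Feasibility counts in-window submissions against scheduled slots
(`n_participants × days × slots/day`; 2016 under the default plan for 12
participants).  `mean_samples_per_day` divides total submissions by all
participant-days.  Retention is (last counted submission day)/7 in weeks.
Adherence thresholds report the fraction of participants submitting at
least 55% / 75% of their own scheduled slots.  The alcohol-positive count
is defined from BrAC > 0 among submitted samples, *independent of
identity verification*; verified-negative counts require identity
confirmation.  Hence identity-unverified submissions count as submitted
(feasibility) but never as negative (efficacy).

Per-phase negative rates are reported under **both** denominator
conventions — per scheduled slot and per submitted sample — because both
appear in feasibility reporting and they diverge exactly when adherence
differs across phases, which is the phenomenon of interest.

## The GEE estimator

Outcome rows are participant-days (the finest grain consistent with a
daily sampling schedule): `y` = percentage of that day's scheduled
samples that were verified alcohol-negative, on the 0–100 scale, so
coefficients are percentage points and the model is linear (identity
link, Gaussian variance) rather than logistic.  The design is an
intercept, indicator columns for each non-CM phase (CM is the reference),
and the participant-level covariates sex, age, and baseline EtG coded
binary at the 500 ng/mL cut-off.

Estimation alternates (i) the generalized least-squares coefficient
update given the working correlation α, using the closed-form
exchangeable inverse `R⁻¹x = x/(1−α) − α/((1−α)(1+α(k−1)))·Σx`, and (ii)
Liang–Zeger moment updates: dispersion `φ = Σe²/(N−p)` and
`α = Σ_clusters Σ_{j<k} e_j e_k / (φ·(Npairs − p))`.  Convergence is
declared when the largest coefficient change is below 1e-8 (cap 100
iterations; non-convergence is flagged on the result, not raised).  α is
clipped to `[−1/(k_max−1)+1e-6, 1−1e-6]` so degenerate
perfectly-correlated clusters remain solvable.  Rank deficiency is
detected up-front via QR and reported with the offending column names.

Inference uses the robust sandwich `B⁻¹MB⁻¹`
(`B = ΣXᵢᵀRᵢ⁻¹Xᵢ`, `M = Σgᵢgᵢᵀ`, `gᵢ = XᵢᵀRᵢ⁻¹eᵢ`), two-sided Wald
p-values with a Normal reference and `estimate ± z₀.₉₇₅·SE` intervals —
the common GEE defaults.  Because the plain sandwich is anticonservative
with few clusters, a Mancl–DeRouen correction (cluster residuals inflated
by `(I−Hᵢ)⁻¹`) is available via `small_sample=True`; it is off by default
to match standard software conventions.  These moment-estimator
conventions (ddof = p in both φ and α) are the ones mainstream GEE
implementations use, which is what makes an exact cross-implementation
agreement check meaningful; the test suite verifies agreement with
statsmodels to 1e-6 on simulated clustered datasets, and that the
independence working model reproduces the OLS closed form.

**Estimator-calibration study.** The parameter-recovery check simulates
cohorts with a known population-averaged −20 percentage-point second-A
vs CM contrast (phase means chosen so E[y|B]=80 and E[y|A2]=60 under
heterogeneous Beta adherence) and requires the robust 95% CI to cover the
truth in ≥ 90% of 200 replicates.  These cohorts use 24 participants:
with very few clusters the sandwich variance is known to undercover, and
the calibration study is sized so the robust-variance asymptotics it
relies on actually apply.  The full study plan (56 days × 3 slots) is
retained; 200 replicates complete in well under a minute.

## The frozen reference ("pilot") cohort

Published feasibility pilots of this design report only aggregates.
`remotecm.pilot` fabricates a fixed participant-level event log whose
aggregates equal every published count (submissions 411/700/249 per
phase of 504/1008/504 scheduled; positives 64/85/40; verified negatives
347/615/209; match scores 1266 at ≥80 and 94 below, 13 of them
staff-unconfirmed; 10/12 and 7/12 participants above the 55%/75%
adherence thresholds; mean retention 7.5 weeks).  Two allocation facts
are forced rather than free: (a) the 13 staff-unconfirmed images sit on
alcohol-positive submissions — the only placement simultaneously
consistent with the verified-negative counts and the confusion matrix —
and (b) each participant's submissions fill the *last* slots of each
phase range, pinning last-submission days (and hence retention) exactly.
Everything else (which slots are positive, the BrAC values cycling
through 0.01–0.21, the score values 95/65/50) is arbitrary and frozen.
Participant-level quantities derived from this cohort — including the GEE
coefficients in the README example — reflect the fabricated allocation,
not any real cohort, and the documentation says so wherever they appear.

## Numerical and interface conventions

* CSV artifacts: UTF-8, comma-separated, LF endings, mandatory headers,
  empty field = null; a leading `#` provenance comment (version, seed,
  config hash) that all readers skip.
* Config files (YAML/JSON) are validated strictly — unknown keys are
  rejected — and one packaged file (`data/default_config.yaml`) holds
  every simulator default, so distribution choices live in configuration
  rather than code.
* CLI exit codes: 0 success, 2 validation/configuration error, 3 GEE
  non-convergence.
* The analysis report is a versioned JSON document checked against a
  shipped structural schema.

## Known limitations

* The simulator's behavioral model is intentionally minimal (independent
  Bernoulli slots given a profile); it cannot generate reactive or
  autocorrelated drinking patterns.
* The GEE assumes the identity-link linear model on the percent scale;
  with outcomes near 0 or 100 a linear model can predict outside the
  range (population-averaged contrasts remain interpretable).
* With 12 clusters the default sandwich intervals are optimistic; use
  `small_sample=True` for analyses at that scale.
* Retention cannot distinguish "stopped submitting" from "withdrew";
  only the last counted submission is observed.
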