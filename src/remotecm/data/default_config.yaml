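# Default study configuration: 14/28/14-day A-B-A plan, 3 samples/day.
# Control phases pay $2.00 flat per in-window submission; the CM phase runs
# the $2.00 / +$0.25 / $3.50-cap escalating schedule with reset after a
# missed, alcohol-positive or identity-unverified sample.
plan:
  windows:
    scheduled_times: ["09:00", "14:00", "20:00"]
    window_minutes: 30
  phases:
    - label: A1
      condition: control
      duration_days: 14
      schedule: {mode: flat, base_amount: 2.00}
    - label: B
      condition: cm
      duration_days: 28
      schedule:
        mode: escalating
        base_amount: 2.00
        increment: 0.25
        cap: 3.50
        reset_outcomes: [missed, positive, unverified]
    - label: A2
      condition: control
      duration_days: 14
      schedule: {mode: flat, base_amount: 2.00}

# Population priors for the behavior simulator.  Means are calibrated to the
# aggregate behavior of a 12-participant feasibility cohort: per-phase
# submission ~0.815/0.694/0.494, ~14% of submitted samples alcohol-positive,
# ~7% of images below the 80% match cut-off, ~1% impostor submissions, ~2%
# of attempts lost to app failures.  kappa is a Beta concentration; larger
# means less between-participant heterogeneity.
simulation:
  n_participants: 12
  priors:
    p_submit:
      A1: {mean: 0.83, kappa: 40}
      B: {mean: 0.71, kappa: 40}
      A2: {mean: 0.50, kappa: 40}
    p_positive: {mean: 0.158, kappa: 60}
    cm_effect: {mean: 0.04, sd: 0.02, low: 0.0, high: 0.5}
    p_lowquality: {mean: 0.06, kappa: 80}
    p_impostor: {mean: 0.01, kappa: 200}
    p_techfail: {mean: 0.02, kappa: 100}
    p_late: 0.02
  brac_range: [0.01, 0.21]

analysis:
  threshold: 80.0            # facial-match cut-off, percent
  denominator: scheduled     # negative-rate convention: scheduled | submitted
  count_late_as_submitted: false
  control_pays_unverified: true
  gee:
    reference_phase: B
    small_sample: false

seed: 0
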