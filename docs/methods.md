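# Methods

## Evidence synthesis

Each trial contributes an unadjusted mean difference in serum-creatinine
change, md = mean_trt − mean_ctl (μmol/L), with
se² = sd_trt²/n_trt + sd_ctl²/n_ctl and a normal 95% CI (±1.96·se). Trials
reporting only md and a 95% CI are accepted by back-computing
se = (CI_high − CI_low)/3.92.

Pooling is inverse-variance. Heterogeneity: Q = Σwᵢ(mdᵢ − m̄)² with
wᵢ = 1/seᵢ², df = k−1, I² = max(0, (Q−df)/Q), and the DerSimonian–Laird
moment estimator τ² = max(0, (Q−df)/(Σw − Σw²/Σw)). Random-effects weights
are 1/(seᵢ² + τ²). The automatic model rule selects random effects when
p(Q) ≤ 0.10 or I² ≥ 25% and fixed effects otherwise; exact boundary values
go to random effects (the conservative reading of a rule stated as two
strict inequalities with a gap). The CI multiplier stays 1.96 with no
Knapp–Hartung adjustment, matching the classic DL implementation in the
era's meta-analysis software. Meta-regression is univariable — one
moderator at a time, as the source analysis reports one p-value per
covariate — by weighted least squares with weights 1/(seᵢ² + τ²_DL) and a
normal-approximation slope p-value. τ² is the moment estimator throughout
(whether the original used REML is unstated; MoM matches the pooling
estimator and keeps the two stages consistent).

## eGFR and staging

The Chinese-population MDRD equation gives
eGFR = 186·Scr^−1.154·age^−0.203·0.742[female]·1.233 with Scr in mg/dL.
The package keeps creatinine in μmol/L everywhere (the unit of the trial
outcomes) and converts by ÷88.4 inside the equation — a single internal unit
prevents silent double conversion, and it is the only physically consistent
reading given μmol/L effect sizes. The inverse (creatinine from a target
eGFR) is the algebraic power-law inverse and round-trips to 1e-9 relative.

CKD stages use the KDIGO eGFR bands, half-open with the lower bound
inclusive: stage 3 = [30, 60), stage 4 = [15, 30), stage 5 = [0, 15)
mL/min/1.73 m². The thresholds are serializable config so alternative rules
are testable.

## Microsimulation

A cohort (default 10,000 patients) is sampled per stage: age ~ truncated
normal(60, 10) on [18, 90], sex Bernoulli (male proportion 0.6), serum
creatinine truncated normal — stage 3: (170, 25) on [100, 260]; stage 4:
(330, 45) on [240, 450] μmol/L — and annual GFR decline truncated
normal(1.7, 0.5) at zero, the 1.7 mean being the published rate. These
distribution families and parameters stand in for an unavailable
supplementary table; they are config-overridable and the cost/utility
analogues are namespaced `placeholder_*`.

The treated arm receives the pooled WMD as a one-time baseline creatinine
shift, identical for stage-3 and stage-4 starters (the source reports
similar improvements at both stages); the control arm's shift is zero, so
the WMD carries the whole between-arm difference. Decline is applied to
eGFR directly (the stated mechanism is a falling GFR), each patient's
decline is drawn once at baseline and held constant, ages advance one year
per cycle, and trajectories are restaged annually — monotone 3→4→5 because
decline is non-negative.

Transition probabilities come from person-time: annual rate =
events / person-years at risk, p = 1 − exp(−rate). The person-time estimate
is horizon-robust; the alternative first-year event proportion is noisier
and horizon-dependent but available as `conversion: first_year`. Risk sets
are anchored at the post-shift baseline: every patient at or above the
stage-4 threshold accrues 3→4 risk time from year 0 until stage-4 entry —
including treated patients lifted above the stage-3 band, whose added delay
is real treatment effect — and 4→5 risk time runs from stage-4 entry to
stage-5 entry. This convention makes the coupled-cohort monotonicity
property exact: under common random numbers a more negative shift can never
increase either probability. Only patients already at stage 5 post-shift
are excluded.

By default the 3→4 probability is estimated on a stage-3 cohort and 4→5 on
a stage-4 cohort (`design: separate`); a single stage-3 cohort feeding both
(`design: common`) is supported. The simulation horizon is 40 years —
longer than the 20-year economic horizon — so the slower 4→5 pathway
accrues adequate exposure; with the person-time estimator the extra years
change only Monte Carlo precision, not the estimand.

## Markov cohort model

Five states in fixed order (CKD 3, CKD 4, CKD 5 non-HD, CKD 5 HD, death);
death absorbing, progression irreversible; the cohort starts in stage 3.
Within a cycle death competes first and progression applies to survivors
(p_move = p·(1−m)); the alternative additive ordering is a config switch and
raises an infeasibility error when m + p > 1. Mass entering stage 5 splits
89.1% to hemodialysis. Rows sum to 1 within 1e-12 by construction.

Rewards are accumulated on the occupancy trace with the trapezoid half-cycle
correction (weight ½ at t = 0 and t = horizon, 1 elsewhere) and discounted
by (1+r)^−t at boundary t, r = 0.05/year over 20 cycles. With
`half_cycle: false` rewards land at end-of-cycle boundaries t = 1..T, the
convention under which a constant unit-utility stream reproduces the
closed-form annuity (1 − 1.05⁻²⁰)/0.05 ≈ 12.4622 — this pins down the
discount timing unambiguously.

Drug cost per cycle is (pack price / tablets per pack) · daily tablets ·
365 · compliance ≈ CNY 4,184.32 at the published dosing, added to the
treated arm's state costs only while occupying CKD 3/4 (the therapy has no
claimed stage-5 effect); the set of drug-bearing states is config. Death is
pinned to zero cost and utility.

The comparison reports ΔCost, ΔQALY, the full-precision ICER when ΔQALY ≠ 0
(the published rounded increments 24,721/0.39 imply ≈63,387; the published
63,001 corresponds to an unrounded ΔQALY ≈ 0.3924 — the package never forces
the rounded value), dominance flags, and NMB = WTP·ΔQALY − ΔCost at
WTP = CNY 80,976/QALY.

## Sensitivity analysis

One-way bounds are the reported 95% CI when present, else ±30% of base
(probabilities and utilities clipped to [0,1]); the tornado table evaluates
the ICER (or NMB) at each bound holding the rest at base and sorts by
descending output range. A model failure at a bound is recorded as missing
with a warning rather than crashing the table.

PSA families follow convention: gamma for costs and dose, beta for
probabilities, proportions and utilities, parameterized by method of moments
from (mean, sd) — gamma shape = mean²/sd², scale = sd²/mean; beta
α = mean·(mean(1−mean)/sd² − 1), β = α(1−mean)/mean. Where no sd is
reported it defaults to (high − low)/3.92 from the OWSA range (how ranges
became distributions is unstated in the source; this is the standard
normal-range reading). Draws are independent across parameters (no
correlation structure is given); 1,000 Monte Carlo iterations per run,
deterministic under the seed, with infeasible draws resampled (counted,
capped at 100 retries). The CEAC reports, at each λ on a grid from 0 to
3× GDP per capita (CNY 242,928) in 1,000-CNY steps, the fraction of draws
with λ·ΔQALY − ΔCost strictly positive (ties count as not cost-effective);
the discount rate is held fixed in the PSA (varied only in the tornado), as
is common practice under national guideline rates.

## Synthetic data and what passing tests show

`gen_trials` draws true study effects θᵢ ~ N(−19, 20²) and per-arm summary
statistics (n per arm 31–85, within-arm SD 8–15 μmol/L) so the typical
study SE ≈ 2 puts I² near 0.99 — the heterogeneity regime of the real
evidence base — with covariates inside the observed ranges (age 38–75,
treatment duration 2–26 weeks). Measured CI coverage of the true WMD under
these conditions is ≈94% (DL's known mild undercoverage at extreme
heterogeneity), above the 93% the recovery check requires.

The generator emulates summary-level structure only: it does not model
skewed creatinine distributions, correlated covariates, small-study or
publication-bias effects, or outcome-dependent reporting. The placeholder
economics preserve ordinal structure (utility CKD3 > CKD4 > CKD5;
hemodialysis costliest) but not the magnitudes of the unavailable
supplementary table. Passing tests therefore validate the estimators,
model mechanics and their analytic identities — not the published base-case
numbers, which are recoverable only by supplying the supplementary values
through the same config surface.

## Numerical choices and limitations

- Exact boundary ties in the model-selection rule go to random effects.
- Crossing times are closed-form (floor((eGFR₀−θ)/d)+1), so the
  zero-variance cohort reproduces analytic probabilities to 1e-12 and the
  10,000-patient estimate is bit-reproducible under a fixed seed.
- Stage seeds derive from one `SeedSequence` spawn per run; result files
  contain no timestamps, so a rerun from a manifest is byte-identical.
- The economic model is a cohort model; individual-level simulation of the
  economic outcomes, adverse-event costs/disutilities, peritoneal dialysis
  and transplant states, and regression to earlier CKD stages are out of
  scope by design.
- The ICER is undefined (dominance flags instead) when increments change
  sign; NMB is always reported.
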