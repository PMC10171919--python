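# Methods

`oncocea` implements a cost-effectiveness analysis of serplulimab (an
anti-PD-1 antibody) versus regorafenib for previously treated
unresectable or metastatic MSI-H/dMMR colorectal cancer, from the
perspective of China's health-care system, as a fully tested pipeline
over synthetic evidence.  This note records the model, its assumptions,
the tunable parameters, and the design choices made where the design was
genuinely open.

## Evidence synthesis

**Synthetic cohorts.** The real intervention-arm patient-level data are
not public, so the package generates stand-ins with the statistical
anatomy the analysis requires.  Overall survival follows a mixture cure
model: a Bernoulli "cured" indicator (logistic in the baseline
covariates, centred so the marginal cure fraction equals the configured
value) marks long-term survivors whose death time lies beyond any trial
horizon; the uncured draw from a configurable parametric latent
distribution.  Progression-free survival is drawn conditionally
truncated at the subject's OS time, which guarantees `pfs_time <=
os_time` row by row.  Cured subjects are durable responders with
configurable probability (`long_pfs_prob`, default 0.7), producing the
plateau in both endpoints.  Censoring is administrative — a uniform
accrual window plus fixed follow-up, so subject *i*'s potential
follow-up is `followup + U(0, accrual)` months — with optional
exponential dropout (off by default).

Packaged defaults: intervention arm n=74, cure fraction 0.45,
log-normal latent OS (mu=2.2, sigma=0.8 on log-months, median ≈ 9
months among the uncured), Weibull PFS (scale 8, shape 1.2), accrual 12
months, follow-up 36 months (the follow-up used by the trial-horizon
scenario).  Comparator hidden cohort n=136 (the comparator trial's
regorafenib arm size) with log-logistic OS (median ≈ 8.8 months) and
PFS (median ≈ 3.2 months), the medians reported for regorafenib in
advanced CRC.  These defaults are study conditions, not tuning knobs.

What the generator does *not* emulate: informative censoring,
measurement error in event times, inter-site heterogeneity, and any
correlation between covariates.  Passing tests therefore demonstrate
the correctness of the machinery under the stated data-generating
assumptions, not the clinical validity of any particular estimate.

**KM reconstruction.** Comparator evidence enters as digitized
Kaplan-Meier coordinates plus the printed numbers-at-risk table, and is
converted to pseudo individual patient data with the iterative
interval algorithm of Guyot and colleagues: censoring times are spread
evenly within each risk-table interval, event counts at each digitized
coordinate are chosen so the running product-limit estimate tracks the
curve (with error diffusion on the integer rounding so miscounts do not
compound), and the censoring count is iterated until the implied number
at risk matches the printed anchor.  Two at-risk conventions exist in
the wild — the printed number at a scheduled time may or may not count
subjects whose (redated) event lands exactly on that instant — and the
algorithm resolves each anchor with whichever convention is closer to
consistency.  In the final interval, with no anchor ahead, the
censoring count is chosen to match the reported total event count when
one is supplied, and assumed zero otherwise.  Residual subjects are
censored at the last digitized time.  Events precede censorings on
ties.  Digitized times are taken as exact; survival values are only
clamped to be nonincreasing, with the number of repairs logged.

**MAIC.** The intervention arm is reweighted to the comparator
population's published baseline moments (unanchored direction —
weights *into* the comparator population).  Weights take the form
`w_i = exp(alpha'(x_i - x_target))` with `alpha` minimizing the convex
objective `sum_i exp(alpha'(x_i - x_target))` (analytic gradient, BFGS
on standardized covariates, gradient tolerance 1e-8); the stationarity
condition is exactly the method-of-moments constraint.  Categorical
covariates enter as indicators; metastatic site is reduced to a
liver-metastasis indicator (the published covariate list names the
categories but not the encoding; one defensible encoding is fixed
here).  Weights are rescaled to sum to n (frequency-weight convention)
before entering any likelihood, and the effective sample size
`(Σw)²/Σw²` is reported.  Targets outside the sample's support and
collinear covariate sets raise errors naming the offending column.

## Survival extrapolation

Six families are fitted by maximum likelihood to the (weighted)
censored data with fixed parameterizations (t in months):
exponential `S=exp(-λt)`; Weibull `S=exp(-(t/σ)^κ)`; gamma
(shape/rate via the regularized incomplete gamma); log-normal
`S=1-Φ((ln t-μ)/σ)`; log-logistic `S=1/(1+(t/α)^β)`; Gompertz hazard
`λe^{γt}` with `S=exp(-(λ/γ)(e^{γt}-1))` (γ may be negative, giving a
defective distribution — useful for plateauing PFS).  Optimization runs
on unconstrained scales (log for positive parameters), Nelder-Mead
polished by BFGS from several moment-based starts; the covariance is
the inverse observed information (central-difference Hessian) on the
unconstrained scale — the scale on which the PSA draws parameters.
AIC ranks the fits (ties under 0.01 go to the smaller model), BIC is
reported alongside, and a configuration override stands in for the
visual-inspection step of curve selection.

The mixture cure model `S(t) = π + (1-π)S_u(t)` is fitted on
(logit π, latent parameters) with a multi-start grid π ∈ {0.1,…,0.7};
a fit pinned at the π boundary is flagged, and a warning is emitted
when the longest follow-up time is an event (no identifiable plateau).

Base-case family choices (configuration defaults): Gompertz for
intervention PFS, log-normal mixture cure for intervention OS,
log-logistic for both comparator curves.

**Background-mortality floor.** Cured patients still die faster than
the general population, so every extrapolated curve is floored by
k-fold general-population mortality (k=2 base case, k=4 scenario).  The
floor composes on per-cycle conditional probabilities, matching the
4-week grid the Markov model runs on: per cycle,
`d* = max(d_model, 1-(1-d_pop)^k)` where `d_model` is the curve's
conditional death probability and `d_pop` converts the
sex-mix-averaged annual `qx` at the attained age via
`1-(1-qx)^(28/365.25)`.  Attained age advances by cycle length from the
cohort start age; the sex mix is fixed at baseline (cohort model, not
microsimulation).  The floor is applied identically to both arms.  The
packaged life table is synthetic — a Gompertz-Makeham schedule
calibrated to life expectancy near 77 years (male) / 81 (female),
closing with qx=1 at age 100 — because the official yearbook table is
not redistributable here; any real table with the same CSV schema can
be swapped in.  Start age 55 and 60% male are required configuration
values with no claim of fidelity to the unpublished trial demographics.

## Markov model

Three states (progression-free, progressed, dead) on 28-day cycles,
everyone starting progression-free.  Death risk applies equally from
both alive states, taken from the OS curve
(`p_death = 1 - S_os[j+1]/S_os[j]`), and progression is the PFS exit in
excess of death (`p_prog = max(0, (1 - S_pfs[j+1]/S_pfs[j]) -
p_death)`), with both clamping events counted.  The evidence base
provides only two curves per arm and no state-specific mortality; this
equal-risk construction is the unique choice under which the trace
reproduces both curves exactly on cycle boundaries (the model then
coincides with a partitioned-survival analysis whenever no repair
fires).  Independently extrapolated curves can cross; `S_pfs :=
min(S_pfs, S_os)` repairs crossings before transition derivation.  The
lifetime horizon stops once cumulative deaths exceed 99%; the 36-month
scenario runs 39 complete cycles (39 x 28 = 1092 days), the nearest
whole cycle count not exceeding 36 months.  No half-cycle correction in
the base configuration (a midpoint-discounting switch exists for
sensitivity use).

## Economics

All costs are 2022 USD (source evidence converted at 6.7413 CNY/USD)
and live in a versioned fixture file, never in code.  Per cycle, while
progression-free: drug acquisition (serplulimab 3 mg/kg q2w at a 65-kg
reference weight, rounded up to whole 100-mg vials — no vial sharing —
twice per cycle, $3,315.68, capped at 26 cycles ≈ 2 years; regorafenib
21 x 160 mg days, fixture value $2,149.19 kept verbatim although
21 x $102.34 = $2,149.14), administration (infusion only; zero for the
oral comparator in PFS), time-banded monitoring (bands at 3 and 5
years), hospitalization.  While progressed: monitoring,
administration, hospitalization, subsequent treatment.  One-off:
diagnosis and expected one-off AE management at cycle 0; end-of-life
cost ($2,046.84) on the mass entering death each cycle.  Periodic AEs
(hypertension only, by default) convert trial-horizon incidence to a
per-cycle probability via `r = -ln(1-inc)/horizon`,
`p = 1-exp(-r·cycle)`; the conversion horizon defaults to the arm's
assumed median treatment duration (12 months intervention, 3 months
comparator) since the source evidence does not state one.  Known
transcription tensions kept verbatim and documented: the
hospitalization unit values (73.38/110.08/146.77 vs days x 73.78) and
the small nonzero PD "administration" cost for the oral comparator.

Utilities 0.84 (PFS) / 0.57 (PD) in the base case, with 0.94/0.87
(trial-measured) and 0.73/0.59 (alternative literature) as scenario
sets.  One-off AE disutilities are charged once at cycle 0 for one
cycle's duration (the minimal choice; the source is silent on
duration); periodic disutilities accrue per cycle among
progression-free patients.  Life-years and QALYs accrue per cycle at
occupancy-at-cycle-start x 28/365.25 years, discounted at an annual 5%
(costs and outcomes separately configurable) as `(1+r)^(-t)` with `t`
in years at cycle start.  The ICER is `Δcost/ΔQALY` with dominance
flags, judged against a willingness-to-pay threshold of $36,036/QALY
(triple GDP per capita).

## Uncertainty

**OWSA.** Every economic parameter (costs, AE incidences and
disutilities, utilities) plus both discount rates, varied one at a time
to ±20% bounds (95% CIs would take precedence if supplied), utilities
capped at 1 after perturbation; structural zeros keep degenerate
zero-width ranges and are flagged rather than dropped.  Output is a
tornado table sorted by |ICER range|.

**PSA.** 1000 seeded Monte Carlo draws.  Beta distributions for
incidences, utilities and disutilities; gamma for costs; both
moment-matched to mean = base and SD = 20% of base (infeasible beta
SDs raise an error with the feasible bound).  Survival parameters are
drawn per fitted curve as multivariate normal on the unconstrained
scale through the Cholesky factor of the fit covariance, and the
transition schedules are re-derived from the drawn parameters on every
draw — fit uncertainty propagates through the whole model, not through
perturbed curves.  Survival blocks are correlated within a fit only;
economic parameters are independent.  The CEAC reports, per
willingness-to-pay value on a 0–60,000 grid in 500 steps, the exact
fraction of draws with positive incremental net monetary benefit.

**Scenarios.** (1) direct comparison — the intervention curves refit
with unit weights; (2) 36-month horizon; (3) k=4 mortality multiplier;
(4a/4b) the alternative utility sets, which by construction change
QALYs only.

## Numerical choices and limitations

Times are months throughout evidence synthesis and convert to cycles
only inside the model grid (1 month = 365.25/12 days; cycle = 28 days).
Monetary fixtures carry two-decimal values; reports round at cent
precision.  The convergence tolerances are 1e-8 (MAIC gradient), 1e-10
(fit gradient), 1e-12 (trace conservation).  Fit covariances that fail
Cholesky by rounding are projected to the nearest PSD matrix.

The default problem sizes — 74 intervention subjects, a 136-subject
hidden comparator, 800-cycle maximum grid, 1000 PSA draws, and
100-replicate recovery studies at n=2000 — were chosen as the smallest
sizes at which every property of interest is measurable with
comfortable Monte Carlo margins.

Because the real trial IPD and the actual digitized comparator curves
are not public, the packaged base case cannot (and does not try to)
reproduce the published headline ICER; what the package establishes is
the arithmetic of every published identity that *is* recomputable, and
the statistical correctness of every stage of the chain on data whose
ground truth is known.
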