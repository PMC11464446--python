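# Methods

## Model structure

The package implements a three-state cohort model for first-line treatment
of advanced urothelial carcinoma: progression free (PFS), progressed
disease (PD), and dead. All patients start in PFS; movement is one-way.
Although such models are conventionally described as Markov models, state
membership here is read directly off the two fitted survival curves of each
strategy (a partitioned-survival analysis): at cycle boundary `t`,
`pfs = min(S_PFS(t), S_OS(t))`, `dead = 1 − S_OS(t)`, and PD is the
remainder. This is the unambiguous construction when transitions are
"calculated from the fitted curves", and it guarantees the three
occupancies sum to one. The `min` cap resolves any extrapolated curve
crossing; no transition-matrix mode is provided. An individual-level
microsimulation exists only as a test oracle (comonotone event times, so
its expectation equals the partitioned reading exactly).

Cycle length is 21 days (one treatment cycle); the horizon is 15 years =
`ceil(15·365/21)` = 261 cycles, by which point 97.6 % of the chemotherapy
cohort and 88 % of the combination cohort have died. Time is measured in
months of 30.4375 days; the published survival parameters only reproduce
the trial medians in those units.

## Survival model

Both endpoints in both arms follow the log-logistic law
`S(t) = 1/(1+(λt)^γ)`. The published formula for this distribution omits
the reciprocal; we use the form above because the published scales then
satisfy `median = 1/λ` ≈ the trial medians (13.1/6.4/34.5/16.0 vs
12.5/6.3/31.5/16.1 months). Five further families (exponential, Weibull,
log-normal, Gompertz, generalized gamma in the (μ, σ, Q) parameterization)
are implemented for model selection by AIC, ties broken by BIC, then by
parsimony. Gompertz evaluation permits negative shape; fitting constrains
it positive so that S(∞) → 0.

Two fitting objectives are provided, selectable per call because the
original workflow's choice is not documented:

* **MLE** on individual times, used directly for simulated data and, for
  bare curves carrying numbers at risk, after an interval reconstruction
  in the spirit of published pseudo-IPD methods (events at the curve's
  drop points against the current risk set, censorings spread into the
  following interval).
* **Weighted least squares** on the complementary log-log scale for
  digitized coordinates without at-risk numbers, with Greenwood-style
  inverse-variance weights `S(ln S)²/(1−S)`; equal weights would let the
  noisy curve tail dominate. Its AIC/BIC use the Gaussian
  pseudo-likelihood of the transformed residuals and are comparable only
  across families fitted to the same points.

Digitized curves are cleaned before fitting: isotonic clipping to monotone
non-increasing, duplicate times keeping the lower survival.

## Economics

Per cycle, each strategy accrues (all amounts USD 2023; the 7.03 CNY/USD
conversion is metadata only):

* **Drug acquisition** on the on-treatment fraction, whole vials per
  administration with no sharing (a linear-pricing switch exists for
  threshold work). Dosing: EV 1.25 mg/kg capped at 125 mg on days 1 and 8;
  pembrolizumab 200 mg flat; gemcitabine 1000 mg/m² twice per cycle;
  cisplatin 70 mg/m² or carboplatin at AUC 5 via the Calvert formula
  `dose = AUC·(CrCl+25)`, mixed 54.3 %/45.7 % per the trial's
  cisplatin-eligibility split. Reference patient: 65 kg, 1.72 m², CrCl 70
  mL/min.
* **Routine tests and follow-up** on all alive patients; **best supportive
  care** on PD occupancy. A single `bsc_proportion` scales the whole PD
  care package (BSC + the PD share of tests and follow-up), because the
  published BSC-uptake scenario moves costs by far more than the BSC line
  item alone can.
* **Terminal care** once per incident death; **adverse-event management**
  once at cycle 1 as the incidence-weighted sum over grade ≥3 events with
  incidence >5 %.

QALYs accrue as occupancy × utility (PFS 0.84, PD 0.80) per cycle-year,
minus a one-time incidence-weighted AE disutility (0.28) lasting one cycle
— the sources give no AE durations. Discounting uses the exact exponent
`(1+r)^(−21k/365)` at each cycle's end, r = 0.05.

### Treatment-duration rules (the decisive calibration)

The source tables pin every price and utility but not *which cohort
fraction* receives each drug each cycle. The published totals identify
these rules rather precisely, because total cost is linear in each vial
price: the EV-price scenario ladder has slope 149.0 vials and the
horizon ladder fixes how drug spend grows over time. The shipped defaults
are the configuration that reproduces those fingerprints:

* **Enfortumab vedotin** (no cycle cap): a log-logistic time-on-treatment
  curve with median 7 months — the trial's reported median EV duration —
  and the PFS shape 1.2676. Treat-to-progression overshoots the published
  spend tail by ~2×; a hard stop at the median truncates it to zero; the
  duration curve matches the spend increments across 3/6/10/15-year
  horizons to ~1 %. The curve's shape stays pinned under subgroup
  hazard-ratio transforms (treatment duration is a trial observation, not
  a function of subgroup survival).
* **Pembrolizumab**: alive-weighted (treatment beyond progression) up to
  the 35-cycle cap; the published spend (~$131 k, horizon-constant) rejects
  both PFS-weighting and a duration-curve rule.
* **Chemotherapy**: PFS-weighted up to the 6-cycle cap.

All three rules are per-drug configuration (`accrual: pfs | alive |
duration_curve`), and the run metadata records which rule produced any
artifact.

### Accrual timing

Occupancy for accrual is read at the cycle midpoint (half-cycle
correction), configurable to `start` or `end`. Calibration against the
published totals decided the default: midpoint accrual lands QALYs/costs
within ~1.5 % on both arms, while start-of-cycle accrual pushes the
intervention cost ~3 % high.

With these conventions the base case computes EV-PEMB $380,896 / 3.210
QALYs versus chemotherapy $23,037 / 1.686 QALYs, ICER $234,770 per QALY,
and a joint price-threshold multiplier of 0.129 — all within ~1.5 % of the
published 375,420.24 / 3.22, 23,369.67 / 1.70, 232,256.16 and 13.1 %.

## Sensitivity analysis

One-way analysis runs the full model at each parameter's range ends
(everything else at base) and reports ICER spreads sorted for a tornado
display. The PSA draws every uncertain parameter per its published
distribution family: Gamma for costs and creatinine clearance, Beta for
incidences and utilities, Normal for weight and body-surface area
(truncated at 0.1× base to exclude nonphysical draws), discount rate
fixed. Moments are matched to (base, SD) with SD = (max−min)/3.92, ranges
being 95 % intervals; an infeasible Beta moment match falls back to a
range-preserving scaled Beta with mean at base (flagged on the sample
frame). Survival parameters carry no published uncertainty and are held
fixed in the PSA — a documented limitation shared with the source
analysis. The price-threshold search bisects the joint EV + pembrolizumab
multiplier to |ICER − WTP| < $1, exploiting cost linearity in prices.

## Subgroups and scenarios

Subgroups apply the published PFS/OS hazard ratios to the *comparator's*
fitted curves on the cumulative-hazard scale, `S_sub = S_ref^HR` — the
log-logistic is not a proportional-hazards family, so this is a modelling
convention inherited from the cited methodology, and both arms share the
same reference curves (the comparator arm uses HR = 1). Costs and
utilities stay at base; whether the original analysis re-used them
unchanged is unstated, and we assume yes.

Scenarios are declared config transforms: horizon 3/6/10 years, BSC uptake
30 %/50 %, EV vial price at US/Norwegian/Japanese references, and a cure
model. The cure model freezes progression at a configurable time (default
20 months — the original criterion, "no progression by the data cut-off",
is not computable from printed information): patients still progression
free are cured, stop treatment, keep one routine-tests item per cycle, and
die only at a background rate (default 0.02/year, configurable); progressed
patients keep the modelled OS hazard. Its published row is treated as a
directional check only (QALYs above base, ICER below base but above the
WTP), since the original construction is not reproducible from the printed
description — notably its intervention-arm cost *rises* by $104 k, which no
reading with treatment stopping at cure can produce.

The background-mortality hazard floor (`1−(1−q)^(21/365)` per cycle,
replacing the modelled hazard wherever smaller) is available model-wide but
defaults off: no life-table values are printed, and the modelled
late-extrapolation hazard (~8 %/year) already exceeds plausible background
rates at these ages, so a realistic floor would not bind anyway.

## Synthetic data

`synthetic` generates the one input the pipeline cannot take from a table:
survival curves. Event times come from inverse-transform sampling of any
supported family; default censoring mimics trial-like follow-up
(administrative cut-off at 25 months plus 5 %/year exponential dropout) —
fixture conventions, not claims about the trial. Kaplan-Meier estimation
uses lifelines. Digitization emulation samples an even time grid over the
plotted window (by default up to where the curve falls below 2.5 %,
because published axes do not extend into the exhausted tail and a heavy
tail's last event time can lie far beyond any figure), reads the step
function, adds truncated Gaussian jitter, and re-monotonizes. The
full-circle validation (truth → cohort of 2,000 → KM → digitize → refit)
recovers all four published parameter sets within 5 %; what passing shows
is fidelity of the fitting stage at trial-like sample sizes, not that the
published curves themselves were digitized correctly.

## Numerical choices and limitations

* All stochastic components take explicit seeds (`numpy` Generator); no
  global random state. Same seed → byte-identical artifacts.
* Fit optimization: Nelder-Mead on log-transformed parameters with
  perturbed restarts only on non-convergence; degenerate curves (all
  survival 1, or fewer usable points than twice the parameter count)
  raise a fit error with a diagnostic.
* The generalized gamma's quantile has no closed form and is inverted by
  bracketed root finding; all other families use closed forms.
* Zero-incidence adverse events are carried with zero ranges and never
  vary; a cohort already exhausted on a curve transitions with
  probability 1 by convention.
* Costs use point estimates of weight/BSA/CrCl; per-patient heterogeneity
  enters only through sensitivity analysis. Societal costs, EVPI, and
  covariate-adjusted survival are out of scope.
* The calibrated drug-accrual rules reproduce the published totals but
  remain inferences from those totals, not documented facts about the
  original implementation; they are the package's shipped defaults and
  every alternative remains one config key away.
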