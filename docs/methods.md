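# Methods

This note documents the modeling conventions, parameter choices, numerical
decisions and known limitations of the package. Everything stated here is
computed by the code and exercised by the test suite; nothing is asserted
that the tests or `scripts/acceptance.py` do not themselves produce.

## Decision problem

Two strategies for second-line treatment of advanced EGFR-mutant NSCLC
after EGFR-TKI failure: sacituzumab tirumotecan (sac-TMT, 5 mg/kg IV on
days 1 and 15 of each 28-day cycle) versus platinum-based chemotherapy
(pemetrexed 500 mg/m² + carboplatin AUC 5 every 21 days ×4, then pemetrexed
maintenance). Three health states (PFS, PD, death), all patients entering
in PFS; Chinese healthcare-system perspective, direct medical costs only,
2025 USD.

## Time and discounting conventions

- 1 month = 365.25/12 days; the 28-day cycle is 0.9199 months.
- Horizon: the 130 full 28-day cycles inside 10 years (~9.97 years); the
  chemotherapy cohort is >99% dead at the horizon, the sac-TMT arm's
  terminal death share is reported by the trace.
- Discounting at 5%/year, continuous-in-cycle: factor (1.05)^(−t_years)
  evaluated at each cycle boundary.
- Half-cycle correction as trapezoidal state membership,
  0.5·(m_k + m_{k+1}), applied identically in both engines (a config flag
  switches to start-of-cycle accrual). Symmetric treatment avoids a
  spurious engine discrepancy.
- Year length for the annual-mortality-to-cycle conversion is 365 days
  (the "28-day probability" convention): with annual probability p,
  r = −ln(1−p) and p_cycle = 1 − exp(−r·28/365).

## Survival curves

Seven candidate families with shape/scale parameterizations chosen so that
the tabulated coefficients reproduce the trial's printed medians:
log-logistic S(t) = 1/(1+(t/scale)^shape), so the sac-TMT OS median equals
the scale, 27.354 months (consistent with a median not reached at ~18
months follow-up); Weibull-PH S(t) = exp(−rate·t^shape) gives a chemo OS
median of 17.7 months against the printed 17.4; the chemo PFS log-logistic
median is 4.59 months, a plausible second-line chemotherapy PFS. Parameters
are month-scaled. Generalized gamma uses the Prentice (μ, σ, Q) form;
gamma uses shape/rate. Gompertz requires a positive shape so that S → 0.

Fitting maximizes the right-censored log-likelihood
Σ[δ·ln f(t) + (1−δ)·ln S(t)] by Nelder–Mead on log-transformed positive
parameters (closed form for the exponential). One in-house likelihood is
used uniformly across all seven families because no single installed
library fits all of them; `lifelines` serves as an independent oracle in
the tests for the families it covers. Model selection takes the lowest
AIC, ties broken by BIC; an AIC/BIC disagreement on the winner is logged.

## Pseudo-IPD reconstruction

`reconstruct_ipd` inverts the product-limit construction from digitized
curve coordinates plus a numbers-at-risk table: within each risk-table
interval the censoring count is chosen (exhaustive search, smallest count
on ties) so the implied at-risk number at the interval end matches the
published one, censorings are spread evenly over the interval, and event
counts at each digitized drop follow d_j = n_j(1 − S_j/S_prev) with the
running model survival used for subsequent conditioning. Digitized values
are clamped non-increasing (isotonic running minimum, logged) before
reconstruction. The record count equals the initial at-risk count exactly;
an optional total-event count is honored by flipping the latest
events/censorings. Round-trip accuracy (simulate → KM → digitize →
reconstruct → KM) is within ±0.03 survival at risk-table times for n=200.

## Engines

**Partitioned survival.** Occupancy read off the curves at each boundary;
the PFS share is capped at OS where independently fitted curves cross
(the chemo arm's log-logistic PFS exceeds its Weibull OS in the far tail;
the capped count is logged).

**Markov.** Per-cycle rows built from the same curves:

- PFS exit: 1 − S_PFS(t+Δ)/S_PFS(t), with the same min(S_PFS, S_OS)
  crossing guard as the PSM so the closure below cannot be starved.
- PFS→death: background mortality (8.04‰/year → 6.19e−4 per cycle),
  floored at the total exit probability so PFS→PD is never negative.
- PD→death: closes the OS curve. The deaths still owed by the OS curve at
  the end of the cycle — cumulative target 1 − S_OS(t+Δ), minus deaths
  already realized and background deaths out of PFS this cycle — are
  assigned to PD as a probability against the running PD occupancy,
  clamped to [0,1] (clamp count logged; zero when PD is empty).

Targeting the cumulative rather than per-cycle death increment makes the
entry transient self-correcting: at model start PD is empty and PFS→death
is capped at background mortality, so the first cycle's OS deaths can only
be realized up to p_bg; the deficit (≤0.006 for the base-case curves) is
repaid as soon as PD has mass. From the second cycle boundary on, the
cohort death share tracks 1 − S_OS within 0.004 (sac-TMT) / 0.0002
(chemo), and on exponential curves the Markov trace reproduces the PSM
trace to 1e−6 per cycle. Death is absorbing; rows sum to 1 exactly.

A consequence worth stating plainly: because the schedule is constructed
to reproduce the input curves, the two engines give nearly identical
traces and therefore nearly identical QALYs and ICERs here. A Markov model
whose PD→death closure is specified differently (the construction is not
uniquely determined by a three-state diagram plus two curves) can produce
a materially different split between PFS/PD time; this structural
uncertainty is a known limitation of cross-model comparisons of this
design, and reproducing any *particular* alternative closure is out of
scope.

## Economics

- Reference patient 65 kg, 1.72 m², CrCl 70 mL/min; carboplatin dose via
  Calvert, AUC·(CrCl+25) = 475 mg.
- **Vial policy** (committed calibration knob): `exact` — the administered
  milligrams are priced linearly (325 mg of sac-TMT costs 325/200 of the
  vial price). Whole-vial pricing without sharing (`ceil`) is available in
  config and unit-tested; exact-dose pricing is the committed base case
  because whole-vial pricing overshoots the reference base-case and
  scenario-1 cost totals by >20%, while exact pricing lands within ~4% of
  both — the reference analysis evidently costed administered dose.
- Chemotherapy's 21-day regimen is converted to a daily rate and accrued
  per 28-day model cycle; induction = 4 regimen cycles = 84 days = the
  first three model cycles. Carboplatin is used for 100% of the platinum
  backbone (cisplatin configurable).
- Routine follow-up per model cycle (committed defaults): 1 consultation,
  1 CBC, 1 biochemistry, 1 urinalysis, CT every 2 cycles, and per
  administration: injection + preparation fee + 1 nursing day + 1 bed day.
  MRI is not part of the routine bundle (knob: `mri_every_n_cycles: 0`);
  the bundle also applies in PD (without drug administrations).
- PD drug mix (committed knob): 100% best supportive care ($436.19/cycle);
  pemetrexed and osimertinib mixes are config options.
- Grade ≥3 adverse events (incidence ≥5%): expected costs applied once at
  model entry (Σ incidence × cost; $388.71 sac-TMT, $759.66 chemo).
- AE disutilities are applied once, at model entry, as an **absolute
  expected QALY decrement** Σ incidence × |disutility| (0.1478 sac-TMT,
  0.1506 chemo) — not scaled by cycle length. This is the convention that
  reproduces the reference QALY totals; scaling the decrement by one
  cycle's length leaves both arms ~0.15 QALYs high.
- Treatment costs accrue only in PFS (treatment until progression).

The follow-up frequencies, PD mix and vial policy are calibration knobs
because the reference analysis does not print them; they were fixed once
by minimizing the deviation of the two partitioned-survival total costs
from the reference base case (achieved: +2.7% sac-TMT, +0.5% chemo) and
are committed in `data/basecase.yaml`.

## Sensitivity analysis

- **OWSA**: every tabulated parameter varied to its low/high bound
  (tabulated ranges; ±20% where no range is given), all else at base,
  ICERs recomputed deterministically; entries with non-positive
  incremental QALYs are flagged, not dropped. The 0–8% discount-rate
  variation is a methodological scenario reported alongside the parameter
  tornado rather than ranked within it. The four largest-spread parameters
  are the PD utility, the sac-TMT vial price, the PFS utility, and the
  sac-TMT-arm neutropenia incidence; no tested variation brings the ICER
  below the $41,811 threshold (minimum ~$72,700).
- **PSA**: 1,000 second-order iterations; Gamma for costs, Beta for
  utilities/probabilities, Beta on |d| then negated for disutilities; all
  moment-matched to mean = base, sd = (high−low)/3.92. Infeasible moments
  fall back to uniform(low, high) with a logged warning. One seeded
  generator draws parameters in fixed registry order, so runs are
  bit-reproducible from (seed, config). Survival-curve parameters carry no
  tabulated distribution and are held fixed (a logged limitation: curve
  uncertainty is not propagated). Scenario overrides rescale a parameter's
  range proportionally so relative uncertainty is preserved.
- **Scenarios**: (1) sac-TMT at the NRDL-negotiated $637/200 mg (price
  only; QALYs bit-identical); (2) WTP at 1×/2×/3× per-capita GDP
  ($13,937/$27,874/$41,811, the 1× value derived as a third of the 3×
  threshold); (3) regional 3×-GDP thresholds (Zhejiang $59,532, Jiangsu
  $70,155, Shanghai $96,180, Beijing $100,380).

## Synthetic data

The generator emulates the structure of the source trial — two arms of 188
patients (376 randomized 1:1), right-censored PFS/OS per arm, digitized
step curves with risk tables — with the base-case fitted curves as the
generating truth, administrative censoring at 24 months and 5% uniform
random dropout. PFS/OS are comonotone (shared uniform rank), guaranteeing
PFS ≤ OS per subject. It does **not** emulate covariates, treatment
switching, interval-censored assessment schedules, or correlated
digitization error, so passing round-trip and recovery tests demonstrates
correctness of the reconstruction/fitting machinery, not robustness to
those real-data features.

## Numerical choices

- Parametric survival evaluated through `scipy.stats` frozen
  distributions; positivity constraints enforced at construction.
- S(t)=0 in the interval-transition formula returns 1 with a warning
  (absorbing tail); transition rows are exact probability rows (sum 1).
- Fit recovery on n=5000 synthetic records is within 10% in shape/scale
  form; the Weibull-PH rate is compared as scale = rate^(−1/shape)
  because the (shape, rate) pair is ill-conditioned (a 4% shape error
  mechanically induces a >10% rate error at a rate near zero).
- AIC ties broken by BIC; equal both → first encountered.
- Reported tables round to 2 decimals; all comparisons and JSON output at
  full precision.

## Known limitations

- The Markov PD→death closure is one defensible construction among
  several; alternatives shift QALY totals by up to ~0.1 (see Engines).
- The PSA propagates the tabulated utility ranges (PD utility
  0.031–0.473), which make the ICER distribution wide; probability
  statements at thresholds close to the ICER's central mass (e.g. the
  $96,180–$100,380 regional thresholds) are therefore graded, not 0/100%.
  At the $41,811 national threshold the probability of cost-effectiveness
  is exactly 0 in 1,000 iterations.
- Cost totals depend on unprinted resource-use details absorbed into the
  committed calibration knobs; their joint effect is bounded by the ~3%
  residual on the base-case totals.
- No EVPI, no correlated draws, no societal costs, no covariate-adjusted
  survival, no cure/spline extrapolations.
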