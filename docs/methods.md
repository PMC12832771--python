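# Methods

## Model structure

The decision model is a partitioned survival model (PSM) with four
states — progression-free on first-line therapy (PFS), the second-line
interval between first and second progression (PFS2), progressive
disease after second progression (PD), and death — monthly cycles, and
a default horizon of 240 cycles (20 years). Transitions are
irreversible and death is absorbing. Occupancy is read directly off two
survivor curves rather than a transition matrix:

    PFS(t)   = min(S_PFS(t), S_OS(t))
    Death(t) = 1 − S_OS(t)
    PFS2(t) + PD(t) = S_OS(t) − PFS(t)

Independently extrapolated curves can cross; the `min()` cap is the
standard PSM repair and the number of capped cycles is reported in the
trace diagnostics rather than silently absorbed.

**PFS2/PD split.** Two curves cannot identify three alive states. The
cohort entering the post-progression remainder at cycle s is assigned
an exponential time in PFS2 with monthly exit hazard λ₂ (per-cycle exit
probability 1 − e^(−λ₂), applied from the end of the entry cycle), and
the resulting PFS2 mass is truncated so it never exceeds the remainder;
PD takes the rest. λ₂ = 0 keeps all post-progression mass in second
line, λ₂ → ∞ empties it into PD. The default λ₂ = ln 2 / 6 (median six
months in second line, a typical second-line progression time in
advanced HCC) is an explicit, swappable assumption, and a user-supplied
second partition curve can replace the convolution entirely.

## Survival inputs

Published KM figures are consumed as digitized (time, survival)
coordinates plus the printed number-at-risk row. Digitization noise up
to a tolerance (default 0.01 survival probability) is repaired by
running-minimum clipping; anything larger is an error naming the
offending point.

Pseudo individual patient data are recovered per risk-table interval:
the censoring count is adjusted iteratively (censoring times spread
uniformly over the interval) until the implied number at risk matches
the printed value at the next boundary, and integer event counts at
each coordinate follow by inverting the product-limit recursion, with
largest-residual rounding. Beyond the last risk-table entry the
previous interval's censoring rate is carried forward, unless a total
event count is supplied, in which case the final interval's censoring
is chosen to match it where feasible. Ties use the standard
events-before-censorings convention. Infeasible tables (counts
irreconcilable with the curve drops beyond max(5, 5% of n)) raise an
error carrying per-interval diagnostics.

Five parametric families are fitted to the reconstructed data by
censored maximum likelihood: exponential S = e^(−λt); Weibull
S = exp(−(t/σ)^k); Gompertz S = exp(−(b/a)(e^(at) − 1)); log-normal
S = 1 − Φ((ln t − μ)/σ); log-logistic S = 1/(1 + (t/α)^β). The
exponential MLE is the closed form λ̂ = d/Σt; the two-parameter
families are maximised with Nelder–Mead on log-transformed positive
parameters (the Gompertz shape and log-normal μ stay unconstrained)
from a moment-based start plus three perturbed restarts, tolerance
1e-10 on the objective. Extrapolations are combined with Akaike
weights, wᵢ ∝ exp(−ΔAICᵢ/2); BIC is reported but not used for
weighting. Averaging acts on the survivor functions themselves (the
probability scale, not log-survival or hazards), so the averaged curve
is bounded by its components at every time point.

## Economics

Costs accrue per cycle against state occupancy: first-line drug and
administration against PFS (treat-to-progression), weighted subsequent
therapy against PFS2, best supportive care against PD, follow-up
against all alive states. Adverse-event management costs and
disutilities are one-time first-cycle quantities (grade ≥3 events with
between-arm differences); end-of-life cost multiplies incident deaths
each cycle. Discounting uses the end-of-cycle convention with factor
(1+r)^(−t/12); a half-cycle (trapezoid) correction is available but off
by default, matching per-cycle accrual in common PSM software. QALYs
weight occupancy by state utilities 0.84 (PFS), 0.76 (PFS2), 0.68 (PD),
0 (death), minus the first-cycle AE disutility term.

Dosing arithmetic uses a month of 365.25/12 days. IV components are
accounted at a continuous administration rate (cycle length / interval)
with a cumulative cap for induction (four q3w doses of the doublet) and
a delayed start for maintenance (480 mg flat q4w thereafter); daily
oral drugs consume dose × 365.25/12 mg per active cycle — sorafenib at
800 mg/day is 24,350 mg/cycle. Prices are per mg with no vial-wastage
rounding by default. Body weight enters as a point mean (70 kg US,
65 kg China) selecting the lenvatinib dose tier (8 mg < 60 kg, 12 mg
otherwise); the male proportion is carried as a passthrough parameter
only, since no mechanism for it is defined in the model.

Decision outcomes: ICER = ΔC/ΔE computed only when neither weak
dominance applies; NMB = WTP·ΔE − ΔC; WTP thresholds $150,000/QALY (US)
and $39,933.67/QALY (China, three times per-capita GDP), with
$22,031.53 and $95,160.78 as the provincial extremes for the Chinese
acceptability grid.

## Uncertainty analyses

One-way ranges default to ±20% around base values (utilities capped at
1; discount rate 0 to 8%); results are ranked by absolute ICER spread,
and a model failure at an extreme flags the row instead of dropping it.
The two-way analysis grids the two immunotherapy prices. The PSA draws
gamma variates for cost-type parameters and beta variates for
utilities, both by method of moments with mean at base and SD
defaulting to 20% of the mean (5 percentage points for utilities),
1,000 draws; survival parameters are held at base because the economic
stage, not the fitting stage, is being propagated — an explicit scope
choice. Acceptability probabilities are exact empirical fractions of
draws with positive NMB. Price thresholds are found by bisection on a
price multiplier (single drug or both jointly) to |ICER − WTP|/WTP <
1e-4, with monotonicity verified numerically and "always/never
cost-effective in range" reported when there is no crossing. Scenario
re-runs cover horizons of 4/5/10/20 years, PFS-only accrual, exclusion
of AE disutilities, an alternative PFS source, comparator restriction
to lenvatinib or sorafenib alone, and the population switch.

## Synthetic trial generator

The generator emulates the structure of the modelled trial: two arms of
335 and 333 subjects (98 and 110 in the China subgroup), OS medians
23.7 versus 20.6 months, PFS medians near 9 months, uniform accrual
over 10 months with an administrative cutoff at 40.2 months so
follow-up is uniform on [30.2, 40.2] months (median 35.2). The
immunotherapy arm uses log-logistic truths (shape 1.5) for OS and PFS —
the heavy power tail emulates the late plateau of immunotherapy
survival and, with equal shapes, guarantees S_PFS(t) ≤ S_OS(t) at every
t by scale ordering alone; the control arm uses Weibull truths (shape
1.25). The China subgroup widens the control OS median to 17.5 months,
mirroring the direction of the published subgroup contrast. Per-subject
PFS and OS are coupled comonotonically: one uniform draw pushed through
both inverse survivors, equivalent to OS = PFS plus a non-negative
post-progression increment, which preserves both marginals exactly
while enforcing the per-subject ordering.

What it does **not** emulate: dropout or loss to follow-up (censoring
is purely administrative), covariates and subgroup heterogeneity beyond
sample size and the OS median, treatment switching, response endpoints,
and digitization pixel noise (curves are exact product-limit output).
Passing round-trip tests therefore demonstrates correctness of the
reconstruction and fitting machinery under clean conditions, not
robustness to messy digitization.

Economic parameter sets for both countries are complete but
**synthetic placeholders** (flagged `synthetic=True`): unit prices,
AE costs and incidences, subsequent-therapy mixes, follow-up/BSC/
end-of-life costs are plausible round numbers for each payer
perspective, not sourced tariffs. Utilities, discount rates and WTP
thresholds are the modelled base-case values.

## Numerical behaviour and limitations

- Reconstruction fidelity: on 300-subject arms with 20–35%
  administrative censoring the product-limit curve of the reconstructed
  cohort stays within 0.02 sup-norm of the input curve, and the
  reconstructed cohort size equals the initial number at risk exactly.
- Parameter recovery: censored MLE at n = 5,000 is unbiased with
  relative sampling SD under 5% for all parameters (≈4.7% for the
  Gompertz shape, the hardest case).
- Subgroup-scale instability is real and intended: at ~100 subjects per
  arm the Akaike weights move substantially between seeds (heavy-tailed
  families can claim weight on Weibull-truth data), so extrapolated
  incremental QALYs vary widely. This reflects genuine structural
  uncertainty in tail extrapolation from small samples; the model
  averaging exposes it rather than hiding it.
- The PSM reads marginal survivor curves only; it cannot represent
  within-subject dependence beyond the PFS ≤ OS constraint, and the
  PFS2 duration assumption is unidentifiable from the two curves (see
  λ₂ above).
- Currency outputs are serialised as half-up-rounded decimal strings to
  cents; probabilities keep full double precision. All randomness flows
  from a single integer seed per run, and result bundles are
  byte-reproducible for a fixed seed and configuration.
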