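# Methods

## Scope and model overview

`epfassay` implements the statistics used to screen entomopathogenic
fungal isolates and quantify their virulence against insect larvae. Four
estimation problems are covered: a weighted screening index over
plate-culture and bioassay traits (BEI), quantal probit dose–response with
lethal-concentration intervals, median lethal time at fixed doses, and
simple phenotyping arithmetic. A seeded generator produces complete
synthetic datasets with retained ground truth so every stage is testable
end to end.

## Screening index

For one isolate, SG is the mean germination percentage over replicate
counts of 100 spores, RSR = W/D where D is the mean first
plate-sporulation day over uncensored replicates and W the experiment
window (default 20 days), and LM the mean percent host-larva mortality
over the screening window (10 days for the wax-moth assay). The index is

    BEI = (w_SG/100)·SG + (w_RSR/100)·RSR + (w_LM/100)·LM

with default weights (37, 13, 50). The weights act as percentage
coefficients on SG and LM (0–100 scales) while RSR enters on its raw
~1–2 ratio scale; applying the weights literally to all three terms would
push the index far above 100 and is inconsistent with the bundled
reference table, which this reading reproduces within ±0.1 on all 27
isolates. Weights are configurable but the normalisation is fixed.

Selection uses a strict threshold (BEI > 80 by default). Group boundaries
place 85.0 in G2 (so G1 is strictly > 85) and close the lower edges; the
efficacy classes are LE < 70, ME [70, 80), HE ≥ 80 with the upper bound
open — mortalities above 90% remain HE rather than forming a fourth
class. DPCS replicate means are taken before the ratio, and germination is
averaged as percentages (identical to averaging counts at n = 100). An
isolate that never sporulates within the window has undefined RSR and
undefined BEI; it is reported as missing and never selected.

## Probit dose–response

The response model is P(death | c) = C + (1−C)·Φ(α + β·x), x = log₁₀ c.
No classical +5 offset is added to α; `ProbitFit.legacy_intercept`
converts for comparison with older software. Replicates are pooled within
dose before fitting; replicate-level dispersion is picked up by the
heterogeneity factor instead.

Natural mortality C is handled by Abbott pre-correction of observed
proportions (default, matching the usual bioassay workflow), by joint MLE
of (α, β, C) via Nelder–Mead on a logit-transformed C, or ignored.
Corrected proportions below 0 are clamped to 0 for fitting.

Estimation is Fisher scoring (IRLS with the probit working response),
started from a working-probit regression on proportions clamped to
[1/(2n), 1−1/(2n)], converged when the log-likelihood changes by less
than 1e-8 (at most 100 iterations). On non-convergence the fit falls back
to a brute-force grid search over α ∈ [−6, 6], β ∈ [0.01, 3] with
successive zoom-ins, and the fit is flagged. The covariance is the inverse
expected information at the optimum; it matches a probit GLM's to
numerical precision on well-posed data.

Degenerate inputs: a uniform response at every dose (all dead or all
alive) carries no gradient information and raises; a flat response at an
interior proportion yields β ≈ 0 and a `non-informative` flag; perfect
separation (only 0% and 100% doses) yields a flagged finite fit on clamped
proportions with deliberately inflated variance rather than a divergent
Newton iteration.

Goodness of fit is the Pearson chi-square over dose levels with df = k−2
and heterogeneity h = max(1, chi²/df). LCp = 10^((Φ⁻¹(p) − α)/β).
Fiducial limits follow Finney's Fieller construction on the log₁₀-dose
scale with g = t²·v_ββ/β²; when g ≥ 1 the interval is reported unbounded
(a value, not an error). The quantile t is normal unless the chi-square is
significant at the 5% level, in which case a Student-t with df = k−2
inflated by √h is used. Gating on significance rather than on any h > 1
matters: chi²/df exceeds 1 about 39% of the time under a correctly
specified binomial model (df = 3), and inflating in all those cases makes
the intervals conservative (Monte-Carlo coverage ≈ 98%); with the
significance gate the measured coverage of the 95% LC50 interval is
within the 92–98% band (see the acceptance tests, 1000 simulations at
5 doses × 200 larvae).

## Median lethal time

The default LT50 estimator interpolates each replicate's cumulative
mortality series at the 50% crossing: with s_d the proportion dead by the
end of day d (s_0 := 0), LT50 = (d−1) + (0.5 − s_{d−1})/(s_d − s_{d−1})
for the first day d with s_d ≥ 0.5, clipped below at day 1. Replicates
that never reach 50% inside the window are censored: excluded from the
mean ± SE (sample SD/√r) and counted, never imputed. The estimator is
invariant to appending post-crossing days. A probit-on-log₁₀-time MLE of
the daily increments (right-censoring survivors past the window) is the
configurable alternative; at the bioassay's n = 20 per replicate the
interpolation estimator is the more robust default because it is defined
for every crossing replicate without a convergence step. LT50 is computed
on uncorrected treatment mortality by default (control mortality in these
assays is near zero); an option Abbott-corrects the series day by day
first, re-monotonised by a running maximum.

## Synthetic data generator

The generator emulates the standard screening/virulence design: decadal
doses 10⁴–10⁸ spores·ml⁻¹, 3 replicates × 20 larvae, a 7-day leafminer
window and a 10-day wax-moth screening window at 10⁷ spores·ml⁻¹, 100
spores counted per germination replicate, plate sporulation observed up to
day 20. Per isolate, latent parameters are drawn uniformly from
configured ranges: probit intercept α ∈ (−2.8, −1.2) and slope
β ∈ (0.35, 0.9) — placing LC50 within the 10³–10⁵ spores·ml⁻¹ span typical
of virulent isolates (positive intercepts under this parameterization
would put LC50 at or below 1 spore·ml⁻¹ and saturate every dose, leaving
nothing to estimate) — control mortality in (0, 0.05), germination
probability in (0.80, 0.97), first sporulation day in (10, 16), wax-moth
mortality in (0.75, 1.0).

Final deaths per replicate are Binomial(n, C + (1−C)·Φ(α + β·log₁₀ c));
death days discretize a log-normal on log₁₀ days whose median shifts
linearly in log dose, m(c) = 3.0 − 0.5·(log₁₀ c − 6) days (σ = 0.15,
clipped at 1 day), landing LT50 between about 2 and 4 days across the
grid — inside the 1.9–5.7-day range typical of virulent isolates. The
time model is a deliberate invention: it exists to give the LT50
estimators a known target, not to model insect pathophysiology. Control
replicates at dose 0 draw Binomial(n, C) deaths at uniform days.

Randomness is organised as per-isolate substreams keyed by
(seed, isolate index, stage), so adding isolates or stages never perturbs
earlier draws, and identical configurations reproduce byte-identical CSV
bundles.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: between-replicate overdispersion (real
replicates share rearing containers), dose-preparation error on the
nominal concentrations, mortality from handling, time-varying hazards
beyond the log-normal shape, and any correlation between screening traits
and virulence across isolates.

## Numerical choices and problem sizes

Proportions are clamped at 1e-10 for likelihood evaluation; the Fisher
scoring tolerance is 1e-8 in log-likelihood; grid-search refinement zooms
three times from an 81-point grid. Tie-breaks: optimum temperature prefers
the 28 °C control, otherwise the lowest tied temperature. Validation is
fail-fast with file/line context on CSV ingestion.

Test and acceptance runs use scaled designs chosen to keep the suite
fast while leaving the statistical conclusions stable: oracle-agreement
checks use 20 random instances of ≤ 5 doses; parameter recovery uses 200
isolates at 3 × 20 larvae and 100 isolates at 1000 larvae per dose;
interval coverage uses 1000 simulated datasets at 5 doses × 200 larvae
on a decadal grid centred at the true LC50.

## Known limitations

* Only the probit link is provided (no logit/complementary log-log), and
  no hierarchical pooling across isolates.
* Fiducial limits assume the asymptotic normality of (α̂, β̂); at 3 × 20
  larvae per dose with LC50 far outside the dose grid the intervals can
  be erratic (flagged via g and the separation/convergence fields).
* LT50 aggregation treats replicates as independent; a pooled
  survival-model alternative (Kaplan–Meier/Cox) is out of scope.
* The screening index is a fixed-weight linear composite; no attempt is
  made to estimate weights from data.
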