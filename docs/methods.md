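# Methods

## The statistical model

The outcome is the known-implantation-data live-birth label (KID_LB) of a
transferred Day-2 embryo. The working model is a penalized additive
logistic regression with a cluster random effect:

```
logit p_i = β₀ + f_t2(t2_i) [+ f_age(age_c(i))] + β_MN·MN_i
            + β_short·1[cc2_i short] + β_long·1[cc2_i long] + u_c(i),
u_c ~ N(0, σ_u²)
```

The **Base Model** omits the age smooth, the **Age Model** includes it.
Covariates: t2 (two-cell timing, hpi), cc2 = t3 − t2 banded into
short / medium / long with boundaries inclusive to medium (defaults
9.33 h / 11.45 h, following the published cleavage-window guideline;
configurable because clinic-specific cutoffs vary), and multinucleation
as a binary deselection marker. The four-cell timing t4 enters only a
screening rule: 1 iff t4 is present and strictly below a threshold chosen
by grid search (30–50 h in 0.5 h steps), with missing t4 mapped to 0.

### Smooths

Each smooth is a P-spline: a cubic B-spline basis (10 functions) on
equally spaced knots spanning the training range, padded by `degree`
knots per side, penalized by the squared second differences of adjacent
coefficients. Outside the training range the basis extrapolates linearly
(first-order expansion at the boundary). Each smooth carries a
sum-to-zero constraint absorbed by a null-space reparameterization; the
constrained dof is added back when reporting the smooth's edf, so a
second-order penalty at λ→∞ reports edf 2 (its constant + linear null
space) and a smooth's edf always lies in [2, n_basis].

### Fitting

Penalized IRLS maximizes the binomial log-likelihood minus
½Σλⱼ·(penalty) − ½u'u/σ_u², treating the per-cycle intercepts as
ridge-penalized coefficients. The random-effect block is profiled out of
every weighted least-squares solve (its cross-products are diagonal per
cycle), so each iteration costs O(n·p²) regardless of the number of
cycles. Step-halving enforces a monotone decrease of the penalized
deviance; convergence is max |Δcoefficient| < 1e-8 within 200 iterations,
with non-convergence flagged on the model rather than raised. Complete
separation is detected (near-zero deviance with extreme linear
predictors) and flagged.

λ and σ_u are chosen by Nelder–Mead on the Laplace-approximate restricted
likelihood over (log λⱼ, log σ_u), started from λ=1, σ_u=0.5, with a
coordinate-wise log-grid fallback (λ ∈ 10⁻³…10³) if the optimizer fails.
This PQL-like criterion is an approximation — exact for the Gaussian
working model, biased for binary data with tiny clusters. Two documented
consequences: with one embryo per cycle σ_u is only weakly identified
(for pure Bernoulli singleton clusters it is not identifiable at all),
and perfectly concordant double transfers push σ_u up because a shared
outcome looks like unbounded within-cycle correlation.

Effective dof per term is the trace of the influence matrix restricted to
the term's columns; AIC = deviance + 2·total edf, used by greedy forward
selection (add the candidate with the largest AIC decrease; stop when no
candidate decreases it). Note AIC's ~16% false-inclusion rate for a
1-dof null candidate is inherent, not a defect. Term p-values are Wald
statistics on the penalized coefficients against χ² with the term's edf —
approximate, as penalized Wald tests are; no multiple-testing correction
is applied.

### Prediction

Population-level scores set u = 0 (held-out cycles have no fitted
intercept); `use_random_effect="fitted"` is available for training-data
diagnostics only. Because predictions are conditional on u = 0, they sit
below observed marginal rates whenever the fitted σ_u is large — this is
visible in the stratified calibration table on cohorts with concordance
selection, and is the documented reason the calibration check uses a
single-transfer cohort where the model is correctly specified.

## Validation

AUC is the Mann–Whitney rank statistic with midrank ties. The clustered
validation partitions *cycles* (never embryos) into 5 folds, fits once
per fold on the training cycles, scores the held-out embryos at the
population level, then draws 200 cycle-level bootstrap resamples of the
held-out fold — 1,000 AUCs, summarized by mean and percentile 2.5/97.5
interval. Resampling whole cycles keeps DET pairs intact; embryo-level
resampling would be anti-conservative under outcome concordance. A
repeated-cross-validation mode (B full k-fold repeats with fresh splits)
is available behind `CVConfig.mode` because the two natural readings of
"k-fold with bootstrap" differ; the within-fold bootstrap is the default.
Resamples with a single outcome class yield a missing AUC, excluded from
the summary and counted.

## Stratification and the age-averaged counterfactual

Embryos are cross-classified by maternal-age tertile and Age-Model-score
tertile. Edges are the empirical 1/3 and 2/3 quantiles; assignment is by
value with intervals [min, e1], (e1, e2], (e2, max], so tied values land
in one tier and distinct-valued cohorts split within one embryo of equal
thirds (2,147 distinct values give tiers of 715/716/716). Per stratum the
report holds the count, observed live-birth fraction, mean predicted
probability, and the within-stratum AUC of three score sets: Age Model,
Base Model, and the Age Model re-scored after replacing every age by its
age-tier's arithmetic mean of embryo-level ages (a cycle-weighted mean is
available by flag). Score tertiles from the Age Model are reused for all
tables. All stratification quantities are in-sample by design —
descriptive, not validation. The counterfactual isolates age's
contribution: if age acts additively, replacing it by a within-tier
constant leaves within-stratum ranking to the morphokinetic terms, so the
counterfactual AUCs should track the Base Model's. With independently
fitted models the agreement is approximate; the tests assert 0.03.

## ICSI t2 sensitivity

ICSI fertilisation time is known to the minute; conventional IVF is not,
so the two groups' morphokinetic clocks may be offset. `shift_icsi_t2`
adds δ hours to t2 of ICSI-cycle embryos (t3 unchanged; cc2 recomputed
and clamped at 0 with a log entry if the shift inverts the order), and
`auc_vs_shift_curve` refits the model at each grid point (default −2…+2 h
in 0.1 h steps) and records the in-sample AUC. Smoothing parameters are
selected by REML once on the unshifted data and held fixed across the
grid: re-selecting at each shift would multiply cost ~100× without
changing the qualitative curve, and a fixed penalty makes the zero-shift
point bit-identical to the unshifted analysis. Positive shift means later
ICSI t2. A flat curve (the default scenario gives max |ΔAUC| ≈ 0.004–0.02)
says the model tolerates fertilisation-timing uncertainty.

The argmax of the curve can in principle recover a planted IVF/ICSI
offset, but identification depends on the *shape* of the t2 effect: a
near-linear effect absorbs any between-group shift (the refit AUC curve
is flat to ~0.001 within ±0.5 h), so the recovery experiment uses a
designed scenario — a sharp threshold-shaped t2 effect
(−3·expit((t2−26)/0.4)), a tight t2 distribution (SD 1.0 h), balanced
insemination mix, single transfers, and a ±3 h grid so the argmax has
two-sided information around the planted +1.4 h. Under that design the
argmax localizes the offset to within ±0.1–0.3 h.

## The synthetic cohort generator

The generator emulates the structure of a Day-2 KID transfer cohort:

* 1,506 cycles (865 SET / 641 DET by rounding the SET fraction), hence
  2,147 transferred embryos; maternal age uniform on 25–42 y; 65% ICSI.
* Timings (hpi, rounded to 2 decimals as annotation precision):
  t2 ~ N(26, 3) truncated > 18; cc2 a short/medium/long mixture with 70%
  mass in the medium band (truncated normals per band); t4 = t3 + N(1,
  0.8) truncated > 0.05; tPNf = t2 − N(3.5, 0.8); 10% of t4 values
  blanked. Multinucleation Bernoulli(0.2); fragmentation 50·Beta(1.3, 8)
  with no outcome effect (so variable selection has a true negative).
* Outcome: logistic in intercept 0.55, a strictly decreasing age effect
  −0.22·softplus(age−31; scale 3), a mildly curved t2 effect
  −0.035·(t2−22)² whose optimum sits on the fast flank (so the effect is
  two-sided across the cohort), multinucleation −0.7, cc2 short/long
  −0.5/−0.45, and a cycle intercept with SD 0.3. Each embryo's label is
  drawn from its own probability; DET cycles with discordant labels are
  then removed by the concordance filter, reproducing the cohort's
  inclusion rule (~85% of cycles kept; post-filter live-birth rate
  ≈ 0.165). A `cycle_latent` mode that draws one outcome per DET cycle at
  the pair-mean probability is available when a deterministic cohort size
  matters; it halves within-pair covariate effects and makes the filter a
  no-op, so it is not the default.

Effect scales were calibrated once so the default cohort reproduces the
documented structure of such cohorts: single-variable AUC ordering with
age highest (~0.72) then t2, in-sample model AUCs near 0.70 (Base) and
0.79 (Age), and nine populated age × score strata. A strictly one-sided
(penalty-only) t2 effect provably empties the oldest-age/highest-score
stratum at the truth level, so the two-sided flank shape is structural,
not cosmetic.

What the generator does **not** emulate: patient-level clustering across
repeated cycles, embryo-morphology grades, day-3+ kinetics, clinic drift
over time, and informative missingness (t4 is missing completely at
random). Passing tests therefore demonstrate the pipeline's correctness
on its assumed data-generating law, not clinical performance.

Parameter-recovery experiments use single-transfer (SET-only) cohorts:
with per-embryo outcomes and no selection, the fitted embryo-level
conditional model is exactly the generative law, so planted effects are
recovered without the attenuation or σ_u inflation that concordance
selection induces.

## Numerical choices and degenerate inputs

* IRLS: probabilities clipped to [1e-10, 1−1e-10]; working weights
  floored at 1e-10; Cholesky solve with least-squares fallback.
* REML: log λ clipped to [−10, 14], log σ_u to [−7, 2.5]; Nelder–Mead
  xatol 0.05 (λ precision beyond that does not move the fit).
* Tertile ties: tied values are never split across tiers (value-based
  assignment against quantile edges).
* Shift-curve argmax ties resolve to the smallest |shift|, then the
  smaller shift; AUCs are compared after rounding to 12 decimals so
  bit-level noise cannot break a genuine tie.
* Empty or single-class strata and single-class bootstrap resamples give
  missing entries (logged), never exceptions; a single-class *training*
  outcome is an error.
* Constant covariates for smooths raise a degenerate-covariate error.

## Known limitations

* The Laplace/PQL likelihood is approximate for binary data; σ_u under
  concordant DET data is an effective, not structural, parameter, and
  population-level (u = 0) probabilities are conditionally scaled.
* Wald p-values on penalized terms are approximate; no multiplicity
  control.
* In-sample screening and stratification AUCs are optimistic by
  construction; the bootstrap CV numbers are the validated ones.
* Per-patient random effects (patients contributing several cycles) are
  not modelled; the cluster unit is the treatment cycle.
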