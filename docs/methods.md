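# Methods

## The calibration problem for competing risks

A prediction model for a time-to-event outcome with a competing event is
judged at a horizon t₀ by its cumulative incidence function (CIF)
F₁(t₀ | **X**): the probability that the primary event occurs by t₀ given
covariates, acknowledging that the competing event may occur first.
Calibration asks whether subjects given predicted risk Î really experience
the event at rate Î.  Binning subjects by predicted risk and comparing bin
means against a nonparametric CIF (the decile comparator implemented in
`binned_calibration`) answers this coarsely; the package's main tool is a
*smoothed* curve that avoids binning altogether.

## Smoothed calibration curves

Let Î be the predicted CIF at t₀ from the model under assessment.  A
secondary Fine-Gray subdistribution hazard model is fit to the same
subjects with a single "covariate": a restricted cubic spline basis in
cloglog(Î) = log(−log(1 − Î)).  The cloglog scale is the natural link: a
Fine-Gray model with proportional subdistribution hazards is exactly linear
in cloglog of its own CIF, so a perfectly calibrated model yields a
diagonal curve regardless of the spline.  The secondary model's predicted
incidence at t₀, Îˢ = 1 − exp(−Λ̂₀(t₀)·e^{s(cloglog Î)}), is the smoothed
observed risk.  Reported quantities:

* the curve (Î, Îˢ) on a 100-point grid spanning the 1st–99th percentile
  of Î (the display range; extremes are data-poor),
* ICI (mean |Îˢ − Î| over subjects), E50 (median), E90 (90th percentile,
  type-7 interpolation), Emax (maximum).

Metrics are always computed from per-subject values, never from the display
grid, so they are weighted by the actual distribution of predicted risk.

Knots default to 3 (10th/50th/90th percentiles of the transformed values);
4 and 5 knots (5/35/65/95 and 5/27.5/50/72.5/95, Harrell's convention) are
available.  The Monte Carlo knot study shows why 3 is the default: mean
curves are indistinguishable, but replicate-to-replicate variability — and
hence mean ICI — grows with the knot count, most visibly at the later
evaluation times.  Knot placement happens on the cloglog scale; because the
transform is monotone this selects the same subjects as placing them on the
probability scale, though interpolated percentile values differ slightly.
The spline's nonlinear columns are divided by (t_k − t₁)² for conditioning;
a test verifies fitted curves are invariant to this constant.

`administrative_censor_at_t0=True` recodes follow-up beyond t₀ as censoring
at t₀ before fitting the secondary model.  This option guards against
non-proportional subdistribution hazards in the secondary model, at the
price of discarding later events; it is off by default.

## The Fine-Gray engine

The Fine-Gray model is estimated by the weighted-data route: the sample is
expanded into start-stop counting-process rows in which subjects with a
competing event at Tᵢ remain in the risk set afterwards, carrying the
inverse-probability-of-censoring weight G(s−)/G(Tᵢ−) at each later
primary-event time s, with G the reverse Kaplan-Meier estimate of the
censoring survival.  For right-censored data this coincides with the
original estimating-equation formulation.  Choices that matter:

* **Tie convention.** At a tied time the risk set for either Kaplan-Meier
  estimator is everyone with follow-up ≥ t (events and censorings at t
  both remain at risk for the other's "event").  This makes the
  Aalen-Johansen identity CIF₁ + CIF₂ + S = 1 exact, which is tested to
  1e−12.
* **Expansion granularity.** The weight is a step function of s that
  changes only where G jumps, so the default expansion emits one interval
  per censoring time rather than one per primary-event time (the
  ``granularity="event"`` form is available; a test confirms both yield
  identical fits).  Without censoring a competing-event subject costs two
  rows instead of one per event time, which is what makes the Monte Carlo
  studies cheap.
* **Risk-set extension** stops at the last primary-event time, or earlier
  at the last time G > 0; a competing event with G(Tᵢ−) = 0 raises a
  degenerate-weight error (unreachable for data expanded with their own G
  under the tie convention above, but a supplied external G can trigger it).
* **Partial likelihood.** Weighted Cox with Breslow tie handling, maximized
  by Newton-Raphson from β = 0, up to 50 iterations with up to 20 step
  halvings.  Risk-set sums over the start-stop rows are accumulated by a
  difference-array/cumulative-sum scheme, so each iteration is linear in
  the number of rows.  Covariates are centred internally; the Breslow
  baseline Λ̂₀ (jumps at primary-event times only) is mapped back to the
  original scale.  Convergence: gradient max-norm < 1e−8 or relative
  log-likelihood change < 1e−10; the improvement test in step-halving uses
  a relative tolerance of 1e−9·(|ℓ| + 1) because the float64 resolution at
  typical log-likelihood magnitudes is of that order.  Monotone-likelihood
  divergence (|β| escaping) and failed halving mark the fit non-converged;
  the calibration layer raises rather than returning a silent bad curve.
* No analytic standard errors are produced; the observed-information
  diagonal is kept only as a convergence diagnostic.

## The simulator

`generate` implements indirect simulation of a competing-risk process.
With covariate x ~ N(0,1), primary linear predictor lp1 and competing lp2:

* Z ~ Bernoulli(φ), φ = 1 − (1 − p)^{e^{lp1}}; p is the long-run primary
  incidence for a subject with covariate 0.
* Z = 1: T₁ drawn by inverse transform from F₁(t|x)/φ where
  F₁(t|x) = 1 − (1 − p(1 − e^{−t}))^{e^{lp1}}.
* Z = 0: T₂ ~ Exponential(e^{lp2}).

This construction makes the cause-1 subdistribution *exactly* proportional
on the subdistribution-hazard scale with coefficient β₁ — the basis of the
coefficient-recovery and `true_cif` oracle tests.  Default parameters
(p = 0.5, β₁ = 1, β₂ = 0.25) are the reference conditions of the
validation studies.  Options: a quadratic primary predictor
β₁x + 0.25β₁x² (paired with a linear fitted model to study
mis-specification), a bivariate-normal two-covariate design with
lp1 = 0.50x₁ + β₂′x₂ and lp2 = 0.25x₁ + 0.25x₂ (fitted model omits x₂),
and outcome generation with a shifted p in a validation population that
shares the covariate distribution.

Exponential censoring is calibrated by bisection on the rate over
[1e−6, 100] until a super-population's censored proportion is within 0.001
of target; a unit-exponential draw is reused across bisection steps so the
proportion is monotone in the rate.  Evaluation times are the
10/25/50/75/90th percentiles of event time — of *observed* time when
censoring is on — in a seeded super-population (1,000,000 at full scale;
the studies and tests here use 100,000, which moves the percentiles by well
under the Monte Carlo noise of the metrics).

What the generator does *not* emulate: real covariate measurement error,
non-proportional subdistribution hazards, informative censoring, or ties
(times are continuous).  Passing tests therefore demonstrate correctness of
the machinery and the method's operating characteristics under these clean
conditions, not robustness to those features of real data.

## The Monte Carlo studies

`run_study` reproduces six designs, with the factor grids fixed: knot
selection (p ∈ {0.25, 0.5, 0.75} × k ∈ {3,4,5}, N = 1000); correct model
with censoring (censored fraction 0–0.6 by 0.2, N = 2000, 3 knots);
correct model without censoring (N ∈ {500, 1000, 2000} × β₁ ∈
{0.25, 0.5, 1} × p ∈ {0.25, 0.5, 0.75}, 27 cells); omitted quadratic (same
27 cells); omitted main effect (ρ ∈ {0, 0.25, 0.5, 0.75} × β₂′ ∈
{0.25, 0.5, 1}, N = 1000, p = 0.5, 12 cells); incidence shift
(p.validation ∈ {0.3 … 0.7}, β₁ = 0.5, N = 1000).  Replicates default to a
desk-scale 100 (1000 at full scale); per-replicate seeds derive from the
master seed through a `SeedSequence` counter scheme so every scenario is
independently reproducible.  Mean curves average replicate curves on a
common 100-point grid spanning the union of the replicates' display
ranges, each replicate contributing where its own curve is defined, with
2.5th/97.5th percentile bands.  Replicates whose secondary model fails to
converge are excluded from averaging but counted and reported.

Desk-scale findings (recomputed by `scripts/acceptance.py` and asserted in
the test suite): near-zero mean ICI for correct models (≈0.001–0.005 across
evaluation times); a clear inflation when a quadratic term is omitted
(≈0.017–0.05, with the U-shaped curve signature); no detectable signal when
a main effect is omitted but the covariate distribution is unchanged
(gap ≤ 0.01 to the matched full-model baseline — a genuine blind spot of
calibration-in-distribution, not a defect of the metric); a symmetric rise
of mean ICI as validation incidence departs from derivation incidence; and
mean ICI ordering 3 ≤ 4 ≤ 5 knots at the later times.

## Limitations

* The secondary model assumes proportional subdistribution hazards in the
  spline of cloglog(Î); the administrative-censoring option is the provided
  mitigation, and its behaviour under strong non-proportionality is not
  characterized here.
* Pseudo-value-based curves, calibration intercept/slope analogues and
  discrimination measures are out of scope.
* Single competing cause; collapse multiple causes to status 2 beforehand.
* No left truncation, interval censoring, or time-varying covariates.
* Coefficient-level agreement with other Fine-Gray implementations is not
  claimed (spline normalization and estimation-route details differ);
  fitted curves and metrics are the stable quantities.
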