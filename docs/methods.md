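# Methods

## The question and the design

The package estimates whether countries with higher health-security
capacity — summarized by a 0–100 composite index built from 96
sub-indicators, 37 indicators, and 6 categories — protected their essential
childhood immunization coverage during 2020–2022. Coverage, in percent of
the target cohort per country-vaccine-year, is the outcome; treatment is a
deterministic partition at a score cutoff (score ≥ cutoff, ties treated);
2015–2019 are pre-pandemic years and 2020–2022 post-pandemic. Because
immunization coverage is itself one indicator of the composite, the index
is re-averaged without that indicator before any cutoff is applied, so
exposure and outcome share no data.

The outcome model motivating the design is a two-way fixed-effect panel
model,

    Coverage_it = α + γ_t + δ_i + θ · Treated_i × Post_t + X_i'β + ε_it,

with year effects γ_t, country effects δ_i, and categorical covariates X
(World Bank income group, WHO region). Estimation does not run this OLS;
it uses a doubly-robust difference-in-differences estimator (below), which
is consistent under the same parallel-trends assumption while adjusting
for covariate-linked trend differences.

## The doubly-robust 2×2 estimator

For a base year b and target year t, with unit-level change
ΔY_i = Y_it − Y_ib, treatment indicator D_i and dummy design X_i
(reference level = alphabetically first per factor):

* propensity model: logistic regression of D on X, probabilities clipped
  to [0.001, 0.999]. The fit uses an L2-stabilized solver (C = 1e4) so
  covariate cells with no treated countries — guaranteed here, e.g. no
  African country clears high cutoffs — degrade to clipped near-zero
  propensities instead of a separation failure;
* outcome model: least squares of ΔY on X among controls only, predictions
  μ̂(X) for all units; rank-deficient designs resolve aliased columns by
  the minimum-norm solution with a warning;
* ATT:  θ̂ = Ê_w1[ΔY − μ̂(X)] − Ê_w0[ΔY − μ̂(X)], with w1 uniform over
  treated units and w0 ∝ p̂(X)/(1 − p̂(X)) over controls.

The estimate is consistent if either working model is correct; a property
test verifies |bias| < 0.1 pp at ~5,000 units when exactly one model omits
an interaction the truth contains. With an intercept-only design the
estimator collapses, exactly, to the classical difference in group means
of ΔY (checked to 1e−10).

Analysis units are country-vaccine series (12 per country) by default;
`unit="country-mean"` collapses to one series per country. All inference
clusters at the country level.

### Inference

Standard errors come from the estimator's asymptotic linear
representation, including the first-step corrections for the estimated
propensity (logit score × inverse Hessian) and for the control-side
outcome regression. Unit-level influence values are summed within country
clusters; the variance is the sum of squared cluster contributions with a
G/(G−1) factor, and 95% intervals are normal (±1.96·se). A 199-draw
country-cluster bootstrap (both working models refitted per draw) is
available as alternative inference and agrees with the analytic standard
errors within 15% on synthetic panels.

### Event study, averaging, pre-trend test

`estimate_did` fits the three post-year ATTs against base year 2019, and
placebo ATTs for each pre year against a rolling t−1 base. The pooled
2020–2022 effect is the unweighted mean of the three yearly ATTs — the
identity mean(0.74, 1.23, 0.76) = 0.91 holds by construction — with
variance from the averaged cluster influence contributions.

The parallel pre-trend test is a joint Wald test that all placebo ATTs are
zero, with the joint covariance from the stacked cluster influences.
Because a modest number of treated countries carries most of that
covariance, the plain χ² reference overrejects (measured size 0.095 at
nominal 0.05 over 400 null replicates). The statistic is therefore
referred to a Hotelling-type F distribution whose denominator degrees of
freedom use a Satterthwaite-style effective cluster count,
ν = (Σ_c q_c)² / Σ_c q_c² with q_c the squared norm of cluster c's
influence vector — the standard small-sample family of cluster-robust
corrections. Measured size under the default study conditions is 0.035
(1,000 replicates), slightly conservative and inside the 0.05 ± 0.02
band. A singular covariance falls back to the pseudo-inverse with reduced
degrees of freedom; a noiseless perfectly parallel panel returns W = 0,
p = 1 exactly.

## The sliding-cutoff sweep

For every cutoff on a grid (0–100 step 1 for composite scores; −2.5..2.5
step 0.1 for World Bank governance indicators, matching the one-decimal
reporting of those cutoffs), the sweep assigns treatment, requires at
least `min_group = 5` countries per group, fits the event study, and
gates on the pre-trend test (pass = p ≥ 0.05; failing fits are retained
for diagnostics). The minimum qualifying cutoff is the smallest cutoff
whose record passes both gates with a significantly positive pooled
effect (95% CI above zero; an any-year rule is available). No
multiplicity correction is applied across cutoffs or across score
variables, matching the procedure the sweep reproduces; consequences are
discussed under Limitations.

## The synthetic generator

`generate_panel` draws coverage from the two-way fixed-effect process
above. Defaults describe the emulated study conditions:

* 191 countries × 12 vaccines × 2015–2022 (18,336 cells);
* α = 85, common year effects with a mild +0.2 pp/yr pre-trend and dips
  of −2.3/−3.7/−2.9 pp in 2020–2022, echoing the global coverage dip;
* country effects N(0, 3²), vaccine intercepts N(0, 2²) (the latter
  cancel in ΔY; they exist so vaccine series differ in level);
* income-group coverage levels +3/0/−3/−7 pp (High → Low) and
  post-period income trends 0/−0.5/−1.0/−1.5 pp — poorer countries
  decline more after 2019, so income confounds trends, not just levels;
* iid noise N(0, 3²), coverage clipped to [0, 100] (warning above 1%
  clipping, error above 10%);
* planted effects τ = (0.74, 1.23, 0.76) pp for countries whose composite
  score clears s* = 57, the effect scale the pipeline is meant to detect;
* composite scores: a per-country latent capacity N(38 + c·shift(income),
  12²) with confounding strength c = 12 shifting High vs Low income by
  ±12 points; 96 Beta-shaped sub-indicators around the latent mean
  aggregate by equal-weight means up the 96→37→6→1 tree. At cutoff 57
  this yields ≈ 20–30 treated countries, almost all high-income, with
  Africa empty — reproducing the overlap structure the estimator must
  survive;
* attributes: WHO-region marginals matching the analyzed 191 countries
  and a stylized income-by-region mixture; governance indicators are
  income-linked with N(0, 0.5²) scatter, truncated to [−2.5, 2.5].

Optional pre-trend violations add a differential pre-2020 slope, either
for treated countries (`pretrend_slope`, pp/yr) or per score band
(`pretrend_bands`). All randomness flows from the single `seed`; the same
truth reproduces byte-identical tables.

What the generator does not emulate: reporting heterogeneity across
vaccines (noise is homoscedastic), serial correlation in ε beyond the
fixed effects, country-year shocks shared across vaccines, bounded-scale
ceiling effects near 100% coverage (clipping is kept below ~0.1% by the
defaults), and any epidemic dynamics. Passing tests therefore demonstrate
the statistical machinery under the assumed data-generating process, not
the substantive findings on the real immunization data.

## Calibration results the tests compute

Over seeded Monte-Carlo replicates at study scale (191 × 12): planted
yearly effects are recovered with |mean bias| < 0.05 pp and 95% CI
coverage inside [0.92, 0.97] (500 replicates); pre-trend test size is
0.035 at α = 0.05 (1,000 replicates); analytic and bootstrap standard
errors agree within 15%.

## The threshold-recovery fixture

One experiment asks the sweep to localize a planted threshold: scores
evenly spaced on 0–100, protective effect only above 60. Effect dilution
cannot localize the threshold — at any cutoff c < 60 the treated group
still contains a (100−60)/(100−c) ≥ 0.4 fraction of truly affected
countries, so the diluted ATT stays significant far below 60 whenever the
test has power. The fixture therefore also plants offsetting pre-trend
bands below the threshold (+3 pp/yr for score < 30, −3 pp/yr for
30 ≤ score < 60, α lowered to 65 to keep the 12-pp 2015 offsets inside
the coverage scale): every cutoff below 60 mixes the bands asymmetrically
and should fail the parallel-trends gate, while any cutoff ≥ 60 leaves
the control group's band slopes exactly offsetting.

Even so, localization is bounded: the influence-function covariance of
the placebo estimates includes the between-country slope dispersion the
bands create, so the pre-trend Wald z at cutoff c scales like
0.41·(60−c) *independently of the planted slope magnitude* (signal and
estimated dispersion both scale with it; verified empirically — slopes of
5 and 8 pp/yr recover identically). Reliable gating therefore begins ~6+
points below the threshold, and the sweep recovers the planted 60 at
52–56 across seeds. A ±3 window corresponds to moving ~6 of 191 countries
(3% of the score distribution), below the resolution of any mean-based
statistic at this sample size; the corresponding acceptance test states
the ±3 requirement and fails, documenting the resolution limit rather
than masking it.

## Numerical choices and degenerate inputs

* Propensity clipping [0.001, 0.999]; intercept-only designs use the
  closed-form treated share.
* Units missing either year of a 2×2 pair are dropped pairwise with a
  tally; an estimate is refused only when a whole group vanishes.
* Percentile of a cutoff = fraction of analyzed countries strictly below
  it, reported rounded to two decimals alongside the raw fraction.
* Composite re-aggregation recomputes only the removed node's ancestor
  chain, bottom-up; removing an only child or the root is refused.
* Loess trendlines (effect vs cutoff) use tricube weights, degree 2, span
  0.75; pointwise standard errors come from the linear-smoother variance
  form with residual degrees of freedom n − 2tr(L) + tr(LLᵀ). Windows too
  small for the polynomial degree are widened with a warning.
* Display rounding is two decimals; CSV output keeps full precision.

## Problem sizes used by the test suite and acceptance script

Monte-Carlo batteries run at the emulated study scale (191 × 12 units)
with 500–1,000 replicates for calibration checks, 20 seeds for the
threshold sweep, 199 bootstrap draws, and ~5,000 units × 200 replicates
for the double-robustness property; the zero-effect sweep specificity
check uses 20 replicates on the supported-overlap grid (cutoffs 30–70,
step 5). These sizes were chosen so each property is measured with a
Monte-Carlo error well inside the asserted tolerance.

## Known limitations

* **Poor-overlap cutoffs.** Where one group falls below ~20 countries,
  the control-side outcome regression (9 dummy parameters) overfits a
  handful of clusters and the influence-function variance is
  anti-conservative (conditional Monte Carlo: empirical sd ≈ 0.38 vs mean
  se ≈ 0.21 at a 13-control-country cutoff). The sweep's `min_group`
  floor of 5 does not protect against this; treat estimates at extreme
  percentiles with caution or raise `min_group`.
* **Multiplicity.** The sweep scans many correlated cutoffs without
  correction; under a null panel, some cutoff qualifies in roughly 10–30%
  of replicates depending on grid and overlap. The minimum qualifying
  cutoff is an onset order statistic and is biased toward lower values.
* **Resolution.** Threshold localization is limited to several score
  points at n = 191 (see the fixture discussion above).
* **Inference flavor.** Analytic influence-function standard errors are
  the default; the cluster bootstrap is provided but 100–200× slower.
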