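# Methods

## Model

Cumulative adoption of basic PHR functionality is modelled with the Bass
mixed-influence diffusion model.  A non-adopter at time *t* adopts with
hazard *p + q·F(t)/m*: *p* (external/innovation coefficient, per year)
captures adoption pressure independent of the installed base — marketing,
availability, policy; *q* (internal/imitation coefficient, per year)
captures social contagion proportional to the adopted fraction *F(t)*.
The closed form is

F(t) = m (1 − e^{−(p+q)t}) / (1 + (q/p) e^{−(p+q)t}),

with F(0) = 0 and F → m.  At q = 0 this reduces exactly to the exponential
m(1 − e^{−pt}); for q > p there is an interior inflection at
t* = ln(q/p)/(p+q) (S-curve regime), while q ≤ p gives immediate
deceleration (inverse-J).  Model time is **t = calendar year − start year**,
with adoption zero at the introduction year.  This convention reproduces the
reported per-year curve estimates for the 2001- and 2004-introduction
scenarios to ≤ 0.1 percentage points; the reported 2007-start column is only
consistent with t = year − start + 1 and is not used as an anchor.

Assumptions worth stating: a single homogeneous adopting population; a fixed
market potential m (default 1.0 — the entire weighted adult population can
adopt; the survey percentages are of that population); no repeat or
discontinued adoption; and a product whose definition does not change over
the fitting window.

## Data

The observed series is the weighted fraction of survey respondents answering
yes to *both* PHR items (online tracking of personal health information and
electronic communication with a provider) in each cross-sectional survey
year.  Tabulation is a weighted sum over the four joint response categories;
respondents missing either item are excluded by default (listwise deletion),
with `treat_as_no` available as the alternative policy.  Percentages are
kept at full precision internally and rounded to 2 dp only at report
boundaries.  Only point estimates are produced: the weights are used for
population scaling, not for design-based variance estimation.

## Estimation

(p, q) are estimated for a fixed start year by least squares on the
adoption-fraction scale, subject to the study's fitting band: every
|predicted − observed| ≤ 0.02 (2 percentage points, absolute — the relative
reading is ruled out because the reported residuals exceed 2% of the
observed values).  Default bounds are p ∈ [10⁻⁶, 0.5], q ∈ [0, 1], m fixed.

The optimizer is deterministic: a 25 × 21 grid over (log₁₀ p, q) (p gridded
log-uniformly because plausible values span decades), bounded
least-squares refinement (trust-region reflective, tolerances 10⁻¹⁰) from
the best 5 grid points, then a feasibility check against the band.  If the
SSE minimizer violates the band, an SLSQP solve with per-year band
constraints is attempted from each start; only if no feasible point exists
is the unconstrained minimizer returned flagged infeasible.  Two runs with
identical inputs give bit-identical results.  Reported diagnostics include
the per-year signed residuals (predicted − observed, percentage points),
their mean, the SSE, the q/p ratio, and the best grid objective (the
returned objective is never worse).

Degenerate series (non-increasing observed fractions) still return the
bounded minimizer, with a warning diagnostic, so sensitivity tables never
abort on one bad row.

### Sensitivity, stability, policy targets

- **Introduction-year sensitivity**: the same series is refitted under each
  candidate start year (2001/2004/2007 by default).  Later starts shift
  influence from internal to external (q falls, p rises, q/p falls).  Under
  the standard time convention no parameter pair within bounds keeps the
  2007-start fit inside the ±2 pp band (the first observation is only one
  model-year after introduction, forcing F(1) ≈ p below the band), so that
  row is reported infeasible with q collapsing to its bound.
- **Stability check**: the series is refitted with its most recent
  observation withheld and the two horizon forecasts compared.  With three
  observations this leaves a two-point refit that is *exactly identified*
  (two free parameters), so the reduced fit reproduces the remaining points
  with zero residual and can land on a substantially different curve: for
  the observed series with start 2004 the 2020 forecast moves from 51.7% to
  27.5% (a 24 pp swing; 18 pp for start 2001).  The check therefore reports
  a genuine fragility of two-parameter fits to three-point series; a small
  difference should *not* be expected from a least-squares refit, and the
  package reports the difference as computed rather than forcing stability.
- **Policy-target curve**: the same estimator applied to the meaningful-use
  milestones (5% by 2014, 10% by 2017; introduction 2004).  Being a
  two-point target set it is fitted exactly; its external coefficient is far
  below, and its q/p far above, the 2004 observed-data fit — the policy
  schedule encodes slower, more contagion-dependent diffusion than observed.

## Forecasting

Scenario trajectories are the continuous closed form evaluated at integer
calendar years (the discrete annual recursion ΔN = (p + qN/m)(m − N) is
provided only as a diagnostic; it requires p + q < 1 for monotone annual
steps and converges to the closed form as the step is refined).  Scenarios
are aligned on calendar years, with years before a scenario's introduction
counted as zero adoption; comparisons report per-year differences against a
reference scenario over the common year range.  Threshold years are the
first trajectory year at or above a target fraction; targets at or above m
are rejected as unreachable.

## Synthetic surveys

The generator emulates the structure of the real tabulations: for each
survey year it draws n respondents (default 10,000), assigns them to the
four joint categories with probabilities (F(t) from a true Bass curve,
comm-only rate, track-only rate, remainder), and gives them positive weights
that sum to a target population (default ramping 152M → 182M across the
default years 2008/2011/2013, matching the scale of the real weighted
totals).  Default marginal single-item rates are 0.10 per arm, inside the
8–13% band of the real tabulations; the default truth is the
2004-introduction estimate (p = 0.007, q = 0.214).  Weights are gamma-shaped
with unit mean and coefficient of variation 0.5 (dispersion configurable) —
enough to exercise weighted tabulation without modelling the real survey's
stratified design.

Noise modes: `none` allocates category counts by largest-remainder rounding
and rescales weights within categories so weighted fractions equal the
design probabilities exactly; `binomial` draws category counts multinomially
per year (noise attaches to the joint category, the analysis object, not to
items independently).  All randomness flows from a single seeded generator
consumed in fixed order (per year: weights, then counts), so datasets are
bit-reproducible; recovery experiments derive replicate seeds from the
design seed via a seed sequence.

What passing synthetic tests shows: the tabulation→fit→forecast machinery is
self-consistent and recovers known parameters at survey scale (mean
recovered q within 0.05 of truth over 100 replicates at n = 10,000/year).
What it does not show: robustness to the real survey's sampling frame, mode
effects, nonresponse adjustment, or item-wording drift across iterations.

## Numerical choices

- Coefficient anchoring: where reported rounded coefficients conflict with
  the reported q/p ratio, the ratio is authoritative (p = q ÷ ratio); the
  ratio carries more significant digits and reproduces the reported curve
  estimates, while the 3-dp p does not.
- q = p is classified inverse-J (strict inequality required for the S-curve
  regime).
- The threshold inverse t(F) is the closed form, exact to ~10⁻⁹ below
  saturation; it is ill-conditioned as F → m (dt/dF → ∞).
- Fitting tolerances: refinement tolerances 10⁻¹⁰; exactly identified
  two-point fits reach residuals ≈ 0 at machine precision.
- Monte-Carlo problem sizes: recovery experiments default to 3 survey years
  × 10,000 respondents × 100 replicates, matching the scale at which the
  recovery tolerances were calibrated.

## Limitations

- Three observations fitting two parameters leave essentially no residual
  degrees of freedom: the fit is a calibration, not a test, of the Bass
  model, and no standard errors are produced (none were reported in the
  original analysis either).
- Forecast levels at distant horizons are extremely sensitive to the assumed
  introduction year (2020 levels range from ~35% to ~59% across 2001–2007
  starts with the reported coefficients) and to the last observed point (see
  the stability check above).
- Market potential m is fixed, not estimated; with three points, jointly
  estimating (p, q, m) would be exactly identified and unstable.
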