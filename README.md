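# phrdiffusion

Bass diffusion modelling of personal health record (PHR) adoption among US
consumers, built for health-policy analysts and health-services researchers
who want to forecast consumer uptake of patient-facing health IT from sparse
cross-sectional survey data.

PHR use is measured by two items from the HINTS survey (Health Information
National Trends Survey, years 2008/2011/2013): tracking personal health
information online, and communicating with a doctor's office by
email/Internet.  Respondents answering *yes to both* define the adoption
fraction per survey year (weighted to the US adult population).  Adoption is
modelled with the Bass mixed-influence diffusion model: the hazard of
adoption at time *t* is *p + q·F(t)/m*, combining an external (innovation,
*p*) and an internal (imitation/word-of-mouth, *q*) force, with cumulative
adoption

    F(t) = m · (1 − e^{−(p+q)t}) / (1 + (q/p) · e^{−(p+q)t}),   F(0) = 0,

where *m* is the market potential (1.0 here) and *t* is years since the
technology's introduction.  When *q > p* the curve is S-shaped with an
inflection at *t\* = ln(q/p)/(p+q)*; the ratio *q/p* ("motivation
coefficient ratio") measures how word-of-mouth-dominated the diffusion is.

The package provides:

- **Weighted tabulation** of respondent-level two-item survey CSVs into
  joint-category counts/percentages and the adoption series
  (`phrdiffusion.survey`).
- **Constrained estimation** of (*p*, *q*) by deterministic multi-start
  bounded least squares, subject to the study's fitting band (every residual
  within ±2 percentage points), with introduction-year sensitivity analysis,
  a leave-last-year-out stability check, and fitting of the diffusion curve
  implied by meaningful-use (MU) policy milestones (`phrdiffusion.model`).
- **Forecasting**: annual scenario trajectories, threshold-crossing years,
  and scenario-vs-policy comparisons (`phrdiffusion.forecast`).
- **Synthetic surveys** whose true prevalence follows a configurable Bass
  curve, for end-to-end validation and parameter-recovery Monte Carlo
  (`phrdiffusion.simulate`).
- A **pipeline + CLI** (`phrdiffusion run --config ...`) and the published
  reference values in `phrdiffusion.datasets`.

## Worked example

```python
from phrdiffusion import AdoptionSeries, BassDiffusion

series = AdoptionSeries([2008, 2011, 2013], [0.0516, 0.0980, 0.1717])
result = BassDiffusion(series, start_year=2001).fit()
print(result.summary())
```

```
Bass diffusion model results
==============================================
Scenario:            start 2001
Start year:          2001
Observations:        3
Market potential m:  1
External p:          0.002383
Internal q:          0.260633
Ratio q/p:           109.390
SSE (fraction):      8.113e-05
Feasible (±2 pp): True
Mean difference:     -0.060 pp
----------------------------------------------
  year  observed %  fitted %  diff pp
  2008        5.16      4.58   -0.576
  2011        9.80     10.45   +0.646
  2013       17.17     16.92   -0.251
```

The fit says: with a 2001 introduction, external influence is tiny
(*p* ≈ 0.0024) and imitation dominates (*q/p* ≈ 109), the classic slow-start
S-curve; every fitted year is within the ±2 pp band of the observed survey
rates.  Sweeping the introduction year shows the expected trade-off — the
later the assumed start, the more the fit leans on external influence:

```python
from phrdiffusion import FitConfig, sensitivity_analysis

table = sensitivity_analysis(series, [2001, 2004, 2007], FitConfig(start_year=2001))
print(table.frame)
```

```
 start_year      p     q  q_over_p  objective  feasible
       2001 0.0024 0.261    109.39   0.000081      True
       2004 0.0071 0.214     30.04   0.000140      True
       2007 0.0301 0.000      0.00   0.000762     False
```

Projecting the 2001-start fit forward gives a 2020 adoption level of 57.1%
(`result.project(2020).value_at(2020)`), well above the MU policy milestones
(5% by 2014, 10% by 2017); fitting a Bass curve directly to those milestones
(`fit_policy_targets`) yields a lower *p* and a higher *q/p* than any
observed-data scenario — the policy targets describe slower diffusion than
the data imply.

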