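# admatch

Attributable deaths from short-term air-pollution exceedances, estimated by
propensity-score matching.

## The problem

Health impact assessments routinely ask how many deaths in a city over some
period are attributable to days on which an air-pollution summary exceeded a
regulatory threshold. The standard answer fits a Poisson regression of daily
deaths on exposure and confounders and integrates the fitted curve — which
ties the estimate to a parametric exposure-response model and, when impacts
are reported by cause or age, to several mutually inconsistent model fits.

`admatch` implements the alternative causal, design-based estimator for this
question. Each day *i* carries a lag 0–1 exposure *X*ᵢ (mean of current- and
previous-day PM₁₀), a treatment indicator *W*ᵢ = 1{*X*ᵢ ≥ 40 μg/m³}, and two
potential death counts *Y*ᵢ(1), *Y*ᵢ(0). The estimand is the sample total of
attributable deaths over treated days,

    AD = Σᵢ Wᵢ (Yᵢ(1) − Yᵢ(0)),

i.e. the deaths that would have been avoided had every high-exposure day been
a low-exposure day. *Y*ᵢ(0) is never observed on treated days; it is imputed
by **matching**: a logistic propensity model êᵢ = P(Wᵢ = 1 | Zᵢ) is fit on
background covariates only (season-specific day-of-week and holiday terms, an
influenza-epidemic indicator, a cubic regression spline on calendar time with
5 df per year, a tensor product of thin-plate spline bases in lag 0–3
temperature × relative humidity, heat and July–August indicators), each
treated day is paired with the control day of closest êᵢ (nearest neighbor,
with replacement), and

    ÂD = Σ_{Wᵢ=1} (Yᵢ_obs − Yᵢ_matched-control).

Because one match set drives every outcome, cause- and age-specific totals
add up exactly to the overall total. The variance follows the Abadie–Imbens
matching-estimator form: with control reuse counts *K*ᵢ,

    Var(ÂD) = Σᵢ (Wᵢ − (1 − Wᵢ)Kᵢ)² σ̂²ᵢ,

where σ̂²ᵢ is a same-group nearest-neighbor estimate of the day-level outcome
variance. Balance diagnostics (standardized differences, % bias, and the
Wheeler–Watson two-sample statistic for the circular covariate day-of-year)
check that matching actually removed the confounding.

The package also ships a synthetic-data generator that realizes **both**
potential outcomes per day (coupled Poisson arms via common random numbers),
so the true sample AD is known exactly and the whole pipeline can be
validated end to end.

## Worked example

```python
from admatch import AttributableDeathsEstimator
from admatch.simulate import generate_series, milan_like_config

series, truth = generate_series(milan_like_config(seed=1))  # 4 years of days
est = AttributableDeathsEstimator().fit(series)             # design phase
imp = est.estimate()                                        # analysis phase

print(f"treated days : {imp.n_treated}")
print(f"estimated AD : {imp.ad}   (true sample AD: {truth.true_ad})")
print(f"90% CI       : ({imp.ci[0]:.1f}, {imp.ci[1]:.1f})")
```

prints

```
treated days : 773
estimated AD : 761   (true sample AD: 1080)
90% CI       : (-126.8, 1648.8)
```

773 of the 1458 analysed days exceeded 40 μg/m³; matching estimates that 761
deaths over four years are attributable to those exceedances, a single-run
estimate whose 90% interval comfortably covers the exact simulated truth of
1080. The cause × age breakdown (`est.impact_table_`) sums exactly to 761 in
every margin, and the balance panel shows what matching bought:

```
  covariate  delta_pre  delta_post  pct_bias
 propensity      1.280       0.004    99.687
     temp03      1.040       0.004    99.658
   humidity      0.641       0.064    90.003
  influenza      0.324       0.028    91.308
warm_season      0.820       0.021    97.409
```

Pre-matching, treated (winter-peaked) days differ from controls by more than
one standard deviation in temperature; after matching the standardized
differences are near zero. `est.sensitivity()` re-estimates the total after
excluding influenza-epidemic treated days from the summation (here: 307
deaths over the remaining 706 treated days).

The same pipeline runs from the shell:

```bash
admatch all --seed 1 --out runs/demo     # simulate -> design -> match -> report
admatch impact --input series.csv --exclude-influenza --out impact.csv
```

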