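# dfareg

Scale-dependent bivariate regression built on detrended fluctuation
analysis (DFA) and detrended cross-correlation analysis (DCCA).

## The problem

A single regression coefficient compresses the dependence between two
environmental time series into one number, even when the coupling differs
between hours, days and months.  Hourly air-quality records of
neighbouring cities are a canonical example: fine-particulate (PM2.5)
concentrations are nonstationary, long-range dependent, seasonally
modulated — and a city may influence its neighbour strongly at synoptic
scales while showing little coupling at short scales, or the reverse.

`dfareg` estimates the bivariate linear model

    Y = β₀ + β₁ X₁ + β₂ X₂ + ε

*per time scale*.  The OLS closed form writes β̂₁, β̂₂ entirely in terms of
variances and covariances of the three series; replacing these with
DFA/DCCA scale-dependent fluctuation functions F²(n) — variances and
covariances of polynomially detrended profile segments of window length
n — yields coefficient curves

    β̂₁(n) = [F²_{X₁Y}(n)·F²_{X₂}(n) − F²_{X₂Y}(n)·F²_{X₁X₂}(n)] / [F²_{X₁}(n)·F²_{X₂}(n) − F²_{X₁X₂}(n)²]

(and symmetrically for β̂₂(n)), one bivariate regression per scale.  Per
scale the package also provides coefficient variances (via the DFA
fluctuation of the scale-dependent residuals with the N−3 divisor), a
determination coefficient R²(n), a standardized coefficient β*(n), an
elasticity η(n), DCCA and partial-DCCA correlation coefficients, and
surrogate-shuffle significance machinery (per-scale Monte-Carlo critical
values t^c(n) and ρ^c(n)), plus the simulators used to validate all of
it: ARFIMA(0, d, 0) long-memory noise and binomial multifractal cascades.

It is written for researchers in environmental epidemiology, air-quality
monitoring and econophysics who work with nonstationary coupled series.

## Worked example

```python
import numpy as np
from dfareg import ArfimaSpec, DFARegression, gen_arfima

x1 = gen_arfima(ArfimaSpec(d=0.3, length=10_000, seed=11))
x2 = gen_arfima(ArfimaSpec(d=0.3, length=10_000, seed=12))
eps = np.random.default_rng(13).standard_normal(10_000)
y = 1.0 + x1 + 2.0 * x2 + eps

model = DFARegression(y, x1, x2)
res = model.fit()            # default: 30 log-spaced scales in [10, 1000]
print(res.summary().iloc[[0, 10, 29]].round(4).to_string(index=False))
b1, b2 = res.average_over_scales()
print(f"scale-averaged: beta1={b1:.4f}  beta2={b2:.4f}")
ols = res.ols_baseline()
print(f"OLS baseline:   beta1={ols.beta1:.4f}  beta2={ols.beta2:.4f}  R2={ols.r_squared:.4f}")
```

prints

```
 scale  beta1  beta2   var1   var2  r_squared  beta_star1  beta_star2    eta1   eta2  usable
    10 1.0078 2.0116 0.0001 0.0001     0.8261      0.4060      0.8081 -0.0720 0.2982    True
    49 0.9298 2.0124 0.0001 0.0000     0.9100      0.3869      0.8700 -0.0664 0.2984    True
  1000 1.0312 2.0358 0.0000 0.0000     0.9810      0.3629      0.9320 -0.0736 0.3018    True
scale-averaged: beta1=0.9932  beta2=1.9987
OLS baseline:   beta1=0.9940  beta2=2.0093  R2=0.8699
```

The coefficient curves recover the true (1, 2) at every scale; R²(n)
grows with scale because detrending at larger windows retains more of
the shared long-memory signal relative to the white error term.  The
elasticities are small here because the simulated series have near-zero
means — on concentration data (strictly positive) they measure relative
sensitivity.

A command-line interface mirrors the library:

```sh
dfareg simulate pm25-fixture --length 20000 --seed 1 --out pm25.csv
dfareg fit --input pm25.csv --y site1 --x1 site2 --x2 site3 --out run
dfareg pdcca --input pm25.csv --cols site1,site2,site3 --pair site1,site2 --out rho.csv
dfareg test-t --input pm25.csv --y site1 --x1 site2 --x2 site3 \
       --alpha 0.01 --shuffles 1000 --seed 7 --out ttest.csv
dfareg split-seasons --input data.csv --timestamp-column time --out seasonal
```

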