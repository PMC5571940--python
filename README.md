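# beetlekern

Dispersal-kernel estimation of pollen beetle (*Brassicogethes aeneus*)
colonization of winter oilseed rape (OSR) fields from woodland
overwintering sources.

Pollen beetles overwinter in woodlands and migrate into OSR in early
spring; fields near woods are attacked harder and earlier.  Given
per-point beetle counts (number per ten plants, several weekly dates)
and a woodland map, this package estimates *how far* the beetles
disperse and *which* dispersal hypotheses the data support.  It is
aimed at landscape ecologists and IPM modellers working with count
surveys around semi-natural habitat.

## The model

Counts are negative binomial, `y ~ NB(mu, theta)`, with

```
mu(t, i) = gamma_g * sum_w gamma_d(d_iw, delta(t)) * A_w
gamma_d(d, delta) = exp(-(d/delta)^n) / (K * pi * delta^2)
delta(t) = beta_d + beta_dt * (t - 1)
```

where the sum runs over 100 m woodland source pixels w (area `A_w`,
optionally only the 100 m peripheral band) within 5 km of point *i*,
`gamma_d` is a gaussian (K=1, n=2) or exponential (K=2, n=1) 2-D
kernel, and `gamma_g = exp(coef)` is a categorical size factor
(date/field/site designs).  The mean dispersal distance is
`D_mean = 2*delta` (exponential) or `sqrt(pi)/2 * delta` (gaussian).
Models are fitted by adaptive Metropolis MCMC (Geweke and
Raftery–Lewis stopping), compared by AIC across a factorial modality
grid (size factor x origin x split/merged/none point structure x
kernel x site-dependent dispersal), and benchmarked against the
conventional buffer GLM `log mu = beta_G + log A_BW` with the buffer
radius scanned from 0.2 to 5 km.  See `docs/methods.md` for details.

## Worked example

Simulate a study under the default conditions (4 sites of 4 x 6 km
with 14–33% woodland cover, 24 fields x 5 points x 4 weekly dates,
gaussian kernel with `beta_d = 1.35` km, `theta = 1`) and refit it:

```python
import beetlekern as bk
from beetlekern.synthetic import StudyDesign, baseline_truth, simulate_study

study = simulate_study(StudyDesign(), baseline_truth(), seed=1)
print("total count:", bk.total_count(study.table))

spec = bk.ModelSpec("date", origin="area", point_structure="split",
                    kernel="gaussian")
fit = bk.fit_model(study.table, study.raster, spec, seed=2,
                   block_size=5000, max_blocks=4)
print(fit.estimates.round(3))
print("AIC:", round(fit.aic, 1))
print("mean dispersal distance (km):", round(fit.mean_dmean(), 2))

scan = bk.scan_buffer_radius(study.table, study.raster)
print("best buffer radius (km):", scan.best_radius_km)
```

Output:

```
total count: 2214
              value     lo     hi
parameter
beta_d        1.288  1.076  1.612
beta_dt       0.035 -0.106  0.150
coef[date=1]  2.423  2.144  2.722
coef[date=2]  1.623  1.303  1.940
coef[date=3]  4.470  4.251  4.706
coef[date=4]  3.628  3.407  3.882
log_theta    -0.127 -0.323  0.072
AIC: 1940.2
mean dispersal distance (km): 1.19
best buffer radius (km): 2.2
```

`beta_d` is the kernel distance scale (km) at the first date and
`beta_dt` its weekly change; here the 95% interval for `beta_d` covers
the generating value 1.35 and the implied mean dispersal distance is
1.19 km.  The date coefficients (log scale) track the simulated
abundance wave — the dip on the rainy second week, the peak at
flowering — and `log_theta ~ 0` recovers `theta = 1`.  The buffer
baseline prefers a disk radius of ~2 km, the same spatial reach seen
through a cruder lens.

A command-line interface mirrors these steps
(`beetlekern simulate | fit-all | buffer-scan | summarize`); run
`beetlekern --help`.

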