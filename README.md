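# dispersalkit

Analysis toolkit for **mark-release-recapture (MRR) dispersal studies of
bark beetles**, built around the experiment design used for the
golden-haired pine bark beetle *Hylurgus ligniperda*: marked beetles are
released at the centre of a grid of kairomone-baited panel traps arranged
in concentric rings (40–960 m), and the decline of per-trap recaptures
with distance is used to infer the population's dispersal kernel.

It is aimed at forest entomologists and biosecurity modellers who need
quantitative dispersal estimates (what fraction of a source population
travels beyond 1 km?) from sparse trap-recapture data with ~1 % recapture
rates.

## What it computes

**Mechanistic trap-catch models.** The expected per-trap recapture
percentage at distance *r* is modelled by time-integrated diffusion with
constant disappearance:

* simple diffusion  P(r) = A′ r^(−1/2) e^(−r/B)
* heterogeneous diffusion  P(r) = A1′ r^(−1/2) e^(−r/B1) + A2′ r^(−1/2) e^(−r/B2)
  (short- and long-distance disperser subpopulations, B1 < B2)
* mixed diffusion + equal redistribution  P(r) = A′ r^(−1/2) e^(−r/B) + C′
  (flat-tail null model)

fitted by Gaussian maximum likelihood with optional exponential or power
variance functions of the fitted mean, compared by AIC, Akaike weights
and likelihood-ratio tests, with delta-method prediction bands.

**Dispersal kernel.** For the heterogeneous model the cumulative fraction
settling within r_max is closed-form via incomplete gamma functions,

x(r_max) = Σ_k A_k′ B_k^{3/2} γ(3/2, r_max/B_k) / Σ_k A_k′ B_k^{3/2} Γ(3/2),

with quantile inversion and jackknife (leave-one-observation-out) 95 %
confidence bands.

**Density–distance GLM.** Poisson log-link regression of ring-summed
recapture counts on log distance × sex with a log trap-count offset, AIC
model selection, back-transformed prediction bands.

**Directionality.** Net displacements projected on the E–W and N–S axes,
capture-count-weighted pooling across releases, within-release bootstrap
SEs, weighted one-sample t tests, and drift expressed relative to the RMS
dispersal scale.

**Auxiliary tests.** Yates-corrected χ² for 2×2 tables, exact two-sided
binomial sex-ratio tests, Benjamini–Hochberg FDR screen.

**Simulator.** A spatial MRR simulator (gamma(3/2, B) settling kernels,
mixtures, optional drift, nearest-trap capture) generating datasets in the
same CSV schemas the analysis reads, so every stage is testable without
field data.

The packaged fixtures include the study's release/recapture summary
table, its fitted diffusion parameters, and both trap-grid designs (170
and 200 traps).

## Worked example

```python
import numpy as np
import dispersalkit as dk
from dispersalkit.diffusion import eval_model

# dispersal kernel from the packaged best-model parameters
tab = dk.load_fixture("table3_diffusion_params")
best = tab[(tab.model == "heterogeneous") & (tab.variance == "power")]
params = dk.DiffusionParams(kind="heterogeneous", **dict(zip(best.param, best.estimate)))
for r in (100, 1000, 5000):
    print(f"fraction dispersing beyond {r:>5} m: {100*(1-dk.kernel_cdf(params, r)):5.1f} %")
print(f"median dispersal distance: {dk.quantile_distance(params, 0.5)/1000:.2f} km")

# refit the heterogeneous model to noisy replicate data
rng = np.random.default_rng(1)
r_all = np.tile([40., 80., 160., 320., 640., 960.], 6)
y = np.abs(eval_model(params, r_all) * (1 + 0.05 * rng.standard_normal(r_all.size)))
model = dk.DiffusionTrapCatchModel(r_all, y, kind="heterogeneous", variance="power")
print(model.fit().summary())
```

prints

```
fraction dispersing beyond   100 m:  79.0 %
fraction dispersing beyond  1000 m:  46.7 %
fraction dispersing beyond  5000 m:   1.6 %
median dispersal distance: 0.90 km

Diffusion trap-catch model: heterogeneous / variance power
n obs = 36, k = 6, loglik = 268.8103, AIC = -525.62
         param     estimate          se      ci_low     ci_high
      A1_prime       3.1841      0.2224       2.748        3.62
            B1       21.449      0.5021       20.46       22.43
      A2_prime     0.040071   0.0005919     0.03891     0.04123
            B2         1048       23.44        1002        1094
 variance_coef       1.2085     0.07096       1.069       1.348
         sigma      0.12343     0.05139     0.02271      0.2242
max |score| at optimum = 2.84e-08
```

Nearly half the flight-experienced population disperses beyond 1 km: the
short-distance component (B1 ≈ 21 m) describes beetles settling within
tens of meters, while the long-distance component (B2 ≈ 1 km) carries
80 % of the settling mass. Refitting to six simulated replicate releases
with 5 % noise recovers both spatial scales.

A full pipeline run (simulate → GLM → diffusion → kernel →
directionality → stats) is driven by a YAML config:

```sh
dispersalkit run --config examples/simulate.yaml --seed 7 --out out/
dispersalkit stats --chi2 75 73 68 17 --binom 12 14
```

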