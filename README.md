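# predselect

Infer whether a squid predator eats juvenile fish **at random**, prefers
**smaller fish** (size selection), or prefers **slower-growing fish**
(growth selection), from the age–length data that otoliths record.

Sagittal otoliths survive digestion, so the fish found in a predator's
stomach can be aged (daily increments; the first forms at 2 days post-hatch,
hence age = increment count + 2) and their standard length (SL) at capture
and at every earlier age reconstructed by the biological-intercept method.
Comparing these "consumed" fish with "netted" fish caught alongside the
predator reveals which phenotypes predation removes — the question at the
heart of growth-selective survival in fish early life history. The package
also computes the predator's feeding-habit metrics (digestion-state
inversion to time at predation, occurrence rate, predator–prey mass ratio
PPMR) and screens sites for prey-head rejection, a squid behaviour that can
masquerade as size selection.

## The model

The original population (before nets and predation) has a linear mean
age–SL law with Gaussian scatter and an empirical age distribution f₀:

    SL | age = a  ~  Normal(β₀ + β₁·a, σ²)

It is inferred from the netted sample by weighted least squares with
weights 1/r(SL), where r is the logistic net-retention curve, so that
length classes the mesh loses count more. Predation then reweights the
population density with a selection weight w:

    f_c(a, l) = f₀(a) · φ(l; β₀ + β₁a, σ) · w(a, l) / Z

with w ≡ 1 (random predation), a decreasing logistic in l (size selection,
2 parameters: half-point and width), or the same logistic in the residual
l − (β₀ + β₁a) (growth selection). Each model is fitted to the consumed
sample by maximum likelihood with the population parameters plugged in, so
AIC = 2k − 2 lnL with k = 0 or 2, and each selective model is tested
against random predation with a parametric bootstrap likelihood-ratio test
(resamples drawn from f₀·φ, alternative refitted, p = (1+#{LR_b ≥ LR_obs})/(B+1)).

Before fitting, sites are screened for head rejection: prey above the SL
at which predator/prey mass < 13.2 are "unpalatable"; if they form α_n %
of the netted sample, rejection (60–100 % probable per encounter) would
leave at most U(α_n) = 0.4·α_n·100/(100 − 0.6·α_n) % of them in stomachs,
and a site whose consumed share falls below that bound (with α_n > 5 %) is
excluded. After fitting, hatch cohorts are assigned by Ward clustering on
(age, SL) and back-calculated growth trajectories are compared between
consumed and netted fish at 5-day ages with a MANOVA (Wilks' Λ) plus
per-age F tests.

A synthetic-data module generates populations, net catches, consumed
samples, otoliths and squid records with known ground truth, so the whole
chain is testable end to end.

## Worked example

```bash
predselect simulate --seed 7 --out demo/data
predselect report --data demo/data --out demo/out --boot 500 --seed 7
```

The default simulation is one site whose squid prefer slow growers
(selection half-point at residual −2 mm, width 2 mm). The report prints:

```
# rejection screen
 site  year  threshold_sl  alpha_n  alpha_c  expected_upper  flagged
St.01  2008          73.0      0.0      0.0             0.0    False
# selectivity fits
          scope  n_consumed selected  lnL_random  aic_random  lnL_size  aic_size   p_size  lnL_growth  aic_growth  p_growth stars_growth
site:St.01:2008          12   growth    -108.855     217.709  -108.072   220.143 0.449102    -102.469     208.937  0.001996           **
```

Reading it: no fish exceeded the head-rejection threshold (73 mm), so the
site is clean. Among the three predation models the growth-selective one
has the lowest AIC (208.9 vs 217.7 random, 220.1 size) and its bootstrap
likelihood-ratio test against random predation gives p ≈ 0.002 (**) — the
simulated growth selection is recovered from only 12 consumed fish. The
run also writes `events.csv` (per-squid digestion ratio, digestion
duration, clock time at predation, PPMR range), `screen.csv`, `fits.csv`,
`trajectories.csv` and a `run_log.yaml` recording every setting and seed.

The same stages are available as `predselect validate / screen / feeding /
fit / cohorts`, and as plain functions (`predselect.selectivity.compare_models`,
`predselect.rejection.screen_site`, ...) for scripted use.

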