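# Methods

## Scope

`predselect` implements an inference chain for detecting size- versus
growth-selective predation on juvenile fish from otolith-reconstructed
age–length (age–SL) data, together with the predator's feeding-habit
metrics and a prey-head-rejection screen. Every stage runs on synthetic
data with known ground truth generated by `predselect.synthdata`.

## Reconstruction from otoliths

Ages come from daily increment counts plus 2, because the first increment
is deposited at 2 days post-hatch (dph) when the larva is about 3 mm long;
that (age 2, 3 mm, hatch radius) point is also the biological intercept.
For each fish the otolith-radius→SL relation is taken as linear between
the hatch anchor and the capture point, so SL at any interior age is

    SL(a) = SL_h + (OR(a) − OR_h) · (SL_cap − SL_h) / (OR_cap − OR_h),

with OR(a) the cumulative increment radius. The series therefore ends at
the measured capture SL exactly — an identity the tests assert for every
record. When only a radius and a count are available, equal widths are
assumed (a data-quality note, logged by the reader).

Netted fish have measured SL; consumed fish do not, so their capture SL is
first reconstructed through the linear OR–SL calibration SL = c0 + c1·OR
and mass through the allometry W = p·SL^q. Calibration constants are
config inputs (or fitted from a reference table by OLS / log–log OLS);
the package defaults — hatch radius 10 µm, 2.5 µm of radius per mm of SL,
p = 1e-5 g/mm³, q = 3 — describe a generic juvenile carangid and are the
same constants the synthetic generator uses, so round-trips are exact on
noise-free data.

Otoliths recovered from a stomach are paired left/right per fish with the
rule that two otoliths within 2 mm of reconstructed SL may be one
individual; among feasible left–right matchings the total |ΔSL| is
minimised by optimal assignment, which makes the grouping deterministic
and order-independent. The left otolith supplies the individual's SL.

## Feeding habits

The digestion ratio DR (stomach wet weight as % of total reconstructed
prey weight, computed only for single-species stomachs) is inverted
through a linear gastric-evacuation model, by default DR = −0.176·t +
59.462 at 17 °C (coefficients borrowed from a congeneric squid; fully
configurable per temperature). DR above the intercept means prey fresher
than the line resolves: duration 0 with a `fresh_prey` flag. An
alternative `fraction_digested` convention (value = 100 − DR) is exposed
because reported digestion percentages are sometimes on that scale. Time
at predation is capture time minus duration, wrapping across midnight.
PPMR is predator wet weight over per-prey reconstructed weight; it is
regressed (and prey weight with it) on lunar illumination and mantle
length by OLS, PPMR on the log10 scale because it spans two orders of
magnitude.

## Head-rejection screen

Prey whose SL exceeds the site threshold (mean over squid of the SL whose
mass is predator-mass/13.2) are unpalatable. With a netted unpalatable
share α_n % and per-encounter rejection probability between 0.6 and 1,
random predation would leave between 0 and

    U(α_n) = 0.4 · α_n · 100 / (100 − 0.6·α_n)   %

unpalatable prey in stomachs. A site is flagged when α_n > 5 % and the
consumed share α_c < U(α_n); flagged sites are excluded from selectivity
fitting (rejection there is confoundable with size selection). α uses the
strict comparison SL > threshold.

## Selectivity framework

Population: SL|age normal around a linear law; age distribution f₀ is the
retention-weighted histogram of netted ages on an integer grid padded ±2
days with a small floor (1 % of mass spread over the grid) so consumed
ages just outside the netted range keep finite density — no parametric age
model, because observed age structures are multimodal. The line and σ come
from WLS with weights 1/retention(SL). Those weights correct sampling
bias, not residual variance, so model-based WLS standard errors are
miscalibrated; where the tests need an SE yardstick they use the HC3
sandwich.

Selection weights are 2-parameter decreasing logistics in SL (size) or in
the age-standardised residual (growth); random predation has no free
parameters. This gives the 0/2 parameter-count bookkeeping behind
AIC = 2k − 2 lnL. Population parameters are plug-in, never re-estimated
jointly with selection.

Normalisation uses 200-node Gauss–Legendre quadrature over mean ± 8σ of
SL; for growth selection the weight depends only on the residual, so the
per-age integrals collapse to one. Machine-precision agreement with dense
Simpson integration is verified in the tests (the acceptance bound is
1e-6). Likelihood arithmetic is in the log domain; a theta whose weight
vanishes everywhere evaluates to −∞ rather than NaN. Optimisation is
Nelder-Mead over (half-point, log width) from five data-quantile starts,
with the width floored at 0.05 mm so the quadrature stays resolvable.

**Identifiability.** The (half-point, width) pair sits on a likelihood
ridge: on a Gaussian residual a shifted sharp logistic and a centred wide
one produce nearly the same consumed distribution. Induced functionals
(e.g. the mean residual of consumed fish) are well identified and are what
the parameter-recovery test checks; raw theta values should not be
over-interpreted.

**Bootstrap LRT.** B parametric resamples (default 2000) of the observed
size are drawn from the null density f₀·φ, the alternative refitted on
each, and p = (1 + #{LR_b ≥ LR_obs})/(B + 1), which cannot be zero.
Resample refits start from the argmax of a precomputed theta grid (the
normaliser over the grid depends only on the population, so it is computed
once) followed by a short Nelder-Mead polish at loose tolerance — the LR
only enters through its rank. Fixed seed gives a reproducible p.

**Calibration and its limits.** With consumed data drawn from the null
density the test actually tests, the measured rejection rate at α = 0.05
is ~3.5 % (200 runs, B = 500, n = 50). When the full chain is simulated —
true population → netted sample of ~60 → plug-in population fit → test —
the rate rises to ~11 %: the observed residuals carry the line-estimation
error that null resamples generated from the fitted line lack. This
anti-conservatism at survey-like netted sample sizes is inherent to the
plug-in design and should be kept in mind when reading borderline p
values; propagating population uncertainty into the bootstrap is out of
scope here.

**Model selection.** The minimum-AIC model is reported (ties break toward
fewer parameters, then model name). Under the null the AIC penalty of 4
still lets one of the two correlated alternatives win roughly a quarter of
the time, so "random selected" is the modal but not a ≥85 % outcome; the
bootstrap p values, not AIC alone, carry the evidential weight. Under
strong growth selection (half −2 mm, width 2 mm, n = 100) the growth model
wins with p < 0.05 in ~99 % of runs. Pooling size-selected cohorts with
different age ranges shifts the pooled consumed regression parallel-down
and makes the growth model win in about a third of runs (versus ~none
unpooled): size and growth selection are distinguishable only locally.

## Cohorts and trajectories

Hatch cohorts are Ward-linkage clusters on standardised (age, SL), with k
per year supplied by config (multimodality is judged by eye or
silhouette); labels are ordered young→old. Growth trajectories
(back-calculated SL at 5-day ages) are compared between consumed and
netted fish over the common age window with a one-way MANOVA using Wilks'
Λ (the repeated-measures structure enters through the multivariate
response; no sphericity correction is applied), followed by per-age F
tests. A single-column window degenerates to one-way ANOVA (F = t²). When
the window holds more ages than residual degrees of freedom allow it is
coarsened from the youngest end, with a warning.

## Synthetic data: what it emulates and what it does not

The generator draws ages uniformly (optionally from Gaussian cohort
mixtures), SL from the linear-Gaussian law, weight from the allometry,
net retention as an increasing logistic (default l50 = 25 mm, width 3 mm,
i.e. mild bias at the default population), selection weights as above, and
otolith radii linear in SL with equal increment widths and optional
Gaussian measurement noise. Default population: 10,000 fish (3,000 in the
simulation-heavy tests), ages 25–60 d, β₀ = 1.2 mm, β₁ = 0.9 mm/d,
σ = 3 mm — a juvenile fish reaching ~20–55 mm, consistent with the hatch
anchor at (2 d, 3 mm). Residuals are homoscedastic by default
(heteroscedastic growth is not modelled); increments carry no daily
growth signal beyond the linear trend; there is no temperature dependence,
movement, or multi-species prey field. Passing tests therefore establish
the correctness and operating characteristics of the *procedure* under
its own assumptions, not the realism of any particular field estimate.

## Test problem sizes

Simulation-based checks use populations of 3,000, netted samples of 40–60,
consumed samples of 20–100, 100–200 replicates, and B = 199–500 bootstrap
iterations; these sizes mirror the survey scale (tens of fish per site)
while keeping the full suite to a few minutes. The default B for analysis
runs remains 2,000.
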