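# Methods

This note documents the models implemented in `reeftrack`, the assumptions
behind them, the defaults that matter, and what the synthetic-data
generator does and does not emulate.

## The data-generating setting

A high-density acoustic positioning study: tagged reef fish carry coded
transmitters firing at Uniform(60 s, 180 s) intervals (mean 120 s); a grid
of moored receivers (550–600 m spacing) logs each transmission it hears;
a hyperbolic positioning solver turns transmissions heard on ≥ 3 receivers
into planar positions with a unitless error-sensitivity score (HPE). The
package takes detections, positions, receiver metadata, a daily
environmental series, habitat polygons and auxiliary relocations
(recaptures, mobile-glider detections) and estimates fate, site fidelity,
space use and dispersal per fish.

All within-study geometry is planar, in meters, in one projected frame;
only long-range relocations (recaptures up to hundreds of km away) are
handled geodesically, via the haversine formula on a spherical Earth of
radius 6,371 km — the planar error is negligible below ~20 km and the
geodesic handling only matters for the dispersal tail. Daily metrics use
UTC calendar dates throughout.

## Position-error filtering

Known-location tags give per-detection horizontal errors (Δx, Δy). After
censoring the upper 5% of HPE values (outlier control), errors are binned
by floor(HPE) with increment 1 and each bin summarized as

    2DRMS_i = 2 sqrt( (1/n_i) Σ_j (Δx_ij² + Δy_ij²) ).

Bins with fewer than 3 observations are merged upward into the next bin
(variance control; a lone bin is kept). Per-bin 2DRMS is regressed on mean
HPE by OLS. When calibration tags exist in several array regions, a
one-line model and a line-per-region model are compared by small-sample
AICc **on the same per-region bin table**; the winner defines the filter.
Fish positions whose predicted 2DRMS exceeds the accuracy threshold
(default 20 m) are censored. For isotropic Gaussian error of SD a·HPE the
expected slope is 2√2·a and the intercept 0, which is how the calibration
tests validate slope recovery.

## Detection range

p(d) = p₀ / (1 + exp(κ(d − d₅₀))), fitted by maximum likelihood on
Bernoulli (distance, detected) trials with parameters optimized on
(logit p₀, log d₅₀, log κ). d₅₀ is the 50% detection range by
construction (p(d₅₀) = p₀/2). Complete separation (all successes or all
failures) raises an error recommending a wider distance span. The logistic
is the standard range-test model; only the 50% and maximum ranges are
identifiable constraints in the emulated study, and the generator's
default curve (d₅₀ = 346 m for fish-spec tags, 700 m for sync tags,
κ = 0.005 m⁻¹ giving a maximum range near 1.7 km) reflects them.

## Centers of activity

Detections in complete isolation (no other detection of the same tag
within ± 60 min) are removed as spurious. Each (tag, bin) center of
activity is the unweighted mean of the **distinct** detecting receivers'
coordinates (30-min bins for fate/fidelity work, 4-h bins for
long-distance movement and dispersal, where coarser bins bridge coverage
gaps). Bins heard on fewer than 3 receivers are dropped, except on the
tag's final detection date, where bins with ≥ 1 receiver are retained
(departing fish move fast and thin out their detections); retained
final-date COAs carry their receiver count so downstream users can see
the relaxation. The residence index is detection days over the inclusive
first-to-last-day span, so continuous presence scores exactly 1.

## Fate assignment

Rules fire in priority order, hard evidence first: recapture inside the
array ⇒ captured; a ≥ 7-day run of days with depth SD < 0.25 m (and ≥ 3
depth values per day) ⇒ mortality, unless a predation signature
immediately precedes it; a sustained (≥ 1 h) run outside the resident
envelope — COA displacement rate > 0.75 m/s and/or bin-to-bin mean-depth
jumps > 5 m — followed within two days by the tag going stationary or
leaving the array ⇒ predated; emigration by any of (1) movement toward
the array edge (final location within one receiver spacing of the hull
boundary, with a large final outward displacement) then silence,
(2) confirmation by recapture or live glider detection outside the array,
(3) a group exit within 48 h of a confirmed emigrant; detections to study
end ⇒ survived; an abrupt stop in the array interior ⇒ captured; anything
else ⇒ unknown. Fish never detected at all (when a tag roster is given)
are recorded as unknown. Events within the 3-day capture-tagging-release
recovery window are CTR-flagged and excluded from event histories.

The speed floor alone cannot separate predators from fast resident moves
(confirmed live fish match predator speeds), which is why the detector
requires a stationary-or-exit sequel and accepts a water-column-use
signature in place of speed. The 5 m depth-excursion default and the
2-day sequel window are heuristics matched to the simulator's predation
behavior; both are exposed in `FateRuleConfig`.

## Site fidelity

Event histories start on day 0 (tagging); emigration is the event; all
other fates censor at their date; fish with a CTR event or more than one
daily detection gap (gap count, not length) are excluded. Unknown fates
are analyzed both ways — censored, and recoded as emigrations — because
the truth is a mixture; more events can only lower the curve, which the
tests assert as an invariant.

The product-limit estimator uses Greenwood's variance and log(−log)
confidence intervals; quantiles are first crossings and report NaN when
the curve never reaches the level. The parametric model is an
intercept-only right-censored Weibull fitted by Nelder–Mead on
(log k, log λ) with CIs by the delta method on the log cumulative hazard;
residence quantiles are t_q = λ(−ln q)^{1/k}. Both are cross-checked
against lifelines in the tests (agreement to ≈ machine precision), and
against each other in the exponential (k → 1) limit.

Low-pressure days are those whose daily median atmospheric pressure falls
strictly below the 0.5th percentile of all daily medians. The
daily-emigration GLM is E_i ~ Binom(n_i, p_i), logit(p_i) = β₀ + β₁·low_i,
fitted by iteratively reweighted least squares written in-package
(statsmodels only verifies it in tests); candidate single covariates
(pressure class, temperature, tilt) are ranked by AIC. Marginal
probabilities use the delta method on the logit scale; the low:regular
ratio CI uses the delta method on log(p_l) − log(p_r). Expected fidelity
over t days containing D_L low-pressure days is
S(t) = (1 − p_r)^(t−D_L) (1 − p_l)^(D_L).

## Space use

Between consecutive filtered positions no more than 60 min apart, the
Brownian-bridge kernel places the animal at time fraction α at
N((1−α)z₀ + αz₁, α(1−α)Tσ_m² + ((1−α)² + α²)δ²), with δ the accepted
position-error threshold (20 m) and σ_m² the Brownian motion variance,
estimated per fish by leave-one-out likelihood on position triplets. The
bridge is integrated over α by 10-point midpoint quadrature (50-point in
the oracle tests; the difference is below 1%), each pair weighted by its
time span, on a 10 × 10 m grid with origins snapped to cell multiples so
daily grids align. Note the endpoint-error term interpolates as
((1−α)² + α²) — the standard kernel — so two coincident positions with
σ_m → 0 give a scale *mixture* of Gaussians (mean variance 2δ²/3), not a
single δ-Gaussian; the tests use the mixture closed form, and validate
the χ²₂ isopleth areas (area_p = −2 ln(1−p) π σ²) on an exactly Gaussian
density where they hold.

The tracking-duration UD is the equal-weight average of daily densities
on the union grid ("weighted average of the daily UDs" read as averaging
density surfaces — each daily UD already carries its internal Δt weights;
averaging the *areas* instead is available as a diagnostic by contouring
the daily UDs individually). Fish qualify with ≥ 33 estimable UD-days and
a mean of ≥ 18 daily positions; others are excluded with a reason code.
Isopleths are the smallest cell sets holding the stated mass (a 10⁻⁹
tolerance guards exact-tie cumulative sums); areas are cell counts ×
100 m², bit-exact on the grid. Centroids are 8-connected components of
the 90% isopleth with area ≥ 100 m²; a space-use shift is a centroid
whose first active day strictly follows the last active day of every
previously used centroid, so alternating use never counts as a shift.

Movement rates are per-step distance over time; the corrected rate
subtracts twice the position-error threshold from the distance (floored
at zero) — the worst-case error correction used to vouch for rates above
the 0.75 m/s literature maximum. Long-distance movements are pairs of
locations > 2,000 m apart within a rolling 48 h window; qualifying pairs
sharing a location merge into one event (union-find), so a single
traverse is counted once.

## Dispersal

Per fish with ≥ 100 days from first to last location: the maximum
pairwise distance among 4-h COAs, recaptures and glider relocations
(convex-hull diameter for speed; haversine when geographic coordinates
are present). Emigrated/unknown fish never relocated outside the array
are right-censored at their within-array maximum. Kernels are fitted by
maximizing Σ_uncensored log f(x) + Σ_censored log S(x) over log
parameters (Nelder–Mead, multi-start for Burr's c–k ridge); Burr XII
(S(x) = (1 + (x/s)ᶜ)⁻ᵏ) is implemented explicitly (verified against
scipy's burr12 to 1e-12) and the other families use scipy distributions.
AIC = 2k − 2ℓ ranks the candidates; exceedance probabilities are the
fitted survival function at 2, 10 and 200 km. Burr's c and k trade off
along a likelihood ridge, so at realistic sample sizes the tail
probabilities are much better identified than k itself; the tests
therefore bound c tightly, k loosely, and the tail functional tightly.

## The synthetic-data generator

`SimConfig` defaults are the emulated study's conditions: 85 fish, a
942-day study window, 8 × 8 receivers at 550 m, interpulse delay
Uniform(60, 180) s, fish-tag d₅₀ = 346 m, daily emigration hazard
4 × 10⁻⁴ multiplied by 175 on low-pressure days, low-pressure frequency
0.5% (regular ~1018 mbar, low ~1004 mbar), mortality/capture/predation
hazards of order 2–3 × 10⁻⁴ per day (annual fate fractions near the
emulated cohort's), depths bounded in [0, 38] m, HPE ~ Gamma(2, 1.7) with
true error SD = 1.2·HPE — which puts ~86% of positions under the 20 m
threshold and the median reference-tag error near 4 m. Movement is an
Ornstein–Uhlenbeck walk (stationary SD 30 m, relaxation time 1 h, 10-min
steps) around habitat-biased centroids that shift with probability
0.004/day; emigrants run off-array at 0.3 m/s toward a Burr-distributed
destination (c = 1.2, k = 0.9, s = 1 km, giving S(2 km) ≈ 0.34); dead
tags transmit in place with depth SD ≈ 0.03 m; predators cruise the array
at 1.5 m/s with full-water-column depth excursions for 4 h before
leaving; captures stop transmitting instantly. Captured fish always
produce an in-array recapture record; 40% / 25% of emigrants are later
recaptured / glider-detected at their destination.

What the generator does **not** emulate: receiver loss and array
reconfiguration mid-study (every receiver runs the whole window), tag
code collisions, ambient-noise variation by habitat, staggered tagging
dates, tidal or diel behavior, and gradual detection-efficiency decay.
Passing tests therefore show the estimators recover truth under clean
study conditions with realistic sampling noise — not that they are robust
to the logistical failures real arrays suffer.

## Problem sizes and numerical choices

Tests and the acceptance script run scaled cohorts chosen to exercise
every stage at meaningful sample sizes: a 200-fish / 90-day cohort with
balanced competing risks for fate validation, a 120-fish / 180-day cohort
for the end-to-end pipeline, 3,000 fish over two simulated years
(~1.8 M fish-days) for the emigration GLM, 20,000 calibration positions,
5,000 range trials, and n = 500 with 15% censoring for kernel recovery.
Determinism: every random stream derives from one integer seed through
`numpy.random.SeedSequence` with CRC-stable salts, so identical seeds give
identical files across processes and platforms. Optimizers are
Nelder–Mead on log/logit-transformed parameters with tight tolerances;
degenerate inputs (no events, no low-pressure days, complete separation,
single calibration bin) raise typed, messageful errors rather than
returning garbage.

## Known limitations

- Fate rules are tuned to well-separated signatures; overlapping
  behaviors (a slow predator, a fish dying at the array edge) will land
  in `unknown` or be misread, as they are for human readers of real data.
- The predation water-column signature is a heuristic with no
  field-quantified envelope; its parameters are config, not science.
- The Weibull fidelity model is intercept-only; time-varying covariates
  and frailty are out of scope.
- UD computation is dense-grid; fish ranging over tens of kilometres
  would need a sparse implementation.
- The emigration GLM treats fish-days as independent Bernoulli trials;
  group exits (criterion 3) mildly violate that independence.
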