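# reeftrack

Movement-ecology analysis for acoustic-telemetry studies of resident reef
fish — built around the kind of high-density acoustic positioning system
(APS) study used for red snapper (*Lutjanus campechanus*) on the West
Florida Shelf: a grid of moored receivers logs coded transmissions from
surgically implanted tags, a positioning solver triangulates fish locations
when ≥ 3 receivers hear a transmission, and the analyst must turn millions
of noisy detections into defensible estimates of **site fidelity**,
**space use** and **dispersal** — the three movement metrics that decide
whether area-based management (artificial-reef fishing zones, protected
areas) can work for a species.

The package implements the full analysis chain, each statistical step as a
model object with a `fit()` returning a results object:

- **Position-error calibration** (`positioning.PositionErrorModel`) —
  known-location sync/reference tags give measured horizontal errors,
  summarized per unit HPE bin (after censoring the upper 5% of HPE) as
  2DRMS_i = 2·√((1/nᵢ)·Σⱼ(Δxᵢⱼ² + Δyᵢⱼ²)); an OLS of 2DRMS on mean HPE
  (per array region, region count chosen by AICc) predicts each fish
  position's error, and positions with predicted 2DRMS > 20 m are censored.
- **Detection range** (`positioning.DetectionRangeModel`) — maximum
  likelihood logistic curve p(d) = p₀ / (1 + exp(κ(d − d₅₀))).
- **Centers of activity** (`positioning.compute_coas`) — mean of the
  distinct detecting receivers' coordinates per 30-min or 4-h bin, after
  spurious-detection removal; the ≥ 3-receiver rule is relaxed on each
  fish's final detection date.
- **Fate assignment** (`fates.classify_fates`) — rule-based terminal
  classification (survived / emigrated / mortality / predated / captured /
  unknown) from depth and movement signatures, recaptures and glider
  relocations, with a 3-day capture-tagging-release recovery window.
- **Site fidelity** (`fidelity`) — event-history analysis with emigration
  as the event: a hand-rolled Kaplan–Meier product-limit estimator
  (Greenwood variance, log(−log) CIs) and a right-censored Weibull MLE
  S(t) = exp(−(t/λ)ᵏ), each run with unknown fates censored *and* recoded
  as emigrations; plus a binomial GLM for daily emigration probability,
  E_i ~ Binom(n_i, p_i), logit(p_i) = β₀ + β₁·[low-pressure day], fitted
  by IRLS, whose marginal probabilities feed the projection
  S(t) = (1 − p_r)^(t−D_L) · (1 − p_l)^(D_L).
- **Space use** (`spaceuse`) — Brownian-bridge utilization distributions on
  a 10 × 10 m grid at daily and tracking-duration scales, 50/90/95%
  isopleths, high-use "centroids" (90% components ≥ 100 m²) and temporal
  shift detection, movement rates with a worst-case position-error
  correction, and long-distance movements (> 2,000 m within 48 h).
- **Dispersal** (`dispersal`) — per-fish maximum pairwise distance among
  4-h COAs, recaptures and glider relocations over ≥ 100 tracked days,
  right-censored for fish that left unobserved; censored ML fits of Burr
  XII (S(x) = (1 + (x/s)ᶜ)⁻ᵏ), Weibull, lognormal, gamma and exponential
  kernels ranked by AIC, with tail exceedance probabilities P(X ≥ d).
- **Synthetic studies** (`synthetic`) — a ground-truth generator (receiver
  grids, OU residency with centroid shifts, competing daily risks,
  logistic detection, HPE-proportional position error) so every estimator
  is validated against known truth.

## Worked example

```python
import numpy as np
from reeftrack.synthetic import (SimConfig, simulate_calibration_positions,
                                 simulate_range_trials, simulate_daily_emigration)
from reeftrack.positioning import PositionErrorModel, estimate_range
from reeftrack.fidelity import EmigrationGLM, project_fidelity

cfg = SimConfig(seed=42)
calib = simulate_calibration_positions(cfg, 20_000, (0.0, 0.0))
print(PositionErrorModel(calib).fit().summary())

trials = simulate_range_trials(cfg, np.arange(50, 1300, 50), 200)
print(estimate_range(trials).summary())

daily = simulate_daily_emigration(cfg, n_fish=3000, study_days=730)
dep = EmigrationGLM(daily).fit()
print(dep.summary())
print("projected S(365) with 5 low-pressure days:",
      round(project_fidelity(dep.p_regular, dep.p_low, 365, 5), 3))
```

prints

```
Position-error calibration (2DRMS vs HPE)
  HPE censor quantile: 0.95
  threshold: 20.0 m
  region group pooled: 2DRMS = 3.549 * HPE + -0.327
  model comparison:
    1-region: AICc = 10.53  <- selected

Logistic detection-range model
  p0        = 1.0000
  d50       = 367.3 m (distance at p = p0/2)
  steepness = 0.00501 /m
  loglik    = -2071.04 on 5000 trials

Daily emigration probability (binomial logit GLM)
  regular-pressure days: p_r = 0.00042 (0.00039-0.00045)
  low-pressure days:     p_l = 0.07205 (0.06516-0.07961)
  ratio p_l / p_r = 173.5
  loglik = -951.91, AIC = 1907.83

projected S(365) with 5 low-pressure days: 0.592
```

Reading it: the calibration line says a fish position with HPE 6 carries a
predicted 2DRMS of ~21 m and would be censored at the 20 m accuracy
threshold; the range model recovers the generator's 50% detection range
(346 m) within sampling error; the emigration GLM says a fish is ~170×
more likely to leave the study area on a low-atmospheric-pressure (storm)
day, and compounding those daily probabilities over a year containing five
such days predicts ~59% of fish remain.

## Command-line pipeline

Every stage is also a CLI subcommand operating on a project directory:

```sh
reeftrack simulate --seed 7 -p proj --n-fish 60 --study-days 180
reeftrack calibrate -p proj
reeftrack filter-positions -p proj        # reports the retention fraction
reeftrack coa -p proj && reeftrack coa -p proj --bin-minutes 240
reeftrack fates -p proj
reeftrack fidelity -p proj --unknown-as censored
reeftrack fidelity -p proj --unknown-as emigrated
reeftrack space-use -p proj
reeftrack movement -p proj
reeftrack dispersal -p proj
```

Artifacts are plain CSV/GeoJSON; `runlog.jsonl` records seeds and
thresholds per stage.

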