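# sealhab

Winter habitat modelling for satellite-tracked pinnipeds — from noisy Argos
fixes to accessibility-weighted habitat-suitability maps.

Juvenile and sub-adult male Antarctic fur seals overwinter in the seasonal
sea-ice zone, foraging from coastal haul-outs on trips that lengthen as
days shorten. Mapping their winter habitat from satellite telemetry
requires a chain of methods, each of which this package implements as
tested, importable code:

1. **Track cleaning** — near-duplicate removal (≤ 2 min), a
   speed-distance-angle filter (class-Z removal, > 3 m s⁻¹ speeds, spikes
   with inner angles < 15°/25° and legs > 2.5/5 km), and splitting at data
   gaps > 7 days.
2. **State-space regularization** — a correlated-random-walk model
   (integrated Ornstein–Uhlenbeck velocity; Kalman filter + fixed-interval
   smoother, maximum likelihood) that accounts for Argos class-dependent
   measurement error and yields positions every 6 h with standard errors.
3. **Pseudo-absences** — a VAR(1) model of (step length, sin/cos turning
   angle) fitted per track, used to simulate sea-confined null tracks that
   share each trip's start and timestamps; daily 0.1° gridding, removal of
   pseudo-absences adjacent (3×3 cells, ± 2 days) to any presence, and 1:1
   per-seal per-day stratified sampling.
4. **Environmental stack** — 13 covariates (Table-2 style): bathymetry and
   seabed slope (Horn's method), SST/salinity and their gradients, sea-ice
   fraction and thickness, distance to the 15% ice edge (shortest path
   through sea cells), SSH, eddy kinetic energy `EKE = 0.5 (U² + V²)`,
   chlorophyll-a and mixed-layer depth; log(x+1) transforms for CHL and
   EKE; 15-km radius covariate matching; Spearman collinearity screen
   (|ρ| ≥ 0.7).
5. **Boosted regression trees** — Bernoulli gradient boosting with shallow
   best-first trees (written in this package, numba-accelerated), a
   random-number control covariate, leave-one-seal-out cross-validated AUC
   for hyperparameter selection over the standard grid (trees 50–10,000 ×
   complexity {1,3,5} × learning rate {0.005, 0.001, 0.05, 0.01} × bag
   fraction {0.5, 0.6, 0.7}), relative influence, partial dependence, and
   a 50× half-data bootstrap giving per-cell median maps and 95% CI ranges
   with monthly averages.
6. **Accessibility** — a monotone non-increasing binomial model of cell
   accessibility vs distance beyond the ice edge (logistic regression on an
   I-spline basis with sign-constrained coefficients), bootstrapped ×50;
   suitability is multiplied by accessibility and cells with SIC > 15% are
   forced to zero.
7. **Trip analysis** — haul-out detection, trip segmentation,
   departure/arrival histograms in local solar time, daylength (sunrise
   equation) and its Pearson correlation with trip duration, daily maximum
   dive depths, and haul-out demography summaries.

Because real winter tracking data of this kind are not redistributable, the
package ships a first-class synthetic study system (`sealhab.synth`): a
seasonal ice-advance world with spatially correlated ocean fields, seals
that alternate haul-out residency with at-sea trips biased toward a *known*
logistic suitability function, Argos-class observation noise, dive records
and transect censuses. Every downstream stage is tested for recovery of
that known truth.

## Worked example

`examples/04_habitat_model.py` simulates four seals whose movement prefers
deep, relatively warm, low-salinity offshore water, runs the full chain
and fits the model:

```
collinearity screen dropped: [('edge', '|rho|=0.81 with sic')]
selected: BRTConfig(n_trees=150, tree_complexity=3, learning_rate=0.05, bag_fraction=0.5)
CV AUC = 0.888, CV deviance explained = 20.4%
relative influence (%):
sal            30.3
bat            13.3
sst            11.4
...
random_ctrl     1.9
covariates above the random control (1.9%): ['sal', 'bat', 'sst', ...]
partial dependence on SST (degC -> probability):
 -2.0  0.184
  2.0  0.453
  3.0  0.610
```

The three planted drivers (SAL, BAT, SST) head the influence ranking and
beat the random-number control, and the partial-dependence curve for SST
rises — the model recovered the planted preference. (This small example
world keeps under the 1000-tree constraint the full-size experiment
enforces; numbers vary with the seed.)

The other examples cover world simulation (`01`), track cleaning and
regularization (`02`), pseudo-absence construction (`03`), accessibility
weighting (`05`) and the trip/dive/demography report (`06`).

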