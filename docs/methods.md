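# Methods

This note documents the models, numerical choices and synthetic study
system behind `sealhab`, in the spirit of a package vignette: what each
stage assumes, which parameters matter, and what passing the test suite
does and does not demonstrate about real data.

## Track cleaning

Raw Argos fixes are cleaned in three steps, each a pure function returning
a subsequence of its input:

- **Near-duplicate removal.** A sequential scan per individual keeps a fix
  only if it falls more than 2 min after the most recently *kept* fix.
  Scanning against the last kept fix (rather than all prior fixes) is the
  standard thinning rule; both comparisons are strict.
- **Speed-distance-angle filter.** Class-Z fixes (invalid positions) are
  dropped first. A greedy forward pass then removes fixes implying
  great-circle speeds above 3 m s⁻¹ from the last kept fix, and a spike
  pass removes the sharpest internal fix whose inner turning angle is
  below 15° (legs > 2.5 km) or 25° (legs > 5 km), re-evaluating the
  geometry after each removal. The two passes alternate to a fixed point,
  so the output simultaneously satisfies both constraints and the filter
  is idempotent.
- **Gap splitting.** Tracks are split where consecutive fixes are more
  than 7 days apart ("more than" strict); each segment is treated
  independently downstream.

All geodesy is spherical (haversine distances, initial bearings,
R = 6371 km). Speeds are great-circle distance over elapsed time.

## State-space regularization

Each segment is regularized to a 6-h lattice with a continuous-time
correlated random walk: velocity is an Ornstein–Uhlenbeck process
(mean-reversion θ, diffusion σ) and position its integral, discretized
exactly over the irregular inter-event intervals. Events are the union of
observation times and lattice times; observations update the Kalman filter
with a measurement variance fixed per Argos class (defaults 0.25 / 0.5 /
1.5 / 4 / 6 / 10 km for classes 3 / 2 / 1 / 0 / A / B — a published-style
error ladder, configurable); lattice events are prediction-only. (θ, σ)
are estimated by maximum likelihood (Nelder–Mead on log parameters, three
starting points; non-convergence after all restarts flags and excludes the
segment), and the fixed-interval (RTS) smoother yields positions and
standard errors at exactly t₀, t₀+6 h, …. Axes are filtered independently
on a local equirectangular plane per segment, adequate for track-scale
extents. The reported per-step persistence is e^{−θ·6h}.

A discrete-time first-difference CRW on the 6-h lattice was considered
first, assigning each observation to its nearest lattice slot with an
inflated variance; the snap-to-slot approximation floors the achievable
accuracy at the scale of movement per step (~5 km here), which the
continuous-time form removes. On simulated tracks with the default Argos
error mixture, smoothing reduces positional RMSE relative to the raw
(non-Z) observations from ~8 km to ~4 km, in 20 of 20 replicates.

## Haul-outs and trips

The original analysis identified haul-outs visually; we use a reproducible
surrogate: maximal runs of regularized positions within 12 km of a land
cell (and flagged dry when a dry-sensor column exists) lasting at least
6 h. The 12-km default is one 0.1° cell step — centre-to-centre distances
on this grid are ≥ 11.1 km, so the radius cannot meaningfully be smaller;
on finer grids or with continuous coastlines it should be reduced (it is a
parameter). Trips are the intervals between consecutive haul-outs with at
least one at-sea position; a trip is a round trip iff the two haul-out
identities (modal grid cell of the residency) match.

## Pseudo-absences

The habitat model needs an estimate of what was *available* to each seal.
For every segment a VAR(1) is fitted to the state (step length, sin turn,
cos turn) of its longest at-sea run (statsmodels; a minimum-norm
least-squares fallback covers degenerate, perfectly collinear series); the
fitted system is projected into the stationary region if needed. For every
at-sea run (trip) of that segment, null tracks are simulated with the same
timestamps, anchored at the trip's first position, restricted to sea cells
by per-step rejection (100 draws, then 100 more from a 3× widened
innovation; a still-blocked simulation is abandoned and replaced).
Simulations know nothing about the environmental fields.

Presences (at-sea positions of real tracks) and pseudo-absences (simulated
positions) are gridded per individual per UTC day at the 0.1° study grid
(half-open [lower, upper) bins). A pseudo-absence is discarded if any
individual's presence occupies its 3×3 Moore neighbourhood (the cell
itself included) within ± 2 days. Finally a 1:1 stratified sample per
(individual, day) draws min(#presences, #remaining absences) absences
without replacement; strata short of absences keep what they have (no
borrowing across strata).

Fitting on at-sea runs only is deliberate: haul-out residency contributes
long stationary coastal point-masses that would otherwise dominate the
presence set and teach the model coastal geometry rather than habitat.

## Environmental stack

Thirteen covariates on a shared 0.1° grid: BAT (m, negative at sea — the
GEBCO convention), SLP (°), SIC (fraction), EDGE (km), SIT (m), SST (°C),
SSTg (°), SAL (PSU), SALg (°), SSH (m), EKE (m² s⁻², stored log(x+1)),
CHL (mg m⁻³, stored log(x+1)) and MLD (m). Derivations:

- **Slope / gradients** (SLP from BAT, SSTg from SST, SALg from SAL):
  Horn's eight-neighbour method with latitude-corrected cell dimensions;
  edge cells replicate the border, missing neighbours fall back to the
  centre value.
- **EKE** = 0.5 (U² + V²), then log(x+1). The transform is applied once at
  stack-build time and marked in layer attrs so it can never be applied
  twice; the same guard covers CHL.
- **EDGE**: per day, the shortest-path distance from each open-water cell
  to the nearest cell with SIC > 0.15, travelling through sea cells only
  (8-connected, great-circle edge lengths, Dijkstra via a zero-cost
  virtual source). Ice cells get 0, land is missing, days without any ice
  leave the layer missing. Land blocking means EDGE honours coastline
  geometry rather than cutting across peninsulas.
- **Regridding** is bilinear with missing propagation (any missing corner
  → missing target).

Covariate matching averages, per record and covariate, the cells whose
centres lie within 15 great-circle km of the record's cell centre
(boundary ties included) from the same UTC day's layer; missing cells are
ignored in the mean, and an all-missing neighbourhood yields a missing
value that the tree learner later routes to the majority child (CHL is the
only covariate expected to carry missingness).

The collinearity screen computes all pairwise Spearman correlations
(average ranks for ties) and greedily drops the later covariate in the
canonical order above for every pair with \|ρ\| ≥ 0.7, until no pair
exceeds the threshold. Constant covariates have undefined correlations and
are reported, never auto-dropped. In the synthetic world SIT is generated
as a monotone function of SIC plus small noise precisely so the screen has
something real to do.

## Boosted regression trees

The Bernoulli boosted-tree learner is implemented in the package:

- F₀ = logit of training prevalence (0.5 after balanced sampling).
- Per iteration: gradient residuals r = y − p; a best-first regression
  tree with at most `tree_complexity` splits is fitted to r on a random
  `bag_fraction` subsample (without replacement); terminal-node values are
  one-step Newton estimates Σr / Σp(1−p), clipped to ±8; the tree is added
  with shrinkage `learning_rate`.
- Split search is histogram-based: each feature is quantile-binned once
  per fit (≤ 255 cuts; exact value midpoints when a feature has fewer
  unique values, so small-data splits are exact). Missing values route to
  the finite-count majority child, recorded per split for prediction.
- Relative influence is the per-feature sum of realized squared-error
  reductions over all splits, normalized to 100%.
- Partial dependence substitutes each grid value into the covariate's
  column across all stored training rows, averages the ensemble logit and
  inverse-transforms — the direct definition, exact by construction.

Hyperparameters are selected by leave-one-individual-out cross-validation:
all rows of the held-out seal (its presences *and* the pseudo-absences
simulated from its trips, which share its individual id) leave the
training set together. For each (complexity, learning rate, bag fraction)
combination one fit at the maximum tree count is scored on the held-out
fold at every 50-tree checkpoint (stagewise boosting makes the scan exact,
not approximate). The selected combination maximizes mean CV AUC subject
to > 1000 trees, ties broken toward larger learning rates, then smaller
complexities, then fewer trees; if nothing reaches 1000 trees the
constraint is relaxed with a warning. Cross-validated deviance explained
is pooled over folds: 1 − D(model)/D(null), the null being each fold's
training prevalence. The configuration used by the original winter
fur-seal analysis ships as the preset `WINTER2019` (1050 trees, complexity
5, learning rate 0.01, bag fraction 0.5).

A uniform-integer control covariate on [1, 100] is appended before
fitting; covariates whose influence does not exceed the control's are
flagged uninformative.

Uncertainty: the selected model is refitted 50 times (20 in the scaled
recovery experiment) on half-size resamples drawn with replacement;
per-cell daily maps report the median and the 2.5–97.5% range of the
bootstrap predictions, and monthly means average the available days.
At prediction time the random control is held at its midpoint (50.5).

## Accessibility

Every open-water cell becomes a binary observation: 1 if any observed or
simulated location ever fell in it, else 0, with the cell's mean distance
beyond the 15% ice edge as covariate. Accessibility is logistic regression
on an I-spline basis (reverse-cumulated B-splines, degree 2, knots at
distance quantiles) with sign-constrained coefficients entering
negatively — the fitted probability is monotone non-increasing by
construction, not by post-hoc correction — plus a light second-difference
penalty (weight 1.0 by default; 0 disables smoothing, in which case a
dense-knot fit approaches the isotonic pool-adjacent-violators solution,
which is how the tests cross-check it). The model is bootstrapped (half
data, with replacement) and the pointwise median of the curve family is
the point estimate. Weighted maps are suitability × accessibility evaluated
on each day's own EDGE layer, with SIC > 0.15 forced to zero and land
missing.

In synthetic worlds where the preferred habitat sits far from the ice
edge, the fitted accessibility curve comes out nearly flat — the
monotonicity machinery is exercised, but the curve carries little
information there. With ice-associated animals (the real system)
the same code produces a genuinely decreasing curve; the tests cover that
case with data generated from a decreasing logistic.

## Trip statistics

Departure/arrival histograms use local solar time (UTC + longitude/15).
Daylength comes from the sunrise equation with the Spencer harmonic series
for solar declination (the single-cosine approximation errs by up to
0.3 h at \|lat\| = 60°, beyond the package's 0.2 h accuracy target);
cos H₀ is clamped for polar day/night. The daylength–trip-duration
correlation is Pearson's r with daylength evaluated at the trip's midpoint
date and the seal's mean position over the trip (switchable to the
departure date). Dive summaries are per-seal-day maxima and monthly
mean ± SD across seal-days; days without dives are absent, not zero.
Demography summaries report per-haul-out totals and per-class percentages
with across-census SDs. The printed tagging and census tables of the
original field study ship with the package (`sealhab.io.load_tagging_table`,
`load_haulout_totals`) and feed the worked-example summaries (pooled
count 542, pooled trips 243, longest track 197 days, 14 tags retained —
a tag is retained iff it recorded at least one trip).

## Synthetic study system

`sealhab.synth` generates everything the pipeline consumes:

- **World**: a 60 × 60-cell (0.1°) region spanning 6° × 6° with land along
  the northern edge plus a small island, over 120 daily steps starting
  1 March. Dynamic fields are standardized Gaussian random fields
  (Gaussian-filter correlation length 0.5°) evolving as daily AR(1)
  (φ = 0.92), shaped by latitudinal gradients (SST warmer north, −1 °C
  seasonal cooling; SAL fresher north) and seasonal trends (CHL decaying,
  MLD deepening). Sea ice is a deterministic logistic front in latitude
  whose 15% edge advances 2.5° equatorward over the season plus a static
  spatial texture — zero seasonal amplitude therefore yields day-invariant
  SIC, and the amplitude is domain-proportionate (a full-scale multi-degree
  advance would leave the closed domain almost iceless of open water by
  late winter, a situation real animals escape by leaving the region).
  SIT is a monotone function of SIC plus small noise (deliberate
  collinearity). BAT is negative at sea, positive on land.
- **Seals**: a discrete-time 6-h correlated random walk with gamma step
  lengths, von Mises turns and habitat bias — candidate steps are weighted
  by exp(β · suitability); β = 0 is exactly unbiased. True suitability is
  the logistic of a linear combination of per-layer standardized
  covariates, so it lies in [0, 1] by construction. Seals alternate
  haul-out residency (evening departures, morning arrivals, mostly to a
  *different* site) with trips whose mean duration grows through winter.
  Irregular Argos observations (exponential gaps, mean 1.8 h) interpolate
  the true path and add isotropic class-dependent noise.
- **Surveys and dives**: transect censuses draw multinomial counts with the
  observed age-class composition (49.7 / 36.5 / 13.7%); dive-tagged seals
  produce daily depth records whose deepest dives grow as winter advances.

What the synthetic system does *not* emulate: oceanographic physics (fields
are statistical textures), Argos error anisotropy and temporal clustering,
tag failure processes, memory or site fidelity beyond the haul-out
schedule, and model-reanalysis biases in ice concentration. Passing the
recovery tests therefore shows the pipeline's inferential machinery is
correct and recovers a known preference under realistic noise — not that
any particular ecological conclusion transfers to real oceans.

## Recovery experiment

The end-to-end experiment (`pipeline.run_recovery_experiment`) simulates
8 seals for 60–120 days each in the 60 × 60 world with a strong planted
preference (β = 15) for deep, relatively warm, low-salinity offshore
water ({sst: +2, bat: −2, sal: −2} on standardized layers — a water-mass
preference that forces commuting away from the coastal haul-outs, and
whose low-salinity component matches what winter fur-seal habitat models
report) with Argos error SDs scaled to 0.3 of the published ladder, then
runs the full chain with 10 pseudo-tracks per trip and a 20-fit
bootstrap, tuning over a reduced grid (complexity {1, 3, 5} × learning
rate {0.05, 0.01} × bag 0.5, trees to 1500 in 50-tree steps; the full
published grid remains the library default). The offshore design matters:
when the preferred habitat coincides with the haul-out surroundings, the
null tracks (anchored at the same start points) sample nearly the same
habitat as the real ones and even the *true* suitability cannot separate
presence from availability well; commuting to offshore habitat restores a
real contrast. It reports:

- leave-one-seal-out CV AUC and pooled deviance explained;
- whether each planted covariate's relative influence exceeds the random
  control's;
- the Spearman correlation between predicted and true suitability on
  held-out cells — cells inside the sampled envelope (visited by at least
  one real or simulated location) but never used in the training table,
  restricted to open water (SIC ≤ 0.15 on the evaluated days), comparing
  monthly means of the daily bootstrap-median maps with matching monthly
  means of the truth. Ice-covered cells are excluded because they are
  outside the habitat model's applicability domain by design (the
  accessibility model owns them), and never-sampled cells are excluded
  because a use–availability model makes no claim where nothing was
  available — both would otherwise be scored on pure extrapolation;
- monotonicity of every bootstrap accessibility curve on a 1-km grid, and
  the ice-exclusion check (weighted suitability ≡ 0 wherever SIC > 0.15).

Problem sizes (weekly prediction days, 20 bootstrap fits, the reduced
tuning grid) are the package's chosen desk-scale defaults; the paper-scale
settings (50 simulations, 50 bootstrap fits, full grid) are plain
arguments.

## Known limitations

- The movement truth model selects among a finite candidate set (15 draws
  per step), so extremely large β saturates rather than concentrating use
  further.
- The use–availability design identifies *relative* preference within each
  seal-day's reachable range; map-level recovery of the global suitability
  surface is therefore noisier than the cross-validated discrimination,
  and degrades where covariates leave the sampled envelope.
- The accessibility fit assumes a single monotone distance response pooled
  over the season (per-day EDGE layers are used at weighting time).
- Kalman filtering on a per-segment planar projection mildly distorts very
  long east–west segments at high latitude.
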