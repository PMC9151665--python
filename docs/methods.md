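# Methods

## Problem setting

Rice canopy growth is monitored through 8-day NDVI composites; the canopy
state variable is the leaf area index (LAI, m² m⁻²). A process-based crop
model simulates LAI daily from weather; each season its parameters are
re-fitted ("within-season calibration") so that the simulation tracks the
season's observed canopy series. This package also implements the hybrid
variant of that regime: a data-driven regressor first estimates LAI from
climate factors, and the crop model is calibrated to those estimates, so
the final trajectory is physically structured but informed by the
data-driven estimate.

## Process model

Thermal time drives everything. Daily increments are

    ΔGDD_t = max(0, (T_max,t + T_min,t)/2 − T_base),   T_base = 10 °C,

and the canopy follows a logistic-growth/exponential-senescence structure:

    growth (Σ ΔGDD ≤ G_s):  ΔL_t = a · ΔGDD_t · ρ_t · L_t (1 − L_t / b)
    senescence (after G_s): ΔL_t = −c · ΔGDD_t · L_t
    radiation modifier:      ρ_t = min(1, R_t / R_ref)

Integration is daily explicit Euler, matching the daily weather inputs; LAI
is clipped at zero. The structure is deliberately minimal: four
calibratable parameters and a single senescence switch, which is the
smallest model that produces the rise-plateau-decline shape of a rice
season and supports a four-parameter within-season fit.

Calibratable parameters and default bounds:

| parameter | meaning | units | bounds |
|---|---|---|---|
| `L0` | LAI at transplanting | m² m⁻² | [0.01, 0.5] |
| `a`  | relative leaf growth rate | per °C·day | [1e-4, 5e-2] |
| `b`  | asymptotic maximum LAI | m² m⁻² | [2, 8] |
| `c`  | relative senescence rate | per °C·day | [1e-5, 1e-2] |

Fixed season constants (configurable, not calibrated): base temperature
10 °C, senescence onset at 1200 °C·day, reference insolation
20 MJ m⁻² d⁻¹, season length 128 days from transplanting (mid/late-May
transplanting, day-of-year 135–140). The bounds were chosen so that
mid-season LAI peaks fall in the 2.5–4 m² m⁻² range typical of temperate
paddy rice.

## Within-season calibration

The objective is the unweighted sum of squared LAI residuals at the
observation dates. It is the minimal discrepancy consistent with comparing
simulated to observed values date by date; a configuration hook allows an
RMSE or weighted variant. Minimisation uses Powell's direction-set method
(no derivatives — the senescence switch makes the objective only piecewise
smooth) over unit-scaled parameters with bound-constrained line searches,
starting from the bound-interval midpoints unless a start is supplied.

A logit reparameterization (mapping the real line onto each bound interval)
was tried first and rejected: the warp flattens the objective near the
bounds and the direction set stalls on the strongly correlated (L0, a)
valley, returning L0 pinned at its bound on noise-free data. Bounded line
searches in the unit cube recover noise-free truth exactly (objective
~1e-20) from the same midpoint start.

Convergence is declared when the successive objective improvement falls
below 1e-8 or after 200 direction-set iterations; the returned objective is
never allowed to exceed the starting objective. Identifiability is uneven
by design of the observation geometry: `b` is tightly constrained by the
plateau, `a` and `L0` trade off against each other in the early season
(few, small, noisy observations), and `c` is only constrained by post-peak
composites. On twenty synthetic seasons with 0.1 m² m⁻² observation noise
the median relative recovery errors are roughly 14% (L0), 7% (a), 1% (b),
5% (c) — the acceptance suite asserts the 15/15/15/30% envelope.

## Regressor stage

Features are the three climate factors accumulated from the transplant
date to each composite date: insolation (MJ m⁻²) and maximum/minimum
temperature (°C·day). Accumulations are used because a seasonal canopy
state cannot be a function of a single day's weather; an `instantaneous`
switch exists for sensitivity checks. The target is the LAI derived from
(gap-filled) NDVI.

Eleven families are exposed behind one `RegressorSpec` interface:
polynomial linear regression, ridge (α = 0.1) and lasso (α = 0.01) on the
same degree-2 polynomial basis, RBF support vector regression, random
forest, extra trees, gradient boosting, histogram gradient boosting,
XGBoost, LightGBM (library defaults otherwise), and a fully connected
network. Scores are coefficients of determination (R²) on the scored
subset; data are split 0.8/0.2 by a seeded permutation. The ridge/lasso
regularization strengths can be re-derived with `grid_search_alpha`
(argmax of test R², ties to the smallest α).

The network is implemented directly in numpy: hidden layers
(100, 300, 1000, 1000, 300, 100) by default, ReLU activations, inverted
dropout 0.17 after every hidden layer, Adam at learning rate 1e-3, batch
size 100, 1000 epochs in the `paper` profile (200 in the `test` profile).
Inputs and target are standardized internally; a zero-variance target short
circuits to the constant fit. All weight initialisation, shuffling and
dropout draws come from one seeded generator, so training is exactly
reproducible for a given seed and thread count.

## Preprocessing

Composites carry a boolean quality mask, optionally derived from 16-bit QA
words via a configurable bit rule (bit position → required value); full
MOD09A1 semantic decoding is out of scope since the mask is only a
good/bad gate. Gaps are filled with a cubic interpolating spline
(not-a-knot end conditions) through the good points — not-a-knot reproduces
cubic polynomials exactly, which gives the test suite a sharp oracle. Good
values pass through bit-identically; leading/trailing gaps are held at the
nearest good value because spline extrapolation there is unbounded.

NDVI is converted to LAI by the exponential relation `LAI = α·exp(β·NDVI)`
with defaults α = 0.1 m² m⁻², β = 4.0 (NDVI 0.9 ↦ LAI ≈ 3.7, typical for
paddy rice at peak canopy). The coefficients are configuration, so an
empirically fitted relation can be dropped in; `lai_to_ndvi` is the exact
inverse and is what the synthetic generator uses to emit NDVI from
simulated LAI.

## Synthetic data

The generator emulates the statistical structure of the real inputs, not
their physics:

* temperatures: a sinusoidal annual climatology plus AR(1) noise
  (persistence 0.7, innovation 1.5 °C), constant diurnal range;
* insolation: a clear-sky constant (22 MJ m⁻² d⁻¹) attenuated to 35% on
  cloudy days;
* cloud cover: a two-state clear/cloudy Markov chain on days, so cloudy
  spells cluster like monsoon cloudiness; a composite is flagged poor
  quality when more than half of its 8 days are cloudy. An iid
  composite-level gap probability is available as a simpler mode;
* truth: per-pixel parameters drawn uniformly from ranges that keep peak
  LAI in [2, 5] m² m⁻²; trajectories simulated by the process model,
  inverted to NDVI, and degraded with additive LAI-scale noise
  (σ = 0.1 m² m⁻²).

Default region presets are sized so that a full multi-year run produces
sample counts at the scale of the real regional datasets (≈10⁴ composite
samples). The presets named after Korean rice districts are synthetic
climatologies (warmer south, cooler north) used to exercise cross-region
transfer; they are fixtures, not descriptions of the actual places. What
passing tests show is therefore that the pipeline's statistical machinery
is correct under its own assumptions; they say nothing about sensor
calibration, mixed-pixel effects, georeferencing, or any other property of
real imagery.

## Numerical choices and degenerate inputs

* NaNs in paired series are errors, never silently dropped — gap handling
  belongs to preprocessing.
* The Nash–Sutcliffe efficiency is undefined (raises) when the
  observations have zero variance; the normalization `1/(2 − ME)` is the
  smallest smooth rational map through the anchor points 1↦1, 0↦0.5,
  −∞↦0.
* Zero growth (`a = 0`) and zero senescence (`c = 0`) are valid limits;
  `L0 > b` is rejected.
* The train/test splitter gives the training set exactly ⌊n·f⌋ rows.
* Grid-search ties break toward the smallest regularization strength.
* Tree-ensemble predictions are clipped at zero before assimilation (they
  cannot leave the training target range, but linear and network families
  can go negative).

## Problem sizes

The test suite runs everything at desk scale: recovery studies use 20
single-year pixel-seasons, the grid oracle 10, the regressor benchmark
8,000 samples, and end-to-end pipelines 4–12 pixels. The generator accepts
study-scale configurations (hundreds of pixels, seven years) through the
same interface.

## Known limitations

* The process model has no biomass, phenology stages, yield, or
  water/nitrogen stress; senescence is a single threshold switch.
* The calibration fits one pixel-season at a time; there is no joint
  multi-pixel estimation and no Bayesian posterior (the objective/optimizer
  seam is where one would attach it).
* SVR has no seed (it is deterministic); its kernel and C are library
  defaults.
* The synthetic generator has no spatial autocorrelation between pixels
  and no radiative-transfer realism.
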