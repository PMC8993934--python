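# Methods

## Model structure

`hybridevap` couples a process-based evaporation host with an exchangeable
transpiration-stress sub-model at a daily time step.

The host computes potential evaporation with the Priestley–Taylor
formulation, E_p = α · Δ(Ta)/(Δ(Ta)+γ) · Rn/λ, using the FAO-56 closed form
for the saturation-vapour-pressure slope Δ, γ = 0.0665 kPa °C⁻¹,
λ = 2.45 MJ kg⁻¹ and α = 1.26. Ground heat flux is neglected at the daily
scale and negative net radiation floors E_p at zero.

Soil water is a tipping-bucket column: rainfall (less interception)
infiltrates the top layer, moisture above porosity cascades downward, the
bottom layer's excess drains freely out of the column. Transpiration is
extracted from the wettest layer, soil evaporation from the surface layer,
and extraction is capped at the water available above residual moisture
(shortfalls are reported, never silently absorbed). Mass balance closes to
machine precision at every step and is asserted to < 1e−6 mm over
year-long runs. Tall vegetation uses three layers, short vegetation and
bare soil two. Layer depths default to (100, 400, 800) mm and
(100, 400) mm; they are uncalibrated defaults, as are the hydraulic
constants w_r = 0.05, w_wp = 0.10, w_c = 0.30, porosity = 0.45 (volumetric),
all configurable.

Two stress formulations share one predictor interface:

- **Process**: S_t = sqrt(VOD/VOD_max) · (1 − ((w_c − w_w)/(w_c − w_wp))²),
  with VOD_max the 99th-percentile VOD of the record
  (linear-interpolation percentile). Inputs are clamped
  (VOD ≤ VOD_max, w_wp ≤ w_w ≤ w_c) before evaluation: the raw expression is
  negative below wilting point and exceeds one above critical moisture, and
  a multiplicative stress must stay in [0, 1]. Bare-soil stress is
  S_b = 1 − (w_c − w_1)/(w_c − w_r), clamped likewise.
- **Learned**: a feed-forward network (three hidden layers of 64 ReLU units,
  dropout 0.1, sigmoid output bounding predictions to [0, 1]) over twelve
  features: the absolute values and seasonal anomalies of PAW, VPD, Ta,
  SW_in, VOD and CO₂, in that fixed order. Inputs are z-scored with
  training-set moments stored in the model bundle. One model per vegetation
  class, identical architecture and protocol.

In the daily coupled loop, each land-cover fraction (tall, short, bare) owns
a per-unit-area soil column. The column's PAW = (w_w − w_wp)/(w_c − w_wp),
clamped to [0, 1] (moisture above critical means no water limitation), joins
the covariates; the stress model scales potential transpiration *before*
fraction weighting; the resulting extraction updates the column, so the
next day's stress sees the drawdown. Covariate anomalies during coupled
runs come from a climatology precomputed over the forcing archive (a
process-mode pass supplies the PAW climatology), keeping the daily step a
pure function of its inputs. Open-water evaporation and snow sublimation
are constant stubs (default 0). Vegetated columns also lose an
under-canopy surface-evaporation term (default 0.3 × S_b × E_p, matching
the synthetic world's drying); it is reported as a diagnostic and is not
part of the cell's evaporation total, which follows the
transpiration + bare-soil + interception composition.

Interception is a deliberate simplification of analytical canopy models:
E_i = min(P, c·LAI) with c = 0.2 mm per unit LAI per day; it reduces
infiltration to vegetated columns.

## Training targets and tables

Stress targets are S_t = E_t / E_pt^scaled, clamped to [0, 1] (observed
transpiration can exceed a biased potential; the network's output domain is
[0, 1]). Days with E_pt^scaled ≤ 0.1 mm/day are dropped and counted — the
ratio is unstable near zero. Rain days (P > 0.5 mm, configurable) are
removed before targets are formed, to keep interception loss and wet-sensor
artefacts out of the stress estimates.

E_t comes either from eddy-covariance evaporation partitioned with a
monotone saturating LAI ratio, r = 1 − exp(−k·LAI) (k = 0.6 tall, 0.8
short; any monotone ratio is pluggable), or from per-tree sap flow: daily
volumes per tree are divided by the projected crown area predicted from the
allometry ln A_c = −2.53 + 0.602 ln A_b + 0.0960·MAT − 5.48e−5·MAP
(natural logs, areas in m², MAT °C, MAP mm/yr), averaged per species and
weighted by the stand's basal-area composition (1 cm³ day⁻¹ m⁻² =
10⁻³ mm day⁻¹).

The potential-transpiration bias correction is an affine map matching
E_pt^raw to the observed-transpiration moments on days following rain days
(a dry day immediately after ≥ 1 rain day), under the assumption that
ecosystems transpire at their potential right after rainfall; the map,
fitted on that subset with sample standard deviations (ddof = 1,
configurable), is applied to the whole series. It exactly inverts any
global affine distortion of the potential series when the assumption holds,
which the tests verify on a constructed case. The scaling mode is
configurable (`post_rain`, `full`, `none`); the synthetic world's potential
is undistorted, so its default pipeline uses `none` and the noise-free
world then returns the truth stress exactly.

Seasonal anomalies are departures from a day-of-year climatology smoothed
with a centred circular 31-day moving average (day 366 folded into 365);
raw departures, not z-scores. At least one full year of data is required.

## Network training

The objective is the set-level loss 1 − KGE. Mini-batches of 100 rows are
stepped with Adam (learning rate 1.42e-4) on the analytic gradient of the
batch-level loss (population moments, epsilon-guarded denominators;
gradient verified against finite differences). Rows pool across sites and
split 85:15 into training and validation, seeded. After each epoch the
full-set training and validation objectives are recorded; training stops at
1000 epochs or once the validation objective has not improved for 20
epochs, and the best-epoch weights are restored. Batches with degenerate
(zero-variance) targets are skipped. Runs are deterministic given the
configuration seed on a single thread.

KGE uses population standard deviations throughout (metrics and loss agree
to 1e−12), with r := 0 for a zero-variance prediction — the convention
that makes the constant mean-of-observations benchmark score exactly
1 − √2 ≈ −0.41. The metric errors on zero-mean or zero-variance
observations rather than returning an undefined ratio.

## The synthetic world

The generator fabricates what the model would otherwise need from
flux-tower, sap-flow and satellite archives: daily forcing with seasonal
cycles (temperature with AR(1) noise, cloud-dimmed shortwave, humidity-
derived VPD, VOD/LAI phenology, a slow CO₂ trend), rainfall from a
first-order two-state occurrence chain with exponential depths, and
pseudo-observations produced by evolving a real soil column under a known
ground-truth stress function — a product of a logistic in PAW, exponential
decay in VPD, a thermal optimum, light saturation, sqrt(VOD/VOD_max)
phenology and a weak CO₂ term, clamped to [0, 1]. Observed evaporation is
truth transpiration plus an interception-like term on rain days plus
additive Gaussian noise truncated at zero (default sd 0.05 mm/day).
Sap-flow tables invert the crown-area allometry per tree and spread daily
volumes over a daylight diurnal profile, so upscaling recovers the stand
value exactly.

The default training world pools 50,000 site-days over 20 sites with
distinct climates (mean temperature 4–20 °C, varying wetness); rain-day
filtering and the near-zero-potential cutoff retain roughly 40,000 rows.
Everything is deterministic under the seed.

What passing tests show — and do not. Function recovery (out-of-sample
KGE ≥ 0.9 against the hidden truth; shuffled-target control ≈ 0)
demonstrates that the architecture, loss and protocol can extract a smooth
six-covariate stress signal from noisy targets through the full
table-building pipeline. It does not show that real transpiration stress is
smooth, that satellite retrieval errors are benign, or that the LAI
partition ratio is correct in nature — the world's partition and allometry
are correct by construction.

## Numerical and design choices

- PAW and both stress factors clamped to [0, 1]; behaviour above critical
  moisture (where the unclamped process formula exceeds one) is treated as
  "no limitation".
- The PAW-transect diagnostic sweeps absolute PAW with the other covariates
  at their training medians and the PAW anomaly co-varying with the
  absolute (anomaly = PAW − median climatology); holding the anomaly fixed
  while sweeping the absolute would ask the model about covariate
  combinations that cannot occur.
- Per-layer soil-moisture monotonicity in rainfall holds without
  extraction; with wettest-layer extraction only the column total is
  monotone (extra rain can switch the extraction target between layers).
- Grid runs iterate cells independently; missing forcing days raise rather
  than interpolate.
- The shuffled-target control trains with a 100-epoch cap: with permuted
  targets the validation objective fluctuates around 1 from the start, and
  the cap bounds runtime without affecting the outcome.
- An optional seeded random hyper-parameter search can stand in for a full
  Bayesian search; the default architecture is fixed and exposed entirely
  through `MLPConfig`.

## Problem sizes

Tests and examples use worlds of 5,000–50,000 site-days, networks of
2–3 hidden layers, and coupled runs of 1–2 years; the function-recovery
experiment uses the default 50,000-row world and trains in well under two
minutes on one CPU. The acceptance script evaluates the metric's two
analytic anchor points on a 730-day synthetic record.

## Known limitations

- Soil depths, hydraulic constants and the interception coefficient are
  plausible defaults, not calibrated values.
- The host omits snow, open water, and canopy storage dynamics; the
  simplified interception has no evaporation-during-storm term.
- The learned model is only as transferable as its training covariate
  ranges; the synthetic world samples temperate climates.
- Training on real archives (FLUXNET, SAPFLUXNET, satellite covariates) is
  out of scope; the I/O surface accepts site CSVs and small NetCDF grids
  only.
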