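# hybridevap

A hybrid process/deep-learning model of terrestrial evaporation. A
process-based host — a multi-layer soil water balance coupled to
Priestley–Taylor potential evaporation — exchanges state daily with a
transpiration stress factor that is either a closed-form process function or
a small feed-forward network trained on flux-tower / sap-flow style stress
targets. A seeded synthetic world with a known ground-truth stress function
makes every stage testable end to end, with no external data.

It is written for ecohydrologists and land-surface modellers who want to
experiment with embedding learned sub-models inside a water-conserving host,
and for anyone who needs the building blocks on their own: the stress
formulations, sap-flow crown-area upscaling, Kling–Gupta model scoring, or
the tipping-bucket soil column.

## The model

Actual transpiration is potential transpiration throttled by a stress factor
S_t ∈ [0, 1]:

    E_t = S_t · E_pt,     E_pt from Priestley–Taylor:  E_p = α Δ/(Δ+γ) · Rn/λ

**Process stress** couples microwave vegetation optical depth (VOD) with the
wettest-layer soil moisture w_w:

    S_t = sqrt(VOD / VOD_max) · (1 − ((w_c − w_w)/(w_c − w_wp))²)

with VOD_max the 99th-percentile VOD, w_c critical moisture and w_wp wilting
point. Bare-soil stress is linear in surface moisture:
S_b = 1 − (w_c − w_1)/(w_c − w_r). Plant available water is
PAW = (w_w − w_wp)/(w_c − w_wp).

**Learned stress** is a feed-forward network (default 3 × 64 ReLU units,
sigmoid output) mapping twelve covariates — the absolute values and seasonal
anomalies of PAW, VPD, Ta, SW_in, VOD and CO₂ — to S_t. Its training targets
come from observations, S_t = E_t / E_pt^scaled, where E_t is partitioned
from eddy-covariance evaporation via an LAI ratio (or upscaled from per-tree
sap flow through a crown-area allometry) and E_pt is bias-corrected to the
observed-transpiration moments on days following rain days. Rain days are
removed first. Training minimises 1 − KGE (a set-level objective) with
batches of 100, learning rate 1.42e-4, an 85:15 train/validation split, and
early stopping on the validation objective; one model per vegetation class
(short, tall).

**Coupling.** Each day, per land-cover fraction (tall / short / bare soil,
with three-, two- and two-layer soil columns): the column's PAW joins the
covariates, the stress model converts potential to actual transpiration, and
the extraction updates the column — so tomorrow's stress sees today's
drawdown. Hybrid and process mode differ only in which stress predictor is
plugged in.

**Evaluation** uses the Kling–Gupta efficiency,

    KGE = 1 − sqrt((r−1)² + (σ_sim/σ_obs − 1)² + (μ_sim/μ_obs − 1)²),

with KGE = 1 perfect and KGE = 1 − √2 ≈ −0.41 the score of a constant
mean-of-observations predictor (r := 0 convention) — the benchmark a useful
model must beat.

## Worked example

`examples/03_run_hybrid.py` trains the network on a 12-site synthetic world,
then runs the coupled model both ways over an unseen site:

```
process  mode: KGE vs observed E =  0.355 (r=0.720, alpha=1.454, beta=1.362)
hybrid   mode: KGE vs observed E =  0.857 (r=0.972, alpha=1.083, beta=1.113)
```

The hybrid run replaces only the stress sub-model; the KGE gain (0.36 →
0.86, mainly through the variability ratio α and bias ratio β) shows the
learned stress propagating into better total-evaporation dynamics.
`examples/02_train_stress_model.py` scores the network directly against the
hidden truth function on held-out sites:

```
out-of-sample KGE vs hidden truth: 0.924 (r=0.953, alpha=1.040, beta=1.045)
```

The other examples cover world generation, sap-flow upscaling (an exact
round trip against the generator's allometry) and the metric's anchor
points. A thin CLI chains the whole pipeline:

```
hybridevap all --config examples/demo_config.yaml
```

## Layout

- `src/hybridevap/` — `synthetic` (world generator), `soil` (water balance),
  `pet` (Priestley–Taylor, interception, bias correction), `stress_process`,
  `prep` (training tables), `mlp` (network + 1−KGE training), `coupler`
  (daily loop, site and grid), `metrics`, `config`, `cli`.
- `examples/` — one narrative script per capability.
- `docs/methods.md` — model description, parameter choices, limitations.
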