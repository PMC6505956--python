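# tenurematch

Quasi-experimental evaluation of protected-area effectiveness across
land-tenure regimes, at the forest-pixel level.

## The problem

Protected areas (PAs) are not placed at random: they tend to sit on
remote, steep, high-biomass land that would have faced little clearing
pressure anyway. Naively comparing deforestation inside and outside PA
boundaries therefore conflates the effect of protection with the effect
of location. The same confounding afflicts comparisons *between* tenure
regimes — communally held *ejidos*, private properties, and parceled
ejidos (former ejidos divided into individual holdings) occupy
systematically different land.

`tenurematch` implements the standard quasi-experimental answer for
30 m-pixel forest-loss data: nearest-neighbor matching with replacement
under a Mahalanobis metric (optionally augmented with the linearized
propensity score), propensity trimming to common support, regression
bias adjustment, and balance-driven selection between candidate
estimators. The estimand is the average treatment effect on the treated,

```
ATT = (1/n) Σ_i tt_i,    tt_i = Y_treated(i) − Y_matched control(i),
```

with Y the binary 2000–2014 forest-loss outcome, so a *negative* ATT
means the treatment reduced the probability of forest loss. Effect
heterogeneity along the woody-biomass gradient z (a proxy for old-growth
versus younger forest) is estimated post-matching with a partial linear
model,

```
tt_i = α + x_i'β + f(z_i) + ε_i,
```

fit by the Robinson double-residual scheme with local-linear smoothing
and wild-bootstrap (Mammen weights, percentile-t) pointwise 95% bands
for f. Spillover (leakage) is tested by treating the *unprotected*
pieces of partially protected properties as the treated group against
fully unprotected properties. Significant ATTs convert to avoided
deforestation via |ATT| × n_mc × 0.09 ha × 100 (matched-control pixels,
30 m pixel area, 1% sampling fraction) and to avoided carbon via the
matched-control mean biomass.

Because the real cadastral, PA and forest-change rasters are large and
external, the package ships a first-class synthetic-landscape generator
(`synthgrid`): spatially autocorrelated covariate fields, a Voronoi
property tessellation carrying tenure labels, endogenous PA placement,
outcomes from a known logistic model whose treatment effect τ(z) varies
with biomass, within-property leakage, and — crucially — a stored
counterfactual outcome, so every landscape carries its own ground-truth
ATT for estimator-recovery tests.

## Worked example

```python
import tenurematch as tm

# a 250x250-pixel landscape (30 m cells) with a true protection effect
# of -0.08 on the clearing probability and 30% leakage
cfg = tm.LandscapeConfig(
    grid_width=250, grid_height=250, n_properties=350, seed=1,
    effect_curve_params={"kind": "constant", "value": -0.08},
    leakage_rate=0.3)
landscape = tm.generate_landscape(cfg)
print(f"ground-truth ATT (oracle): {tm.oracle_att(landscape):+.4f}")

frame = tm.build_frame(landscape.to_pixel_table(), fraction=0.4, seed=1)
for biome in ("dry", "moist"):
    est = tm.run_comparison(
        frame.sample, tm.ComparisonSpec(question="A", biome=biome),
        spillover_pool=frame.spillover_pool)
    ...
```

prints

```
ground-truth ATT (oracle): -0.0800
estimation sample: 8992 pixels (+308 in the spillover pool)
dry  : raw ATT -0.109, bias-adjusted -0.070 (SE 0.040, 95% CI [-0.149, +0.008]), n_t=256, n_mc=101, n_cp=3925
moist: raw ATT -0.064, bias-adjusted -0.058 (SE 0.039, 95% CI [-0.136, +0.019]), n_t=326, n_mc=107, n_cp=4099
avoided deforestation (dry): 64.0 ha ~ 3,072 tC avoided emissions
```

Reading this: the true effect of protection in the generator is a
−0.08 change in each treated pixel's clearing probability. Matching
protected pixels to observationally similar unprotected pixels (never
from the same property, within biome) recovers bias-adjusted ATTs of
−0.070 and −0.058 — both within one standard error of the truth.
`n_t, n_mc, n_cp` count treated pixels on common support, distinct
matched controls, and the control pool. The last line converts the dry
ATT into hectares of avoided loss and tonnes of avoided carbon for the
whole landscape (the sample is 1%-style scaled by the extrapolation
module).

The comparison grid mirrors the full study design: question `A`
(protected vs unprotected, any tenure), `B` (within one tenure regime),
`C` (one tenure vs another, within a protection stratum) and
`spillover` (unprotected parts of protected properties vs fully
unprotected properties). `run_pipeline` / the `tenurematch` CLI
(`simulate`, `frame`, `all`, …) run every comparison, the post-matching
partial linear models, and the impact accounting, writing each
intermediate table plus a manifest to a run directory:

```sh
tenurematch all --config cfg.yml --out runs/demo
```

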