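# canolux

Canopy-size and light-use-efficiency analysis for controlled-environment
(vertical-farm) crop trials.

Why do some leafy greens grow faster than others under the same electric
light?  Two quantities explain most of it: how much light a plant actually
intercepts — which depends on its **projected canopy size** (PCS, the
plan-view silhouette area, cm² plant⁻¹) — and how efficiently it turns the
intercepted light into biomass — its **light use efficiency** (LUE, grams of
shoot dry weight per mol of incident photons).  `canolux` implements the
full measurement chain for a two-species, multi-PPFD trial, such as a
mizuna / lettuce comparison across six photosynthetic photon flux densities:

1. **Segmentation** (`canolux.imaging`) — top-down fluorescence-style canopy
   images are thresholded (Otsu or fixed) into plant / background;
   PCS per plant is the foreground area divided by the group size (9).
2. **Growth model** (`canolux.growth`) — each unit's PCS time series is
   fitted with the three-parameter logistic
   `f(x) = a / (1 + exp(−(x − x0)/b))`
   (`a` asymptotic PCS, `x0` inflection day, `b` time constant) and
   evaluated at every day of the crop cycle.
3. **Light budget** (`canolux.light`) — treatment PPFD × photoperiod gives
   the daily light integral, `DLI = PPFD × 3600 s h⁻¹ × h / 10⁶`
   (mol m⁻² d⁻¹); daily PCS × DLI, summed over days 0..harvest, gives the
   total incident light per plant (mol).
4. **Traits** (`canolux.traits`) — `LUE = dry weight / incident light`,
   `SLA = leaf area / dry weight`, `overlap ratio = leaf area / PCS at
   harvest` (≥ 1 when leaves overlie the canopy footprint).
5. **Statistics** (`canolux.stats`) — per trait, OLS with PPFD continuous
   and species categorical; the species × PPFD interaction is pruned when
   not significant at α = 0.05.  Univariate response curves (linear,
   quadratic, exponential rise to maximum, sigmoid) and the early-PCS vs
   final-dry-weight correlation are included.

A **synthetic-experiment generator** (`canolux.synthetic`) renders
ground-truthed canopy images and tables for the full 2 species × 6 PPFD ×
3 block design, so every stage's recovery error is measurable.
`canolux.pipeline.run_pipeline` (or the `canolux` CLI) chains everything
deterministically from one seed.

## Worked example

Render a nine-plant canopy image at a known PCS, segment it, and fit the
growth curve (`examples/02_segment_and_fit.py`):

```text
requested PCS        : 240.00 cm2/plant
rendered ground truth: 239.11 cm2/plant
segmented (Otsu)     : 239.11 cm2/plant (threshold 36)
drawn leaf area      : 1198 cm2/plant (~ overlap ratio x PCS)

generating sigmoid : a=340.0 cm2, x0=18.0 d, b=3.0 d
recovered fit      : a=340.0 cm2, x0=18.00 d, b=3.00 d (R^2=1.00000)
```

The renderer hits the requested projected area to ~0.4%, Otsu segmentation
recovers the rendered mask exactly on clean images, and the logistic fit
returns the generating parameters.  The drawn (pre-occlusion) leaf area of
~1200 cm² at a projected 240 cm² realises the overlap ratio of 5 typical of
a lettuce canopy at high PPFD.

The light budget for a mizuna unit at PPFD 210 µmol m⁻² s⁻¹
(`examples/03_light_budget_and_lue.py`): DLI 12.10 mol m⁻² d⁻¹, total
incident light 3.955 mol plant⁻¹ over 28 days, and with 5.0 g dry weight a
LUE of 1.26 g mol⁻¹.

Other examples: `01_simulate_experiment.py` (build the synthetic trial),
`04_species_ppfd_regression.py` (interaction pruning; recovers the
generating Φ_PSII slope −0.0003 with a ~0.05 species offset),
`05_full_pipeline.py` (end-to-end run with recovery diagnostics, showing
mizuna LUE > lettuce LUE at every PPFD).

## Command line

```sh
canolux simulate --out data --seed 42
canolux segment  --manifest data/manifest.csv --out pcs_long.csv
canolux fit      --pcs pcs_long.csv --harvest-days mizuna=27,lettuce=28
canolux light    --treatments data/treatments.csv --daily pcs_daily.csv
canolux traits   --harvest data/harvest.csv --light incident_light.csv --fits sigmoid_fits.csv
canolux stats    --traits traits.csv --physiology data/physiology.csv
canolux run      --out run_dir --seed 42        # all of the above
```

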