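# Methods

## The measurement chain

The package quantifies crop growth in a controlled-environment trial as the
product of two factors: light capture, driven by projected canopy size
(PCS), and light use efficiency (LUE).  The chain is

    images ──segment──► PCS(tᵢ) ──fit──► a, x0, b ──evaluate──► PCS(d), d = 0..H
    PPFD, photoperiod ──► DLI
    incident(d) = PCS(d)·10⁻⁴ · DLI      [mol plant⁻¹ d⁻¹]
    I = Σ_d incident(d)                   [mol plant⁻¹]
    LUE = DW / I,  SLA = LA / DW,  overlap = LA / PCS(H)

with DW the shoot dry weight (g plant⁻¹), LA the leaf area (cm² plant⁻¹)
and H the harvest day (27 d after seeding for mizuna, 28 d for lettuce).

### Segmentation

Images are single-channel with bright plant tissue on a dark background
(the contrast a chlorophyll-fluorescence imaging rig produces; the
synthesizer emulates exactly this contrast).  The default threshold is
Otsu's method, with a fixed-threshold override for batch reproducibility.
8-connected components below `min_object_px` (default 25 px) are removed as
speckle.  Areas are pure pixel counts × `pixel_scale²` — no sub-pixel
boundary correction, matching the precision of a manual ImageJ-style
workflow.  Plants are not individually delineated: PCS per plant is the
group total divided by the group size (9), i.e. a group mean.  A blank
image under Otsu raises an explicit "no bimodality" error rather than
silently reporting zero area.

### Growth model

PCS over days after seeding follows the three-parameter logistic
`f(x) = a/(1 + exp(−(x − x0)/b))`.  Fits are per experimental unit
(species × PPFD × block) by bounded trust-region nonlinear least squares
(`scipy.optimize.curve_fit`), with analytic initial guesses
(a₀ = 1.05·max PCS; x0₀ = day nearest half-max; b₀ = span/6), bounds
a ∈ (0, 10·max PCS], b ∈ [0.1, 30] d, x0 within the observed span ± 10 d
(precludes flat-line/step degenerate optima), and up to 5 jittered restarts.
The convergence flag is honest: persistent failure raises, carrying the
best attempt.  Day convention: day 0 = seeding; the daily series is the
fitted curve at integer days 0..H inclusive.  The days-0..3 contribution is
negligible (sigmoid tail) but the inclusive-from-zero convention is stated
rather than assumed.

### Light budget

`DLI = PPFD × photoperiod × 3600 / 10⁶` exactly.  Incident light uses
discrete daily summation — not continuous quadrature — because the daily
series itself is the object of interest; the test suite checks the sum
against a 1000-point quadrature oracle over the matching span
[−0.5, H + 0.5] (each day-sample tiles a unit-width bin) and agrees within
2%.  Calculations use the measured tray-centre PPFD means
(53, 128, 210, 281, 345, 410 µmol m⁻² s⁻¹); the round nominal labels
(50…425) are display-only, because the published DLIs derive from the
measured means.

### Traits

All three traits are exact quotients at the experimental-unit (9-plant
group) level.  `pcs_at_harvest` is the sigmoid prediction at H (not the
last raw image), for consistency with the daily series that denominates
incident light; a raw-image alternative is available by supplying a
different `pcs_at_harvest` table.  Overlap ratios < 1 are physically odd
(leaf area smaller than the footprint) and are logged as warnings, not
rejected — they can arise from measurement error.

### Statistics

Per trait: OLS with PPFD continuous and species as a two-level dummy
(lettuce = 0 by default), first with the species × PPFD interaction; if the
interaction p ≥ α (default 0.05) the additive model is refitted and
reported.  When the interaction is retained, per-species slopes are taken
from the interaction model.  On a zero-residual (perfect) fit the t
statistic for the interaction is degenerate, so the rule falls back to the
coefficient's magnitude: numerically zero ⇒ additive.  The split-plot
blocking of the physical design is simplified to fixed effects — block can
be added as a fixed covariate — with no random-effects machinery, matching
how such trials are commonly summarised with plain multiple regression.
Two-sided t-based p-values; no multiple-testing correction.

## Synthetic experiment generator

The generator emulates a mizuna/lettuce trial: 6 PPFD levels at a 16-h
photoperiod, 2 species, 3 blocks, groups of nine plants imaged twice a week
(days 4, 7, 11, 14, 18, 21, 25 plus the day before each harvest — 8 points,
comfortably above the 4-point minimum for a 3-parameter fit).

Species parameter defaults (all overridable) anchor to the reference trial:

| quantity | mizuna | lettuce |
|---|---|---|
| PCS asymptote, high PPFD | 340 cm² (PPFD ≥ 210) | 240 cm² (PPFD ≥ 128) |
| sigmoid x0, b | 18 d, 3 d | 19 d, 3.5 d |
| CCI slope / intercept | 0.08 / 3.0 | 0.01 / 1.5 |
| ACI slope / intercept | 0.015 / 2.25 | 0.004 / 1.8 |
| Φ_PSII slope / intercept | −0.0003 / 0.77 | −0.0003 / 0.72 |
| assimilation slope / intercept | 0.044 / −1.2 | 0.035 / −0.75 |
| LUE (g mol⁻¹), low→high PPFD | 1.26 → 0.75 | 0.60 → 0.74 → 0.60 |
| overlap ratio, low→high PPFD | 1.1 → 2.3 | 1.2 → 5.2 |
| harvest day | 27 | 28 |

Documented assumptions where no anchored value exists: the PCS asymptote at
PPFD 53 is 25% of the species maximum ("much lower" is all that is known);
Φ_PSII intercepts are chosen to keep the +0.05 species offset and the
−0.0003 slope inside (0, 0.85) over the PPFD range; intermediate LUE and
overlap values interpolate between reported endpoints; physiology
intercepts follow from the slope and a known level at PPFD 50 (e.g. CCI ≈ 7
at PPFD 50 for mizuna ⇒ intercept 3.0).  The printed slopes are treated as
exact and the endpoint levels as approximate where the two disagree after
rounding.

Noise is group-level (only 9-plant group means are observable, so
within-group variance is not modelled): multiplicative lognormal on PCS
(cv 0.05) and dry weight (cv 0.07), parameterised with mean exactly 1 so
noise-free identities hold in expectation and exactly at cv = 0; additive
Gaussian on physiology (sd: CCI 2.0, ACI 0.4, Φ_PSII 0.02, assimilation
0.8), chosen so the regressions land in the clearly-significant regime
typical of such trials.  Φ_PSII draws are clamped to (0, 0.85).
Ground-truth identities before noise: DW = LUE × true incident light;
LA = overlap ratio × PCS(H); PCS(x0) = a/2.  One seed reproduces every
file byte-for-byte.

### Rosette renderer

Each plant is a rosette of elliptical "leaves" (aspect 2.5, golden-angle
phyllotaxis) on a dark background (foreground 200, background 20 grey
levels, optional Gaussian sensor noise).  Two areas are controlled at once:
the union (projected) area must equal the requested PCS, and the summed
per-leaf (pre-occlusion) area must be ≈ overlap ratio × PCS.  Leaf count is
⌈3 × overlap ratio⌉ (minimum 6) with per-leaf area fixed at
overlap × PCS / n — this pins the drawn total — and the radial spread of the
leaves is then bisected until the union hits the target: spread 0 stacks
all leaves (union ≈ one leaf-length disk, below target by construction of
n), large spread disjoins them (union ≈ overlap × PCS, above target).  A
final uniform leaf rescale absorbs rasterisation granularity (it preserves
the drawn/union ratio).  Achieved accuracy is ~0.4% on the union across
PCS ∈ [10, 400] cm² and ~2–3% on the drawn area.  All nine plants of a
group share the group-mean PCS, so one solved rosette is stamped under
random dihedral transforms — pixel-count exact and visually varied.

## What the generator does and does not emulate

It reproduces the design (treatments, blocks, cadence), the effect sizes,
the sigmoid trajectory shape, the image contrast regime and the causal
identities linking DW, incident light and LUE.  It does **not** emulate:
optical physics of fluorescence excitation (vignetting, blur, specular
soil); plant-to-plant variation within a group; temporal noise correlation
along a trajectory; PPFD gradients within a tray; or a causal link between
a unit's realised (noisy) canopy trajectory and its dry weight — DW derives
from the *true* curve, so early-PCS/dry-weight correlations across units
reflect shared PPFD dependence plus independent noise, not within-treatment
co-variation.  One consequence: because the lettuce PCS asymptote is
identical at the five upper PPFDs (its canopy size plateaus there), the
attainable lettuce early-PCS/final-DW correlation is capped near ~0.77,
below the ~0.9 a real trial shows where plants' own trajectories drive
their own biomass.  Passing tests therefore demonstrate correctness of the
analysis chain, not field realism of the data.

## Numerical choices and degenerate inputs

- Flat (zero-variance) PCS trajectories raise "no growth signal"; fits need
  ≥ 4 distinct days.
- Segmentation thresholds are strict (`> t`), making foreground counts
  monotone non-increasing in the threshold.
- Response-curve fits allow exact interpolation (n = number of parameters),
  so a two-point linear "fit" — the slope between two printed endpoints —
  is legal and returns R² = 1.
- A constant regression response returns zero slopes with R² = 0 rather
  than failing.
- Incident-light integration is linear in DLI and in uniform PCS scaling to
  round-off.
- Problem sizes in tests and in the acceptance script are the design's own:
  36 units, 8 imaging days, 50-seed fit-quality sweeps, 500-run type-I
  simulations; everything runs in seconds on one core.

## Known limitations

- Incident ≠ absorbed light: no leaf absorptance, so LUE here is per mol
  *incident* on the footprint; electron-transport rates are out of scope.
- No perspective/lens correction, no leaf-level instance segmentation, no
  multispectral support.
- Uncertainty from the sigmoid fit is reported as residual SD only, not
  propagated into LUE.
- The regression is plain OLS; a true split-plot mixed model would give
  different (typically wider) interval estimates for main-plot effects.
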