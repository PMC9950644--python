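# Methods

## Problem and approach

Canopy stomatal conductance (Sc, mol·m⁻²·s⁻¹) falls as irrigation deficit
grows, while canopy reflectance in the red-edge (725 nm) and NIR (808 nm)
bands rises and the canopy surface roughens. The package estimates per-tree
Sc from 4-band imagery by chaining gray-panel calibration, canopy/background
segmentation, vegetation-index and GLCM texture extraction, best-subset
predictor screening under BIC, and three regression families (SVR, random
forest, k-nearest neighbours) compared on VI-only, texture-only and combined
feature sets over a stratified 7:3 split.

## Synthetic study conditions

Real imagery for this design is not publicly available, so a generator
renders the study conditions with exact ground truth. What it emulates, and
what it deliberately does not, bounds what passing tests demonstrate.

**Treatments.** Four irrigation levels: T1 = 100 % of field capacity,
T2/T3/T4 = 80/65/50 %. Scenes default to four trees, one per treatment.

**Spectra.** Canopy band means (unitless reflectance):

| treatment | 560 | 650 | 725 | 808 |
|-----------|-----|-----|-----|-----|
| T1 | 0.08 | 0.05 | 0.28 | 0.42 |
| T2 | 0.08 | 0.05 | 0.31 | 0.45 |
| T3 | 0.08 | 0.05 | 0.35 | 0.48 |
| T4 | 0.08 | 0.05 | 0.39 | 0.53 |

Green/red are stress-invariant; red-edge/NIR rise monotonically. The values
are plausible for dense green citrus canopy; no numeric fidelity to any
field measurement is claimed — only the qualitative ordering. Soil is
spectrally distinct (0.12/0.18/0.22/0.25), i.e. brighter in red and darker
in NIR than canopy.

**Geometry.** Trees are irregular blobs (greedy top-k pixels of a
union-of-disks score field), so masks have complex boundaries like real
canopies; each tree claims exactly its target pixel count, making the scene
canopy fraction (default 0.35) exact to one pixel. A gray reference panel
(default reflectance 0.5 per band) occupies the top-left corner.

**Texture.** Within-canopy variation is a Gaussian random field smoothed to
correlation length `texture_grain` (default 3 px) and scaled by
`noise_sd` (default 0.02 reflectance units). Stress both amplifies the
field (gains 1.0/1.2/1.4/1.6) and *shortens its correlation length*
(factors 1.0/0.85/0.70/0.55). The second mechanism matters: texture
statistics are computed on per-tree min-max quantised images, and min-max
quantisation is invariant to pure amplitude scaling, so amplitude alone
carries no GLCM signal. Shortening the correlation length produces the
expected qualitative pattern — 808 nm GLCM correlation (COR) falls with
stress (hence correlates positively with Sc) while contrast/dissimilarity
rise (negative with Sc) — and concentrates the usable texture signal in the
NIR band, because only the canopy noise field (not the soil) is
stress-modulated and the NIR stress contrast is largest.

**Colour composite.** The RGB image used for HSV and visible-VI
segmentation is a fixed transform of the visible bands: saturated green for
canopy (hue ≈ 100°), desaturated brown for soil (hue ≈ 20°), plus two
deliberate confounders a colour segmenter must survive: ochre "litter"
patches on ~6 % of soil (hue just below the green gate, moderate greenness)
and a dark canopy-cast shadow rim (greenish chromaticity, value ≈ 0.05).
The shadow rim is a trap for greenness-only thresholds — excess green
depends only on the green chromatic fraction, not brightness — while the
HSV value gate rejects it. This is a synthetic stand-in: how the study
system produced its colour imagery is unknown, so segmentation scores on
these scenes demonstrate correct mechanics and the expected method ordering
(HSV above EXG-Otsu), not field performance.

**Stomatal conductance.** Per-treatment truncated normals on
[0.0080, 0.0245] with means 0.0195/0.0170/0.0140/0.0112 and common SD
0.0022, chosen so a balanced 120-sample campaign pools to mean ≈ 0.0154 and
SD ≈ 0.0037. Sc depends on treatment only (plus noise), not on pixels:
features inherit the stress signal through the spectral/texture generators,
matching the causal structure the analysis assumes.

**Not emulated:** radiative transfer, leaf angles, solar geometry,
illumination gradients, registration error, mixed pixels at sub-pixel
scale. Passing tests therefore validate algorithmic correctness and the
designed statistical structure, not robustness to those effects.

A feature-space twin (`generate_feature_table`) samples the same structure
directly (band means + noise → indices; texture statistics as
stress-trended Gaussians, signal confined to 808 nm) for fast modelling
experiments, and `plant_linear_response` overwrites Sc with a known linear
signal on chosen predictors at a requested signal-to-noise ratio (SD ratio;
default 3, so the planted model's own R² ≈ 0.9) for recovery benchmarks.

## Numerical and design choices

**Calibration.** R₁ = (DN₁/DN₂)·R₂ per band; output clipped to [0, 1] by
default with clipped pixels counted (specular pixels can exceed the panel).
The panel DN is the mean over the plate interior, inset on each side by a
margin fraction of the half-extent (default ⅓, ceiling-rounded so
degenerate margins fail loudly) — the pixel-space analogue of sampling away
from the plate rim, since ground-sample distance is not modelled.

**Segmentation.** HSV gates default to H ∈ [35°, 120°], S ∈ [0.15, 1],
V ∈ [0.1, 1] (green vegetation); hue wrap-around is supported. Otsu runs on
an equal-width histogram between the data min and max (default 256 bins);
the returned threshold is the lowest bin edge within 1e-9 relative
tolerance of the maximal between-class variance — cuts sweeping empty bins
tie exactly in exact arithmetic, and the tolerance makes the tie-break
stable in floating point. VI-Otsu mask polarity labels the class with
higher mean excess green as canopy, so sign-flipped indices behave
identically. Both methods finish with a morphological open/close of radius
1 (configurable). ACC is intersection-over-reference (recall-like), kept
as the headline "accuracy" for comparability; plain pixel accuracy is
reported alongside. MCC is 0 with a degeneracy flag when any confusion
marginal is empty.

**GLCM.** Defaults: 32 gray levels, distance 1, four directions (0/45/
90/135°) pooled, symmetric. Quantisation is equal-width between the masked
min and max; pixels outside the canopy mask are excluded from pairs, and
texture is computed per tree over its bounding box. Gray levels are indexed
from 0; this shifts MEA/VAR absolute values relative to a 1-based
convention but no contrast-type statistic or any downstream model. Entropy
uses the natural log. Homogeneity uses 1/(1+(i−j)²), correlation uses
(Σ i·j·p − μxμy)/(σxσy) with COR := 0 flagged when a marginal SD vanishes. A
perfectly flat region returns the degenerate limits (HOM = SEC = 1, all
else 0) rather than failing, so noise-free scenes stay processable.

**BIC.** Gaussian profile likelihood, BIC = n·ln(RSS/n) + k·ln(n), dropping
the additive constant n(ln 2π + 1) that cancels in all comparisons; k
counts intercept + slopes. Absolute BIC magnitudes are therefore
convention-dependent; `relative_to_null=True` reports BIC minus the
intercept-only model's, the convention of R's best-subset summaries. An
exact fit (RSS = 0) maps to −∞ so it wins every comparison. Screening is
exhaustive (2ᵖ − 1 fits, guarded at p ≤ 25) on centred sufficient
statistics — subset RSS needs only the centred Gram matrix — with ties
broken toward smaller subsets, then lexicographically. A 19-candidate full
screen is ~0.5 M fits and runs in seconds.

A known statistical property, not a defect: with ~8 spurious candidates at
n = 100, minimum-BIC selection admits a noise variable whenever its
scale-free RSS improvement (≈ χ²₁) exceeds ln n, so the exact-support
recovery rate of a planted two-variable model plateaus near
(1 − P[χ²₁ > ln 100])⁸ ≈ 0.77 *regardless of SNR*; the true support is
essentially always *contained* in the selection. Tests assert containment
plus a realistic exact-recovery floor.

**Regression.** SVR: RBF, C = 1, γ = 2. RF: 50 trees, seeded. KNR: 5
neighbours, uniform weights, Euclidean — "library defaults" pinned
explicitly since defaults are toolkit-dependent. Two scaling choices are
deliberate. (i) Features for SVR/KNR are min-max rescaled to [0, 1] on the
modelling set only: with γ = 2, z-scored features put typical squared
pairwise distances near 2·d ≈ 10 and the kernel collapses toward the
identity (validation R² ≈ 0.25 on the planted benchmark), while [0, 1]
features keep it informative (≈ 0.8). The forest sees raw features. (ii)
SVR's response is z-scored (inverse-transformed for reporting): its default
ε-tube of 0.1 dwarfs conductance values (~0.015), otherwise yielding a
constant predictor. The split is a single seeded 7:3 partition
(84/36 at n = 120), optionally stratified by treatment; a k-fold utility is
provided but not part of the headline design. R² may be negative on
validation (model worse than the mean); this is reported, not clipped. A
`low_sc_bias` diagnostic (mean residual in the lowest measured quartile)
quantifies the over-prediction of low conductance.

**Pipeline.** One global seed is fanned out per stage by hashing the stage
name (SHA-256, reduced below 2³¹), so stages are independently reproducible
and a re-run reproduces artifact checksums bit for bit. Stage failures
abort with the stage name; artifacts already written are kept.

**Problem sizes.** Default campaign: 30 four-tree scenes of 128×128 px
(120 trees), matching the designed 84/36 split; oracle cross-checks use
200 random instances each (images ≤ 16×16, ≤ 8 gray levels for the
brute-force GLCM); the planted-signal modelling benchmark uses 50
replicates and the support-recovery benchmark 100 replicate screens. These
sizes were chosen so the entire suite and the reproduction script each run
in minutes on a single core while keeping Monte-Carlo error well below the
margins being asserted.

## Limitations

- Segmentation and modelling scores on synthetic scenes transfer to real
  imagery only insofar as the generator's assumptions hold; the colour
  composite and its confounders are stand-ins, not reconstructions.
- Texture features are computed per tree over bounding-box canopy pixels;
  real studies must also choose windowing, resolution and quantisation, all
  of which materially affect GLCM statistics.
- No hyperparameter search: the three model families run at fixed,
  documented settings, so comparisons are between those settings, not
  between families at their respective best.
- The HSV thresholds are sensible defaults for green vegetation, not fitted
  values; they are first-class configuration.
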