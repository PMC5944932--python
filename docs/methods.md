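# Methods

## The phantom model

A phantom emulates one high-power field of Ki-67-stained tissue: brown
(DAB-positive) and blue (hematoxylin-counterstained) nuclei scattered over a
bright, slightly noisy background. It is *not* a physical model of staining —
colours are palette draws, not Beer–Lambert chromogen mixtures — but it
preserves the properties that matter for validating enumeration methods:
realistic crowding and overlap, variable stain intensity and cell size, and,
crucially, an exactly known count and pixel-level class mask for every
nucleus.

### Object library

The default library is procedural: 50 positive and 40 negative objects, each a
single ellipse-shaped nucleus or a clump of 2–5 overlapping ellipses.

| parameter | default | rationale |
|---|---|---|
| ellipse axes | uniform 14–26 px | nuclei of 14–26 px diameter crowd realistically at the ~33 px grid pitch |
| clump overlap | 10–40% of the smaller nucleus | overlapping cells make segmentation non-trivial; found by bisection on the rasterised intersection |
| palette centres | brown (150, 90, 50), blue (70, 80, 150) | DAB vs hematoxylin hues, far from the background in every channel |
| per-object colour jitter | ±15/channel | staining-intensity variation between cells |
| per-nucleus jitter, texture noise | ±10/channel, σ = 8 | visual separation of clump members; chromatin-like graininess |

Object #1 of each class is always a single nucleus so the exact-count sampler
below can terminate for any target. Each object keeps one mask per constituent
nucleus; their union is the object mask. A library of real RGBA crops with a
JSON manifest can be substituted; clumps without per-nucleus masks are
rejected, because the ground truth would stop being exact.

### Synthesis

1. Canvas of `canvas_size²` px (default 1000²); each channel of each pixel an
   independent uniform integer in `[bg_low, bg_high]` (default [190, 250]).
2. `grid_n²` candidate locations (default 900) at the centres of a regular
   grid — base point `(⌊(a−½)·canvas/grid_n⌋, ⌊(b−½)·canvas/grid_n⌋)` so the
   margins are half a cell — each perturbed by independent integer offsets in
   `[−jitter, +jitter]` (default ±11) and clamped to the canvas.
3. Positive objects are drawn uniformly with replacement until their nucleus
   counts sum **exactly** to `round(G·total/100)` (ties round up); when fewer
   than 5 nuclei remain, the draw is restricted to objects that still fit. A
   clump may therefore never overshoot: the phantom is a reference standard
   only if its count is exact. Negative objects fill the remainder the same
   way.
4. Each object is rescaled by a uniform factor from `scale_range` (default
   [0.8, 1.25], roughly symmetric on the log scale), placed with its mask
   centroid on a uniformly chosen free grid location — locations where the
   scaled patch would cross the border are redrawn, since a clipped nucleus
   would make the count ambiguous — and composited by its mask. Later objects
   overwrite earlier ones; the class mask resolves overlaps identically, so
   overlapping nuclear pixels are counted once.
5. Gaussian smoothing (σ = `smoothing_sigma`, default 1.0) is applied only on
   a 2-px band around object boundaries (dilation XOR erosion of the
   foreground with a 3×3 element). Band-limited smoothing softens the pasted
   edges without invalidating the ground-truth masks.

One `numpy` PCG64 generator seeded from the spec drives background, jitter,
draws, scales and placement in that fixed order, so a (spec, library) pair
regenerates byte-identically. Note the background consumes a
range-dependent number of raw random words, so two specs differing in any
field generally diverge in *all* later draws; reproducibility is per-spec, not
per-stage, within one phantom.

### Dataset design

The default dataset has 42 images in ten `r_n` bins of width 10 percentage
points with counts (4, 4, 7, 4, 5, 6, 3, 3, 3, 3); the last bin is closed at
100. `G` is drawn uniformly within each bin and redrawn in the rare case
where rounding to an integer nucleus count would push the exact ratio out of
the bin (e.g. G = 9.99 rounds to r_n = 10.0).

## Ratios

For one image: `r_n = 100·n⁺/n`, `r_a = 100·A⁺/(A⁺+A⁻)`,
`r_t = 100·A⁺/canvas²`, where counts come from ground truth and areas are
class-mask pixel counts (overlaps counted once, attributed to the top
object). All three are reported in percent. `r_n` is undefined (an error) for
zero total nuclei.

## Area-to-count calibration Ψ

`D = r_a − r_n` is a smooth function of `r_a`: structurally zero at the
homogeneous extremes (`r_a` → 0 or 100) and largest at intermediate mixing —
it measures heterogeneity. It is approximated by a quadratic
`Ψ(r_a) = a·r_a² + b·r_a + c`, fitted by ordinary least squares of observed D
on the polynomial basis, giving `r̂_n = r_a − Ψ(r_a)`, clamped to [0, 100].
The residual SD uses the sample (n−1) denominator. The 95% band around Ψ is a
pointwise OLS *prediction* interval (Student-t, n−3 df).

The held-out protocol evaluates the calibration as it would be used: hold out
one image per ratio bin at random (10 test images), fit on the remainder (32
with the default design), and report the sample SD of `r_n − r̂_n` on the
held-out images. The calibration is specific to the image class it was fitted
on; applying it to another stain or tumour type requires refitting.

## Agreement statistics

- **Lin's CCC** `= 2·cov(x,y) / (var x + var y + (mean x − mean y)²)` with
  population (1/n) moments; 95% CI from Lin's asymptotic variance on the
  Fisher z scale. CCC ≤ |Pearson| by construction (it multiplies Pearson by a
  bias-correction factor ≤ 1).
- **Pearson / Spearman** points from scipy; CIs via the Fisher transform with
  the standard 1/(n−3) variance. Degenerate cases (|r| = 1, n ≤ 3) collapse
  the CI to the point estimate or the full range rather than producing NaNs.
- **Bland-Altman**: differences are estimate − truth; limits of agreement are
  bias ± 1.96 × sample SD.
- **R² decomposition** (statsmodels OLS): total R² from the two-predictor fit
  on (r_n, r_a); a predictor's semi-partial R² is total R² minus the other
  predictor's single-predictor R².
- Panels: readers are scored on r_n and r_t directly; for r_a the reader's
  r_n estimate is used as a surrogate, probing whether readers asked for a
  count ratio are really judging an area fraction.

SD conventions: population (1/n) moments inside CCC; sample (n−1) SD for bias
rows and residuals.

## Image-only estimator

A pixel is **background** when it is bright overall (min channel ≥ `bg_low`,
default 190) or nearly so (min channel ≥ `bg_low − margin`, default margin 40)
with channel spread ≤ `spread_max` (default 60); otherwise it is **positive**
when R − B > δ (default 15), **negative** when B − R > δ, and ties go to the
nearer palette centre. The thresholds follow from the phantom's design: the
background's min channel is ≥ 190 and its spread at most 60, while both
nucleus palettes keep every channel well below 150. The two-clause background
rule exists for the smoothing band, where blurred pixels drift between the
classes; the outer, background-dominated part of the band is reabsorbed by the
margin clause. On default phantoms the pixel classification agrees with the
ground-truth class mask on ≳ 99% of pixels; the boundary band is the dominant
error source. A deliberate non-goal: no per-nucleus detection, counting or
clump splitting — the point of Ψ is that areas suffice.

Because the estimator's systematic area bias is smooth in `r_a`, the
quadratic calibration absorbs it; this is why Ψ is fitted on *estimated*
`r_a` against *true* `r_n` in the end-to-end workflow.

## Problem sizes and numerical choices

- Default study: 42 images of 1000² px, 900 nuclei each; the full loop
  (generation → classification → calibration → scoring) runs in well under a
  minute on one CPU. Unit tests use a reduced 300² / 100-nuclei spec.
- Tie-break in count rounding: half rounds up. Mask scaling uses
  nearest-neighbour, image scaling bilinear. Degenerate downscale of a
  1-px object keeps one pixel.
- Seeds: the study runner fans a top-level seed out to per-stage child seeds
  by fixed offsets (library +1, dataset +2, held-out draw +3, mod 2³¹).

## What the phantom does and does not show

Passing tests on phantoms demonstrates correctness of the *measurement and
calibration machinery* against exact truth. The phantom lacks tissue
architecture (ducts, lobules, vessels, stroma), staining artifacts,
out-of-focus blur, and spatial clustering beyond uniform placement; the
procedural objects lack nucleoli and chromatin texture. Performance numbers
on phantoms are therefore an upper bound, not a claim about clinical images,
and any colour-threshold estimator tuned to this palette must be re-derived
(e.g. via stain deconvolution) for real slides.
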