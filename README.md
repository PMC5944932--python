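# ihcphantom

Synthetic Ki-67 immunohistochemistry (IHC) images with **exact** per-nucleus
ground truth, plus the statistical machinery to score readers and algorithms
against that truth.

## Why a digital phantom?

The Ki-67 labeling index — the fraction of tumor nuclei staining positive for
the proliferation marker — guides therapy decisions, yet the "ground truth"
used to validate automated nuclei counters is almost always produced by
pathologists, who are slow, expensive and disagree with each other. A *digital
phantom* inverts the problem: generate images that look like stained tissue but
whose positive and negative nucleus counts are known exactly by construction.
Readers and algorithms can then be scored against an indisputable reference
standard.

`ihcphantom` provides:

- an **object library** of brown (DAB-positive) and blue
  (hematoxylin-counterstained) nucleus objects — single nuclei and clumps of
  2–5 overlapping nuclei — drawn procedurally by default (50 positive, 40
  negative) or loaded from RGBA crops;
- a **phantom generator**: a 1000×1000 canvas with uniform-noise background in
  [190, 250], 900 jittered grid locations (±11 px), and objects sampled with
  replacement until the positive nucleus count hits `round(G·900/100)`
  *exactly*, then composited, randomly scaled, and edge-smoothed;
- the three **ratios** per image (all percent): the count ratio
  `r_n = positive nuclei / total nuclei`, the area ratio
  `r_a = positive nuclear area / total nuclear area`, and
  `r_t = positive nuclear area / image area`;
- a quadratic **area-to-count calibration**
  `Ψ(r_a) = a·r_a² + b·r_a + c ≈ D = r_a − r_n`, so that
  `r_n ≈ r_a − Ψ(r_a)` — replacing expensive nucleus detection with cheap area
  measurement — with a one-image-per-bin held-out evaluation protocol;
- **agreement statistics**: Lin's concordance correlation coefficient (CCC)
  with 95% CI, Pearson and Spearman correlations with CIs, bias ± SD,
  Bland-Altman series, and a total / semi-partial R² regression decomposition;
- a baseline **image-only estimator** (colour-rule pixel classification) that
  closes the validation loop end to end.

## Worked example

Generate one phantom with 40% positive nuclei:

```bash
$ ihc-phantom generate --positive-pct 40 --seed 7 --out demo
phantom.png: 360 positive / 900 nuclei; r_n=40.00% r_a=39.99% r_t=9.55%
```

Exactly 360 of the 900 nuclei are Ki-67 positive (`r_n` = 40.00% by
construction); they cover 39.99% of the nuclear area (`r_a`) and 9.55% of the
whole image (`r_t`). `demo/` also contains the ground truth as JSON (every
placed object with its class, count, location, scale and z-order) and a
label-mask PNG (0 background / 1 positive / 2 negative).

The full validation study — 42 images across ten `r_n` bins, area measurement
from the images alone, held-out calibration of Ψ, and agreement scoring:

```python
from ihcphantom import RunConfig, run_full_study

report = run_full_study(RunConfig(seed=1, out_dir="demo_study"))
print(report.n_images, round(report.ccc_rn, 4), round(report.heldout_sd, 3))
# 42 0.9997 0.847
```

Here the image-based pipeline's predicted count ratios agree with the exact
truth at CCC = 0.9997 over the 42 images, and on the ten held-out images the
prediction error of `r_n` has a standard deviation of 0.85 percentage points.
All artifacts (images, ground truth, ratio tables, fitted model, agreement
reports) land in `demo_study/`. The same run is available from the shell as
`ihc-phantom full-study --seed 1 --out demo_study`.

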