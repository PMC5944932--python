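"""Baseline image-only estimator: colour-rule pixel classification.

The phantom renders nuclei from brown (positive) and blue (negative)
palettes on a bright noisy background, so a palette rule -- rather than
stain deconvolution, which presumes Beer-Lambert colour mixing -- is
the faithful way to recover areas from the image alone:

- *background*: the pixel is bright overall (min channel >= ``bg_low``),
  or nearly so (min channel >= ``bg_low - margin``) with a small channel
  spread -- this second clause absorbs boundary pixels blurred toward
  the background;
- otherwise *positive* when R - B > delta, *negative* when B - R >
  delta, and ties go to the nearer palette centre.

``estimate_ratios`` turns the classification into (r_a, r_t) and maps
r_a to an r_n estimate through a fitted quadratic calibration,
replacing per-nucleus detection with area measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import PhantomError
from .mapping import MappingModel, predict_rn
from .objects import BLUE_CENTER, BROWN_CENTER
from .phantom import NEGATIVE, POSITIVE
from .ratios import RatioSet

#: Default thresholds, derived from the phantom's design: the background
#: is uniform in [190, 250] (spread at most 60), while both nucleus
#: palettes keep every channel far below 150.
BG_LOW = 190
MARGIN = 40
SPREAD_MAX = 60
DELTA = 15


@dataclass
class PixelClassification:
    """Per-pixel labels plus the two class areas in pixels."""

    label_raster: np.ndarray  # (h, w) uint8 in {0 background, 1 positive, 2 negative}
    positive_area: int
    negative_area: int


def classify_pixels(
    image: np.ndarray,
    bg_low: int = BG_LOW,
    margin: int = MARGIN,
    spread_max: int = SPREAD_MAX,
    delta: int = DELTA,
) -> PixelClassification:
    """Classify every pixel as background / positive / negative by colour."""
    if image.ndim != 3 or image.shape[2] != 3 or image.dtype != np.uint8:
        raise PhantomError("classify_pixels expects an 8-bit RGB image")
    img = image.astype(np.int16)
    mn = img.min(axis=2)
    spread = img.max(axis=2) - mn
    bg = (mn >= bg_low) | ((mn >= bg_low - margin) & (spread <= spread_max))
    rb = img[..., 0] - img[..., 2]
    labels = np.zeros(image.shape[:2], dtype=np.uint8)
    pos = ~bg & (rb > delta)
    neg = ~bg & (rb < -delta)
    labels[pos] = POSITIVE
    labels[neg] = NEGATIVE
    rest = ~bg & ~pos & ~neg
    if rest.any():
        px = img[rest].astype(np.int32)
        d_brown = ((px - BROWN_CENTER.astype(np.int32)) ** 2).sum(axis=1)
        d_blue = ((px - BLUE_CENTER.astype(np.int32)) ** 2).sum(axis=1)
        labels[rest] = np.where(d_brown <= d_blue, POSITIVE, NEGATIVE)
    return PixelClassification(
        label_raster=labels,
        positive_area=int((labels == POSITIVE).sum()),
        negative_area=int((labels == NEGATIVE).sum()),
    )


def estimate_areas(image: np.ndarray, **thresholds) -> tuple[float, float]:
    """(r_a, r_t) in percent from pixel classification alone."""
    pc = classify_pixels(image, **thresholds)
    nuclear = pc.positive_area + pc.negative_area
    r_a = 100.0 * pc.positive_area / nuclear if nuclear else 0.0
    r_t = 100.0 * pc.positive_area / image.shape[0] / image.shape[1]
    return r_a, r_t


def estimate_ratios(image: np.ndarray, model: MappingModel, **thresholds) -> RatioSet:
    """Full image-only estimate: areas by colour rule, count ratio via Psi."""
    r_a, r_t = estimate_areas(image, **thresholds)
    return RatioSet(r_n=float(predict_rn(model, r_a)), r_a=r_a, r_t=r_t, source="algorithm")
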