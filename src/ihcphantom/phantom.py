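"""Phantom synthesis: noisy canvas, perturbed grid, exact-count placement.

A phantom is a synthetic Ki-67 field with *exact* ground truth.  The
synthesis recipe:

1.  a ``canvas_size``-square canvas whose channels are independent
    uniform integers in ``[bg_low, bg_high]`` (default 190-250) -- a
    bright, slightly noisy background resembling unstained tissue;
2.  ``grid_n**2`` candidate locations (default 900) at cell centres of a
    regular grid, each perturbed by independent integer offsets in
    ``[-jitter, +jitter]`` (default +-11) to break the regular look;
3.  positive objects drawn with replacement from the library until their
    nucleus counts sum *exactly* to ``round(G * total / 100)``, then
    negative objects to the remainder;
4.  each object uniformly rescaled by a factor from ``scale_range``,
    placed at a uniformly chosen free grid location (locations where the
    scaled patch would cross the border are redrawn), and composited by
    its mask, later objects over earlier ones;
5.  Gaussian smoothing (sigma = ``smoothing_sigma``) restricted to a
    2-px band around object boundaries, so ground-truth masks stay valid.

A single seeded generator drives background, jitter, object draws,
scales and placement in that fixed order, so a (spec, library) pair
regenerates byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.ndimage as ndi
from PIL import Image

from .errors import GenerationError
from .objects import Label, NucleusObject, ObjectLibrary

#: Ratio bins (percent) of the ten-subset study design; last bin closed at 100.
TABLE1_BINS: tuple[tuple[float, float], ...] = tuple(
    (10.0 * i, 10.0 * (i + 1)) for i in range(10)
)
#: Images per bin in the default 42-image design.
TABLE1_COUNTS: tuple[int, ...] = (4, 4, 7, 4, 5, 6, 3, 3, 3, 3)

BACKGROUND, POSITIVE, NEGATIVE = 0, 1, 2


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero toward +inf."""
    return int(math.floor(x + 0.5))


def bin_index(r_n: float, bins: Sequence[tuple[float, float]] = TABLE1_BINS) -> int:
    """Index of the ratio bin containing ``r_n`` (percent); last bin closed."""
    for i, (lo, hi) in enumerate(bins):
        if lo <= r_n < hi or (i == len(bins) - 1 and lo <= r_n <= hi):
            return i
    raise ValueError(f"r_n={r_n} outside all bins")


@dataclass(frozen=True)
class PhantomSpec:
    """All generation parameters for one phantom."""

    canvas_size: int = 1000
    grid_n: int = 30
    bg_low: int = 190
    bg_high: int = 250
    jitter: int = 11
    positive_pct: float = 20.0
    total_nuclei: int = 900
    scale_range: tuple[float, float] = (0.8, 1.25)
    smoothing_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.positive_pct <= 100.0:
            raise ValueError("positive_pct must be in [0, 100]")
        if self.bg_low > self.bg_high:
            raise ValueError("bg_low must not exceed bg_high")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")
        if self.grid_n < 1 or self.canvas_size < 1:
            raise ValueError("grid_n and canvas_size must be >= 1")
        if self.total_nuclei < 0:
            raise ValueError("total_nuclei must be >= 0")
        if not self.scale_range[0] <= self.scale_range[1]:
            raise ValueError("scale_range must be (lo, hi) with lo <= hi")

    @property
    def n_locations(self) -> int:
        return self.grid_n**2

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scale_range"] = list(self.scale_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["scale_range"] = tuple(d["scale_range"])
        return cls(**d)


@dataclass(frozen=True)
class PlacedObject:
    """One composited object: identity, class, count and exact position."""

    object_id: str
    label: Label
    nucleus_count: int
    location: tuple[int, int]  # (x, y): mask centroid, x = column, top-left origin
    scale: float
    z_order: int


@dataclass
class GroundTruth:
    """Exact reference standard for one phantom."""

    placed: list[PlacedObject]
    n_positive_nuclei: int
    n_negative_nuclei: int
    class_mask: np.ndarray  # (h, w) uint8 in {0 background, 1 positive, 2 negative}
    spec: PhantomSpec

    @property
    def total_nuclei(self) -> int:
        return self.n_positive_nuclei + self.n_negative_nuclei

    def validate(self) -> None:
        pos = sum(p.nucleus_count for p in self.placed if p.label == "positive")
        neg = sum(p.nucleus_count for p in self.placed if p.label == "negative")
        if pos != self.n_positive_nuclei or neg != self.n_negative_nuclei:
            raise GenerationError("placed-object counts disagree with nucleus totals")
        if self.total_nuclei != self.spec.total_nuclei:
            raise GenerationError("nucleus total disagrees with spec")
        expected = round_half_up(self.spec.positive_pct * self.spec.total_nuclei / 100.0)
        if self.n_positive_nuclei != expected:
            raise GenerationError("positive nucleus count is not round(G*total/100)")
        if (self.class_mask == POSITIVE).any() != (self.n_positive_nuclei > 0):
            raise GenerationError("positive pixels inconsistent with positive count")

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "n_positive_nuclei": self.n_positive_nuclei,
            "n_negative_nuclei": self.n_negative_nuclei,
            "placed": [
                {
                    "object_id": p.object_id,
                    "label": p.label,
                    "nucleus_count": p.nucleus_count,
                    "location": list(p.location),
                    "scale": p.scale,
                    "z_order": p.z_order,
                }
                for p in self.placed
            ],
        }

    @classmethod
    def from_dict(cls, d: dict, class_mask: np.ndarray) -> "GroundTruth":
        placed = [
            PlacedObject(
                object_id=p["object_id"],
                label=p["label"],
                nucleus_count=int(p["nucleus_count"]),
                location=(int(p["location"][0]), int(p["location"][1])),
                scale=float(p["scale"]),
                z_order=int(p["z_order"]),
            )
            for p in d["placed"]
        ]
        return cls(
            placed=placed,
            n_positive_nuclei=int(d["n_positive_nuclei"]),
            n_negative_nuclei=int(d["n_negative_nuclei"]),
            class_mask=class_mask,
            spec=PhantomSpec.from_dict(d["spec"]),
        )


@dataclass
class Phantom:
    """Rendered image plus its exact ground truth."""

    image: np.ndarray  # (h, w, 3) uint8
    truth: GroundTruth


def make_background(spec: PhantomSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Uniform-integer RGB background in [bg_low, bg_high], inclusive."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    return rng.integers(
        spec.bg_low,
        spec.bg_high + 1,
        size=(spec.canvas_size, spec.canvas_size, 3),
        dtype=np.uint8,
    )


def make_grid(
    spec: PhantomSpec, rng: np.random.Generator | None = None
) -> list[tuple[int, int]]:
    """grid_n**2 cell-centre locations, each perturbed by +-jitter and clamped.

    The base location for grid index (a, b), a, b in 1..grid_n, is
    ``(floor((a - 1/2) * canvas / grid_n), floor((b - 1/2) * canvas / grid_n))``
    so margins are half a grid cell.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n, c = spec.grid_n, spec.canvas_size
    base = np.array(
        [
            (math.floor((a - 0.5) * c / n), math.floor((b - 0.5) * c / n))
            for a in range(1, n + 1)
            for b in range(1, n + 1)
        ],
        dtype=np.int64,
    )
    offsets = rng.integers(-spec.jitter, spec.jitter + 1, size=(n * n, 2))
    pts = np.clip(base + offsets, 0, c - 1)
    return [(int(x), int(y)) for x, y in pts]


def sample_objects_to_count(
    library: ObjectLibrary,
    label: Label,
    target_nuclei: int,
    rng: np.random.Generator,
) -> list[NucleusObject]:
    """Draw objects with replacement until counts sum exactly to the target.

    Draws are uniform over the class pool, except that once fewer than 5
    nuclei remain the draw is restricted to objects that still fit, so
    the sum lands exactly on the target (a clump may never overshoot the
    ground truth).
    """
    if target_nuclei < 0:
        raise ValueError("target_nuclei must be >= 0")
    pool = library.pool(label)
    drawn: list[NucleusObject] = []
    remaining = target_nuclei
    while remaining > 0:
        if remaining < 5:
            eligible = [o for o in pool if o.nucleus_count <= remaining]
            if not eligible:
                raise GenerationError(
                    f"no {label} object with nucleus_count <= {remaining}; "
                    "cannot hit the target count exactly"
                )
        else:
            eligible = pool
        obj = eligible[int(rng.integers(len(eligible)))]
        drawn.append(obj)
        remaining -= obj.nucleus_count
    return drawn


def _scale_object(obj: NucleusObject, scale: float) -> tuple[np.ndarray, np.ndarray]:
    if scale == 1.0:
        return obj.image, obj.mask
    img = ndi.zoom(obj.image, (scale, scale, 1.0), order=1)
    mask = ndi.zoom(obj.mask.astype(np.uint8), scale, order=0).astype(bool)
    if not mask.any():  # degenerate downscale; keep at least one pixel
        mask = np.ones((1, 1), dtype=bool)
        img = obj.image[:1, :1]
    return img, mask


def generate_phantom(spec: PhantomSpec, library: ObjectLibrary) -> Phantom:
    """Run the full synthesis recipe; see the module docstring for the steps."""
    rng = np.random.default_rng(spec.seed)
    image = make_background(spec, rng)
    locations = make_grid(spec, rng)

    n_pos = round_half_up(spec.positive_pct * spec.total_nuclei / 100.0)
    n_neg = spec.total_nuclei - n_pos
    pos_objects = sample_objects_to_count(library, "positive", n_pos, rng)
    neg_objects = sample_objects_to_count(library, "negative", n_neg, rng)
    if len(pos_objects) + len(neg_objects) > len(locations):
        raise GenerationError(
            f"{len(pos_objects) + len(neg_objects)} objects exceed "
            f"{len(locations)} grid locations"
        )

    class_mask = np.zeros((spec.canvas_size, spec.canvas_size), dtype=np.uint8)
    available = list(range(len(locations)))
    placed: list[PlacedObject] = []
    c = spec.canvas_size
    for z, obj in enumerate(pos_objects + neg_objects):
        scale = float(rng.uniform(*spec.scale_range))
        patch, mask = _scale_object(obj, scale)
        h, w = mask.shape
        ys, xs = np.nonzero(mask)
        cy, cx = int(round(ys.mean())), int(round(xs.mean()))
        chosen = None
        for k in rng.permutation(len(available)):
            x, y = locations[available[k]]
            ty, tx = y - cy, x - cx
            if 0 <= ty and 0 <= tx and ty + h <= c and tx + w <= c:
                chosen = int(k)
                break
        if chosen is None:
            raise GenerationError(
                f"object {obj.id} (scale {scale:.2f}) fits at no free grid location"
            )
        x, y = locations[available.pop(chosen)]
        ty, tx = y - cy, x - cx
        image[ty : ty + h, tx : tx + w][mask] = patch[mask]
        class_mask[ty : ty + h, tx : tx + w][mask] = (
            POSITIVE if obj.label == "positive" else NEGATIVE
        )
        placed.append(
            PlacedObject(obj.id, obj.label, obj.nucleus_count, (x, y), scale, z)
        )

    if spec.smoothing_sigma > 0 and placed:
        fg = class_mask != BACKGROUND
        foot = np.ones((3, 3), dtype=bool)
        band = ndi.binary_dilation(fg, foot) ^ ndi.binary_erosion(fg, foot)
        blurred = ndi.gaussian_filter(
            image.astype(np.float64), sigma=(spec.smoothing_sigma, spec.smoothing_sigma, 0)
        )
        image[band] = np.clip(np.rint(blurred[band]), 0, 255).astype(np.uint8)

    truth = GroundTruth(placed, n_pos, n_neg, class_mask, spec)
    truth.validate()
    return Phantom(image=image, truth=truth)


def smoothing_band(truth: GroundTruth) -> np.ndarray:
    """The 2-px boundary band where edge smoothing was applied."""
    fg = truth.class_mask != BACKGROUND
    foot = np.ones((3, 3), dtype=bool)
    return ndi.binary_dilation(fg, foot) ^ ndi.binary_erosion(fg, foot)


def generate_dataset(
    design: Sequence[tuple[tuple[float, float], int]] | None = None,
    seed: int = 0,
    library: ObjectLibrary | None = None,
    spec_template: PhantomSpec | None = None,
) -> list[Phantom]:
    """Generate a binned phantom dataset (default: the 42-image design).

    For each (ratio-bin, n_images) entry, positive percentages are drawn
    uniformly within the bin; a draw is rejected and repeated if rounding
    to an integer nucleus count would push the exact ground-truth ratio
    outside the bin.  Per-image seeds are spawned from ``seed``.
    """
    if design is None:
        design = list(zip(TABLE1_BINS, TABLE1_COUNTS))
    if spec_template is None:
        spec_template = PhantomSpec()
    if library is None:
        from .objects import build_procedural_library

        library = build_procedural_library(seed=seed)
    rng = np.random.default_rng(seed)
    phantoms: list[Phantom] = []
    total = spec_template.total_nuclei
    for (lo, hi), n_images in design:
        last = (lo, hi) == tuple(design[-1][0])
        for _ in range(n_images):
            for _attempt in range(1000):
                g = float(rng.uniform(lo, hi))
                r_n = 100.0 * round_half_up(g * total / 100.0) / total
                if lo <= r_n < hi or (last and lo <= r_n <= 100.0):
                    break
            else:  # pragma: no cover - would need a pathological bin
                raise GenerationError(f"cannot draw a ratio inside bin [{lo}, {hi})")
            child_seed = int(rng.integers(2**31))
            spec = dataclasses.replace(spec_template, positive_pct=g, seed=child_seed)
            phantoms.append(generate_phantom(spec, library))
    return phantoms


# ---------------------------------------------------------------------------
# Ground-truth persistence: JSON + label-mask PNG


def save_ground_truth(truth: GroundTruth, json_path: str | Path, mask_path: str | Path) -> None:
    Path(json_path).write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True))
    Image.fromarray(truth.class_mask, mode="L").save(mask_path)


def load_ground_truth(json_path: str | Path, mask_path: str | Path) -> GroundTruth:
    d = json.loads(Path(json_path).read_text())
    mask = np.asarray(Image.open(mask_path).convert("L"), dtype=np.uint8)
    return GroundTruth.from_dict(d, mask)


def save_image(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(image, mode="RGB").save(path)
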