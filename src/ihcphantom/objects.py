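"""Library of nucleus "objects": single nuclei and clumps of 2-5 nuclei.

In a Ki-67 immunostain, proliferating nuclei take up the brown DAB
chromogen while resting nuclei show only the blue hematoxylin
counterstain.  The phantom generator samples pre-rendered *objects* --
a single nucleus or a clump of overlapping nuclei -- from a library and
composites them onto a canvas.  By default the library is procedural:
ellipse-shaped nuclei with class-specific palettes, per-object colour
jitter and pixel texture noise, so the package is fully self-contained.
A library of real cropped nuclei (RGBA patches plus a JSON manifest)
can be loaded instead.

Every object carries its exact nucleus count and one binary mask per
constituent nucleus, which is what makes the phantom's ground truth
exact rather than annotated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from PIL import Image
from skimage.draw import ellipse as _draw_ellipse

from .errors import LibraryLoadError

Label = Literal["positive", "negative"]

#: Palette centres: DAB brown for Ki-67 positive, hematoxylin blue for negative.
BROWN_CENTER = np.array([150, 90, 50], dtype=np.int16)
BLUE_CENTER = np.array([70, 80, 150], dtype=np.int16)

#: Full ellipse axis lengths in pixels before per-placement scaling.
AXIS_RANGE = (14.0, 26.0)
#: Per-object colour jitter (+- per channel) around the palette centre.
COLOR_JITTER = 15
#: Extra per-nucleus shade jitter inside a clump.
NUCLEUS_JITTER = 10
#: Gaussian texture noise added inside the mask, in intensity units.
TEXTURE_SIGMA = 8.0
#: Pairwise overlap of consecutive clump nuclei, as fraction of the smaller area.
OVERLAP_RANGE = (0.10, 0.40)
#: Sampling weights for nucleus counts 1..5 in the procedural library.
COUNT_WEIGHTS = (0.35, 0.25, 0.18, 0.12, 0.10)

MIN_NUCLEI, MAX_NUCLEI = 1, 5
_WORK = 256  # working canvas for clump rasterisation, cropped afterwards


@dataclass
class NucleusObject:
    """A placeable nucleus object: RGB patch + mask + exact count.

    ``mask`` is the union of ``per_nucleus_masks``; the per-nucleus masks
    may overlap each other (that is the point of a clump).
    """

    id: str
    label: Label
    image: np.ndarray  # (h, w, 3) uint8
    mask: np.ndarray  # (h, w) bool
    nucleus_count: int
    per_nucleus_masks: list[np.ndarray] = field(default_factory=list)

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    def validate(self) -> None:
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError(f"{self.id}: image must be (h, w, 3)")
        if self.mask.shape != self.image.shape[:2]:
            raise ValueError(f"{self.id}: mask extent differs from image")
        if not MIN_NUCLEI <= self.nucleus_count <= MAX_NUCLEI:
            raise ValueError(
                f"{self.id}: nucleus_count {self.nucleus_count} outside "
                f"[{MIN_NUCLEI}, {MAX_NUCLEI}]"
            )
        if len(self.per_nucleus_masks) != self.nucleus_count:
            raise ValueError(f"{self.id}: per-nucleus masks do not match count")
        union = np.zeros_like(self.mask)
        for m in self.per_nucleus_masks:
            if m.shape != self.mask.shape:
                raise ValueError(f"{self.id}: per-nucleus mask extent mismatch")
            union |= m
        if not np.array_equal(union, self.mask):
            raise ValueError(f"{self.id}: mask is not the union of per-nucleus masks")
        if not self.mask.any():
            raise ValueError(f"{self.id}: empty mask")
        r = float(self.image[..., 0][self.mask].mean())
        b = float(self.image[..., 2][self.mask].mean())
        if self.label == "positive" and not r > b:
            raise ValueError(f"{self.id}: positive object is not brown-dominant")
        if self.label == "negative" and not b > r:
            raise ValueError(f"{self.id}: negative object is not blue-dominant")


@dataclass
class ObjectLibrary:
    """Pools of positive and negative objects the generator samples from."""

    positives: list[NucleusObject]
    negatives: list[NucleusObject]
    provenance: Literal["procedural", "loaded"] = "procedural"
    seed: int | None = None

    def pool(self, label: Label) -> list[NucleusObject]:
        return self.positives if label == "positive" else self.negatives

    def validate(self) -> None:
        for obj in self.positives + self.negatives:
            obj.validate()


def _ellipse_mask(cy: float, cx: float, ry: float, rx: float, theta: float) -> np.ndarray:
    mask = np.zeros((_WORK, _WORK), dtype=bool)
    rr, cc = _draw_ellipse(cy, cx, ry, rx, rotation=theta, shape=(_WORK, _WORK))
    mask[rr, cc] = True
    return mask


def _clump_masks(rng: np.random.Generator, count: int) -> list[np.ndarray]:
    """Rasterise ``count`` ellipses, consecutive pairs overlapping 10-40%.

    The overlap fraction (relative to the smaller ellipse) is monotone in
    the centre distance, so the distance is found by bisection on the
    rasterised intersection.
    """
    masks: list[np.ndarray] = []
    prev = (float(_WORK / 2), float(_WORK / 2), 0.0, 0.0)  # cy, cx, max radius
    for i in range(count):
        ry = rng.uniform(*AXIS_RANGE) / 2.0
        rx = rng.uniform(*AXIS_RANGE) / 2.0
        theta = rng.uniform(0.0, np.pi)
        if i == 0:
            cy, cx = _WORK / 2.0, _WORK / 2.0
            masks.append(_ellipse_mask(cy, cx, ry, rx, theta))
        else:
            pcy, pcx = prev[0], prev[1]
            pmask = masks[-1]
            parea = pmask.sum()
            target = rng.uniform(*OVERLAP_RANGE)
            phi = rng.uniform(0.0, 2.0 * np.pi)
            lo, hi = 0.0, (prev[2] + max(ry, rx)) * 1.2
            cy = cx = 0.0
            mask = pmask
            for _ in range(30):
                d = 0.5 * (lo + hi)
                cy = pcy + d * np.sin(phi)
                cx = pcx + d * np.cos(phi)
                mask = _ellipse_mask(cy, cx, ry, rx, theta)
                frac = np.logical_and(pmask, mask).sum() / min(parea, mask.sum())
                if frac > target:
                    lo = d
                else:
                    hi = d
            masks.append(mask)
        prev = (cy, cx, max(ry, rx))
    return masks


def _render_object(
    rng: np.random.Generator, label: Label, count: int, object_id: str
) -> NucleusObject:
    masks = _clump_masks(rng, count)
    union = np.zeros((_WORK, _WORK), dtype=bool)
    for m in masks:
        union |= m
    ys, xs = np.nonzero(union)
    y0, y1 = max(ys.min() - 2, 0), min(ys.max() + 3, _WORK)
    x0, x1 = max(xs.min() - 2, 0), min(xs.max() + 3, _WORK)
    union = union[y0:y1, x0:x1]
    masks = [m[y0:y1, x0:x1] for m in masks]

    center = BROWN_CENTER if label == "positive" else BLUE_CENTER
    base = center + rng.integers(-COLOR_JITTER, COLOR_JITTER + 1, size=3)
    img = np.zeros(union.shape + (3,), dtype=np.int16)
    for m in masks:  # later nuclei shade over earlier ones in the overlap
        shade = np.clip(base + rng.integers(-NUCLEUS_JITTER, NUCLEUS_JITTER + 1, 3), 0, 255)
        img[m] = shade
    noise = rng.normal(0.0, TEXTURE_SIGMA, size=img.shape)
    img = np.where(union[..., None], np.clip(np.rint(img + noise), 0, 255), 0)
    obj = NucleusObject(
        id=object_id,
        label=label,
        image=img.astype(np.uint8),
        mask=union,
        nucleus_count=count,
        per_nucleus_masks=masks,
    )
    obj.validate()
    return obj


def _draw_counts(rng: np.random.Generator, n: int) -> list[int]:
    """Nucleus counts for one class: all of 1..5 represented first, rest weighted."""
    counts = list(range(MIN_NUCLEI, min(n, MAX_NUCLEI) + 1))
    extra = n - len(counts)
    if extra > 0:
        counts.extend(
            int(c)
            for c in rng.choice(
                np.arange(MIN_NUCLEI, MAX_NUCLEI + 1), size=extra, p=COUNT_WEIGHTS
            )
        )
    return counts


def build_procedural_library(
    seed: int, n_positive: int = 50, n_negative: int = 40
) -> ObjectLibrary:
    """Build the default procedural object library.

    The default pool sizes (50 positive, 40 negative) mirror the object
    collection the phantom design is based on.  Object #1 of each class is
    always a single nucleus, which guarantees the exact-count sampler can
    terminate for any target.  Deterministic for a given seed.
    """
    if n_positive < 1 or n_negative < 1:
        raise ValueError("n_positive and n_negative must both be >= 1")
    rng = np.random.default_rng(seed)
    positives = [
        _render_object(rng, "positive", c, f"pos-{i:03d}")
        for i, c in enumerate(_draw_counts(rng, n_positive))
    ]
    negatives = [
        _render_object(rng, "negative", c, f"neg-{i:03d}")
        for i, c in enumerate(_draw_counts(rng, n_negative))
    ]
    return ObjectLibrary(positives, negatives, provenance="procedural", seed=seed)


# ---------------------------------------------------------------------------
# Disk round trip: one RGBA PNG per object plus manifest.json


def save_library(library: ObjectLibrary, path: str | Path) -> Path:
    """Write the library as RGBA PNGs + per-nucleus mask PNGs + manifest.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = []
    for obj in library.positives + library.negatives:
        rgba = np.dstack([obj.image, (obj.mask * 255).astype(np.uint8)])
        fname = f"{obj.id}.png"
        Image.fromarray(rgba, mode="RGBA").save(path / fname)
        entry: dict = {
            "file": fname,
            "label": obj.label,
            "nucleus_count": obj.nucleus_count,
        }
        if obj.nucleus_count > 1:
            mask_files = []
            for k, m in enumerate(obj.per_nucleus_masks):
                mname = f"{obj.id}_n{k}.png"
                Image.fromarray((m * 255).astype(np.uint8), mode="L").save(path / mname)
                mask_files.append(mname)
            entry["per_nucleus_mask_files"] = mask_files
        manifest.append(entry)
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return path / "manifest.json"


def load_library(path: str | Path, manifest: str | Path | None = None) -> ObjectLibrary:
    """Load an object library from a directory of RGBA patches.

    The manifest lists, per object: ``file``, ``label``, ``nucleus_count``
    and, for clumps, ``per_nucleus_mask_files``.  Single-nucleus objects
    without explicit per-nucleus masks get ``[mask]``; a clump without
    them is an error because the ground truth would no longer be exact.
    """
    path = Path(path)
    manifest_path = Path(manifest) if manifest is not None else path / "manifest.json"
    if not manifest_path.exists():
        raise LibraryLoadError(f"manifest not found: {manifest_path}")
    entries = json.loads(manifest_path.read_text())
    positives: list[NucleusObject] = []
    negatives: list[NucleusObject] = []
    for entry in entries:
        name = entry.get("file", "<missing file field>")
        label = entry.get("label")
        count = entry.get("nucleus_count")
        if label not in ("positive", "negative"):
            raise LibraryLoadError(f"{name}: label must be positive/negative, got {label!r}")
        if not isinstance(count, int) or not MIN_NUCLEI <= count <= MAX_NUCLEI:
            raise LibraryLoadError(
                f"{name}: nucleus_count must be an integer in "
                f"[{MIN_NUCLEI}, {MAX_NUCLEI}], got {count!r}"
            )
        fpath = path / name
        if not fpath.exists():
            raise LibraryLoadError(f"{name}: file not found in {path}")
        rgba = np.asarray(Image.open(fpath).convert("RGBA"))
        image = rgba[..., :3].copy()
        mask = rgba[..., 3] > 127
        if count == 1:
            per_masks = [mask]
        else:
            mask_files = entry.get("per_nucleus_mask_files")
            if not mask_files:
                raise LibraryLoadError(
                    f"{name}: clump of {count} nuclei has no per-nucleus masks"
                )
            per_masks = []
            for mname in mask_files:
                mpath = path / mname
                if not mpath.exists():
                    raise LibraryLoadError(f"{name}: per-nucleus mask {mname} not found")
                per_masks.append(np.asarray(Image.open(mpath).convert("L")) > 127)
        obj = NucleusObject(
            id=Path(name).stem,
            label=label,
            image=image,
            mask=mask,
            nucleus_count=count,
            per_nucleus_masks=per_masks,
        )
        try:
            obj.validate()
        except ValueError as exc:
            raise LibraryLoadError(str(exc)) from exc
        (positives if label == "positive" else negatives).append(obj)
    return ObjectLibrary(positives, negatives, provenance="loaded")
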