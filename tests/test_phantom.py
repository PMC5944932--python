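"""Phantom synthesis: grid geometry, exact counts, compositing, determinism."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ihcphantom import (
    GenerationError,
    PhantomSpec,
    generate_dataset,
    generate_phantom,
    make_background,
    make_grid,
    sample_objects_to_count,
    save_ground_truth,
    load_ground_truth,
)
from ihcphantom.objects import NucleusObject, ObjectLibrary
from ihcphantom.phantom import TABLE1_BINS, round_half_up, smoothing_band
from .conftest import SMALL_SPEC


def test_background_bounds_and_determinism():
    spec = PhantomSpec(canvas_size=200, seed=4)
    bg = make_background(spec)
    assert bg.shape == (200, 200, 3)
    assert bg.min() >= 190 and bg.max() <= 250
    assert np.array_equal(bg, make_background(spec))
    flat = dataclasses.replace(spec, bg_low=200, bg_high=200)
    assert (make_background(flat) == 200).all()


def test_grid_cell_centres_and_jitter_bounds():
    spec = PhantomSpec(seed=2)
    locs = make_grid(spec)
    assert len(locs) == 900
    base = [
        (math.floor((a - 0.5) * 1000 / 30), math.floor((b - 0.5) * 1000 / 30))
        for a in range(1, 31)
        for b in range(1, 31)
    ]
    for (x, y), (bx, by) in zip(locs, base):
        assert abs(x - bx) <= 11 and abs(y - by) <= 11

    exact = make_grid(dataclasses.replace(spec, jitter=0))
    assert exact == base
    # the base formula itself: index (16, 15) maps to (516, 483)
    assert base[15 * 30 + 14] == (516, 483)
    assert (516 - 11, 483 + 11) == (505, 494)


def test_sampling_hits_target_exactly(small_library):
    rng = np.random.default_rng(0)
    drawn = sample_objects_to_count(small_library, "positive", 360, rng)
    assert sum(o.nucleus_count for o in drawn) == 360
    assert sample_objects_to_count(small_library, "negative", 0, rng) == []


@settings(max_examples=30, deadline=None)
@given(target=st.integers(min_value=0, max_value=300), seed=st.integers(0, 2**16))
def test_sampling_exact_for_any_target(small_library, target, seed):
    rng = np.random.default_rng(seed)
    drawn = sample_objects_to_count(small_library, "positive", target, rng)
    assert sum(o.nucleus_count for o in drawn) == target


def test_sampling_impossible_target_errors(small_library):
    clumps5 = [o for o in small_library.positives if o.nucleus_count == 5]
    lib = ObjectLibrary(positives=clumps5, negatives=small_library.negatives)
    # no sum of 5s reaches 7 exactly: after one draw 2 remain and nothing fits
    with pytest.raises(GenerationError, match="exactly"):
        sample_objects_to_count(lib, "positive", 7, np.random.default_rng(1))


def test_generated_counts_and_mask(small_phantom):
    truth = small_phantom.truth
    assert truth.n_positive_nuclei == 40  # G=40% of 100
    assert truth.n_negative_nuclei == 60
    assert set(np.unique(truth.class_mask)) <= {0, 1, 2}
    assert (truth.class_mask == 1).any() and (truth.class_mask == 2).any()


def test_all_positive_and_all_negative_extremes(small_library):
    ph0 = generate_phantom(dataclasses.replace(SMALL_SPEC, positive_pct=0.0), small_library)
    assert ph0.truth.n_positive_nuclei == 0
    assert not (ph0.truth.class_mask == 1).any()
    ph100 = generate_phantom(dataclasses.replace(SMALL_SPEC, positive_pct=100.0), small_library)
    assert ph100.truth.n_negative_nuclei == 0
    assert not (ph100.truth.class_mask == 2).any()


def test_no_two_objects_share_a_location(small_phantom):
    locs = [p.location for p in small_phantom.truth.placed]
    assert len(locs) == len(set(locs))


def test_locations_on_perturbed_grid(small_phantom):
    # the grid is drawn after the background from the same stream; rebuild both
    rng = np.random.default_rng(SMALL_SPEC.seed)
    make_background(SMALL_SPEC, rng)
    grid = set(make_grid(SMALL_SPEC, rng))
    assert all(p.location in grid for p in small_phantom.truth.placed)


def test_background_pixels_in_bounds_outside_band(small_phantom):
    band = smoothing_band(small_phantom.truth)
    bg = (small_phantom.truth.class_mask == 0) & ~band
    pixels = small_phantom.image[bg]
    assert pixels.min() >= SMALL_SPEC.bg_low and pixels.max() <= SMALL_SPEC.bg_high


def test_regeneration_is_byte_identical(small_library, small_phantom):
    again = generate_phantom(SMALL_SPEC, small_library)
    assert np.array_equal(again.image, small_phantom.image)
    assert np.array_equal(again.truth.class_mask, small_phantom.truth.class_mask)
    assert again.truth.placed == small_phantom.truth.placed


def test_rounding_ties_up():
    assert round_half_up(4.5) == 5
    assert round_half_up(359.5) == 360
    assert round_half_up(0.4999) == 0


def test_dataset_respects_custom_design(small_library):
    design = [((30.0, 40.0), 2), ((90.0, 100.0), 1)]
    phantoms = generate_dataset(design, seed=6, library=small_library, spec_template=SMALL_SPEC)
    assert len(phantoms) == 3
    rn = [100.0 * p.truth.n_positive_nuclei / p.truth.total_nuclei for p in phantoms]
    assert 30.0 <= rn[0] < 40.0 and 30.0 <= rn[1] < 40.0
    assert rn[2] >= 90.0


def test_single_bin_dataset(small_library):
    phantoms = generate_dataset(
        [(TABLE1_BINS[0], 1)], seed=8, library=small_library, spec_template=SMALL_SPEC
    )
    assert len(phantoms) == 1
    assert 100.0 * phantoms[0].truth.n_positive_nuclei / phantoms[0].truth.total_nuclei < 10.0


def test_ground_truth_json_round_trip(tmp_path, small_phantom):
    jf, mf = tmp_path / "t.json", tmp_path / "t_mask.png"
    save_ground_truth(small_phantom.truth, jf, mf)
    loaded = load_ground_truth(jf, mf)
    assert loaded.spec == small_phantom.truth.spec
    assert loaded.placed == small_phantom.truth.placed
    assert loaded.n_positive_nuclei == small_phantom.truth.n_positive_nuclei
    assert np.array_equal(loaded.class_mask, small_phantom.truth.class_mask)


def test_too_many_objects_for_grid(small_library):
    spec = dataclasses.replace(SMALL_SPEC, grid_n=3, total_nuclei=100)
    with pytest.raises(GenerationError):
        generate_phantom(spec, small_library)


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        PhantomSpec(positive_pct=101.0)
    with pytest.raises(ValueError):
        PhantomSpec(bg_low=251, bg_high=250)
    with pytest.raises(ValueError):
        PhantomSpec(jitter=-1)
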