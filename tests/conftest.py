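"""Shared fixtures: object libraries and generated phantom sets.

Everything is generated programmatically at test time; the heavier
session fixtures (the default library and the 42-image study set) are
built once and reused across test modules.
"""

import numpy as np
import pytest

from ihcphantom import (
    PhantomSpec,
    build_procedural_library,
    generate_dataset,
    generate_phantom,
    ratios_from_truth,
)
from ihcphantom.estimator import estimate_areas

#: Reduced spec for fast unit tests: 100 nuclei on a 300-px canvas.
SMALL_SPEC = PhantomSpec(canvas_size=300, grid_n=10, total_nuclei=100, positive_pct=40.0, seed=5)


@pytest.fixture(scope="session")
def library():
    """Default-shaped procedural library: 50 positive, 40 negative objects."""
    return build_procedural_library(seed=7)


@pytest.fixture(scope="session")
def small_library():
    """Small library for fast sampling tests; still has all counts 1-5."""
    return build_procedural_library(seed=3, n_positive=12, n_negative=10)


@pytest.fixture(scope="session")
def small_phantom(small_library):
    return generate_phantom(SMALL_SPEC, small_library)


@pytest.fixture(scope="session")
def study_set(library):
    """The default 42-image binned dataset plus truth and estimated ratios."""
    phantoms = generate_dataset(seed=11, library=library)
    truth = [ratios_from_truth(p.truth) for p in phantoms]
    est = np.array([estimate_areas(p.image) for p in phantoms])
    return {
        "phantoms": phantoms,
        "truth_rn": np.array([t.r_n for t in truth]),
        "truth_ra": np.array([t.r_a for t in truth]),
        "truth_rt": np.array([t.r_t for t in truth]),
        "est_ra": est[:, 0],
        "est_rt": est[:, 1],
    }
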