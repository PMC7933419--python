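"""Shared fixtures: a small phantom and its derived objects."""
from __future__ import annotations

import numpy as np
import pytest

from imsischemia import normstats, synthgen
from imsischemia.synthgen import PhantomSpec


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A reduced phantom that keeps every structural element of the default."""
    return PhantomSpec(
        grid=(30, 30),
        n_features=120,
        n_de_up=12,
        n_de_down=12,
        seed=20240915,
    )


@pytest.fixture(scope="session")
def small_design():
    return synthgen.make_design(["15min", "4h"], n_per_cell=5)


@pytest.fixture(scope="session")
def small_cohort(small_spec, small_design):
    return synthgen.generate_cohort(small_spec, small_design, as_matrix=True)


@pytest.fixture(scope="session")
def small_matrix(small_spec):
    fm, gt = synthgen.generate_phantom_matrix(
        small_spec, "fx_isch", "ischemic", "4h"
    )
    return fm, gt


@pytest.fixture(scope="session")
def small_norm(small_matrix):
    fm, gt = small_matrix
    return normstats.log2_transform(normstats.mstus_normalize(fm)), gt


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
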