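"""Shared fixtures: small, fast phantom cases and cohorts.

The ``small`` geometry (48^3 grid, 4 mm voxels) keeps single-case tests in
the sub-second range while preserving every structural property of the
default study geometry.
"""

from __future__ import annotations

import numpy as np
import pytest

from sirtomics.phantom import PhantomConfig, generate_case, generate_cohort

SMALL_KW = dict(
    grid_shape=(48, 48, 48),
    liver_radius_mm=52.0,
    lobe_radius_mm=38.0,
    tumor_radius_mm=14.0,
)


def small_config(**overrides) -> PhantomConfig:
    kw = {**SMALL_KW, **overrides}
    return PhantomConfig(**kw)


@pytest.fixture(scope="session")
def small_case():
    return generate_case(small_config(seed=7), label="NR", case_id="case_small")


@pytest.fixture(scope="session")
def noiseless_case():
    return generate_case(small_config(seed=11, noise_model="none"), case_id="case_clean")


@pytest.fixture(scope="session")
def small_cohort():
    """17 cases, 5 responders, small geometry — the modeling workhorse."""
    return generate_cohort(17, 5 / 17, small_config(), seed=3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
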