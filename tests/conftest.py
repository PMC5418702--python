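"""Shared fixtures: phantoms sized for fast unit tests."""

from __future__ import annotations

import numpy as np
import pytest

from nmfseg.phantom import PhantomSpec, generate_study

#: compact geometry for pipeline-level tests (same tissue layout as the
#: default phantom, smaller grid so a full solve takes a few seconds)
SMALL_GEOMETRY = dict(
    shape=(48, 48, 6),
    brain_radii_mm=(21.0, 22.0, 12.0),
    ventricle_offset_mm=(5.0, -6.0, 0.0),
    ventricle_radii_mm=(3.0, 5.0, 5.0),
    vessel_xy_mm=((12.0, -8.0), (8.0, 13.0)),
    vessel_radius_mm=1.5,
    lesion_center_mm=(-7.0, 4.0, 0.0),
    necrosis_radius_mm=3.5,
    rim_radius_mm=6.5,
    edema_radius_mm=9.5,
)


def make_small_phantom(seed: int = 0, **overrides):
    spec = PhantomSpec(seed=seed, **{**SMALL_GEOMETRY, **overrides})
    return spec, generate_study(spec)


@pytest.fixture(scope="session")
def small_phantom():
    """Deterministic small noisy phantom shared across tests."""
    return make_small_phantom(seed=0)


@pytest.fixture(scope="session")
def default_phantom():
    """The full-size default phantom (64 x 64 x 10, sigma 0.05)."""
    spec = PhantomSpec(seed=0)
    return spec, generate_study(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
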