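"""Shared fixtures: small fast phantoms for unit tests.

Unit tests run on a 32-voxel grid so the whole suite stays quick; the
experiment-scale tests build their own 64-voxel cohorts.
"""

import numpy as np
import pytest

from strokewmh import (
    LabelMask,
    LesionGeometry,
    SiteEffect,
    TissueModel,
    generate_cohort,
    generate_subject,
)


@pytest.fixture(scope="session")
def small_geom() -> LesionGeometry:
    return LesionGeometry(
        shape=(32, 32, 32),
        brain_semiaxes_mm=(13.0, 14.0, 11.0),
        ventricle_centers_mm=((-4.0, -1.0, 1.0), (4.0, -1.0, 1.0)),
        ventricle_semiaxes_mm=(2.0, 5.0, 3.0),
        n_wmh_clusters=6,
        n_wmh_jitter=2,
        wmh_radius_range_mm=(1.2, 2.2),
        d_pv_mm=6.0,
        stroke_radius_mm=4.0,
    )


@pytest.fixture(scope="session")
def small_subject(small_geom):
    return generate_subject(TissueModel(), small_geom, SiteEffect.identity(), seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_geom):
    return generate_cohort(4, geom=small_geom, base_seed=40)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_mask(rng, shape=(12, 12, 12), p=0.2, role="WMH_AUTO") -> LabelMask:
    return LabelMask(rng.random(shape) < p, np.eye(4), role)


def ball_mask(shape, center, radius, role="WMH_AUTO") -> LabelMask:
    idx = np.indices(shape, dtype=float)
    d2 = sum((idx[i] - center[i]) ** 2 for i in range(3))
    return LabelMask(d2 <= radius**2, np.eye(4), role)
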