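import numpy as np
import pytest

from lvshape.personalize import default_template
from lvshape.synthetic import (
    LVGeometryParams,
    default_population_spec,
    generate_lv_surface,
    sample_cohort,
)


@pytest.fixture(scope="session")
def uniform_wall_mesh():
    """Constant 8 mm wall: plain semi-ellipsoid plus normal offset."""
    params = LVGeometryParams(
        septal_bump_amp_mm=0.0,
        apical_dilation=0.0,
        lvot_inward_mm=0.0,
        base_thickness_mm=8.0,
    )
    return generate_lv_surface(params)


@pytest.fixture(scope="session")
def bump_mesh():
    """8 mm wall with a 9 mm septal bump (17 mm peak), no spiral, no LVOT."""
    params = LVGeometryParams(
        base_thickness_mm=8.0,
        septal_bump_amp_mm=9.0,
        spiral_drift_rad=0.0,
        lvot_inward_mm=0.0,
    )
    return generate_lv_surface(params)


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture(scope="session")
def random_shape_sample():
    """Twenty random anatomies spanning all generative factors."""
    rng = np.random.default_rng(42)
    meshes = []
    for _ in range(20):
        params = LVGeometryParams(
            length_mm=80.0 + rng.normal(0.0, 4.0),
            endo_base_radius_mm=24.0 + rng.normal(0.0, 1.5),
            base_thickness_mm=8.0 + rng.normal(0.0, 0.8),
            septal_bump_amp_mm=5.0 + rng.normal(0.0, 1.5),
            septal_bump_center=(0.2 + rng.normal(0.0, 0.15), 0.25 + rng.normal(0.0, 0.05)),
            spiral_drift_rad=rng.normal(0.0, 0.15),
            apical_dilation=abs(rng.normal(0.08, 0.04)),
            lvot_inward_mm=abs(rng.normal(1.0, 0.8)),
            sphericity_exp=2.0 + rng.normal(0.0, 0.15),
        )
        meshes.append(generate_lv_surface(params))
    return meshes


@pytest.fixture(scope="session")
def small_cohort():
    """Thirty-subject default-design cohort (15 per group)."""
    spec = default_population_spec(n_per_group=15, seed=123)
    return sample_cohort(spec)
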