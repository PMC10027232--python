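import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_scene():
    """Small noiseless, well-separated scene with ground truth (no spheres,
    no outliers, flat rough-free soil) for exact-recovery checks."""
    from canopy_pheno.synthetic import SceneSpec, generate_scene

    spec = SceneSpec(
        rows=1,
        plants_per_row=2,
        ground_slope=0.0,
        ground_roughness=0.0,
        noise_sigma=0.0,
        n_outliers=0,
        sphere_diameters=(),
        ground_density=1.0,
        margin=50.0,
        seed=11,
    )
    return spec, generate_scene(spec)
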