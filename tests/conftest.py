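import numpy as np
import pytest
from hypothesis import settings

import octfundus as of

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sphere_model():
    return of.SurfaceModel(kind="sphere", base_radius_um=13000.0)


@pytest.fixture(scope="session")
def staph_model():
    return of.SurfaceModel(
        kind="staphyloma", base_radius_um=13000.0, bowl_depth_um=800.0, bowl_sigma_um=1500.0
    )


@pytest.fixture(scope="session")
def staph_set_speckle(staph_model):
    """Seeded 12-scan staphyloma acquisition with moderate speckle."""
    return of.render_radial_set(staph_model, eye_id="staph", speckle_sigma=0.2, seed=7)


@pytest.fixture(scope="session")
def sphere_set_clean(sphere_model):
    return of.render_radial_set(sphere_model, eye_id="sphere", speckle_sigma=0.0, seed=1)


@pytest.fixture(scope="session")
def staph_profiles(staph_model):
    """Noiseless dense curvature profiles of the staphyloma phantom."""
    traces = of.sample_radial_traces(staph_model, n_angles=12, half_width_um=4500, step_um=1.0)
    return [(a, of.curvature_profile(t)) for a, t in traces]


@pytest.fixture(scope="session")
def sphere_profiles(sphere_model):
    traces = of.sample_radial_traces(sphere_model, n_angles=12, half_width_um=4500, step_um=1.0)
    return [(a, of.curvature_profile(t)) for a, t in traces]


def flat_band_image(n_rows=60, n_cols=40, band_row=30, thickness=3, lo=0.1, hi=0.9):
    """Uniform background with one bright horizontal band (float in [0,1])."""
    img = np.full((n_rows, n_cols), lo)
    img[band_row : band_row + thickness, :] = hi
    return img
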