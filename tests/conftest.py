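import numpy as np
import pytest

from seedvigor.synthetic import (
    SceneSpec,
    default_wavelength_grid,
    make_class_spectra,
    render_scene,
)


@pytest.fixture(scope="session")
def wavelengths_120():
    return default_wavelength_grid(120)


@pytest.fixture(scope="session")
def class_models(wavelengths_120):
    return make_class_spectra(1, wavelengths_120)


@pytest.fixture(scope="session")
def small_scene(class_models):
    """2x5 = 10 seeds on a 64x128x120 cube, default noise/scatter."""
    spec = SceneSpec(grid_rows=2, grid_cols=5, height=64, width=128,
                     n_bands=120, rng_seed=7)
    return render_scene(spec, class_models)


@pytest.fixture(scope="session")
def clean_models(wavelengths_120):
    """Class models with the scatter/noise channels switched off."""
    models = make_class_spectra(1, wavelengths_120)
    for m in models.values():
        m.slope_sd = 0.0
        m.offset_sd = 0.0
        m.noise_sd = 0.0
    return models


@pytest.fixture(scope="session")
def clean_scene(clean_models):
    spec = SceneSpec(grid_rows=2, grid_cols=5, height=64, width=128,
                     n_bands=120, rng_seed=7)
    return render_scene(spec, clean_models)
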