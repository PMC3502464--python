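import numpy as np
import pytest

from oximap import (
    default_model,
    load_reference_table,
    make_band_grid,
    medullary_ray_scene,
    render_cube,
)
from oximap.synthetic_fundus import BASELINE_SO2


@pytest.fixture(scope="session")
def extinction():
    return load_reference_table()


@pytest.fixture(scope="session")
def bands76():
    return make_band_grid(450.0, 700.0, 76)


@pytest.fixture(scope="session")
def baseline_so2():
    """Arm-mean saturations (fractions) of the emulated baseline cohort."""
    return {key: mean for key, (mean, _) in BASELINE_SO2.items()}


@pytest.fixture(scope="session")
def clean_scene(baseline_so2):
    return medullary_ray_scene(baseline_so2, noise_kind="none")


@pytest.fixture(scope="session")
def clean_cube(clean_scene, bands76, extinction):
    return render_cube(clean_scene, bands76, extinction)


@pytest.fixture(scope="session")
def model28(bands76, extinction):
    return default_model(bands76, extinction=extinction)
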