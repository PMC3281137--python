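import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", max_examples=25, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from cartchem.synth import (AcquisitionConfig, make_basis_spectra,
                            make_composition_phantom, render_spectral_image)


@pytest.fixture(scope="session")
def basis():
    return make_basis_spectra()


@pytest.fixture(scope="session")
def wavenumbers(basis):
    return basis.wavenumbers


@pytest.fixture()
def control_phantom():
    return make_composition_phantom(n_depth=40, group="control", seed=7,
                                    sample_id="C01")


@pytest.fixture()
def noiseless_acq():
    return AcquisitionConfig(noise_sd_single_scan=0.0, thickness_cv=0.0,
                             paraffin_level_max=0.0, seed=3)


@pytest.fixture()
def small_image(control_phantom, basis, noiseless_acq):
    return render_spectral_image(control_phantom, basis, noiseless_acq)
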