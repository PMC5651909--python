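import numpy as np
import pytest

from fretion import (
    PhotophysicsParams,
    assign_ground_truth,
    estimate_correction_factors,
    generate_mesh,
    preprocess,
    render_calibration_images,
    render_stack,
)


@pytest.fixture(scope="session")
def mesh100():
    return generate_mesh(100, (512, 512), seed=1, geometry="sheet")


@pytest.fixture(scope="session")
def mesh40():
    return generate_mesh(40, (256, 256), seed=3, geometry="sheet")


@pytest.fixture(scope="session")
def cluster7():
    return generate_mesh(7, (256, 256), seed=2, geometry="cluster")


@pytest.fixture(scope="session")
def phys_noise_free():
    return PhotophysicsParams(noise="none", autofluorescence=0.0, z_slices=1)


@pytest.fixture(scope="session")
def phys_noisy():
    return PhotophysicsParams(noise="poisson", seed=7)


@pytest.fixture(scope="session")
def uniform_truth(mesh40):
    return assign_ground_truth(mesh40, "uniform", 0.25, 0.25)


@pytest.fixture(scope="session")
def uniform_stack(uniform_truth, phys_noisy):
    return render_stack(uniform_truth, phys_noisy)


@pytest.fixture(scope="session")
def calibration_factors(phys_noisy):
    donor = preprocess(render_calibration_images(phys_noisy, "donor_only"))
    acceptor = preprocess(render_calibration_images(phys_noisy, "acceptor_only"))
    return estimate_correction_factors(donor, acceptor)
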