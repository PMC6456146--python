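import numpy as np
import pytest

import fibrec as fr


@pytest.fixture(scope="session")
def grid32():
    return fr.make_grid(32)


@pytest.fixture(scope="session")
def spots32(grid32):
    centers = fr.spot_lattice(8, grid32)
    return fr.spot_basis(centers, 0.06, grid32)


@pytest.fixture(scope="session")
def scheme3():
    """Default three-input polarization scheme (beta=pi/2, gamma=pi)."""
    return fr.DEFAULT_SCHEME


@pytest.fixture(scope="session")
def sensor32(grid32):
    return fr.sensor_from_grid(grid32, 2048, seed=2)


@pytest.fixture(scope="session")
def well_conditioned_instance(grid32, spots32, scheme3, sensor32):
    """Noiseless calibrated instance whose ground truth lies in the span."""
    kernel = fr.make_kernel(5, 200, 1.0, 0.5, grid32)
    inputs = fr.make_polarized_inputs(spots32, spots32, scheme3)
    calib = fr.measure_calibration(inputs, kernel, sensor32, scheme3, 0.0, 1)
    rng = np.random.default_rng(9)
    M = spots32.n_functions
    truth = rng.standard_normal(2 * M) + 1j * rng.standard_normal(2 * M)
    field = fr.VectorField(
        spots32.values @ truth[:M], spots32.values @ truth[M:], grid32
    )
    out = fr.apply_transform(kernel, field)
    g = fr.sample_sensor(out, sensor32)
    system = fr.assemble_system(calib, g)
    return {"kernel": kernel, "calib": calib, "system": system, "truth": truth}


@pytest.fixture(scope="session")
def ill_conditioned_instance(grid32, spots32, scheme3, sensor32):
    """Seeded noisy instance with fast spectral decay and 3-sparse truth."""
    kernel = fr.make_kernel(6, 200, 8.0, 0.7, grid32)
    inputs = fr.make_polarized_inputs(spots32, spots32, scheme3)
    calib = fr.measure_calibration(inputs, kernel, sensor32, scheme3, 0.0, 3)
    M = spots32.n_functions
    truth = np.zeros(2 * M, dtype=complex)
    truth[[5, 40, 100]] = [2 + 1j, -1.5, 1j]
    field = fr.VectorField(
        spots32.values @ truth[:M], spots32.values @ truth[M:], grid32
    )
    out = fr.apply_transform(kernel, field)
    g = fr.sample_sensor(out, sensor32, noise_sigma=0.02, seed=4)
    system = fr.assemble_system(calib, g)
    return {"kernel": kernel, "calib": calib, "system": system, "truth": truth}
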