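import numpy as np
import pytest

import ureakin as uk


@pytest.fixture(scope="session")
def pbs_chemistry() -> uk.Chemistry:
    """Urea/urease in 0.33 mM phosphate buffer at bulk pH 7.4."""
    return uk.load_chemistry("pbs_urea")


@pytest.fixture(scope="session")
def au_chemistry() -> uk.Chemistry:
    """Urea/urease in the artificial-urine-like effective medium."""
    return uk.load_chemistry("au_urea")


@pytest.fixture(scope="session")
def pbs_truth() -> uk.KineticParameters:
    """Reference kinetic parameters for the PBS medium (K_M = 10.88 mM)."""
    return uk.KineticParameters(k_m=10.88e-3, kbar_v=2.2e-4)


@pytest.fixture(scope="session")
def au_truth() -> uk.KineticParameters:
    """Reference kinetic parameters for the AU medium (kbar_V ~ 1e-6.07 M)."""
    return uk.KineticParameters(k_m=32.45e-3, kbar_v=8.6e-7)


@pytest.fixture(scope="session")
def grid12() -> np.ndarray:
    """12-point log grid spanning 0.1-50 mM, in mol/L."""
    return np.geomspace(1e-4, 5e-2, 12)


@pytest.fixture(scope="session")
def noise_free_dataset(pbs_chemistry, pbs_truth, grid12) -> uk.CalibrationDataset:
    """Noise-free synthetic PBS calibration dataset at the reference truth."""
    spec = uk.GeneratorSpec(
        chemistry=pbs_chemistry, truth=pbs_truth, s_b_grid=grid12,
        noise_sd_ph=0.0, seed=0,
    )
    return uk.generate_dataset(spec)


def random_chemistry_and_point(rng: np.random.Generator):
    """One random but physically sensible chemistry, parameters and S_B.

    Parameters are drawn log-uniformly over realistic windows: buffers of
    1e-5 to 1e-2 mol/L with pKa 5-9, acid/base product couples around the
    carbonate/ammonium range, and kinetic parameters inside the optimiser
    box.
    """
    buffer = uk.BufferSystem(
        c_wb=10.0 ** rng.uniform(-5, -2),
        ka_w=10.0 ** rng.uniform(-9, -5),
        ph_b=rng.uniform(5.0, 9.0),
        kbar_w=10.0 ** rng.uniform(-0.5, 0.5),
    )
    products = uk.ProductSystem(
        n_a=float(rng.integers(1, 3)),
        ka_a=10.0 ** rng.uniform(-8, -4),
        n_b=float(rng.integers(1, 3)),
        ka_b=10.0 ** rng.uniform(-11, -8),
    )
    transport = uk.TransportModel(kbar_h=10.0 ** rng.uniform(-0.5, 0.5))
    params = uk.KineticParameters(
        k_m=10.0 ** rng.uniform(-4, -1),
        kbar_v=10.0 ** rng.uniform(-8, -2),
    )
    s_b = float(10.0 ** rng.uniform(-5, -1.3))
    return buffer, products, params, transport, s_b
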