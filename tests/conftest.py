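import numpy as np
import pytest

from pgtkit import fixtures as fx
from pgtkit import transport as tr
from pgtkit.model import BeamSpec, DetectorSpec


@pytest.fixture(scope="session")
def water_phantom():
    return tr.homogeneous("water", 400.0)


@pytest.fixture(scope="session")
def pmma_phantom():
    return tr.homogeneous("pmma", 400.0)


@pytest.fixture(scope="session")
def cavity_phantom():
    return fx.insert_phantom(169.0, 5.0, "air")


@pytest.fixture(scope="session")
def bone_phantom():
    return fx.insert_phantom(169.0, 20.0, "bone")


@pytest.fixture(scope="session")
def beam_230():
    return BeamSpec(E0=230.0, f_bunch=106.0, n_protons=1e8, gamma_yield=0.16)


@pytest.fixture(scope="session")
def ring_detector():
    return DetectorSpec(alpha=90.0, d=300.0, radius=25.4, eff=0.5, sigma_det=0.3)


def fixed_step_transport(phantom, E0, z_end, dz=1e-3):
    """Independent fixed-step (1 um default) transport oracle.

    Midpoint (RK2) update for the energy ODE and trapezoidal accumulation of
    1/v for the transit time; deliberately avoids the package's adaptive
    integration paths.
    """
    z = np.arange(0.0, z_end + dz / 2, dz)
    E = np.empty(len(z))
    E[0] = E0
    for i in range(len(z) - 1):
        m = phantom.material_at(min(z[i], phantom.length - 1e-9))
        e = E[i]
        if e <= tr.E_FLOOR:
            E[i + 1] = e
            continue
        k1 = m.rho * tr.stopping_power(m, e) / 10.0
        em = max(e - 0.5 * dz * k1, tr.E_FLOOR)
        k2 = m.rho * tr.stopping_power(m, em) / 10.0
        E[i + 1] = max(e - dz * k2, tr.E_FLOOR)
    inv_v = 1.0 / tr.velocity(np.maximum(E, tr.E_FLOOR))
    t = np.concatenate([[0.0], np.cumsum(0.5 * (inv_v[1:] + inv_v[:-1]) * dz)])
    return z, E, t
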