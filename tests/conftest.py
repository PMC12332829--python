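import numpy as np
import pytest

import cvinverse as cv

# printed interface parameter sets of the stepwise sensor build-up
BARE = cv.InterfaceParams(D=1e-5, k0=4.5e-3, alpha=0.5, ECSA=0.1256)
NANOCOMPOSITE = cv.InterfaceParams(D=6e-5, k0=2.1e-3, alpha=0.5, ECSA=0.1256)
ANTIBODY = cv.InterfaceParams(D=1.2e-5, k0=6.5e-3, alpha=0.5, ECSA=0.1125)

# printed 4PL parameter sets (electrochemical sensor / ELISA)
FOURPL_EC = cv.FourPLParams(a=-15.2, b=-0.64, c=8.92, d=-12.5)
FOURPL_ELISA = cv.FourPLParams(a=0.183, b=1.83, c=79.4, d=3.63)


@pytest.fixture(scope="session")
def couple() -> cv.RedoxCouple:
    """10 mM oxidized probe at room temperature, E_f0 = -0.25 V."""
    return cv.RedoxCouple(c_b=1e-5, E_f0=-0.25, T=298.0)


@pytest.fixture(scope="session")
def protocol() -> cv.CVProtocol:
    """Default protocol: -0.6..+0.1 V, 100 mV/s, 10 mV steps, one cycle."""
    return cv.CVProtocol()


@pytest.fixture(scope="session")
def fine_protocol() -> cv.CVProtocol:
    """2 mV recording steps, for oracle checks that need unquantized peaks."""
    return cv.CVProtocol(E_step=0.002)


def grid_for(D: float, protocol: cv.CVProtocol, n_points: int = 500) -> cv.SpatialGrid:
    return cv.make_grid(cv.domain_length(D, protocol), n_points)


@pytest.fixture(scope="session")
def bare_trace(couple, protocol) -> cv.CVTrace:
    """Noise-free voltammogram at the bare-electrode parameter set."""
    return cv.simulate_cv(BARE, couple, protocol, grid_for(BARE.D, protocol))


def synthetic_peak_trace(
    I_ox_uA: float = 50.0,
    I_red_uA: float = -60.0,
    E_ox: float = -0.25,
    E_red: float = -0.31,
    n: int = 141,
):
    """Hand-built triangular-sweep trace with Gaussian current bumps at the
    requested peak positions/heights; peaks fall exactly on samples."""
    proto = cv.CVProtocol()
    t = np.linspace(0.0, proto.duration, n)
    E = cv.waveform(proto, t)
    direction = np.concatenate([[E[1] - E[0]], np.diff(E)])
    i = np.zeros(n)
    width = 0.05
    cath = direction < 0
    i[cath] += I_red_uA * 1e-6 * np.exp(-((E[cath] - E_red) / width) ** 2)
    i[~cath] += I_ox_uA * 1e-6 * np.exp(-((E[~cath] - E_ox) / width) ** 2)
    # snap the exact extrema onto the nearest samples of each sweep
    jr = np.where(cath)[0][np.argmin(np.abs(E[cath] - E_red))]
    jo = np.where(~cath)[0][np.argmin(np.abs(E[~cath] - E_ox))]
    i[jr] = I_red_uA * 1e-6
    i[jo] = I_ox_uA * 1e-6
    E[jr] = E_red
    E[jo] = E_ox
    return cv.CVTrace(t=t, E=E, i=i, cycle=np.zeros(n, dtype=int))
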