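import numpy as np
import pytest

import ctdinuc as cd


@pytest.fixture(scope="session")
def cfg():
    return cd.BroadeningConfig()


@pytest.fixture(scope="session")
def ga_model():
    return cd.reference_model("GA")


@pytest.fixture(scope="session")
def ag_model():
    return cd.reference_model("AG")


@pytest.fixture(scope="session")
def ag_anti_anti_model():
    return cd.reference_model("AG", "anti-anti")


@pytest.fixture(scope="session")
def probe():
    return cd.probe_grid()


@pytest.fixture(scope="session")
def steady():
    return cd.steady_state_grid()


@pytest.fixture(scope="session")
def ag_tas_clean():
    """Noise-free AG reference matrix (shared; read-only)."""
    return cd.reference_tas("AG")


@pytest.fixture(scope="session")
def ga_tas_clean():
    return cd.reference_tas("GA")


@pytest.fixture(scope="session")
def ga_tas_noisy():
    """GA reference matrix with the default 1e-5 OD noise, fixed seed."""
    return cd.reference_tas("GA", noise_sigma=1e-5, seed=11)


def single_exp_tas(tau_ps=5.0, amplitudes=None, times=None, wavelengths=None):
    """Noise-free single-exponential matrix for fit tests."""
    if times is None:
        times = np.linspace(1.0, 50.0, 60)
    if wavelengths is None:
        wavelengths = np.linspace(400.0, 600.0, 9)
    if amplitudes is None:
        amplitudes = 1e-4 * np.sin(np.linspace(0.3, 2.8, wavelengths.size))
    da = np.exp(-times[:, None] / tau_ps) * np.asarray(amplitudes)[None, :]
    return cd.TASMatrix(times, wavelengths, da), np.asarray(amplitudes)


def biexp_tas(tau1=3.0, tau2=30.0, times=None, wavelengths=None, seed=0):
    rng = np.random.default_rng(seed)
    if times is None:
        times = np.linspace(1.0, 120.0, 80)
    if wavelengths is None:
        wavelengths = np.linspace(350.0, 650.0, 12)
    a1 = 1e-4 * rng.uniform(-1, 1, wavelengths.size)
    a2 = 1e-4 * rng.uniform(-1, 1, wavelengths.size)
    da = (
        np.exp(-times[:, None] / tau1) * a1[None, :]
        + np.exp(-times[:, None] / tau2) * a2[None, :]
    )
    return cd.TASMatrix(times, wavelengths, da), (a1, a2)
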