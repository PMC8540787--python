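import numpy as np
import pytest

from pulsetf import (
    AGE_TEMPLATES,
    REFERENCE_PARAMS,
    SampledSignal,
    generate_intravascular_pulse,
)


@pytest.fixture(scope="session")
def ref_params():
    """Reference constitutive constants (vessel modulus from the vessel-only
    slope, skin pair from the grid-search fit)."""
    return REFERENCE_PARAMS


@pytest.fixture(scope="session")
def band_limited_stress():
    """A smooth periodic stress built from 5 harmonics with decaying
    amplitudes and seeded phases (T = 0.65 s, dt = 1 ms)."""
    dt, T = 1e-3, 0.65
    n = int(round(T / dt))
    t = np.arange(n) * dt
    rng = np.random.default_rng(7)
    v = np.zeros(n)
    for k in range(1, 6):
        v += (1.0 / k**2) * np.cos(2 * np.pi * k * t / T + rng.uniform(0, 2 * np.pi))
    return SampledSignal(1e3 * v, dt, unit="Pa", periodic=True, period=T)


@pytest.fixture(scope="session")
def age65_pulse():
    return generate_intravascular_pulse(AGE_TEMPLATES[65])


def fft_strain_oracle(stress, params):
    """Independent frequency-domain route: per-harmonic transfer H(i*w_k)."""
    from pulsetf import harmonic_transfer

    X = np.fft.rfft(stress.values)
    wk = 2 * np.pi * np.fft.rfftfreq(stress.n, stress.dt)
    return np.fft.irfft(X * harmonic_transfer(params, wk), stress.n)


def rel_l2(x, y):
    return np.linalg.norm(np.asarray(x) - np.asarray(y)) / np.linalg.norm(np.asarray(y))
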