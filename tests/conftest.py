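import numpy as np
import pytest

import ggcbench as gb


@pytest.fixture(scope="session")
def two_node_model():
    """Two coupled 40 Hz oscillators, unidirectional 1 -> 2."""
    return gb.build_two_node_oscillator_model()


@pytest.fixture(scope="session")
def snr2_model():
    """Two-node AR(2) network with 1 -> 2 coupling [0.2, -0.1]."""
    return gb.build_snr_network_model(2, [(1, 2)])


@pytest.fixture(scope="session")
def chain_model():
    """Three-node chain 1 -> 2 -> 3."""
    return gb.build_snr_network_model(3, [(1, 2), (2, 3)])


@pytest.fixture(scope="session")
def grid_400():
    """Default frequency grid: 400 samples at 200 Hz."""
    return np.fft.rfftfreq(400, 1 / 200.0)


def parametric_ggc_pairwise(model, freqs):
    """Independent oracle: Geweke's bivariate measure from the model itself.

    Evaluates the transfer function directly from the coefficient matrices
    (no spectral factorization anywhere) and applies the bivariate formula.
    Only valid for 2-channel models.
    """
    assert model.n_channels == 2
    fs = model.sampling_rate
    p = model.order
    sigma = model.noise_cov
    values = np.zeros((2, 2, len(freqs)))
    for fi, f in enumerate(freqs):
        a = np.eye(2, dtype=complex)
        for k in range(1, p + 1):
            a -= model.coeffs[k - 1] * np.exp(-2j * np.pi * f * k / fs)
        h = np.linalg.inv(a)
        s = h @ sigma @ h.conj().T
        for i, j in ((0, 1), (1, 0)):
            corr = sigma[j, j] - sigma[i, j] ** 2 / sigma[i, i]
            den = s[i, i].real - corr * abs(h[i, j]) ** 2
            values[i, j, fi] = np.log(s[i, i].real / den)
    return values
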