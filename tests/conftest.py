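import numpy as np
import pytest

from calwave import fdf


@pytest.fixture(scope="session")
def wave_params():
    """Study conditions used across FDF tests: Gamma = 10, d = 2 um lattice."""
    def make(D, tau, n_sites=24, sigma_conc=5.0, d=2.0):
        return fdf.FDFParameters.regular(
            n_sites,
            D=D,
            d=d,
            sigma_conc=sigma_conc,
            tau=tau,
            ca_threshold=0.6,
            ca_basal=0.1,
        )

    return make


@pytest.fixture(scope="session")
def continuous_run(wave_params):
    """One continuous-regime simulation (D = 190 um^2/s, beta = 1.9), shared."""
    p = wave_params(190.0, 0.04, n_sites=16)
    return fdf.simulate_fdf(p, fdf.SimulationGrid.for_params(p))
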