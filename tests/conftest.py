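import numpy as np
import pytest

from fractaldiff import WalkParameters


@pytest.fixture
def bilayer_params():
    """Calibration of the lipid-bilayer tracking example: lambda = 0.0559 um,
    tau = 3.77e-4 s (from lambda and the unobstructed D = 4.15 um^2/s)."""
    return {"lambda_mfp": 0.0559, "tau": 3.77e-4, "D": 4.15}


@pytest.fixture
def unit_walk():
    """Ordinary diffusion with unit mean free path and step time."""
    return WalkParameters(lambda_mfp=1.0, tau=1.0, alpha=1.0)


def msd_alpha1_closed_form(n_steps):
    """Independent oracle: at alpha = 1 the crossover equation is the
    quadratic x*(2+x) = 2*n, so x = -1 + sqrt(1 + 2n) and y = x^2."""
    n = np.asarray(n_steps, dtype=float)
    return (-1.0 + np.sqrt(1.0 + 2.0 * n)) ** 2
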