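import numpy as np
import pytest

from cscdyn import DivisionProbabilities, KineticParameters, RadiationParameters


@pytest.fixture(scope="session")
def default_params() -> KineticParameters:
    """The measured baseline parameter set (SW620 in-situ values)."""
    return KineticParameters()


@pytest.fixture(scope="session")
def default_radiation() -> RadiationParameters:
    return RadiationParameters()


@pytest.fixture(scope="session")
def reduced_root_oracle():
    """Brute-force sign-scan root finder for the reduced proportion equation.

    Independent of the package's root finding: evaluates dR/dt on a dense
    uniform grid and returns midpoints of sign changes (plus exact grid
    zeros), accurate to the grid spacing.
    """

    def scan(params: KineticParameters, n: int = 1_000_001):
        k_t, k_n, k_c = params.k_transition, params.k_nscc_division, params.k_csc_mitosis
        e = params.e
        grid = np.linspace(0.0, 1.0, n)
        f = (k_c * e * grid + k_t * (1.0 - grid)
             - grid * (k_c * grid + k_n * (1.0 - grid)))
        roots = [0.5 * (grid[i] + grid[i + 1])
                 for i in np.nonzero(np.sign(f[:-1]) * np.sign(f[1:]) < 0)[0]]
        roots.extend(grid[i] for i in np.nonzero(f == 0.0)[0])
        return sorted(roots)

    return scan
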