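"""Shared fixtures and independent numerical oracles for the test suite."""

import numpy as np
import pytest
from scipy.integrate import quad

from multispawn import LVCModel, make_model


@pytest.fixture(scope="session")
def sloped_ci():
    return make_model("sloped_ci")


@pytest.fixture(scope="session")
def flat_rabi():
    return make_model("flat_rabi")


@pytest.fixture(scope="session")
def uncoupled():
    return make_model("uncoupled_harmonic")


@pytest.fixture(scope="session")
def random_lvc_2state():
    """A dense random 2-state, 3-mode model for oracle tests."""
    rng = np.random.default_rng(42)
    lam = np.zeros((2, 2, 3))
    lam[0, 1] = lam[1, 0] = rng.normal(0, 0.1, 3)
    return LVCModel(
        omega=rng.uniform(0.5, 2.0, 3),
        energies=[0.0, 0.8],
        kappa=rng.normal(0, 0.3, (2, 3)),
        lam=lam,
    )


@pytest.fixture(scope="session")
def random_lvc_3state():
    rng = np.random.default_rng(7)
    lam = np.zeros((3, 3, 2))
    for a in range(3):
        for b in range(a + 1, 3):
            lam[a, b] = lam[b, a] = rng.normal(0, 0.1, 2)
    return LVCModel(
        omega=rng.uniform(0.5, 2.0, 2),
        energies=[0.0, 0.5, 1.3],
        kappa=rng.normal(0, 0.3, (3, 2)),
        lam=lam,
    )


@pytest.fixture(scope="session")
def braket_quad():
    """Expose the quadrature oracle to test modules as a fixture."""
    return gaussian_braket_quadrature


def gaussian_braket_quadrature(a, b, operator=None):
    """<chi_a | op | chi_b> by adaptive 1-D quadrature per coordinate.

    The TBFs are coordinate products, so the integral factorizes exactly;
    ``operator`` maps (rho, x) to a per-coordinate factor (identity default).
    Independent of every closed form in the package.
    """
    def factor(rho):
        aa, bb = a.alpha[rho], b.alpha[rho]
        Ra, Rb = a.R[rho], b.R[rho]
        Pa, Pb = a.P[rho], b.P[rho]
        pref = (2 * aa / np.pi) ** 0.25 * (2 * bb / np.pi) ** 0.25

        def integrand(x):
            val = pref * np.exp(
                -aa * (x - Ra) ** 2 - 1j * Pa * (x - Ra)
                - bb * (x - Rb) ** 2 + 1j * Pb * (x - Rb)
            )
            if operator is not None:
                val = val * operator(rho, x)
            return val

        re = quad(lambda x: integrand(x).real, -np.inf, np.inf, limit=200)[0]
        im = quad(lambda x: integrand(x).imag, -np.inf, np.inf, limit=200)[0]
        return re + 1j * im

    out = np.prod([factor(r) for r in range(a.n_modes)])
    return out * np.exp(1j * (b.gamma - a.gamma))
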