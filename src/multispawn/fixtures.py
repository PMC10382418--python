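"""Synthetic inputs: toy vibronic models and random TBF pairs.

Everything the test-suite and the examples consume is generated here as a
pure function of (kind, seed) — no external data.  The shipped two-mode,
two-state sloped-intersection model is a *synthetic stand-in* with the
standard linear-vibronic-coupling functional form and spectroscopically
plausible magnitudes (vibrational quanta of a few hundredths of a Hartree,
interstate coupling of order 0.01 Ha); it is not a fit to any published
molecular parameter set.
"""

from __future__ import annotations

import numpy as np

from .gaussians import TBF
from .models import LVCModel

__all__ = ["make_model", "random_tbf_pair", "MODEL_KINDS"]

MODEL_KINDS = ("uncoupled_harmonic", "flat_rabi", "sloped_ci")


def make_model(kind: str, seed: int = 0) -> LVCModel:
    """Deterministic toy models (``seed`` reserved for randomized variants).

    ``uncoupled_harmonic``
        One mode, two uncoupled states sharing the harmonic surface: the
        coupling machinery must leave populations untouched.
    ``flat_rabi``
        One mode, two states with identical diagonals and a constant
        interstate coupling: electronic and nuclear motion decouple exactly
        and the state populations Rabi-oscillate with period pi/V.
    ``sloped_ci``
        Two modes (one tuning, one coupling), two states, opposite-sign
        linear tuning couplings.  The conical intersection sits on the
        q_coupling = 0 axis at q_t = (E_1 - E_0)/(kappa_0 - kappa_1) ~ -1.18,
        energetically below the Franck-Condon point of the upper state, and
        both adiabatic surfaces slope the same way along the tuning mode at
        the seam (|mean slope| > |half slope difference|): a sloped
        intersection favoring wavepacket recrossing.
    """
    if kind == "uncoupled_harmonic":
        return LVCModel(
            omega=[1.0],
            energies=[0.0, 1.0],
            kappa=np.zeros((2, 1)),
            lam=np.zeros((2, 2, 1)),
        )
    if kind == "flat_rabi":
        lam0 = np.array([[0.0, 0.01], [0.01, 0.0]])
        return LVCModel(
            omega=[1.0],
            energies=[0.0, 0.0],
            kappa=np.zeros((2, 1)),
            lam=np.zeros((2, 2, 1)),
            lam0=lam0,
        )
    if kind == "sloped_ci":
        omega = [0.0095, 0.0033]           # tuning, coupling (Hartree)
        energies = [0.0, 0.02]
        kappa = np.array([[-0.008, 0.0], [0.009, 0.0]])
        lam = np.zeros((2, 2, 2))
        lam[0, 1, 1] = lam[1, 0, 1] = 0.012
        return LVCModel(omega=omega, energies=energies, kappa=kappa, lam=lam)
    raise ValueError(f"unknown model kind {kind!r}; choose from {MODEL_KINDS}")


def random_tbf_pair(dim: int, seed: int, same_widths: bool = False):
    """A reproducible pair of random TBFs for matrix-element oracle tests.

    Widths in [0.2, 5], centers and momenta in [-3, 3], phases in [0, 2 pi):
    wide enough to exercise both near-orthogonal and strongly overlapping
    regimes.
    """
    if dim < 1:
        raise ValueError("dim must be at least 1")
    rng = np.random.default_rng(seed)

    def one(alpha=None):
        return TBF(
            state=0,
            R=rng.uniform(-3, 3, dim),
            P=rng.uniform(-3, 3, dim),
            alpha=rng.uniform(0.2, 5.0, dim) if alpha is None else alpha,
            gamma=rng.uniform(0.0, 2 * np.pi),
        )

    a = one()
    b = one(alpha=a.alpha.copy() if same_widths else None)
    return a, b
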