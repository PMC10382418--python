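"""Frozen-Gaussian trajectory basis functions (TBFs) and their matrix elements.

A TBF is a normalized product of one-dimensional Gaussians

    chi(R) = exp(i gamma) * prod_rho (2 a_rho / pi)^(1/4)
             * exp[-a_rho (R_rho - Rbar_rho)^2 + i Pbar_rho (R_rho - Rbar_rho)]

with fixed (frozen) widths ``a_rho``, a center ``(Rbar, Pbar)`` that follows a
classical trajectory on one adiabatic surface, and a semiclassical phase
``gamma``.  Every bra-ket between two TBFs needed by the multiple-spawning
equations of motion — overlap, nuclear derivative, kinetic energy, and the
time derivative of the ket — has a closed form; those closed forms live here,
both as scalar pair functions and as an all-pairs batched kernel used by the
coupled-set matrix assembly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TBF",
    "overlap",
    "derivative_element",
    "kinetic_element",
    "sdot_element",
    "centroid",
    "PairTable",
    "pair_table",
]

_ids = itertools.count()


def _token() -> str:
    return f"tbf-{next(_ids)}"


@dataclass
class TBF:
    """One frozen-Gaussian trajectory basis function.

    Attributes
    ----------
    state : int
        Electronic state index the center propagates on.
    R, P : (n_modes,) arrays
        Center position and momentum (a.u.).
    alpha : (n_modes,) array
        Per-coordinate Gaussian width, strictly positive (a.u.).
    gamma : float
        Semiclassical phase (radians).
    """

    state: int
    R: np.ndarray
    P: np.ndarray
    alpha: np.ndarray
    gamma: float = 0.0
    id: str = field(default_factory=_token)
    parent_id: str | None = None
    birth_time: float = 0.0

    def __post_init__(self):
        self.R = np.atleast_1d(np.asarray(self.R, float)).copy()
        self.P = np.atleast_1d(np.asarray(self.P, float)).copy()
        self.alpha = np.atleast_1d(np.asarray(self.alpha, float)).copy()
        if not (self.R.shape == self.P.shape == self.alpha.shape):
            raise ValueError("R, P and alpha must have identical shapes")
        if np.any(self.alpha <= 0):
            raise ValueError("all TBF widths must be positive")

    @property
    def n_modes(self) -> int:
        return self.R.size

    def clone(self, **overrides) -> "TBF":
        """Copy with a fresh id unless one is supplied."""
        kw = dict(
            state=self.state, R=self.R, P=self.P, alpha=self.alpha,
            gamma=self.gamma, parent_id=self.parent_id,
            birth_time=self.birth_time,
        )
        kw.update(overrides)
        return TBF(**kw)

    def evaluate(self, R) -> np.ndarray:
        """Value of the TBF at points ``R`` of shape ``(..., n_modes)``."""
        R = np.asarray(R, float)
        dr = R - self.R
        norm = np.prod((2.0 * self.alpha / np.pi) ** 0.25)
        expo = (-self.alpha * dr**2 + 1j * self.P * dr).sum(axis=-1)
        return norm * np.exp(1j * self.gamma + expo)


def _check_pair(a: TBF, b: TBF) -> None:
    if a.n_modes != b.n_modes:
        raise ValueError("TBFs live in spaces of different dimensionality")


@dataclass(frozen=True)
class PairTable:
    """All-pairs closed-form quantities for a stack of N TBFs.

    ``overlap[i, j] = <chi_i | chi_j>`` (phases included); ``deriv[i, j, rho]``
    is ``<chi_i | d/dR_rho | chi_j>``; ``kinetic[i, j] = <chi_i | T_n | chi_j>``
    for the masses supplied; ``centroid[i, j]`` the width-weighted midpoint.
    ``mu`` and ``dmu = mu - Rbar_ket`` are the (complex) first moments used to
    assemble the time-derivative couplings.
    """

    overlap: np.ndarray   # (N, N) complex
    deriv: np.ndarray     # (N, N, m) complex
    kinetic: np.ndarray   # (N, N) complex
    centroid: np.ndarray  # (N, N, m) real
    mu: np.ndarray        # (N, N, m) complex
    dmu: np.ndarray       # (N, N, m) complex
    f: np.ndarray         # (N, N, m) complex, <a|(-2 a_b (R-Rb) + i Pb)|b>/<a|b>


def pair_table(R, P, alpha, gamma, masses) -> PairTable:
    """Closed-form matrix elements for every ordered pair of N TBFs.

    Parameters are stacked per TBF: ``R, P, alpha`` of shape ``(N, m)``,
    ``gamma`` of shape ``(N,)``; ``masses`` of shape ``(m,)``.
    """
    R = np.asarray(R, float)
    P = np.asarray(P, float)
    alpha = np.asarray(alpha, float)
    gamma = np.asarray(gamma, float)
    masses = np.asarray(masses, float)

    aa = alpha[:, None, :]
    ab = alpha[None, :, :]
    Ra = R[:, None, :]
    Rb = R[None, :, :]
    Pa = P[:, None, :]
    Pb = P[None, :, :]

    c = aa + ab
    d = 2.0 * aa * Ra + 2.0 * ab * Rb + 1j * (Pb - Pa)
    e = -aa * Ra**2 - ab * Rb**2 + 1j * (Pa * Ra - Pb * Rb)
    pref = (4.0 * aa * ab / np.pi**2) ** 0.25 * np.sqrt(np.pi / c)
    ov1d = pref * np.exp(d * d / (4.0 * c) + e)
    phase = np.exp(1j * (gamma[None, :] - gamma[:, None]))
    O = ov1d.prod(axis=-1) * phase

    mu = d / (2.0 * c)
    dmu = mu - Rb
    f = -2.0 * ab * dmu + 1j * Pb
    # <a|d^2/dR^2|b> / <a|b> per coordinate
    A = (4.0 * ab**2 * (dmu**2 + 1.0 / (2.0 * c))
         - 4j * ab * Pb * dmu - Pb**2 - 2.0 * ab)
    K = (-A / (2.0 * masses)).sum(axis=-1) * O
    cent = (aa * Ra + ab * Rb) / c
    return PairTable(
        overlap=O, deriv=f * O[..., None], kinetic=K,
        centroid=cent, mu=mu, dmu=dmu, f=f,
    )


def _table2(a: TBF, b: TBF, masses=None) -> PairTable:
    _check_pair(a, b)
    if masses is None:
        masses = np.ones(a.n_modes)
    return pair_table(
        np.stack([a.R, b.R]), np.stack([a.P, b.P]),
        np.stack([a.alpha, b.alpha]), np.array([a.gamma, b.gamma]),
        masses,
    )


def overlap(a: TBF, b: TBF) -> complex:
    """<chi_a | chi_b>, phase factors included; |overlap| <= 1."""
    return complex(_table2(a, b).overlap[0, 1])


def derivative_element(a: TBF, b: TBF, rho: int) -> complex:
    """<chi_a | d/dR_rho | chi_b>."""
    if not 0 <= rho < a.n_modes:
        raise ValueError(f"coordinate index {rho} out of range")
    return complex(_table2(a, b).deriv[0, 1, rho])


def kinetic_element(a: TBF, b: TBF, masses) -> complex:
    """<chi_a | T_n | chi_b> with T_n = -sum_rho (1/2 M_rho) d^2/dR_rho^2."""
    masses = np.atleast_1d(np.asarray(masses, float))
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    return complex(_table2(a, b, masses).kinetic[0, 1])


def sdot_element(a: TBF, b: TBF, b_dynamics) -> complex:
    """<chi_a | d chi_b / dt> given the classical rates of the ket.

    ``b_dynamics`` is ``(dR/dt, dP/dt, dgamma/dt)`` for TBF ``b``, obtained
    from its classical equations of motion.  The derivative is taken through
    the ket's center, momentum and phase (frozen widths).
    """
    dR, dP, dgamma = b_dynamics
    dR = np.atleast_1d(np.asarray(dR, float))
    dP = np.atleast_1d(np.asarray(dP, float))
    t = _table2(a, b)
    term = (-t.f[0, 1] * dR + 1j * t.dmu[0, 1] * dP).sum() + 1j * float(dgamma)
    return complex(t.overlap[0, 1] * term)


def centroid(a: TBF, b: TBF) -> np.ndarray:
    """Width-weighted midpoint (alpha_a R_a + alpha_b R_b)/(alpha_a + alpha_b).

    This is the position where the product |chi_a chi_b| peaks — the
    evaluation point of the zeroth-order saddle-point approximation.
    """
    _check_pair(a, b)
    return (a.alpha * a.R + b.alpha * b.R) / (a.alpha + b.alpha)
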