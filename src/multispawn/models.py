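"""Analytic diabatic model potentials: the linear vibronic coupling (LVC) family.

An LVC model plays the role of the electronic-structure backend for the
multiple-spawning dynamics: it provides diabatic potential matrices, adiabatic
energies, energy gradients and nonadiabatic coupling vectors at any nuclear
geometry, all in closed form.

Conventions
-----------
Coordinates are dimensionless normal modes ``q``.  The kinetic energy is
``sum_i (omega_i / 2) p_i**2``, i.e. the effective mass of mode ``i`` is
``1 / omega_i`` (atomic units, energies in Hartree).  With this choice the
ground vibrational state of the uncoupled model is ``exp(-q**2 / 2)`` per mode,
so a frozen Gaussian of width ``alpha = 1/2`` matches it exactly.

The diabatic matrix is

    W_AA(q) = E_A + sum_i kappa[A, i] q_i + sum_i (omega_i / 2) q_i**2
    W_AB(q) = lam0[A, B] + sum_i lam[A, B, i] q_i          (A != B)

``lam0`` is an optional constant interstate coupling (zero for a strict LVC
model); it makes flat-gap Rabi-type test systems expressible in the same class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import tomllib

import numpy as np

__all__ = [
    "LVCModel",
    "ModelInputError",
    "NearDegeneracyError",
    "DEGENERACY_FLOOR",
    "diabatic_matrix",
    "diabatic_gradient_matrix",
    "adiabatic_surface",
    "adiabatic_gradient",
    "nac_vector",
    "load_model",
    "save_model",
]

#: Minimum adiabatic gap (Hartree) below which nonadiabatic coupling vectors
#: are considered numerically undefined.
DEGENERACY_FLOOR = 1e-8

MODEL_SCHEMA = "multispawn-lvc-1"


class ModelInputError(ValueError):
    """Raised for malformed model definitions or mismatched geometry input."""


class NearDegeneracyError(ArithmeticError):
    """Raised when a coupling vector is requested at a (near-)degenerate point."""

    def __init__(self, gap: float, floor: float = DEGENERACY_FLOOR):
        self.gap = gap
        super().__init__(
            f"adiabatic gap {gap:.3e} Ha below degeneracy floor {floor:.0e}; "
            "nonadiabatic coupling vector diverges at a conical intersection"
        )


@dataclass(frozen=True)
class LVCModel:
    """Linear vibronic coupling Hamiltonian on dimensionless normal modes.

    Parameters
    ----------
    omega : (n_modes,) array
        Harmonic frequency of each mode, Hartree.  Must be positive.
    energies : (n_states,) array
        Vertical energies E_A at the Franck-Condon point (q = 0), Hartree.
    kappa : (n_states, n_modes) array
        Linear intrastate (tuning) coupling constants, Hartree.
    lam : (n_states, n_states, n_modes) array
        Linear interstate coupling constants, Hartree; symmetric in the two
        state indices with a zero diagonal.
    lam0 : (n_states, n_states) array
        Constant interstate coupling, Hartree; symmetric, zero diagonal.
        Zero for a strict LVC model.
    """

    omega: np.ndarray
    energies: np.ndarray
    kappa: np.ndarray
    lam: np.ndarray
    lam0: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        conv = lambda a: np.atleast_1d(np.asarray(a, dtype=float))
        omega = conv(self.omega)
        energies = conv(self.energies)
        m, s = omega.size, energies.size
        kappa = np.zeros((s, m)) if self.kappa is None else np.asarray(self.kappa, float)
        lam = np.zeros((s, s, m)) if self.lam is None else np.asarray(self.lam, float)
        lam0 = np.zeros((s, s)) if self.lam0 is None else np.asarray(self.lam0, float)
        if np.any(omega <= 0):
            raise ModelInputError("all mode frequencies must be positive")
        if kappa.shape != (s, m):
            raise ModelInputError(f"kappa must have shape {(s, m)}, got {kappa.shape}")
        if lam.shape != (s, s, m):
            raise ModelInputError(f"lam must have shape {(s, s, m)}, got {lam.shape}")
        if lam0.shape != (s, s):
            raise ModelInputError(f"lam0 must have shape {(s, s)}, got {lam0.shape}")
        for name, arr in (("lam", lam), ("lam0", lam0)):
            if not np.allclose(arr, np.swapaxes(arr, 0, 1)):
                raise ModelInputError(f"{name} must be symmetric under state exchange")
            if np.any(np.abs(np.diagonal(arr, axis1=0, axis2=1)) > 0):
                raise ModelInputError(f"{name} must have a zero state diagonal")
        for name, arr in (
            ("omega", omega), ("energies", energies),
            ("kappa", kappa), ("lam", lam), ("lam0", lam0),
        ):
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)

    @property
    def n_modes(self) -> int:
        return self.omega.size

    @property
    def n_states(self) -> int:
        return self.energies.size

    @property
    def eff_mass(self) -> np.ndarray:
        """Effective mass per mode (1/omega, dimensionless convention)."""
        return 1.0 / self.omega

    # Thin method wrappers over the module functions.
    def diabatic(self, q):
        return diabatic_matrix(self, q)

    def adiabatic(self, q, prev_vecs=None):
        return adiabatic_surface(self, q, prev_vecs=prev_vecs)

    def gradient(self, q, J):
        return adiabatic_gradient(self, q, J)

    def nac(self, q, I, J):
        return nac_vector(self, q, I, J)


def _check_q(model: LVCModel, q) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape[-1] != model.n_modes:
        raise ModelInputError(
            f"geometry has {q.shape[-1]} coordinates, model has {model.n_modes} modes"
        )
    return q


def diabatic_matrix(model: LVCModel, q) -> np.ndarray:
    """Diabatic potential matrix W(q), shape ``(..., n_states, n_states)``.

    Accepts a single geometry ``(n_modes,)`` or any batch ``(..., n_modes)``.
    """
    q = _check_q(model, q)
    s = model.n_states
    harm = 0.5 * (model.omega * q**2).sum(axis=-1)
    diag = model.energies + q @ model.kappa.T + harm[..., None]
    W = np.einsum("...m,abm->...ab", q, model.lam) + model.lam0
    idx = np.arange(s)
    W[..., idx, idx] = diag
    return W


def diabatic_gradient_matrix(model: LVCModel, q) -> np.ndarray:
    """Coordinate gradient of W, shape ``(..., n_modes, n_states, n_states)``."""
    q = _check_q(model, q)
    m, s = model.n_modes, model.n_states
    base = np.moveaxis(model.lam, 2, 0)  # (m, s, s), constant
    G = np.broadcast_to(base, q.shape[:-1] + (m, s, s)).copy()
    idx = np.arange(s)
    # dW_AA/dq_i = kappa[A, i] + omega_i q_i
    G[..., idx, idx] = model.kappa.T + model.omega[:, None] * q[..., None]
    return G


def _fix_gauge(vecs: np.ndarray, prev_vecs: np.ndarray | None) -> np.ndarray:
    """Fix eigenvector signs: align with prev_vecs, else largest component > 0."""
    if prev_vecs is not None:
        proj = np.sum(prev_vecs * vecs, axis=-2)
        sign = np.where(proj < 0, -1.0, 1.0)
    else:
        comp = np.take_along_axis(
            vecs, np.argmax(np.abs(vecs), axis=-2)[..., None, :], axis=-2
        )[..., 0, :]
        sign = np.where(comp < 0, -1.0, 1.0)
    return vecs * sign[..., None, :]


def _eigh_2x2(W: np.ndarray):
    """Closed-form spectral decomposition of stacked symmetric 2x2 matrices.

    Parametrizing W - wbar*I = r (sigma_z cos 2t + sigma_x sin 2t), the
    eigenpairs are (wbar - r, (-sin t, cos t)) and (wbar + r, (cos t, sin t)).
    Much faster than a LAPACK call per small matrix.
    """
    wbar = 0.5 * (W[..., 0, 0] + W[..., 1, 1])
    half = 0.5 * (W[..., 0, 0] - W[..., 1, 1])
    w12 = W[..., 0, 1]
    r = np.hypot(half, w12)
    energies = np.stack([wbar - r, wbar + r], axis=-1)
    theta = 0.5 * np.arctan2(2.0 * w12, 2.0 * half)
    ct, st = np.cos(theta), np.sin(theta)
    vecs = np.empty(W.shape)
    vecs[..., 0, 0] = -st
    vecs[..., 1, 0] = ct
    vecs[..., 0, 1] = ct
    vecs[..., 1, 1] = st
    return energies, vecs


def adiabatic_surface(model: LVCModel, q, prev_vecs=None):
    """Adiabatic energies (ascending) and gauge-fixed eigenvectors at ``q``.

    ``prev_vecs``, when given, fixes each eigenvector's sign to maximise its
    overlap with the corresponding previous one (continuity along a path);
    otherwise the largest-magnitude component is made positive.
    Works on batched geometries.
    """
    energies, vecs = _surface_raw(model, q)
    return energies, _fix_gauge(vecs, prev_vecs)


def _surface_raw(model: LVCModel, q):
    """Adiabatic energies/eigenvectors without gauge fixing (internal fast
    path for gauge-invariant consumers: energies, Hellmann-Feynman forces)."""
    W = diabatic_matrix(model, q)
    if model.n_states == 2:
        return _eigh_2x2(W)
    return np.linalg.eigh(W)


def adiabatic_gradient(model: LVCModel, q, J: int) -> np.ndarray:
    """Hellmann-Feynman gradient of adiabatic state ``J``: c_J . (dW/dq) . c_J."""
    if not 0 <= J < model.n_states:
        raise ModelInputError(f"state index {J} out of range")
    _, vecs = adiabatic_surface(model, q)
    G = diabatic_gradient_matrix(model, q)
    cJ = vecs[..., :, J]
    return np.einsum("...a,...mab,...b->...m", cJ, G, cJ)


def _nac_two_state(model: LVCModel, q) -> np.ndarray:
    """Smooth closed-form d_01 for a 2-state model (theta-gauge, batched).

    With W - wbar*I = r(sigma_z cos 2t + sigma_x sin 2t), the lower/upper
    eigenvectors are (-sin t, cos t) / (cos t, sin t) and d_01 = grad t,
    a rational function of q with a globally consistent sign away from the
    intersection seam.
    """
    W = diabatic_matrix(model, q)
    G = diabatic_gradient_matrix(model, q)
    delta = W[..., 0, 0] - W[..., 1, 1]
    w12 = W[..., 0, 1]
    ddelta = G[..., 0, 0] - G[..., 1, 1]
    dw12 = G[..., 0, 1]
    denom = delta**2 + 4.0 * w12**2
    return (delta[..., None] * dw12 - w12[..., None] * ddelta) / denom[..., None]


def nac_vector(model: LVCModel, q, I: int, J: int) -> np.ndarray:
    """Nonadiabatic coupling vector d_IJ = <Phi_I | d/dq | Phi_J> at ``q``.

    Antisymmetric in (I, J).  Raises :class:`NearDegeneracyError` when the
    adiabatic gap falls below :data:`DEGENERACY_FLOOR` (the vector diverges
    like 1/gap at a conical intersection).
    """
    if I == J:
        raise ModelInputError("nac_vector requires two distinct states")
    energies, vecs = adiabatic_surface(model, q)
    gap = float(np.min(np.abs(energies[..., J] - energies[..., I])))
    if gap < DEGENERACY_FLOOR:
        raise NearDegeneracyError(gap)
    if model.n_states == 2:
        d01 = _nac_two_state(model, q)
        return d01 if (I, J) == (0, 1) else -d01
    G = diabatic_gradient_matrix(model, q)
    num = np.einsum("...a,...mab,...b->...m", vecs[..., :, I], G, vecs[..., :, J])
    return num / (energies[..., J] - energies[..., I])[..., None]


# ---------------------------------------------------------------------------
# Model files: small TOML documents (read with tomllib, written by hand).

def save_model(model: LVCModel, path) -> None:
    """Write a model definition to a TOML file (units: Hartree / a.u.)."""
    def fmt(a):
        return "[" + ", ".join(repr(float(x)) for x in np.ravel(a)) + "]"

    lines = [
        f'schema = "{MODEL_SCHEMA}"',
        f"n_modes = {model.n_modes}",
        f"n_states = {model.n_states}",
        f"omega = {fmt(model.omega)}",
        f"energies = {fmt(model.energies)}",
        "kappa = [" + ", ".join(fmt(row) for row in model.kappa) + "]",
    ]
    for a in range(model.n_states):
        for b in range(a + 1, model.n_states):
            if np.any(model.lam[a, b] != 0) or model.lam0[a, b] != 0:
                lines += [
                    "",
                    "[[coupling]]",
                    f"states = [{a}, {b}]",
                    f"linear = {fmt(model.lam[a, b])}",
                    f"constant = {float(model.lam0[a, b])!r}",
                ]
    Path(path).write_text("\n".join(lines) + "\n")


def load_model(path) -> LVCModel:
    """Read a model definition written by :func:`save_model`."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    if doc.get("schema") != MODEL_SCHEMA:
        raise ModelInputError(f"unknown model schema {doc.get('schema')!r}")
    m, s = int(doc["n_modes"]), int(doc["n_states"])
    lam = np.zeros((s, s, m))
    lam0 = np.zeros((s, s))
    for entry in doc.get("coupling", []):
        a, b = (int(i) for i in entry["states"])
        lam[a, b] = lam[b, a] = np.asarray(entry.get("linear", np.zeros(m)), float)
        lam0[a, b] = lam0[b, a] = float(entry.get("constant", 0.0))
    return LVCModel(
        omega=np.asarray(doc["omega"], float),
        energies=np.asarray(doc["energies"], float),
        kappa=np.asarray(doc["kappa"], float),
        lam=lam,
        lam0=lam0,
    )
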