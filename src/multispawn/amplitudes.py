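"""Coupled-amplitude dynamics of a set of TBFs.

The complex amplitudes C of the TBFs descending from one ancestor obey

    dC/dt = -i S^{-1} [ (H - i Sdot) C ]

with S the (state-block-diagonal) TBF overlap matrix, Sdot its time
derivative through the classical motion of the kets, and H the Hamiltonian
matrix in the zeroth-order saddle-point approximation (SPA0): same-state
pairs couple through the nuclear kinetic energy plus the adiabatic energy
evaluated at the pair centroid times the overlap; different-state pairs
couple through the first-order nonadiabatic coupling vector at the centroid
contracted with the nuclear-derivative matrix elements.  Second-order
nonadiabatic couplings are omitted.

Numerical safeguards mirror on-the-fly spawning codes: off-diagonal H and
Sdot entries are screened away for pairs whose absolute overlap falls below
``olapthresh`` (S itself is kept exact so it stays positive semidefinite),
H is Hermitized after assembly, and S is inverted through an eigenvalue
pseudo-inverse that discards eigenvalues below ``regthresh``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gaussians import TBF, pair_table
from .models import DEGENERACY_FLOOR, LVCModel, adiabatic_surface
from .propagation import SwarmRates, swarm_rates

__all__ = [
    "SimParams",
    "CoupledSet",
    "Matrices",
    "DegenerateBasisError",
    "assemble_matrices",
    "regularized_inverse",
    "propagate_coefficients",
    "mulliken_population",
    "state_population",
    "nes_count",
]


class DegenerateBasisError(np.linalg.LinAlgError):
    """Overlap-matrix regularization discarded every eigenvalue."""


@dataclass(frozen=True)
class SimParams:
    """Every user-facing knob of a multiple-spawning run.

    Defaults are the reference settings for reduced-dimensional vibronic
    models: nuclear time step 1 atu (reduced to 0.25 atu in coupling
    regions), spawning threshold ``csthresh`` 1e-4 au^-1 on the magnitude of
    the nonadiabatic coupling vector, minimum Mulliken population to spawn
    ``poptospawn`` 0.001, spawning overlap threshold ``omax`` 0.6, matrix
    element screening ``olapthresh`` 0.001, overlap-regularization threshold
    ``regthresh`` 1e-4, and 250 initial conditions.
    """

    timestep: float = 1.0
    csthresh: float = 1e-4
    poptospawn: float = 0.001
    omax: float = 0.6
    olapthresh: float = 0.001
    regthresh: float = 1e-4
    widths: np.ndarray | float | None = None
    n_ic: int = 250
    seed: int = 0
    t_final: float = 2000.0
    initial_state: int | None = None
    coupling_reduction_factor: float = 4.0
    dt_min: float | None = None
    norm_tol: float = 1e-4
    energy_tol: float = 0.02   # catches integrator blow-ups; the saddle-point
                               # approximation itself drifts the quantum energy
                               # by ~1e-3 Ha through strong-coupling passages
    spawn_mode_cap: int = 1000     # spawning-mode duration cap, base steps
    spawn_retry_interval: int = 10  # base steps before a parent may attempt
                                    # another spawn toward the same state
    rearm_fraction: float = 0.5    # re-entry once the indicator falls below
                                   # this fraction of the last handled peak
                                   # and rises again (left one coupling
                                   # region, entering the next)
    coupling_region_threshold: float | None = None  # indicator level marking
                                   # a strong-coupling region for time-step
                                   # reduction; None -> max(csthresh/2, 1.0)
    omax_parent: float | None = None  # split thresholds; default to omax
    omax_swarm: float | None = None
    hermitize: bool = True

    def region_threshold(self) -> float:
        if self.coupling_region_threshold is not None:
            return self.coupling_region_threshold
        return max(0.5 * self.csthresh, 1.0)

    def __post_init__(self):
        for name in ("csthresh", "poptospawn", "regthresh", "timestep"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("omax", "olapthresh"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def resolve_widths(self, model: LVCModel) -> np.ndarray:
        """Per-mode TBF widths.  ``None`` maps to the ground-state width of
        the uncoupled model (alpha = 1/2 in dimensionless coordinates); a
        scalar scales that baseline."""
        base = np.full(model.n_modes, 0.5)
        if self.widths is None:
            return base
        w = np.asarray(self.widths, float)
        if w.ndim == 0:
            return base * float(w)
        if w.shape != (model.n_modes,):
            raise ValueError("widths must be a scalar or one value per mode")
        return w.copy()

    def effective_omax(self) -> tuple[float, float]:
        parent = self.omax if self.omax_parent is None else self.omax_parent
        swarm = self.omax if self.omax_swarm is None else self.omax_swarm
        return parent, swarm


@dataclass(frozen=True)
class Matrices:
    S: np.ndarray
    Sdot: np.ndarray
    H: np.ndarray
    n_pair_evals: int = 0
    n_degeneracy_clamps: int = 0


@dataclass
class CoupledSet:
    """All TBFs descending from one ancestor, plus their amplitude vector."""

    tbfs: list[TBF]
    C: np.ndarray
    t: float = 0.0
    matrices: Matrices | None = None
    model: LVCModel | None = None

    @classmethod
    def from_ancestor(cls, tbf: TBF, model: LVCModel | None = None) -> "CoupledSet":
        return cls(tbfs=[tbf], C=np.array([1.0 + 0.0j]), t=0.0, model=model)

    @property
    def n_tbfs(self) -> int:
        return len(self.tbfs)

    @property
    def states(self) -> np.ndarray:
        return np.array([t.state for t in self.tbfs])

    def norm(self) -> float:
        if self.matrices is None:
            raise RuntimeError("matrices not assembled")
        return float(np.real(self.C.conj() @ self.matrices.S @ self.C))

    def add_tbf(self, tbf: TBF, coefficient: complex = 0.0) -> None:
        self.tbfs.append(tbf)
        self.C = np.append(self.C, complex(coefficient))
        self.matrices = None


def _batch_nac(model: LVCModel, Q: np.ndarray, I: int, J: int):
    """NAC vectors d_IJ at a stack of geometries with the gap clamped to the
    degeneracy floor (returns the vectors and the number of clamped points)."""
    if model.n_states == 2:
        W = model.diabatic(Q)
        delta = W[..., 0, 0] - W[..., 1, 1]
        w12 = W[..., 0, 1]
        denom = delta**2 + 4.0 * w12**2
        floor2 = DEGENERACY_FLOOR**2
        n_clamped = int(np.count_nonzero(denom < floor2))
        denom = np.maximum(denom, floor2)
        from .models import diabatic_gradient_matrix

        G = diabatic_gradient_matrix(model, Q)
        dd = G[..., 0, 0] - G[..., 1, 1]
        dw = G[..., 0, 1]
        d01 = (delta[..., None] * dw - w12[..., None] * dd) / denom[..., None]
        return (d01 if (I, J) == (0, 1) else -d01), n_clamped
    E, V = adiabatic_surface(model, Q)
    from .models import diabatic_gradient_matrix

    G = diabatic_gradient_matrix(model, Q)
    num = np.einsum("...a,...mab,...b->...m", V[..., :, I], G, V[..., :, J])
    gap = E[..., J] - E[..., I]
    n_clamped = int(np.count_nonzero(np.abs(gap) < DEGENERACY_FLOOR))
    gap = np.where(np.abs(gap) < DEGENERACY_FLOOR,
                   np.copysign(DEGENERACY_FLOOR, gap), gap)
    return num / gap[..., None], n_clamped


def assemble_matrices(
    cset: CoupledSet,
    model: LVCModel,
    params: SimParams,
    rates: SwarmRates | None = None,
) -> Matrices:
    """Build (S, Sdot, H) for the coupled set at its current time.

    One electronic evaluation (energies + couplings at the pair centroid) is
    spent per unscreened unordered pair, matching the N(N+1)/2 bookkeeping of
    on-the-fly implementations; screened pairs get zero H and Sdot couplings
    while S itself stays exact.
    """
    tbfs = cset.tbfs
    n = len(tbfs)
    masses = model.eff_mass
    R = np.stack([t.R for t in tbfs])
    P = np.stack([t.P for t in tbfs])
    alpha = np.stack([t.alpha for t in tbfs])
    gamma = np.array([t.gamma for t in tbfs])
    states = cset.states

    table = pair_table(R, P, alpha, gamma, masses)
    same = states[:, None] == states[None, :]
    S = np.where(same, table.overlap, 0.0).astype(complex)

    if rates is None:
        rates = swarm_rates(tbfs, model)
    term = ((-table.f * rates.dR[None, :, :]
             + 1j * table.dmu * rates.dP[None, :, :]).sum(axis=-1)
            + 1j * rates.dgamma[None, :])
    Sdot = np.where(same, table.overlap * term, 0.0).astype(complex)

    keep = np.abs(table.overlap) >= params.olapthresh
    np.fill_diagonal(keep, True)
    iu, ju = np.where(np.triu(keep))

    H = np.zeros((n, n), dtype=complex)
    n_clamped = 0
    if iu.size:
        from .models import _surface_raw

        cents = table.centroid[iu, ju]           # (npairs, m)
        E_c, _ = _surface_raw(model, cents)       # (npairs, S)
        same_p = states[iu] == states[ju]
        # Same-state pairs: kinetic + E_J(centroid) * overlap.
        if np.any(same_p):
            sel = np.where(same_p)[0]
            Jp = states[ju[sel]]
            H[iu[sel], ju[sel]] = (
                table.kinetic[iu[sel], ju[sel]]
                + E_c[sel, Jp] * table.overlap[iu[sel], ju[sel]]
            )
        # Different-state pairs: -sum_rho (1/M_rho) d_IJ,rho(centroid)
        #                         * <chi_i|d/dR_rho|chi_j>.
        diff = np.where(~same_p)[0]
        if diff.size:
            combos = {(int(states[iu[k]]), int(states[ju[k]])) for k in diff}
            for (si, sj) in combos:
                sel = diff[(states[iu[diff]] == si) & (states[ju[diff]] == sj)]
                d, nc = _batch_nac(model, cents[sel], si, sj)
                n_clamped += nc
                H[iu[sel], ju[sel]] = -(
                    d / masses * table.deriv[iu[sel], ju[sel]]
                ).sum(axis=-1)
    # Mirror the strictly-lower triangle (H is Hermitized next; the lower
    # triangle only matters when Hermitization is disabled for diagnostics).
    low = np.tril_indices(n, -1)
    H[low] = np.conj(H.T[low])
    if params.hermitize:
        H = 0.5 * (H + H.conj().T)

    # Screen Sdot couplings for dropped pairs (diagonal always kept).
    drop = ~keep
    np.fill_diagonal(drop, False)
    Sdot = np.where(drop, 0.0, Sdot)

    mats = Matrices(
        S=S, Sdot=Sdot, H=H,
        n_pair_evals=int(iu.size),
        n_degeneracy_clamps=n_clamped,
    )
    cset.matrices = mats
    return mats


def regularized_inverse(S: np.ndarray, regthresh: float) -> np.ndarray:
    """Eigenvalue pseudo-inverse of a Hermitian matrix.

    Eigenvalues below ``regthresh`` (absolute, natural for a unit-diagonal
    overlap matrix) are discarded; inverting on the retained subspace keeps
    the amplitude equations well conditioned when TBFs pile up.
    """
    w, V = np.linalg.eigh(S)
    kept = w >= regthresh
    if not np.any(kept):
        raise DegenerateBasisError(
            f"all {w.size} overlap eigenvalues fall below regthresh={regthresh:g}"
        )
    Vk = V[:, kept]
    return (Vk / w[kept]) @ Vk.conj().T


def propagate_coefficients(
    cset: CoupledSet,
    dt: float,
    params: SimParams,
    matrices_start: Matrices | None = None,
    matrices_end: Matrices | None = None,
    n_sub: int = 4,
) -> np.ndarray:
    """Integrate the amplitude equations over ``dt`` with RK4 substeps.

    S, Sdot and H are interpolated linearly between the supplied endpoint
    matrices (both default to the set's current matrices, i.e. frozen
    matrices).  Returns the updated amplitude vector and stores it on the
    set; the caller is responsible for norm-drift bookkeeping.
    """
    if matrices_start is None:
        matrices_start = cset.matrices
    if matrices_end is None:
        matrices_end = matrices_start
    if matrices_start is None:
        raise RuntimeError("matrices not assembled")

    S0, S1 = matrices_start.S, matrices_end.S
    D0 = matrices_start.H - 1j * matrices_start.Sdot
    D1 = matrices_end.H - 1j * matrices_end.Sdot

    cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}

    def deriv(tau: float, C: np.ndarray) -> np.ndarray:
        x = tau / dt if dt != 0 else 0.0
        hit = cache.get(x)
        if hit is None:
            S = S0 + x * (S1 - S0)
            D = D0 + x * (D1 - D0)
            hit = (regularized_inverse(S, params.regthresh), D)
            cache[x] = hit
        Sinv, D = hit
        return -1j * (Sinv @ (D @ C))

    C = cset.C.astype(complex)
    h = dt / n_sub
    tau = 0.0
    for _ in range(n_sub):
        k1 = deriv(tau, C)
        k2 = deriv(tau + 0.5 * h, C + 0.5 * h * k1)
        k3 = deriv(tau + 0.5 * h, C + 0.5 * h * k2)
        k4 = deriv(tau + h, C + h * k3)
        C = C + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        tau += h
    cset.C = C
    return C


def mulliken_population(cset: CoupledSet, k: int) -> float:
    """Mulliken population of TBF ``k``:
    n_k = sum_{k' same state} Re{ C_k'^* S_k'k C_k }.

    The state restriction is automatic because S carries the electronic
    Kronecker delta.  Populations sum to the total norm Re{C^dag S C}.
    """
    if cset.matrices is None:
        raise RuntimeError("matrices not assembled")
    S = cset.matrices.S
    return float(np.real(cset.C.conj() @ S[:, k] * cset.C[k]))


def state_population(cset: CoupledSet, J: int) -> float:
    """Total population carried by electronic state ``J``."""
    if cset.matrices is None:
        raise RuntimeError("matrices not assembled")
    S = cset.matrices.S
    nk = np.real(cset.C.conj() * (S @ cset.C))
    return float(nk[cset.states == J].sum())


def nes_count(n_tbfs: int) -> int:
    """Electronic evaluations formally needed per step: N(N+1)/2."""
    return n_tbfs * (n_tbfs + 1) // 2
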