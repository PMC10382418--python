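"""Classical propagation of TBF centers and the adaptive time step.

Each TBF center follows Hamilton's equations on a single adiabatic surface
(velocity Verlet, time reversible and symplectic).  The semiclassical phase
integrates the classical Lagrangian, d(gamma)/dt = T - E_J(Rbar), with the
trapezoid (midpoint) value across each Verlet step; any constant offset in
this convention cancels in observables through the amplitude equations.

The step controller implements the adaptive scheme of on-the-fly spawning
codes: a base step away from couplings, a reduced step (factor 4 by default)
whenever any TBF pair sits in a region of sizable nonadiabatic coupling or a
spawning mode is active, and halving upon rejection of a step (norm or energy
drift beyond tolerance) until a floor is reached, at which point the dynamics
aborts with a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gaussians import TBF
from .models import (
    LVCModel,
    adiabatic_surface,
    diabatic_gradient_matrix,
)

__all__ = [
    "StepController",
    "StepContext",
    "StepAbort",
    "adapt_step",
    "classical_energy",
    "surface_energy",
    "verlet_step",
    "phase_step",
    "propagate_tbf",
    "SwarmRates",
    "propagate_swarm",
    "swarm_rates",
]


class StepAbort(RuntimeError):
    """Dynamics cannot continue: the adaptive step fell below its floor."""

    def __init__(self, diagnostic: str, dt: float):
        self.diagnostic = diagnostic
        self.dt = dt
        super().__init__(f"time step {dt:.3e} au below floor ({diagnostic})")


@dataclass
class StepController:
    """Adaptive time-step policy.

    ``dt_base`` is the user's nominal nuclear time step; in coupling regions
    it is divided by ``coupling_reduction_factor`` (4 reproduces the usual
    practice).  Steps whose norm or total-energy drift exceed the rejection
    tolerances are redone with a halved step, down to ``dt_min``.
    """

    dt_base: float
    coupling_reduction_factor: float = 4.0
    dt_min: float = None  # type: ignore[assignment]
    norm_tol: float = 1e-4
    energy_tol: float = 1e-4

    def __post_init__(self):
        if self.dt_min is None:
            self.dt_min = self.dt_base / 100.0
        if not self.dt_min < self.dt_base:
            raise ValueError("dt_min must be smaller than dt_base")
        if not self.coupling_reduction_factor > 1:
            raise ValueError("coupling_reduction_factor must exceed 1")


@dataclass
class StepContext:
    """What the controller needs to know about the step being attempted."""

    in_coupling_region: bool = False
    last_step_accepted: bool = True
    last_dt: float | None = None
    norm_drift: float = 0.0
    energy_drift: float = 0.0


def adapt_step(controller: StepController, context: StepContext) -> float:
    """Next time step to use, or raise :class:`StepAbort`.

    Accepted previous step: the base step, reduced by the coupling factor
    inside coupling regions.  Rejected previous step: half the attempted
    step; below ``dt_min`` the dynamics stops and the abort diagnostic names
    the tolerance that tripped.
    """
    if context.last_step_accepted:
        if context.in_coupling_region:
            return controller.dt_base / controller.coupling_reduction_factor
        return controller.dt_base
    if context.last_dt is None:
        raise ValueError("rejected step requires last_dt")
    dt = context.last_dt / 2.0
    if dt < controller.dt_min:
        which = []
        if context.norm_drift > controller.norm_tol:
            which.append(f"norm drift {context.norm_drift:.2e}")
        if context.energy_drift > controller.energy_tol:
            which.append(f"energy drift {context.energy_drift:.2e}")
        raise StepAbort("; ".join(which) or "repeated step rejection", dt)
    return dt


# ---------------------------------------------------------------------------
# Single-TBF propagation.

def surface_energy(tbf: TBF, model: LVCModel) -> float:
    """Adiabatic potential energy E_J at the TBF center."""
    E, _ = adiabatic_surface(model, tbf.R)
    return float(E[tbf.state])


def classical_energy(tbf: TBF, model: LVCModel) -> float:
    """Classical total energy T + E_J of the TBF center."""
    T = float((tbf.P**2 / (2.0 * model.eff_mass)).sum())
    return T + surface_energy(tbf, model)


def _force(tbf: TBF, model: LVCModel) -> float:
    from .models import adiabatic_gradient

    return -adiabatic_gradient(model, tbf.R, tbf.state)


def verlet_step(tbf: TBF, model: LVCModel, dt: float) -> TBF:
    """One velocity-Verlet step of the TBF center on its adiabatic surface."""
    if dt == 0:
        raise ValueError("dt must be nonzero")
    masses = model.eff_mass
    F0 = _force(tbf, model)
    P_half = tbf.P + 0.5 * dt * F0
    R_new = tbf.R + dt * P_half / masses
    new = tbf.clone(id=tbf.id, R=R_new, P=P_half)
    F1 = _force(new, model)
    new.P = P_half + 0.5 * dt * F1
    return new


def phase_step(tbf: TBF, model: LVCModel, dt: float) -> float:
    """Updated semiclassical phase after one step: trapezoid of T - E_J."""
    L0 = (tbf.P**2 / (2.0 * model.eff_mass)).sum() - surface_energy(tbf, model)
    moved = verlet_step(tbf, model, dt)
    L1 = (moved.P**2 / (2.0 * model.eff_mass)).sum() - surface_energy(moved, model)
    return float(tbf.gamma + 0.5 * dt * (L0 + L1))


def propagate_tbf(tbf: TBF, model: LVCModel, dt: float) -> TBF:
    """Verlet + phase step combined; returns the advanced TBF."""
    new = verlet_step(tbf, model, dt)
    L0 = (tbf.P**2 / (2.0 * model.eff_mass)).sum() - surface_energy(tbf, model)
    L1 = (new.P**2 / (2.0 * model.eff_mass)).sum() - surface_energy(new, model)
    new.gamma = float(tbf.gamma + 0.5 * dt * (L0 + L1))
    return new


# ---------------------------------------------------------------------------
# Batched propagation of a swarm (used by the driver's inner loop).

@dataclass
class SwarmRates:
    """Classical rates of every TBF at its current phase-space point."""

    dR: np.ndarray      # (N, m) = P / M
    dP: np.ndarray      # (N, m) = force
    dgamma: np.ndarray  # (N,)   = T - E_J
    energy: np.ndarray  # (N,)   adiabatic potential energy per TBF


def _batch_state_quantities(model: LVCModel, Q: np.ndarray, states: np.ndarray):
    """(E_J, force) for a stack of centers, each on its own state."""
    from .models import _surface_raw

    E, V = _surface_raw(model, Q)
    G = diabatic_gradient_matrix(model, Q)
    n = Q.shape[0]
    c = V[np.arange(n), :, states]                      # (N, S)
    grad = np.einsum("na,nmab,nb->nm", c, G, c)
    return E[np.arange(n), states], -grad


def step_center(model: LVCModel, state: int, R, P, gamma: float, dt: float):
    """One Verlet + trapezoid-phase step of a bare center (no TBF object).

    Identical arithmetic to :func:`propagate_tbf`; used by the spawning-mode
    scans where object construction per step would dominate the cost.
    """
    masses = model.eff_mass
    states = np.array([state])
    E0, F0 = _batch_state_quantities(model, R[None, :], states)
    L0 = (P**2 / (2.0 * masses)).sum() - E0[0]
    P_half = P + 0.5 * dt * F0[0]
    R_new = R + dt * P_half / masses
    E1, F1 = _batch_state_quantities(model, R_new[None, :], states)
    P_new = P_half + 0.5 * dt * F1[0]
    L1 = (P_new**2 / (2.0 * masses)).sum() - E1[0]
    return R_new, P_new, gamma + 0.5 * dt * (L0 + L1)


def swarm_rates(tbfs: list[TBF], model: LVCModel) -> SwarmRates:
    Q = np.stack([t.R for t in tbfs])
    P = np.stack([t.P for t in tbfs])
    states = np.array([t.state for t in tbfs])
    EJ, F = _batch_state_quantities(model, Q, states)
    dR = P / model.eff_mass
    T = (P**2 / (2.0 * model.eff_mass)).sum(axis=1)
    return SwarmRates(dR=dR, dP=F, dgamma=T - EJ, energy=EJ)


def propagate_swarm(tbfs: list[TBF], model: LVCModel, dt: float) -> SwarmRates:
    """Advance every TBF in place by one Verlet + phase step (two batched
    electronic evaluations for the whole swarm); returns the post-step rates."""
    masses = model.eff_mass
    Q = np.stack([t.R for t in tbfs])
    P = np.stack([t.P for t in tbfs])
    states = np.array([t.state for t in tbfs])

    E0, F0 = _batch_state_quantities(model, Q, states)
    L0 = (P**2 / (2.0 * masses)).sum(axis=1) - E0
    P_half = P + 0.5 * dt * F0
    Q_new = Q + dt * P_half / masses
    E1, F1 = _batch_state_quantities(model, Q_new, states)
    P_new = P_half + 0.5 * dt * F1
    T1 = (P_new**2 / (2.0 * masses)).sum(axis=1)
    L1 = T1 - E1
    dgamma = 0.5 * (L0 + L1)
    for k, t in enumerate(tbfs):
        t.R = Q_new[k]
        t.P = P_new[k]
        t.gamma = float(t.gamma + dt * dgamma[k])
    return SwarmRates(dR=P_new / masses, dP=F1, dgamma=T1 - E1, energy=E1)
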