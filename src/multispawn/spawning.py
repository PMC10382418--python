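"""The spawning algorithm: adaptive growth of the TBF basis.

A parent TBF whose nonadiabaticity indicator (the Euclidean magnitude of the
nonadiabatic coupling vector at its center) exceeds ``csthresh`` — and whose
Mulliken population is at least ``poptospawn`` — triggers a *spawning mode*:
amplitude propagation is suspended, the parent's classical motion is
continued on a reduced time step until the indicator passes a local maximum
(or a duration cap), a child TBF is created there on the coupled state with
zero amplitude and a momentum rescaled along the coupling vector to conserve
the parent's classical energy, and the child is propagated back to the entry
time of the mode.  The child joins the coupled set only if it overlaps its
parent strongly enough at the spawning geometry and does not duplicate an
existing TBF once backpropagated (both gates default to the single ``omax``
threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .amplitudes import CoupledSet, SimParams, _batch_nac, mulliken_population
from .gaussians import TBF, overlap
from .models import LVCModel, adiabatic_surface
from .propagation import step_center

__all__ = [
    "SpawnEvent",
    "EntryDecision",
    "coupling_magnitude",
    "check_entry",
    "omax_tests",
    "run_spawning_mode",
]


@dataclass
class SpawnEvent:
    """Record of one pass through the spawning mode."""

    parent_id: str
    child_id: str | None
    source_state: int
    target_state: int
    t_entry: float
    t_max: float
    indicator_max: float
    accepted: bool
    rejection_reason: str | None = None
    capped: bool = False  # indicator still rising when the duration cap hit


@dataclass(frozen=True)
class EntryDecision:
    enter: bool
    target_state: int
    magnitude: float
    reason: str | None = None  # why entry was skipped


def coupling_magnitude(tbf: TBF, model: LVCModel, J_other: int) -> float:
    """|d_IJ| at the TBF center between its state and ``J_other`` (au^-1).

    Near-degenerate geometries are evaluated with the gap clamped to the
    model's degeneracy floor rather than raising.
    """
    if J_other == tbf.state:
        raise ValueError("coupling_magnitude requires a different state")
    d, _ = _batch_nac(model, tbf.R[None, :], tbf.state, J_other)
    return float(np.linalg.norm(d[0]))


def check_entry(
    tbf: TBF,
    cset: CoupledSet,
    params: SimParams,
    model: LVCModel | None = None,
    magnitudes=None,
) -> EntryDecision:
    """Decide whether ``tbf`` enters the spawning mode toward any other state.

    Entry requires the indicator to exceed ``csthresh`` *and* the TBF's
    Mulliken population to reach ``poptospawn``.  With several candidate
    states, the one with the largest indicator wins.  ``magnitudes`` may
    supply precomputed per-state indicator values (own state entry ignored).
    """
    model = model if model is not None else cset.model
    if model is None:
        raise ValueError("a model is required (pass it or set cset.model)")
    k = next(i for i, t in enumerate(cset.tbfs) if t.id == tbf.id)
    best_state, best_mag = -1, -np.inf
    for J in range(model.n_states):
        if J == tbf.state:
            continue
        mag = (float(magnitudes[J]) if magnitudes is not None
               else coupling_magnitude(tbf, model, J))
        if mag > best_mag:
            best_state, best_mag = J, mag
    if best_mag <= params.csthresh:
        return EntryDecision(False, best_state, best_mag, "coupling")
    if mulliken_population(cset, k) < params.poptospawn:
        return EntryDecision(False, best_state, best_mag, "population")
    return EntryDecision(True, best_state, best_mag)


def omax_tests(
    child: TBF,
    parent: TBF,
    swarm,
    omax: float,
    *,
    child_at_entry: TBF | None = None,
    omax_swarm: float | None = None,
) -> tuple[bool, str | None]:
    """The two overlap gates applied to a candidate child TBF.

    (i) ``|<child|parent>|`` at the spawning geometry must reach ``omax``
    (the new TBF must actually couple to its parent); (ii) the backpropagated
    child (``child_at_entry``, defaulting to ``child``) must not overlap any
    other existing TBF more strongly than ``omax_swarm`` (it must not
    duplicate the swarm).  Both thresholds default to the single ``omax``.
    """
    if omax_swarm is None:
        omax_swarm = omax
    if abs(overlap(child, parent)) < omax:
        return False, "parent-overlap"
    probe = child if child_at_entry is None else child_at_entry
    for other in swarm:
        if other.id in (parent.id, child.id):
            continue
        if abs(overlap(probe, other)) > omax_swarm:
            return False, "redundant"
    return True, None


def _rescale_momentum(
    parent: TBF, model: LVCModel, target_state: int
) -> np.ndarray | None:
    """Child momentum at the parent's geometry: the parent momentum shifted
    along the nonadiabatic coupling direction so the classical total energy
    is conserved on the new surface.  ``None`` when classically forbidden."""
    E, _ = adiabatic_surface(model, parent.R)
    delta_E = float(E[parent.state] - E[target_state])  # energy freed
    d, _ = _batch_nac(model, parent.R[None, :], parent.state, target_state)
    d = d[0]
    norm = np.linalg.norm(d)
    if norm == 0.0:
        # No coupling direction: fall back to a uniform velocity rescale.
        T = float((parent.P**2 / (2.0 * model.eff_mass)).sum())
        if T + delta_E < 0:
            return None
        return parent.P * np.sqrt((T + delta_E) / T) if T > 0 else parent.P
    u = d / norm
    inv_m = 1.0 / model.eff_mass
    a = 0.5 * float((u**2 * inv_m).sum())
    b = float((parent.P * u * inv_m).sum())
    disc = b**2 + 4.0 * a * delta_E
    if disc < 0:
        return None
    roots = ((-b + np.sqrt(disc)) / (2 * a), (-b - np.sqrt(disc)) / (2 * a))
    eta = min(roots, key=abs)
    return parent.P + eta * u


def run_spawning_mode(
    parent: TBF,
    model: LVCModel,
    params: SimParams,
    *,
    target_state: int,
    t_entry: float,
    swarm=(),
) -> tuple[SpawnEvent, TBF | None]:
    """Steps (iv)-(vii): locate the indicator maximum, create and
    backpropagate a child, apply the overlap gates.

    The parent is explored through a forward clone on the reduced time step;
    the caller's parent object stays at the entry time, so resuming the
    coupled propagation from ``t_entry`` needs no explicit backpropagation of
    the parent.  Returns the event record and the accepted child positioned
    at ``t_entry`` (``None`` when rejected).
    """
    factor = params.coupling_reduction_factor
    dt = params.timestep / factor
    max_steps = int(params.spawn_mode_cap * factor)

    def _mag(R):
        d, _ = _batch_nac(model, R[None, :], parent.state, target_state)
        return float(np.linalg.norm(d[0]))

    R, P, g = parent.R.copy(), parent.P.copy(), float(parent.gamma)
    mags = [_mag(R)]
    points = [(R, P, g)]
    running_max = mags[0]
    i_max, capped = None, False
    for step in range(1, max_steps + 1):
        R, P, g = step_center(model, parent.state, R, P, g, dt)
        mag = _mag(R)
        mags.append(mag)
        points.append((R, P, g))
        # First interior three-point maximum on the reduced grid wins; an
        # initial dip of the indicator does not count as a maximum at entry.
        if len(mags) >= 3 and mags[-2] > mags[-3] and mag < mags[-2]:
            i_max = len(mags) - 2
            break
        running_max = max(running_max, mag)
        # Clear decay without a located interior maximum: the indicator is
        # falling away from the entry region; spawn at the best point seen
        # (the entry point for a monotone decrease) instead of scanning on.
        if mag < 0.7 * running_max:
            break
    if i_max is None:
        # Stopped by decay or by the duration cap: best geometry seen.  An
        # indicator still rising at the cap spawns at the cap, flagged.
        i_max = int(np.argmax(mags))
        capped = i_max == len(mags) - 1

    steps_to_max, indicator_max = i_max, mags[i_max]
    Rm, Pm, gm = points[i_max]
    parent_at_max = parent.clone(id=parent.id, R=Rm, P=Pm, gamma=gm)
    t_max = t_entry + steps_to_max * dt

    def event(accepted, child_id=None, reason=None):
        return SpawnEvent(
            parent_id=parent.id, child_id=child_id,
            source_state=parent.state, target_state=target_state,
            t_entry=t_entry, t_max=t_max, indicator_max=indicator_max,
            accepted=accepted, rejection_reason=reason, capped=capped,
        )

    P_child = _rescale_momentum(parent_at_max, model, target_state)
    if P_child is None:
        return event(False, reason="forbidden"), None

    child_at_max = TBF(
        state=target_state, R=parent_at_max.R, P=P_child,
        alpha=parent.alpha, gamma=parent_at_max.gamma,
        parent_id=parent.id, birth_time=t_entry,
    )
    # Backpropagate the child to the entry time of the spawning mode.
    Rc, Pc, gc = child_at_max.R.copy(), child_at_max.P.copy(), child_at_max.gamma
    for _ in range(steps_to_max):
        Rc, Pc, gc = step_center(model, target_state, Rc, Pc, gc, -dt)
    child = child_at_max.clone(id=child_at_max.id, R=Rc, P=Pc, gamma=gc)

    parent_omax, swarm_omax = params.effective_omax()
    ok, reason = omax_tests(
        child_at_max, parent_at_max, swarm, parent_omax,
        child_at_entry=child, omax_swarm=swarm_omax,
    )
    if not ok:
        return event(False, reason=reason), None
    return event(True, child_id=child.id), child
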