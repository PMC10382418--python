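"""Full multiple-spawning runs: initial conditions, time loop, ensembles.

One initial condition seeds one ancestor TBF, and — by the independent
first-generation approximation — one independently propagated coupled set.
The time loop interleaves, on an adaptive nuclear step, the classical
propagation of all TBF centers, assembly of the (S, Sdot, H) matrices,
RK4 integration of the complex amplitudes, and the spawning checks.
Per-state populations are recorded on the base-step grid and averaged
incoherently (equal weights) over initial conditions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .amplitudes import (
    CoupledSet,
    SimParams,
    assemble_matrices,
    propagate_coefficients,
    state_population,
    _batch_nac,
)
from .gaussians import TBF, overlap as gaussian_overlap
from .models import LVCModel
from .propagation import (
    StepAbort,
    StepContext,
    StepController,
    adapt_step,
    propagate_swarm,
    swarm_rates,
)
from .spawning import SpawnEvent, check_entry, run_spawning_mode

__all__ = [
    "InitialCondition",
    "PopulationTrace",
    "RunResult",
    "EnsembleResult",
    "wigner_sample",
    "run_ic",
    "run_ensemble",
    "ensemble_average",
]


@dataclass(frozen=True)
class InitialCondition:
    """Phase-space point (and weight) for one ancestor TBF."""

    R0: np.ndarray
    P0: np.ndarray
    weight: float = 1.0
    index: int = 0

    def __post_init__(self):
        object.__setattr__(self, "R0", np.atleast_1d(np.asarray(self.R0, float)))
        object.__setattr__(self, "P0", np.atleast_1d(np.asarray(self.P0, float)))
        if not (np.all(np.isfinite(self.R0)) and np.all(np.isfinite(self.P0))):
            raise ValueError("initial condition entries must be finite")


@dataclass
class PopulationTrace:
    """Per-state populations, norm and basis-size bookkeeping on a time grid."""

    times: np.ndarray            # (T,) au
    populations: np.ndarray      # (T, n_states) adiabatic populations
    norm: np.ndarray             # (T,)
    n_tbfs: np.ndarray           # (T,)
    n_es: np.ndarray             # (T,) electronic evaluations in last assembly
    energy: np.ndarray | None = None  # (T,) quantum energy Re(C^H C)/norm
    meta: dict = field(default_factory=dict)
    aborted: bool = False

    def to_frame(self) -> pd.DataFrame:
        cols = {"time": self.times}
        for j in range(self.populations.shape[1]):
            cols[f"pop_state{j}"] = self.populations[:, j]
        cols["norm"] = self.norm
        cols["n_tbfs"] = self.n_tbfs
        cols["n_es"] = self.n_es
        if self.energy is not None:
            cols["energy"] = self.energy
        return pd.DataFrame(cols)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class RunResult:
    trace: PopulationTrace
    events: list[SpawnEvent]
    final_set: CoupledSet
    aborted: bool = False
    abort_reason: str | None = None


@dataclass
class EnsembleResult:
    traces: list[PopulationTrace]
    average: PopulationTrace
    events: list[list[SpawnEvent]]
    ics: list[InitialCondition]
    aborted_indices: list[int]
    final_sets: list[CoupledSet] | None = None  # surviving runs, trace order


def wigner_sample(model: LVCModel, n: int, seed: int) -> list[InitialCondition]:
    """Sample ``n`` initial conditions from the Wigner distribution of the
    uncoupled harmonic ground state, centered at the Franck-Condon point.

    In dimensionless normal modes the ground-state Wigner function is the
    product of independent Gaussians with variance 1/2 in both q and p.
    Deterministic under a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    sd = np.sqrt(0.5)
    q = rng.normal(0.0, sd, size=(n, model.n_modes))
    p = rng.normal(0.0, sd, size=(n, model.n_modes))
    return [InitialCondition(R0=q[i], P0=p[i], index=i) for i in range(n)]


def _indicator_table(cset: CoupledSet, model: LVCModel) -> np.ndarray:
    """(N, n_states) matrix of coupling magnitudes |d| per TBF and partner
    state (zero toward a TBF's own state)."""
    n = cset.n_tbfs
    out = np.zeros((n, model.n_states))
    Q = np.stack([t.R for t in cset.tbfs])
    states = cset.states
    for I in sorted(set(int(s) for s in states)):
        sel = np.where(states == I)[0]
        for J in range(model.n_states):
            if J == I:
                continue
            d, _ = _batch_nac(model, Q[sel], I, J)
            out[sel, J] = np.linalg.norm(d, axis=-1)
    return out


def _quantum_energy(cset: CoupledSet) -> float:
    m = cset.matrices
    nrm = cset.norm()
    if nrm <= 0:
        return 0.0
    return float(np.real(cset.C.conj() @ m.H @ cset.C) / nrm)


def run_ic(
    ic: InitialCondition,
    model: LVCModel,
    params: SimParams,
) -> RunResult:
    """Propagate one ancestor TBF (and its descendants) to ``t_final``.

    Deterministic: all randomness lives in the sampling of ``ic``.
    """
    widths = params.resolve_widths(model)
    state0 = (model.n_states - 1 if params.initial_state is None
              else params.initial_state)
    if not 0 <= state0 < model.n_states:
        raise ValueError(f"initial state {state0} out of range")
    ancestor = TBF(state=state0, R=ic.R0, P=ic.P0, alpha=widths, gamma=0.0)
    cset = CoupledSet.from_ancestor(ancestor, model)
    controller = StepController(
        dt_base=params.timestep,
        coupling_reduction_factor=params.coupling_reduction_factor,
        dt_min=params.dt_min,
        norm_tol=params.norm_tol,
        energy_tol=params.energy_tol,
    )

    rates = swarm_rates(cset.tbfs, model)
    mats = assemble_matrices(cset, model, params, rates)

    rec_t, rec_pop, rec_norm, rec_ntbf, rec_nes, rec_en = [], [], [], [], [], []

    def record():
        rec_t.append(cset.t)
        rec_pop.append([state_population(cset, J) for J in range(model.n_states)])
        rec_norm.append(cset.norm())
        rec_ntbf.append(cset.n_tbfs)
        rec_nes.append(cset.matrices.n_pair_evals)
        rec_en.append(_quantum_energy(cset))

    record()
    events: list[SpawnEvent] = []
    # Spawn-attempt throttle.  After an attempt the (parent, target-state)
    # pair is blocked until the earliest of: the parent reaching the vicinity
    # of the located indicator maximum (where a retry is cheap and the child
    # geometry best), a retry interval elapsing, the indicator falling below
    # csthresh, or the indicator leaving the coupling region (well below the
    # traversed peak and rising into the next one).  Redundant children are
    # additionally pre-screened against existing target-state TBFs, which is
    # what keeps repeated spawning through an extended passage from storming.
    blocked: dict[tuple[str, int], dict] = {}
    # consecutive failed attempts per (parent, target): retry backoff
    fail_counts: dict[tuple[str, int], int] = {}
    n_frames = int(round(params.t_final / params.timestep))
    aborted, abort_reason = False, None
    region_thr = params.region_threshold()
    inds = _indicator_table(cset, model)

    for _ in range(n_frames):
        in_coupling = bool(np.any(inds > region_thr))
        dt = adapt_step(controller, StepContext(in_coupling_region=in_coupling))

        jump_rejected = False
        while True:
            snap_tbfs = [t.clone(id=t.id) for t in cset.tbfs]
            snap_C = cset.C.copy()
            snap_mats, snap_rates = mats, rates
            norm0, E0 = cset.norm(), _quantum_energy(cset)

            n_sub = max(1, int(round(params.timestep / dt)))
            dt_sub = params.timestep / n_sub
            # Amplitude RK4 substep stays at a quarter of the *base* step;
            # an already-reduced nuclear step needs no further subdivision.
            n_rk = max(1, int(round(4.0 * dt_sub / params.timestep)))
            cur_mats, cur_rates = mats, rates
            for _s in range(n_sub):
                cur_rates = propagate_swarm(cset.tbfs, model, dt_sub)
                new_mats = assemble_matrices(cset, model, params, cur_rates)
                propagate_coefficients(
                    cset, dt_sub, params,
                    matrices_start=cur_mats, matrices_end=new_mats,
                    n_sub=n_rk,
                )
                cur_mats = new_mats

            cset.matrices = cur_mats
            norm1, E1 = cset.norm(), _quantum_energy(cset)
            norm_drift = abs(norm1 - norm0)
            energy_drift = abs(E1 - E0)
            inds_new = _indicator_table(cset, model)
            jumped = (
                not jump_rejected
                and inds.size == inds_new.size
                and float(inds_new.max()) > 10.0 * max(float(inds.max()), params.csthresh)
            ) if np.isfinite(params.csthresh) else False

            ok = (norm_drift <= controller.norm_tol
                  and energy_drift <= controller.energy_tol
                  and not jumped)
            if ok:
                mats, rates = cur_mats, cur_rates
                break
            # Reject: restore and retry with a halved step.
            cset.tbfs = snap_tbfs
            cset.C = snap_C
            cset.matrices = snap_mats
            mats, rates = snap_mats, snap_rates
            if jumped:
                jump_rejected = True
            ctx = StepContext(
                last_step_accepted=False, last_dt=dt,
                norm_drift=norm_drift, energy_drift=energy_drift,
            )
            try:
                dt = adapt_step(controller, ctx)
            except StepAbort as err:
                aborted, abort_reason = True, err.diagnostic
                break
        if aborted:
            break
        cset.t += params.timestep

        # --- spawning checks at the end of the frame --------------------
        spawned = False
        _, swarm_omax = params.effective_omax()
        for k, tbf in enumerate(list(cset.tbfs)):
            row = inds_new[k]
            for J in range(model.n_states):
                key = (tbf.id, J)
                info = blocked.get(key)
                if info is None:
                    continue
                mag = row[J]
                info["peak"] = max(info["peak"], mag)
                rearmed = (mag < params.csthresh
                           or (mag < params.rearm_fraction * info["peak"]
                               and mag > info["prev"]))
                if rearmed:
                    fail_counts.pop(key, None)
                if rearmed or cset.t >= info["until"]:
                    del blocked[key]
                else:
                    info["prev"] = mag
            decision = check_entry(tbf, cset, params, model, magnitudes=row)
            if not decision.enter:
                continue
            key = (tbf.id, decision.target_state)
            if key in blocked:
                continue
            # Redundancy pre-screen: a live TBF already on the target state
            # and overlapping the parent would make any child redundant;
            # skip the (expensive) spawning mode until it moves away.
            if any(
                other.state == decision.target_state
                and abs(gaussian_overlap(tbf, other)) > swarm_omax
                for other in cset.tbfs
            ):
                continue
            event, child = run_spawning_mode(
                tbf, model, params,
                target_state=decision.target_state,
                t_entry=cset.t, swarm=cset.tbfs,
            )
            events.append(event)
            margin = params.spawn_retry_interval * params.timestep
            if event.accepted:
                fail_counts.pop(key, None)
                backoff = margin
            else:
                fail_counts[key] = fail_counts.get(key, 0) + 1
                backoff = margin * 2 ** min(fail_counts[key] - 1, 5)
            blocked[key] = {
                "peak": decision.magnitude,
                "prev": decision.magnitude,
                "until": max(event.t_max - margin, cset.t + backoff),
            }
            if child is not None:
                cset.add_tbf(child, 0.0)
                spawned = True
                rates = swarm_rates(cset.tbfs, model)
                mats = assemble_matrices(cset, model, params, rates)
        if spawned:
            cset.matrices = mats
            inds_new = _indicator_table(cset, model)
        inds = inds_new
        record()

    trace = PopulationTrace(
        times=np.asarray(rec_t),
        populations=np.asarray(rec_pop),
        norm=np.asarray(rec_norm),
        n_tbfs=np.asarray(rec_ntbf, dtype=int),
        n_es=np.asarray(rec_nes, dtype=int),
        energy=np.asarray(rec_en),
        meta={"ic_index": ic.index, "params": _params_meta(params)},
        aborted=aborted,
    )
    return RunResult(trace=trace, events=events, final_set=cset,
                     aborted=aborted, abort_reason=abort_reason)


def _params_meta(params: SimParams) -> dict:
    out = {}
    for k, v in params.__dict__.items():
        if isinstance(v, np.ndarray):
            out[k] = v.tolist()
        else:
            out[k] = v
    return out


def ensemble_average(traces: list[PopulationTrace]) -> PopulationTrace:
    """Equal-weight arithmetic mean of population traces (incoherent average
    over initial conditions).  Traces on mismatched grids are interpolated
    onto the first trace's grid (with a warning)."""
    if not traces:
        raise ValueError("at least one trace is required")
    ref = traces[0]
    pops, norms, ntbfs, nes = [], [], [], []
    for tr in traces:
        if tr.times.shape != ref.times.shape or not np.allclose(tr.times, ref.times):
            warnings.warn("trace grids differ; interpolating onto common grid")
            pop = np.stack(
                [np.interp(ref.times, tr.times, tr.populations[:, j])
                 for j in range(tr.populations.shape[1])], axis=1)
            nrm = np.interp(ref.times, tr.times, tr.norm)
            ntb = np.interp(ref.times, tr.times, tr.n_tbfs)
            ne = np.interp(ref.times, tr.times, tr.n_es)
        else:
            pop, nrm, ntb, ne = tr.populations, tr.norm, tr.n_tbfs, tr.n_es
        pops.append(pop)
        norms.append(nrm)
        ntbfs.append(ntb)
        nes.append(ne)
    return PopulationTrace(
        times=ref.times.copy(),
        populations=np.mean(pops, axis=0),
        norm=np.mean(norms, axis=0),
        n_tbfs=np.mean(ntbfs, axis=0),
        n_es=np.mean(nes, axis=0),
        meta={"n_traces": len(traces)},
    )


def run_ensemble(
    model: LVCModel,
    params: SimParams,
    ics: list[InitialCondition] | None = None,
    progress: bool = False,
) -> EnsembleResult:
    """Full simulation: Wigner-sample ``params.n_ic`` initial conditions
    (unless supplied), run each independently, and average the survivors.

    Aborted runs are excluded from the average and reported in
    ``aborted_indices``.
    """
    if ics is None:
        ics = wigner_sample(model, params.n_ic, params.seed)
    traces, all_events, aborted, finals = [], [], [], []
    for i, ic in enumerate(ics):
        res = run_ic(ic, model, params)
        all_events.append(res.events)
        if res.aborted:
            aborted.append(i)
        else:
            traces.append(res.trace)
            finals.append(res.final_set)
        if progress:  # pragma: no cover
            print(f"  IC {i + 1}/{len(ics)}: "
                  f"{'aborted' if res.aborted else 'ok'}, "
                  f"{res.final_set.n_tbfs} TBFs")
    if not traces:
        raise RuntimeError("every run aborted; nothing to average")
    avg = ensemble_average(traces)
    avg.meta["aborted"] = aborted
    return EnsembleResult(
        traces=traces, average=avg, events=all_events,
        ics=ics, aborted_indices=aborted, final_sets=finals,
    )


# ---------------------------------------------------------------------------
# Structured-text outputs.

def write_spawn_log(events: list[SpawnEvent], path) -> None:
    rows = [e.__dict__ for e in events]
    cols = ["parent_id", "child_id", "source_state", "target_state",
            "t_entry", "t_max", "indicator_max", "accepted",
            "rejection_reason", "capped"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_metadata(params: SimParams, model: LVCModel, path, **extra) -> None:
    doc = {
        "params": _params_meta(params),
        "model": {
            "n_modes": model.n_modes,
            "n_states": model.n_states,
            "omega": model.omega.tolist(),
            "energies": model.energies.tolist(),
        },
    }
    doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=str)
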