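"""Spawning algorithm: entry gates, mode execution, overlap tests."""

import numpy as np
import pytest

from multispawn import (
    CoupledSet,
    SimParams,
    TBF,
    assemble_matrices,
    check_entry,
    coupling_magnitude,
    omax_tests,
    run_spawning_mode,
)
from multispawn.models import nac_vector
from multispawn.propagation import classical_energy, propagate_tbf


def _tbf(R, P, state=1, alpha=0.5):
    R = np.atleast_1d(np.asarray(R, float))
    return TBF(state=state, R=R, P=np.atleast_1d(np.asarray(P, float)),
               alpha=np.full(R.size, alpha))


def _singleton(tbf, model, params=None):
    cset = CoupledSet.from_ancestor(tbf, model)
    assemble_matrices(cset, model, params or SimParams())
    return cset


class TestCouplingMagnitude:
    def test_small_far_from_intersection(self, sloped_ci):
        tbf = _tbf([3.0, 0.2], [0.0, 0.0])
        # far up the tuning mode the gap is large and the coupling modest
        assert coupling_magnitude(tbf, sloped_ci, 0) < 0.2

    def test_symmetric_in_coupling_mode(self, sloped_ci):
        a = _tbf([0.4, 0.8], [0, 0])
        b = _tbf([0.4, -0.8], [0, 0])
        assert coupling_magnitude(a, sloped_ci, 0) == pytest.approx(
            coupling_magnitude(b, sloped_ci, 0), rel=1e-12)

    def test_matches_nac_vector_norm(self, sloped_ci):
        tbf = _tbf([-0.8, 0.5], [0.1, 0.2])
        ref = np.linalg.norm(nac_vector(sloped_ci, tbf.R, 1, 0))
        assert coupling_magnitude(tbf, sloped_ci, 0) == pytest.approx(
            ref, rel=1e-12)

    def test_finite_difference_norm_oracle(self, sloped_ci):
        # FD of gauge-aligned eigenvectors, then the Euclidean norm
        from multispawn.models import adiabatic_surface

        q = np.array([-0.9, 0.45])
        h = 1e-6
        _, V0 = adiabatic_surface(sloped_ci, q)
        fd = np.empty(2)
        for i in range(2):
            qp, qm = q.copy(), q.copy()
            qp[i] += h
            qm[i] -= h
            _, Vp = adiabatic_surface(sloped_ci, qp, prev_vecs=V0)
            _, Vm = adiabatic_surface(sloped_ci, qm, prev_vecs=V0)
            fd[i] = V0[:, 0] @ ((Vp[:, 1] - Vm[:, 1]) / (2 * h))
        tbf = _tbf(q, [0.0, 0.0])
        assert coupling_magnitude(tbf, sloped_ci, 0) == pytest.approx(
            np.linalg.norm(fd), abs=1e-5)


class TestCheckEntry:
    def test_below_threshold_skips(self, sloped_ci):
        tbf = _tbf([3.0, 0.1], [0, 0])
        cset = _singleton(tbf, sloped_ci)
        d = check_entry(tbf, cset, SimParams(csthresh=10.0), sloped_ci)
        assert not d.enter and d.reason == "coupling"

    def test_low_population_skips(self, sloped_ci):
        tbf = _tbf([-1.0, 0.3], [0, 0])
        cset = CoupledSet(tbfs=[tbf], C=np.array([np.sqrt(0.005) + 0j]))
        assemble_matrices(cset, sloped_ci, SimParams())
        d = check_entry(tbf, cset, SimParams(poptospawn=0.01), sloped_ci)
        assert not d.enter and d.reason == "population"

    def test_reference_run_enters(self, sloped_ci):
        tbf = _tbf([-1.0, 0.3], [0, 0])
        cset = _singleton(tbf, sloped_ci)
        d = check_entry(tbf, cset, SimParams(), sloped_ci)
        assert d.enter and d.target_state == 0
        assert d.magnitude > SimParams().csthresh


class TestOmaxTests:
    def test_redundant_child_rejected(self, sloped_ci):
        parent = _tbf([0.0, 0.0], [0.0, 0.0], state=1)
        child = _tbf([0.0, 0.0], [0.1, 0.0], state=0)
        twin = child.clone()  # existing TBF identical to the child
        ok, reason = omax_tests(child, parent, [parent, twin], omax=0.6)
        assert not ok and reason == "redundant"

    def test_weak_parent_overlap_rejected(self):
        parent = _tbf([0.0], [0.0], state=1)
        child = _tbf([2.0], [0.0], state=0)  # |overlap| = exp(-1) ~ 0.37
        ok, reason = omax_tests(child, parent, [parent], omax=0.6)
        assert not ok and reason == "parent-overlap"

    def test_threshold_edge(self):
        alpha, omax = 0.5, 0.6
        # place the child so that |<child|parent>| = 0.59...
        d = np.sqrt(-2 * np.log(0.599) / alpha)
        parent = _tbf([0.0], [0.0], state=1, alpha=alpha)
        child = _tbf([d], [0.0], state=0, alpha=alpha)
        ok, reason = omax_tests(child, parent, [parent], omax=omax)
        assert not ok and reason == "parent-overlap"

    def test_split_thresholds_reduce_to_single_parameter(self):
        parent = _tbf([0.0], [0.0], state=1)
        child = _tbf([0.5], [0.0], state=0)
        other = _tbf([0.4], [0.0], state=0)
        for omax in (0.2, 0.5, 0.8, 0.95):
            joint = omax_tests(child, parent, [other], omax)
            split = omax_tests(child, parent, [other], omax,
                               omax_swarm=omax)
            assert joint == split


class TestRunSpawningMode:
    def test_back_and_forward_propagation_reverts(self, sloped_ci):
        tbf = _tbf([-0.8, 0.4], [0.3, -0.1])
        fwd = tbf
        for _ in range(40):
            fwd = propagate_tbf(fwd, sloped_ci, 0.25)
        back = fwd
        for _ in range(40):
            back = propagate_tbf(back, sloped_ci, -0.25)
        np.testing.assert_allclose(back.R, tbf.R, atol=1e-10)
        np.testing.assert_allclose(back.P, tbf.P, atol=1e-10)
        assert back.gamma == pytest.approx(tbf.gamma, abs=1e-10)

    def test_decreasing_indicator_spawns_at_entry(self, sloped_ci):
        # start past the seam moving away: the indicator only decays
        tbf = _tbf([-1.18, 1.2], [0.0, 2.0], state=1)
        event, child = run_spawning_mode(
            tbf, sloped_ci, SimParams(spawn_mode_cap=20),
            target_state=0, t_entry=5.0)
        assert event.t_max == pytest.approx(5.0)

    def test_reference_spawn_accepted_with_strong_overlap(self, sloped_ci):
        # a parent heading into the seam produces an accepted child whose
        # overlap with the parent at the spawning geometry passes omax
        from multispawn.gaussians import overlap

        tbf = _tbf([-0.6, 0.3], [-0.5, 0.0], state=1)
        params = SimParams()
        event, child = run_spawning_mode(
            tbf, sloped_ci, params, target_state=0, t_entry=0.0)
        assert event.accepted and child is not None
        assert child.state == 0
        assert event.t_max > event.t_entry
        # reconstruct the parent at t_max and check the overlap gate
        probe = tbf.clone(id=tbf.id)
        nstep = int(round((event.t_max - event.t_entry) /
                          (params.timestep / params.coupling_reduction_factor)))
        for _ in range(nstep):
            probe = propagate_tbf(probe, sloped_ci, 0.25)
        child_fwd = child
        for _ in range(nstep):
            child_fwd = propagate_tbf(child_fwd, sloped_ci, 0.25)
        assert abs(overlap(child_fwd, probe)) >= params.omax

    def test_child_conserves_classical_energy(self, sloped_ci):
        tbf = _tbf([-0.6, 0.3], [-0.5, 0.0], state=1)
        event, child = run_spawning_mode(
            tbf, sloped_ci, SimParams(), target_state=0, t_entry=0.0)
        assert child is not None
        # at the spawning geometry the child's total energy equals the
        # parent's; after separate backpropagation each conserves its own
        nstep = int(round((event.t_max - event.t_entry) / 0.25))
        probe = tbf.clone(id=tbf.id)
        for _ in range(nstep):
            probe = propagate_tbf(probe, sloped_ci, 0.25)
        assert classical_energy(child, sloped_ci) == pytest.approx(
            classical_energy(probe, sloped_ci), abs=1e-6)

    def test_energetically_forbidden_child_rejected(self, sloped_ci):
        # lower-state TBF far below the upper surface with little kinetic
        # energy cannot spawn upward
        tbf = _tbf([0.9, 0.25], [0.0, 0.0], state=0)
        event, child = run_spawning_mode(
            tbf, sloped_ci, SimParams(spawn_mode_cap=5),
            target_state=1, t_entry=0.0)
        if not event.accepted:
            assert event.rejection_reason in ("forbidden", "parent-overlap")
        else:  # if energetically allowed the child must conserve energy
            assert child is not None


class TestSpawnInvariants:
    def test_no_spawns_when_threshold_above_indicator(self, sloped_ci):
        import multispawn as ms

        ic = ms.InitialCondition(R0=[0.2, 0.3], P0=[0.0, 0.1])
        params = SimParams(t_final=300.0, csthresh=np.inf)
        res = ms.run_ic(ic, sloped_ci, params)
        assert len(res.events) == 0
        np.testing.assert_allclose(res.trace.populations[:, 1], 1.0,
                                   atol=1e-9)
        assert res.trace.n_tbfs[-1] == 1

    def test_accepted_spawn_grows_set_and_keeps_norm(self, sloped_ci):
        import multispawn as ms

        ic = ms.InitialCondition(R0=[-0.3, 0.5], P0=[-0.3, 0.0])
        res = ms.run_ic(ic, sloped_ci, SimParams(t_final=400.0))
        accepted = [e for e in res.events if e.accepted]
        assert len(accepted) >= 1
        assert res.trace.n_tbfs[-1] == 1 + len(accepted)
        # norm stays 1 through every spawn (children carry zero amplitude)
        np.testing.assert_allclose(res.trace.norm, 1.0, atol=1e-5)

    def test_evaluation_count_matches_formula_without_screening(
        self, sloped_ci
    ):
        import multispawn as ms
        from multispawn import nes_count

        ic = ms.InitialCondition(R0=[-0.3, 0.5], P0=[-0.3, 0.0])
        res = ms.run_ic(ic, sloped_ci,
                        SimParams(t_final=400.0, olapthresh=0.0))
        np.testing.assert_array_equal(
            res.trace.n_es,
            [nes_count(n) for n in res.trace.n_tbfs])
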