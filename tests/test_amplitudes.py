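"""Matrix assembly (SPA0 + screening), regularized inversion, amplitude
propagation, and population bookkeeping."""

import numpy as np
import pytest
from scipy.linalg import expm

from multispawn import (
    CoupledSet,
    SimParams,
    TBF,
    assemble_matrices,
    mulliken_population,
    nes_count,
    propagate_coefficients,
    regularized_inverse,
    state_population,
)
from multispawn.amplitudes import DegenerateBasisError
from multispawn.gaussians import kinetic_element, overlap, sdot_element
from multispawn.models import LVCModel, adiabatic_surface
from multispawn.propagation import swarm_rates


def _tbf(R, P, state=0, gamma=0.0, alpha=0.5):
    R = np.atleast_1d(np.asarray(R, float))
    return TBF(state=state, R=R, P=np.atleast_1d(np.asarray(P, float)),
               alpha=np.full(R.size, alpha), gamma=gamma)


def _set(tbfs, C=None):
    C = (np.zeros(len(tbfs), complex) if C is None else
         np.asarray(C, complex))
    if C.shape == (len(tbfs),) and not C.any():
        C[0] = 1.0
    return CoupledSet(tbfs=tbfs, C=C)


class TestAssembly:
    def test_single_tbf(self, sloped_ci):
        tbf = _tbf([0.3, -0.2], [0.1, 0.4], state=1)
        cset = _set([tbf])
        m = assemble_matrices(cset, sloped_ci, SimParams())
        np.testing.assert_allclose(m.S, [[1.0]], atol=1e-12)
        E, _ = adiabatic_surface(sloped_ci, tbf.R)
        expect = kinetic_element(tbf, tbf, sloped_ci.eff_mass) + E[1]
        assert m.H[0, 0] == pytest.approx(expect, abs=1e-12)
        assert m.n_pair_evals == 1

    def test_screening_zeroes_distant_couplings(self, sloped_ci):
        a = _tbf([0.0, 0.0], [0.0, 0.0], state=1)
        b = _tbf([8.0, 0.0], [0.0, 0.0], state=1)  # overlap ~ exp(-16)
        cset = _set([a, b])
        m = assemble_matrices(cset, sloped_ci, SimParams(olapthresh=1e-3))
        assert abs(overlap(a, b)) < 1e-3
        assert m.H[0, 1] == 0 and m.H[1, 0] == 0
        assert m.Sdot[0, 1] == 0
        assert m.S[0, 1] != 0  # S itself stays exact
        assert m.n_pair_evals == 2  # diagonal pairs only

    def test_screening_off_reproduces_unscreened(self, sloped_ci):
        tbfs = [_tbf([0.0, 0.0], [0.1, 0.0], state=1),
                _tbf([0.8, 0.2], [-0.1, 0.2], state=1),
                _tbf([0.5, -0.4], [0.0, 0.3], state=0)]
        c0 = _set([t.clone(id=t.id) for t in tbfs])
        c1 = _set([t.clone(id=t.id) for t in tbfs])
        m0 = assemble_matrices(c0, sloped_ci, SimParams(olapthresh=0.0))
        m1 = assemble_matrices(c1, sloped_ci, SimParams(olapthresh=1e-300))
        np.testing.assert_array_equal(m0.H, m1.H)
        np.testing.assert_array_equal(m0.Sdot, m1.Sdot)
        assert m0.n_pair_evals == nes_count(3)

    def test_spa0_energy_term_on_slowly_varying_surface(self, braket_quad):
        # near-linear potential: SPA0 energy x overlap within 1% of the
        # exact quadrature of <a| E(q) |b>
        # (near-equal momenta: the exact first moment acquires an O(dP)
        # imaginary part that the real-centroid evaluation cannot carry)
        m = LVCModel(omega=[1e-4], energies=[0.1], kappa=[[0.05]],
                     lam=np.zeros((1, 1, 1)))
        a = _tbf([0.0], [0.2], alpha=1.0)
        b = _tbf([0.6], [0.17], alpha=1.0)
        cset = _set([a, b])
        mats = assemble_matrices(cset, m, SimParams(olapthresh=0.0))
        kin = kinetic_element(a, b, m.eff_mass)
        spa0_energy = mats.H[0, 1] - kin

        def energy_op(r, x):
            E, _ = adiabatic_surface(m, np.array([x]))
            return E[0]

        exact = braket_quad(a, b, operator=energy_op)
        assert abs(spa0_energy - exact) < 0.01 * abs(exact)

    def test_hermitian_S_and_H(self, sloped_ci):
        tbfs = [_tbf([0.1, 0.0], [0.2, 0.1], state=1),
                _tbf([-0.4, 0.6], [0.0, -0.3], state=0),
                _tbf([0.3, -0.2], [0.1, 0.2], state=1)]
        cset = _set(tbfs)
        m = assemble_matrices(cset, sloped_ci, SimParams(olapthresh=0.0))
        np.testing.assert_allclose(m.S, m.S.conj().T, atol=1e-14)
        np.testing.assert_allclose(m.H, m.H.conj().T, atol=1e-14)

    def test_sdot_matches_pairwise_closed_form(self, sloped_ci):
        tbfs = [_tbf([0.1, 0.3], [0.2, 0.1], state=1, gamma=0.4),
                _tbf([-0.2, 0.5], [0.1, -0.3], state=1, gamma=-0.2)]
        cset = _set(tbfs)
        rates = swarm_rates(tbfs, sloped_ci)
        m = assemble_matrices(cset, sloped_ci, SimParams(olapthresh=0.0),
                              rates=rates)
        for i in range(2):
            for j in range(2):
                ref = sdot_element(
                    tbfs[i], tbfs[j],
                    (rates.dR[j], rates.dP[j], rates.dgamma[j]))
                assert m.Sdot[i, j] == pytest.approx(ref, abs=1e-12)


class TestRegularizedInverse:
    def test_identity(self):
        np.testing.assert_allclose(
            regularized_inverse(np.eye(3, dtype=complex), 1e-4), np.eye(3),
            atol=1e-14)

    def test_rank_deficient_pseudo_inverse(self):
        S = np.array([[1.0, 1.0], [1.0, 1.0]], dtype=complex)
        inv = regularized_inverse(S, 1e-4)
        # retained eigenvalue 2 with eigenvector (1,1)/sqrt(2)
        np.testing.assert_allclose(inv, np.full((2, 2), 0.25), atol=1e-12)

    def test_well_conditioned_matches_direct_inverse(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(4, 4)) + 1j * rng.normal(size=(4, 4))
        S = A @ A.conj().T + 4 * np.eye(4)
        np.testing.assert_allclose(regularized_inverse(S, 1e-4),
                                   np.linalg.inv(S), atol=1e-10)

    def test_all_discarded_raises(self):
        with pytest.raises(DegenerateBasisError):
            regularized_inverse(1e-8 * np.eye(2, dtype=complex), 1e-4)


class TestPropagateCoefficients:
    @staticmethod
    def _frozen_set(sloped_ci, n=3):
        rng = np.random.default_rng(17)
        tbfs = [_tbf(rng.normal(0, 0.6, 2), rng.normal(0, 0.5, 2), state=1)
                for _ in range(n)]
        C = rng.normal(size=n) + 1j * rng.normal(size=n)
        cset = CoupledSet(tbfs=tbfs, C=C)
        assemble_matrices(cset, sloped_ci, SimParams(olapthresh=0.0))
        cset.C = C / np.sqrt(cset.norm())
        return cset

    def test_zero_hamiltonian_leaves_amplitudes(self, sloped_ci):
        cset = self._frozen_set(sloped_ci)
        m = cset.matrices
        frozen = type(m)(S=m.S, Sdot=np.zeros_like(m.Sdot),
                         H=np.zeros_like(m.H))
        C0 = cset.C.copy()
        propagate_coefficients(cset, 0.5, SimParams(),
                               matrices_start=frozen, matrices_end=frozen)
        np.testing.assert_allclose(cset.C, C0, atol=1e-14)

    def test_frozen_matrices_match_matrix_exponential(self, sloped_ci):
        cset = self._frozen_set(sloped_ci)
        m = cset.matrices
        C0 = cset.C.copy()
        Sinv = regularized_inverse(m.S, 1e-12)
        A = -1j * Sinv @ (m.H - 1j * m.Sdot)
        dt = 2.0
        ref = expm(A * dt) @ C0
        propagate_coefficients(cset, dt, SimParams(regthresh=1e-12), n_sub=64)
        np.testing.assert_allclose(cset.C, ref, atol=1e-8)

    def test_single_tbf_modulus_constant(self, sloped_ci):
        tbf = _tbf([0.4, -0.1], [0.2, 0.3], state=1)
        cset = CoupledSet(tbfs=[tbf], C=np.array([1.0 + 0.0j]))
        assemble_matrices(cset, sloped_ci, SimParams())
        for _ in range(20):
            propagate_coefficients(cset, 1.0, SimParams())
        assert abs(abs(cset.C[0]) - 1.0) < 1e-12

    def test_norm_conserved_over_1000_steps(self, sloped_ci):
        # Hermitized H + exact Sdot: norm drift < 1e-6 per 1e3 steps even
        # while the TBF centers move
        tbfs = [_tbf([0.0, 0.0], [0.0, 0.0], state=0),
                _tbf([0.6, 0.3], [0.1, -0.1], state=0)]
        cset = CoupledSet(tbfs=tbfs, C=np.array([1.0, 0.0], complex))
        params = SimParams(olapthresh=0.0, regthresh=1e-12)
        from multispawn.propagation import propagate_swarm

        mats = assemble_matrices(cset, sloped_ci, params)
        cset.C = cset.C / np.sqrt(cset.norm())
        n0 = cset.norm()
        for _ in range(1000):
            rates = propagate_swarm(cset.tbfs, sloped_ci, 0.25)
            new = assemble_matrices(cset, sloped_ci, params, rates)
            propagate_coefficients(cset, 0.25, params,
                                   matrices_start=mats, matrices_end=new)
            mats = new
        assert abs(cset.norm() - n0) < 1e-6


class TestPopulations:
    def test_orthogonal_tbfs_give_modulus_squared(self, sloped_ci):
        tbfs = [_tbf([0.0, 0.0], [0.0, 0.0], state=1),
                _tbf([40.0, 0.0], [0.0, 0.0], state=1)]
        C = np.array([0.6 + 0.2j, 0.3 - 0.7j])
        cset = CoupledSet(tbfs=tbfs, C=C)
        assemble_matrices(cset, sloped_ci, SimParams(olapthresh=0.0))
        for k in range(2):
            assert mulliken_population(cset, k) == pytest.approx(
                abs(C[k]) ** 2, abs=1e-12)

    def test_populations_sum_to_norm(self, sloped_ci):
        rng = np.random.default_rng(23)
        tbfs = [_tbf(rng.normal(0, 1, 2), rng.normal(0, 1, 2), state=s)
                for s in (1, 1, 0, 0, 1)]
        C = rng.normal(size=5) + 1j * rng.normal(size=5)
        cset = CoupledSet(tbfs=tbfs, C=C)
        assemble_matrices(cset, sloped_ci, SimParams(olapthresh=0.0))
        total = sum(mulliken_population(cset, k) for k in range(5))
        assert total == pytest.approx(cset.norm(), abs=1e-12)
        by_state = sum(state_population(cset, J) for J in (0, 1))
        assert by_state == pytest.approx(cset.norm(), abs=1e-12)

    def test_mulliken_matches_double_loop_oracle(self, sloped_ci):
        rng = np.random.default_rng(29)
        tbfs = [_tbf(rng.normal(0, 0.8, 2), rng.normal(0, 0.8, 2), state=1)
                for _ in range(4)]
        C = rng.normal(size=4) + 1j * rng.normal(size=4)
        cset = CoupledSet(tbfs=tbfs, C=C)
        mats = assemble_matrices(cset, sloped_ci, SimParams(olapthresh=0.0))
        for k in range(4):
            ref = sum(
                (np.conj(C[kk]) * mats.S[kk, k] * C[k]).real
                for kk in range(4)
            )
            assert mulliken_population(cset, k) == pytest.approx(ref,
                                                                 abs=1e-12)

    @pytest.mark.parametrize("n,expect", [(1, 1), (2, 3), (10, 55)])
    def test_nes_count_formula(self, n, expect):
        assert nes_count(n) == expect


class TestSimParams:
    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            SimParams(omax=1.5)
        with pytest.raises(ValueError):
            SimParams(csthresh=-1.0)

    def test_width_resolution(self, sloped_ci):
        base = SimParams().resolve_widths(sloped_ci)
        np.testing.assert_allclose(base, [0.5, 0.5])
        np.testing.assert_allclose(
            SimParams(widths=2.0).resolve_widths(sloped_ci), [1.0, 1.0])
        np.testing.assert_allclose(
            SimParams(widths=[0.3, 0.9]).resolve_widths(sloped_ci),
            [0.3, 0.9])

    def test_split_omax_defaults_to_single_value(self):
        assert SimParams(omax=0.4).effective_omax() == (0.4, 0.4)
        assert SimParams(omax=0.4, omax_parent=0.7).effective_omax() == (0.7, 0.4)
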