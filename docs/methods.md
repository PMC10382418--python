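# Methods

This note records the models, conventions, numerical choices and known
limitations behind the package, in the spirit of a methods appendix.

## Model Hamiltonians and conventions

Dynamics run on linear vibronic coupling (LVC) Hamiltonians in
dimensionless normal-mode coordinates q. The diabatic matrix is

    W_AA(q) = E_A + Σ_i κ_{A,i} q_i + Σ_i (ω_i/2) q_i²
    W_AB(q) = λ⁰_AB + Σ_i λ_{AB,i} q_i        (A ≠ B)

with all parameters in Hartree. The kinetic energy is Σ_i (ω_i/2) p_i²,
i.e. the effective mass of mode i is 1/ω_i; with this convention the ground
vibrational state of the uncoupled model is exp(−q²/2) per mode, so the
matching frozen-Gaussian width is α = 1/2 independent of ω, and the Wigner
distribution of that state is a product of Normal(0, 1/2) factors in q and
p. The constant coupling λ⁰ (zero by default) is a mild extension of the
strict LVC form; it exists so that flat-gap Rabi systems — for which the
populations have a closed form — are expressible in the same class for
testing.

Adiabatic states come from diagonalizing W. For two states the spectral
decomposition is evaluated in closed form through the mixing angle
θ = ½·atan2(2W₁₂, W₁₁−W₂₂). Two gauge choices matter:

- **Energy gradients** (Hellmann–Feynman, c_J·∇W·c_J) are gauge invariant.
- **Nonadiabatic coupling vectors** for 2-state models use the globally
  smooth rational form d₀₁ = (ΔW ∇W₁₂ − W₁₂ ∇ΔW)/(ΔW² + 4W₁₂²) (= ∇θ),
  which keeps the *sign* of the coupling consistent between all TBF-pair
  centroids without eigenvector-continuity tracking; an inconsistent sign
  between neighbouring pairs would corrupt the assembled coupling block.
  For ≥3 states the Hellmann–Feynman form with a largest-component-positive
  sign convention is used instead (adequate for testing; the shipped
  dynamics model is 2-state). Coupling vectors diverge like 1/gap at a
  conical intersection; requests within a gap of 1e-8 Ha raise an error in
  the user API and are clamped to that floor (and counted) inside matrix
  assembly.

The shipped dynamics model (`make_model("sloped_ci")`) is a **synthetic**
two-mode, two-state set: tuning mode ω_t = 0.0095 Ha, coupling mode
ω_c = 0.0033 Ha, vertical energies (0, 0.02) Ha, tuning couplings
(−0.008, +0.009) Ha and interstate coupling 0.012 Ha on the coupling mode.
The numbers were chosen once for physical plausibility (vibrational quanta
of 0.1–0.26 eV, interstate coupling ~0.3 eV, gap 0.54 eV — magnitudes
typical of small conjugated cations) and for the qualitative target
geometry: the intersection sits on the coupling-free axis at q_t ≈ −1.18,
energetically below the Franck–Condon point of the upper state, with both
adiabatic surfaces sloping the same way across the seam. A wavepacket
started at the FC point on the upper surface reaches the seam in ~200 atu,
crosses, and recrosses on later oscillations — the recrossing-prone regime
that makes sloped intersections a hard test for trajectory-based methods.

## Spawning dynamics

The TBF ansatz, the amplitude equations dC/dt = −i S⁻¹[(H−iṠ)C], the
centroid (zeroth-order saddle-point) approximation for the Hamiltonian
matrix elements, and the independent-first-generation treatment of initial
conditions follow the standard multiple-spawning formulation; second-order
nonadiabatic couplings are omitted. Details worth recording:

- **Assembly.** S and Ṡ carry the electronic Kronecker delta (TBFs on
  different states have zero overlap in the full braket). Off-diagonal H
  and Ṡ entries of pairs with |⟨χ_a|χ_b⟩| < `olapthresh` are zeroed; S is
  kept exact so it stays positive semidefinite. One electronic evaluation
  (energies + couplings at the pair centroid) is spent per surviving
  unordered pair; with screening off this reproduces the N(N+1)/2 count
  exactly, and the count is recorded in the trace. H is Hermitized
  (H+H†)/2 after assembly; for diagonal width matrices the SPA0 blocks are
  already Hermitian up to roundoff, so this is a safeguard, and it can be
  disabled (`hermitize=False`) for diagnostics.
- **Regularized inversion.** S is inverted through its eigendecomposition
  with eigenvalues below `regthresh` (absolute; S has unit diagonal)
  discarded — a pseudo-inverse on the retained subspace. An empty retained
  subspace is an error.
- **Amplitude integration.** RK4 with the substep bounded by a quarter of
  the *base* nuclear step, with S, Ṡ, H interpolated linearly between the
  endpoints of each nuclear step. When the nuclear step is already reduced
  ×4 inside coupling regions, one RK4 step per nuclear substep keeps the
  same amplitude resolution. With frozen matrices the integrator matches
  the matrix exponential to 1e-8 over hundreds of steps.
- **Classical propagation.** Velocity Verlet (time reversible to 1e-12);
  the semiclassical phase integrates the classical Lagrangian T − E_J with
  the trapezoid value across each step. Any constant offset convention in
  γ cancels in observables through the amplitude equations.
- **Adaptive stepping.** The base step is reduced by
  `coupling_reduction_factor` (4) whenever any TBF's coupling magnitude
  exceeds max(csthresh/2, 1 au⁻¹). The absolute floor exists because the
  reference csthresh (1e-4 au⁻¹) is crossed *everywhere* on an LVC model —
  tying the reduction to csthresh alone would make the reduced step
  permanent, which quadruples cost without measurable benefit (the
  population trace changes by <1e-4 on the shipped model). A step is
  rejected and redone with half the step when the per-step norm drift
  exceeds 1e-4 or the quantum energy Re(C†HC)/norm drifts by more than
  `energy_tol`; below `dt_min` the run aborts with a diagnostic and is
  excluded from ensemble averages (reported). The energy tolerance default
  is 0.02 Ha — deliberately loose, because the saddle-point approximation
  itself moves the quantum energy by up to ~1e-2 Ha per frame through
  strong-coupling passages (measured on the shipped model); a tight energy
  gate would abort every productive run on approximation error that a
  smaller step cannot remove. Norm, by contrast, is conserved by
  construction (Hermitized H, analytic Ṡ), so its gate is tight.
- **Spawning schedule.** Entry requires coupling magnitude > `csthresh`
  and Mulliken population ≥ `poptospawn`. The spawning mode scans the
  parent's classical path on the reduced step until the first interior
  three-point maximum of the indicator; a scan whose indicator decays 30%
  below its running maximum stops early (maximum at entry for a monotone
  decrease), and a scan still rising at the duration cap (1000 base steps)
  spawns at the cap, flagged. The child is created at the maximum with the
  parent's widths and phase and the parent's momentum shifted along the
  coupling vector to conserve classical energy (classically forbidden
  shifts reject the spawn), then backpropagated to the entry time. It is
  accepted if |⟨child|parent⟩| at the maximum ≥ `omax` and its overlap
  with every other TBF at the entry time ≤ `omax` (the two thresholds can
  be split). Because the reference `csthresh` is below the coupling
  magnitude everywhere, "leaving the coupling region" is judged against
  the traversed peak: a parent may attempt again once it nears the located
  maximum, after a retry interval (with exponential backoff on failures),
  or once its indicator has fallen below half the peak it has traversed
  and turns upward into the next region. A cheap pre-screen skips attempts
  while an existing target-state TBF still overlaps the parent above
  `omax` — the redundancy gate is what actually limits basis growth, in
  line with the observation that small spawning thresholds cause rapid
  TBF proliferation controlled by the overlap tests.

Reference parameter values (the `SimParams` defaults): timestep 1 atu
(0.25 in coupling regions), csthresh 1e-4 au⁻¹, poptospawn 0.001, omax 0.6,
olapthresh 0.001, regthresh 1e-4, ground-state TBF widths, 250 initial
conditions. Runs are bit-reproducible for a given seed; the only
randomness is the Wigner sampling of initial conditions.

## Grid reference

The split-operator propagator alternates kinetic half-steps in momentum
space (FFT per mode, T = Σ ω_i k_i²/2) with potential full-steps applied as
the pointwise matrix exponential of W (norm-conserving by construction;
second-order accurate in dt, converged results verified by grid/step
refinement). The wavefunction is stored diabatically — smooth and
single-valued even around the intersection — and observables are obtained
by pointwise projection: adiabatic populations are gauge independent.

The initial state is the Condon wavepacket: the ground-state Gaussian
placed on the upper *diabatic* state. A "pure upper adiabatic" wavepacket
is not globally well defined around a conical intersection (geometric
phase), and the Condon preparation is the standard choice for vibronic
models. The spawning dynamics, by contrast, starts each TBF with unit
amplitude on the upper *adiabatic* surface. At the Franck–Condon point the
two preparations differ by the adiabatic/diabatic mixing across the
coupling mode — on the shipped model the grid run's upper-adiabatic
population starts at 0.862, not 1 — and during the approach to the seam
the grid packet's adiabatic projection rotates continuously while
surface-bound Gaussians change population only by actual transfer. This
representation offset dominates the transient AIMS-vs-grid deviation
(~0.2–0.3 around the first passage on the shipped model); after the
passage the two agree to a few 0.01 in population, and the recrossing near
t ≈ 1900 atu is reproduced. Quantitative agreement of this kind — correct
decay amounts and timing, transient projection offsets — is what passing
the integration tests demonstrates; they do not certify pointwise
agreement through the passage itself.

## Sensitivity analysis

One parameter is varied at a time, all runs (reference included) sharing
the same Wigner-sampled initial conditions, so the value equal to the
reference reproduces the reference trace bit for bit. The signed relative
deviation (P − P_ref)/P_ref of the excited-state population is collected
at every output time with P_ref ≥ 0.01 (a floor against division blow-up
as the reference empties), pooled over times and parameter values — the
most extreme value tested (largest |log(v/v_ref)|) excluded by default —
and summarized by a Gaussian KDE with Scott's bandwidth (sample standard
deviation × n^(−1/5); `scipy.stats.gaussian_kde` supplies the estimator,
cross-checked against a direct kernel sum in the tests). The integrated
absolute nuclear-density deviation ∫|ρ − ρ_ref| dq (Riemann sum, bounded
by 2 for unit-norm densities) provides the basis-independent companion
measure.

## Problem sizes

The package targets desk scale. The test suite uses ensembles of 10
initial conditions to t = 1000 atu (two seam passages) with a 128-point,
±14 grid for the reference; the acceptance script uses 24 initial
conditions to t = 1500 atu plus an 8-IC threshold sweep. Ensembles of a
few hundred initial conditions and longer horizons are straightforward but
take hours, not minutes.

## What the synthetic setting does and does not show

The generator produces LVC models with exactly harmonic diabatic surfaces,
at most two coupled states in the shipped dynamics, and Wigner sampling of
a separable ground state. Passing tests therefore demonstrate the
correctness of the spawning machinery (matrix elements to 1e-8 against
quadrature, exact-limit and conservation properties, the documented
parameter trends) on this class of models. They do not exercise
anharmonicity, on-the-fly electronic structure, second-order couplings
(omitted by construction), >2-state seams, or full-dimensional molecular
widths — and TBF width optimization is out of scope (widths are inputs).
Known limitations: the early-passage transient deviation from the grid
reference discussed above; aborted runs (persistent norm-drift rejection,
a few percent of initial conditions at the reference settings) are
excluded from averages rather than rescued; the general-n_states coupling
gauge is per-call, so ≥3-state dynamics should be treated as experimental;
and overlap screening above its reference value is *not* harmless on this
model — children are spawned at the seam and backpropagated far from their
parents, so part of the transfer flows through pairs with nuclear overlap
between 1e-3 and 0.1, and raising `olapthresh` to 0.1 visibly delays the
transfer (a model-dependent effect: systems whose transfer happens at
large pair overlap are insensitive to it).
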