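# multispawn

Multiple-spawning nonadiabatic quantum dynamics on analytic vibronic
coupling models, with a numerically exact grid reference and a
one-at-a-time parameter sensitivity layer.

## The problem

When a molecule is electronically excited near a conical intersection, the
Born–Oppenheimer separation breaks down: nuclear and electronic motion
couple, and population flows between electronic states. The full / *ab
initio* multiple spawning (FMS/AIMS) framework solves the molecular
time-dependent Schrödinger equation by expanding each nuclear wavefunction
in an adaptive basis of *trajectory basis functions* (TBFs) — frozen
Gaussians

χ_k(R) = e^{iγ_k} ∏_ρ (2α_ρ/π)^{1/4}
exp[−α_ρ(R_ρ−R̄_{kρ})² + i P̄_{kρ}(R_ρ−R̄_{kρ})]

whose centers (R̄, P̄) follow classical trajectories on single adiabatic
surfaces and whose phases γ integrate the classical Lagrangian. The complex
amplitudes C obey

dC/dt = −i S⁻¹ [(H − i Ṡ) C],

with S the TBF overlap matrix, Ṡ its time derivative through the classical
motion, and H the Hamiltonian matrix: same-state pairs couple through the
nuclear kinetic energy and the electronic energy, different-state pairs
through the first-order nonadiabatic coupling vector **d**_IJ =
⟨Φ_I|∂/∂**R**|Φ_J⟩. In the on-the-fly (AIMS) form, electronic quantities
are evaluated once per TBF pair at the pair centroid (the zeroth-order
saddle-point approximation), and the descendants of different initial TBFs
are propagated as independent coupled sets (independent first-generation
approximation), averaged incoherently.

The basis grows by *spawning*: when a TBF's coupling magnitude
|**d**_IJ(R̄)| exceeds `csthresh`, its classical path is scanned forward to
the coupling maximum, a child TBF with zero amplitude is created there on
the coupled state (momentum adjusted along the coupling vector to conserve
energy), backpropagated to the entry time, and admitted if it overlaps its
parent strongly enough and does not duplicate an existing TBF (`omax`), and
if the parent carries enough population (`poptospawn`). Further numerical
controls are the overlap screening of matrix elements (`olapthresh`), the
eigenvalue threshold used to regularize S before inversion (`regthresh`),
the nuclear time step (`timestep`, reduced ×4 in strong-coupling regions),
and the TBF widths.

The package implements this machinery for linear vibronic coupling (LVC)
Hamiltonians — harmonic diabatic surfaces plus linear intra- and
inter-state couplings, the generic generator of conical intersections — in
dimensionless normal modes (mass 1/ω per mode). A split-operator grid
propagator provides the numerically exact reference, and a sensitivity
module reproduces the one-parameter-at-a-time analysis: paired ensembles
per parameter value, signed relative deviations of the excited-state
population pooled over time, and Scott-bandwidth kernel density estimates
of those deviations.

It is written for method developers and students who want a transparent,
fully testable implementation of the spawning machinery at desk scale —
not for on-the-fly electronic-structure dynamics.

## A worked example

```python
import multispawn as ms

model = ms.make_model("sloped_ci")      # 2-mode/2-state LVC, sloped CI
params = ms.SimParams(t_final=800.0)    # reference thresholds built in
ic = ms.wigner_sample(model, 4, seed=1)[0]
result = ms.run_ic(ic, model, params)
tr = result.trace
print(tr.times[-1], tr.populations[-1], tr.n_tbfs[-1])
```

prints (from `examples/03_single_trajectory.py`):

```
800.0  [0.9808  0.0191]  9
```

Starting from one TBF with unit amplitude on the upper adiabatic surface,
the run spawned eight accepted children over two passages through the seam
region, and 98% of the population transferred to the lower state by t = 800
atomic time units; the trace also records the norm (conserved to ~1e-4) and
the per-step electronic-evaluation count N(N+1)/2. The companion scripts in
`examples/` show the model anatomy, the Gaussian matrix elements, the exact
grid reference (whose adiabatic population starts at 0.86, not 1 — the
Condon wavepacket is not a pure adiabatic state), and a spawning-threshold
sensitivity sweep.

A thin CLI wraps the same functions:

```sh
multispawn ensemble --kind sloped_ci --nic 24 --tfinal 1000 --out run
multispawn qd --kind sloped_ci --tfinal 1000 --extent 14 --out qd.tsv
multispawn sweep --parameter csthresh --values 1e-3,1.0,10 --nic 4
```

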