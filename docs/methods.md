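# Methods

## Scope and philosophy

surfhop implements the full toolchain of an overlap-coupling surface-hopping
study — couplings, propagation, initial conditions, spectra, puckering
analysis, kinetics — but replaces the quantum-chemistry layer with analytic
diabatic models.  Everything downstream of the electronic-structure call is
the real algorithm; the models are surrogates whose anchor energies, state
characters and crossing topography are chosen to mimic the thymine singlet
manifold.  Passing tests therefore validate the *machinery* (algebra,
integrators, statistics, conventions), not the photophysics of any real
molecule: the model has two nuclear coordinates instead of 39, its decay
times are its own, and no dynamical time constant is compared against
molecular values.

## Units

Angstrom, femtosecond, electronvolt, amu throughout; ħ = 0.6582119569 eV·fs;
1 eV = 9.648533·10⁻³ amu Å²/fs².  The decoherence parameter α is accepted in
Hartree (its conventional unit) and converted on entry.

## Model Hamiltonians

A `ModelHamiltonian` supplies a symmetric diabatic matrix D(r) and its
analytic gradient.  Adiabatic quantities come from `numpy.linalg.eigh`;
state gradients use the Hellmann–Feynman contraction v_mᵀ(∂D)v_m, which is
exact away from degeneracies (trajectories are stopped before reaching the
exactly degenerate points).

`thymine3s` interpolates target diabatic matrices at six anchor
configurations with Gaussian radial-basis kernels (width 0.40 Å) over a
confining quartic baseline, so the anchor adiabatic energies are exact by
construction.  Design choices worth recording:

* The three S2 energies the reference table does not print (at the S1
  minimum and the two S1/S0 crossings) are filled with smooth values
  (4.60, 5.20, 5.00 eV) and are not asserted anywhere.
* At the crossing anchors the target matrices carry 45° diabatic mixings, so
  avoided-crossing structure — and hence nonadiabatic coupling — develops
  around them; at the minima the diabats are taken unmixed.
* A localized linear baseline term (a multiple of the identity, so no gap is
  affected) is solved for self-consistently so the S0 anchor is an exact
  stationary point of the lowest surface.  Without it the interpolant's
  minimum drifts ~0.17 Å away from the anchor, where the S1/S2 characters
  are inverted and the bright state would be S1.
* One *shape anchor* at the midpoint of the S2min→X21 path (energies 2.70,
  3.85, 4.25 eV, 22.5° mixing) pins the interpolated S2 barrier toward the
  crossing at 0.08 eV; without it the radial-basis interpolant bulges to
  0.37 eV, which would contradict the near-barrierless topography the model
  is meant to reproduce.
* Reduced masses are 12 amu per coordinate (carbon-like); the resulting
  ground-state normal modes are 720 and 1080 cm⁻¹, a realistic ring-mode
  range.
* Oscillator strengths live on the diabats (closed-shell 0, nπ* 0.005,
  ππ* 0.20) and mix into the adiabatic states through the squared rotation
  amplitudes (intensity borrowing).

`single_crossing` (tanh diabats ±0.3 eV, Gaussian coupling 0.04 eV, width
0.4 Å) and `double_crossing` are one-dimensional two-state references; the
single crossing has a Landau–Zener diabatic-passage probability of ~0.74 at
1 eV of collision energy, which the internal-consistency suite uses as a
non-vacuous backdrop.

## Couplings (OD and DD)

Orbitals are expressed in a common orthonormal basis, so the inter-step
orbital overlap is simply C(t)ᵀC(t+Δt); the atomic-orbital overlap a real
interface would insert is the identity.  This isolates the CIS-coupling
algebra from basis-set plumbing.

Phase matching assigns t+Δt orbitals to t orbitals by maximum-|overlap|
Hungarian assignment *within* the occupied and virtual blocks (so the
partition survives), then sign-flips columns so all diagonal overlaps are
non-negative.  CI coefficient matrices are transformed with the recorded
permutation and signs before any contraction.  CI-vector phase continuity
uses the same rule at the state level.

The OD contraction uses the occupied/virtual form with parity P_ij = +1 for
spin-restricted determinants with occupied orbitals kept in ascending index
order; this convention is pinned by exact agreement with the DD determinant
oracle, including a one-electron hand case.  The DD reference expands the
wave-function overlap over all determinant pairs, each a determinant of the
occupied-block overlap with one row and one column substituted by virtual
entries (single-spin convention).

Both estimators antisymmetrize by default, σ = (⟨Ψ_m(t)|Ψ_n(t+Δt)⟩ −
⟨Ψ_n(t)|Ψ_m(t+Δt)⟩)/2Δt, which enforces skew symmetry exactly at finite Δt
and cancels the second-order overlap terms — this is what makes OD and DD
agree to ~10⁻⁶ relative even at orbital-rotation magnitude 10⁻³.  A raw
forward-difference variant is available and converges linearly in Δt.

The analytic oracle: CIS fixtures generated along a two-state model path mix
two fixed Frobenius-orthonormal CI matrices by the model's continuous mixing
angle θ(r), so the exact coupling is dθ/dt.  The default traversal speed is
0.02 Å/fs — a hot but realistic nuclear velocity (~4× thermal carbon at
300 K); at Δt = 0.05 fs the midpoint discretization error of the
antisymmetrized estimator is then ~10⁻⁵/fs, an order below the 10⁻⁴ band
tested.  Orbital drift along the path is off by default (the oracle is then
exact); it can be switched on for stress tests.

## Surface hopping engine

* **Nuclei**: velocity Verlet on the active surface, 0.5 fs.
* **Electronic amplitudes**: iħ ȧ = E(τ)a − iħσ(τ)a integrated with
  Butcher's six-stage 5th-order Runge–Kutta at 0.025 fs substeps.  Energies
  are interpolated linearly across the nuclear step; the overlap-derived σ
  is assigned to the step midpoint and interpolated linearly between
  consecutive midpoints.  The integrator works in a mean-energy gauge (the
  common phase is restored analytically), so only energy differences enter
  the stiffness; per-step norm drift is then < 10⁻⁸, and sharply peaked
  couplings trigger automatic substep refinement (up to 64×) before the
  step is declared failed.
* **Couplings during dynamics** come from the overlap of adiabatic
  eigenvectors between consecutive steps, antisymmetrized — exactly the
  wave-function-overlap TDNC evaluated in the model's diabatic basis.
  Eigenvector sign continuity is enforced step to step.
* **Hopping**: fewest-switches probabilities are accumulated over the
  electronic substeps as the integrated flux
  ∫ 2σ_km Re(a_k*a_m)/|a_k|² dτ (trapezoid), then one uniform draw per
  nuclear step decides.  The substep integration matters: sampling the
  oscillating coherence once per step rectifies its phase and overestimates
  the hop hazard by ~25% on the single-crossing benchmark.  The documented
  per-step Hammes-Schiffer–Tully formula is retained as `hop_probability`.
* **Momentum at hops** is rescaled uniformly along the velocity vector
  (overlap-based propagation supplies no coupling vector to rescale along);
  frustrated hops leave velocities untouched and are counted.
* **Decoherence**: energy-based damping of inactive amplitudes with
  τ_m = ħ/|E_m − E_active| · (1 + α/E_kin), α = 0.1 Hartree default, active
  amplitude rescaled to unit norm.  Without it, residual Stückelberg ringing
  leaves a ~5-percentage-point internal inconsistency after a single
  crossing passage; with it, ensemble fractions and mean populations agree
  essentially exactly.
* **Termination**: while the trajectory runs on S1, an S1−S0 gap below
  0.15 eV (configurable; the 0.30 eV variant shortens crossing times, which
  is tested) stops it and records the time as the S1/S0 crossing-time
  estimate; otherwise trajectories stop at 1 ps.  Ground-state dynamics is
  not continued after termination.  For the thymine protocol, couplings to
  S0 are disabled (`couple_ground=False`), mirroring dynamics whose
  electronic-structure method cannot describe the closed-shell reference
  near the S1/S0 seam; generic models keep them on.
* **Reproducibility**: per-trajectory generators are spawned from the master
  seed with the trajectory index as spawn key, so ensembles are bit-for-bit
  reproducible and independent of scheduling.

## Initial conditions and spectra

Ground-state harmonic Wigner sampling draws q and p per mode from
independent Gaussians with σ_q² = ħ/2μω and σ_p² = ħμω/2 (minimum
uncertainty); cartesian momenta are reconstructed through the mode masses.
Normal modes for model surfaces come from a finite-difference Hessian at the
optimized S0 minimum.

The nuclear-ensemble spectrum sums unit-area Gaussians (default width
0.05 eV, configurable; no broadening value is inherited from anywhere) at
the vertical excitation energies, weighted by oscillator strength, averaged
over the ensemble.  The default output is normalized to unit band maximum;
the unnormalized curve integrates to the mean total oscillator strength
(the sum rule used in testing).  Because the model's vertical-energy
distribution is skewed, the band maximum sits about one line width from the
mean bright vertical energy; a symmetric band would put them on top of each
other.

Window filtering keeps points whose target-state vertical energy lies
within ±0.13 eV (inclusive) of the computed band maximum.  Selection within
the window is uniform over qualifying points; f-weighted resampling is
available as an option and never selects dark points.  With seed 1, 285 of
500 points qualify and the first 115 are propagated, matching the ensemble
size the protocol is built around.

## Ring puckering

Cremer–Pople displacements use the geometric-center origin and the mean
plane fixed by the two trigonometric sum vectors, with the plane normal
chosen right-handed with respect to the ring traversal and the negative-sine
phase convention.  Under these conventions the boat with atoms 3 and 6 above
the plane lands exactly at (θ, φ) = (90°, 120°) — the anchor that validates
the φ-origin choice — and the inverse construction on a regular hexagon
round-trips (Q, θ, φ) to 10⁻¹⁰.  A one-position cyclic relabeling shifts φ
by 120° and reflects θ → 180° − θ (the alternating sum changes parity); a
two-position relabeling leaves θ unchanged.

Boeyens classification is nearest-vertex (spherical Voronoi) over the 38
canonical conformers — 2 chairs, 6 boats, 6 twist-boats (θ = 90°), 6 + 6
envelopes (θ = 54.7°, 125.3°) and 6 + 6 half-chairs (θ = 50.8°, 129.2°) —
with ties broken toward lower φ.  Labels are generated from the ideal
displacement patterns (atoms within 10% of the per-side extreme listed
above/below the type letter, e.g. `3,6B`, `B2,5`, `1H2`, `1E`); twist-boats
carry both locant pairs (`1,4S2,5`), a systematic variant of the
conventional skew labels.  Rings with Q < 10⁻⁶ Å are reported as planar.

Hop maps reflect φ ≥ 180° into the φ < 180° half-plane (the map's mirror
symmetry) and report the φ–time correlation alongside the per-hop
(t, Q, θ, φ, conformer) table.  For `thymine3s`, hop coordinates are mapped
to ring geometries by embedding the puckering coordinate as a ³,⁶B
deformation with Q = 0.96·|y| (so the crossing anchor at y = 0.5 carries
Q = 0.48 Å) and the stretch coordinate as a carbonyl bond of length
1.23 + 0.5x Å.

## Kinetics

The sequential branching model is: S2(t) = f·e^(−t/τ21) + (1−f); the S2→S1
flux feeds S1, of which a fraction g drains with constant τ10 and the rest
is trapped:

S1(t) = (1−g)·f·(1−e^(−k1 t)) + g·f·k1·(e^(−k1 t) − e^(−k2 t))/(k2 − k1),

with k1 = 1/τ21, k2 = 1/τ10 and the equal-rate limit handled analytically.
This is the minimal closed-form scheme consistent with one (f, τ) pair per
process; it is fitted jointly to the S2, S1 and S0 pools by bounded
least squares (`scipy.optimize.curve_fit`).  Fits whose S2 pool does not
decay over the observed window (τ at the bound or vanishing decayed
fraction) are rejected.  Terminated trajectories count as ground-state
population from their crossing time onward.

The worst-case binomial half-width is max_p z·√(p(1−p)/n) = z/(2√n); for
n = 115 at the 90% level this is 7.7%, verified against a 10⁶-replicate
Monte-Carlo quantile estimate.

LIIC paths interpolate chain z-matrix primitives (bonds, angles, torsions
by shortest arc) and rebuild geometries, falling back to cartesian
interpolation for degenerate references; bond-distance series use the
population standard deviation.

## Problem sizes and numerical choices

Default study sizes — 500 Wigner points, 115 trajectories, 1 ps at 0.5 fs,
200 coupling instances, 50 kinetic-recovery seeds, 10⁵ Wigner moment
samples — are the protocol's own scale and run on one CPU in a few minutes;
the coupling-oracle paths use 4000 steps at 0.05 fs.  Tolerances follow the
quantity's construction: quantities exact by construction (anchors,
puckering angles) are asserted near machine precision or at the stated
0.05 eV band; estimator-limited quantities (OD↔DD 10⁻⁶ relative, analytic
coupling 10⁻⁴/fs, energy drift 10⁻⁵ eV/ps, norm 10⁻⁸/step) at their
discretization scale; sampling-limited quantities (Wigner 2%, stochastic τ
recovery 15% median) at their √n scale.

## Known limitations

Two nuclear coordinates cannot reproduce molecular time constants, vibrational
energy redistribution, or the entropic breadth of a real crossing seam; the
model's sub-200 fs decay is a property of the surrogate topography.  The DD
oracle is exponential-cost in spirit and kept to small active spaces.  The
puckering φ-origin is validated only through the ³,⁶B anchor; other
φ-convention variants in the literature differ by reflections or offsets.
The kinetic model ignores a possible third process (slow leakage of the
trapped S2 pool); where real occupation curves contain one, the trapped
fractions absorb it.
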