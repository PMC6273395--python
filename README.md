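# surfhop

Fewest-switches surface hopping (FSSH) with overlap-based time-derivative
nonadiabatic couplings, exercised end to end on analytic model Hamiltonians.
The package is a desk-scale laboratory for the machinery behind excited-state
dynamics studies of pyrimidine nucleobases: it bundles

* **time-derivative couplings between CIS-type wave functions** — the cheap
  *orbital-derivative* (OD) route, which contracts CI coefficients with the
  inter-step molecular-orbital overlap matrix, against the expensive
  *determinant-derivative* (DD) reference built from full Slater-determinant
  overlaps, including the orbital phase-matching step both need;
* **a surface-hopping engine** — velocity-Verlet nuclei (0.5 fs), Butcher
  5th-order electronic amplitudes on interpolated energies and couplings
  (0.025 fs substeps), fewest-switches hopping, energy-based decoherence
  (α = 0.1 Hartree), and a gap-based S1/S0 stop criterion (0.15 eV);
* **initial conditions and spectra** — harmonic-Wigner sampling of the
  vibrational ground state and the nuclear-ensemble absorption spectrum, with
  excitation-window filtering of initial conditions;
* **ring-puckering analysis** — Cremer–Pople (Q, θ, φ) parameters, the
  inverse construction, Boeyens conformer classification, and polar maps of
  hop geometries;
* **excited-state kinetics** — occupation aggregation, a sequential
  branching-model fit yielding (f, τ) pairs per process, worst-case binomial
  confidence half-widths, and LIIC reaction paths.

Because no electronic-structure code is involved, the electronic quantities
come from analytic diabatic models.  The flagship `thymine3s` model is a
two-coordinate (C4O-stretch-like × ring-puckering-like), three-state surface
anchored so that its adiabatic energies at six named configurations — the
S0, S1 and S2 minima, the S2/S1 crossing and the two S1/S0 crossings —
reproduce the reference excitation energies of the thymine singlet manifold
exactly, with a small (0.08 eV) interpolated barrier between the S2 minimum
and the S2/S1 crossing.

## Core quantities

The coupling driving hops is σ_mn = ⟨Ψ_m|∂_t Ψ_n⟩, evaluated by finite
differences from wave-function overlaps between consecutive steps.  For CIS
expansions |Ψ_m⟩ = Σ_ia C_ia^m |Φ_i^a⟩ the OD method assembles

σ_mn = Σ_ia C_ia^m ∂_t C_ia^n + Σ_iab C_ia^m C_ib^n ⟨φ_a|∂_t φ_b⟩
       − Σ_ija C_ia^m C_ja^n ⟨φ_j|∂_t φ_i⟩,

with ⟨φ_j|∂_t φ_i⟩ ≈ S_ji/Δt from the phase-matched orbital overlap matrix,
at cost O(N_occ N_virt²) per state pair instead of the determinantal
O(N_occ⁵ N_virt²).  Hop probabilities follow Hammes-Schiffer–Tully with σ
replacing **F**·**v**, integrated over the electronic substeps.

## Worked example

```python
from surfhop import protocol

res = protocol.run_protocol(seed=1)   # 500 Wigner points -> 115 trajectories
print(res.band_maximum_ev)            # 5.075
print(res.n_selected)                 # 285 points inside the 0.13 eV window
fit = res.kinetic_fit
print(round(fit.f21, 2), round(fit.tau21, 1))   # 0.96 114.8
print(res.hop_map["conformer"].mode()[0])       # 3,6B
```

This runs the full protocol on `thymine3s`: 500 Wigner samples around the
ground-state minimum give a nuclear-ensemble spectrum peaking at 5.075 eV
(the mean bright vertical excitation is 5.03 eV); 115 initial conditions are
taken from the band-maximum ± 0.13 eV window and propagated on the bright S2
state for up to 1 ps with couplings to S0 disabled and the 0.15 eV S1/S0
stop active.  With seed 1 every trajectory reaches the S1/S0 stop (mean
crossing-time estimate 198 fs), the sequential fit assigns 96% of the S2
population a 115 fs decay into S1, and the S2→S1 hop geometries cluster at
the ³,⁶B boat (θ = 90°, φ = 120°) with mean puckering amplitude Q ≈ 0.46 Å —
the same conformer that hosts the model's S2/S1 crossing anchor (Q = 0.48 Å).
The model's decay is much faster than in the molecule the anchors come from;
its two coordinates funnel the wave packet straight to the crossings, and no
dynamical time constant is a fitting target here.

The same steps are available from the shell:

```
surfhop spectrum --model thymine3s --n 500 --seed 1 --out spec_out
surfhop propagate --model thymine3s --n 115 --seed 1 --out run_out
surfhop couple-test --n-occ 3 --n-virt 3 --trials 50
surfhop pucker ideal-boat.xyz
```

Each subcommand writes a `manifest.json` (inputs, seeds, version, timing)
beside its outputs.

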