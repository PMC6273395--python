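"""End-to-end photodynamics protocol on the thymine-like model.

Mirrors the standard nuclear-ensemble + surface-hopping workflow: harmonic
Wigner sampling around the ground-state minimum, vertical excitation
energies and oscillator strengths over the ensemble, the nuclear-ensemble
absorption spectrum, selection of initial conditions from an excitation
window around the band maximum, surface-hopping propagation started in the
bright S2 state with couplings to the ground state disabled and the S1/S0
gap stop criterion active, and finally occupation aggregation, sequential
kinetic fitting and the hop-geometry puckering map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import fssh, initcond, kinetics, pucker
from .models import (
    ModelHamiltonian,
    build_thymine_model,
    evaluate_adiabatic,
    thymine_frame_geometry,
)

logger = logging.getLogger(__name__)

__all__ = ["ProtocolResult", "ground_state_modes", "vertical_excitations", "run_protocol"]


@dataclass
class ProtocolResult:
    model: ModelHamiltonian
    spectrum: initcond.SpectrumCurve
    band_maximum_ev: float
    mean_bright_vertical_ev: float
    window_center_ev: float
    window_halfwidth_ev: float
    n_sampled: int
    n_selected: int
    ensemble: fssh.EnsembleResult
    occupations: kinetics.OccupationSeries
    kinetic_fit: kinetics.KineticFit | None
    hop_map: object  # DataFrame from pucker.hop_pucker_map
    settings: fssh.RunSettings
    seed: int


def ground_state_modes(
    model: ModelHamiltonian, guess: np.ndarray | None = None, h: float = 1e-3
) -> initcond.NormalModeSet:
    """Locate the ground-state minimum and build its harmonic normal modes.

    The minimum is found by quasi-Newton descent of the lowest adiabatic
    surface from ``guess`` (the coordinate origin by default); the Hessian
    is taken by central finite differences with step ``h`` Angstrom.
    """
    x0 = np.zeros(model.n_coords) if guess is None else np.asarray(guess, dtype=float)

    def e0(x):
        return evaluate_adiabatic(model, x).energies[0]

    opt = minimize(e0, x0, method="BFGS", options={"gtol": 1e-10})
    xm = opt.x
    n = model.n_coords
    hess = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            xpp = xm.copy(); xpp[i] += h; xpp[j] += h
            xpm = xm.copy(); xpm[i] += h; xpm[j] -= h
            xmp = xm.copy(); xmp[i] -= h; xmp[j] += h
            xmm = xm.copy(); xmm[i] -= h; xmm[j] -= h
            hess[i, j] = hess[j, i] = (
                e0(xpp) - e0(xpm) - e0(xmp) + e0(xmm)
            ) / (4.0 * h * h)
    return initcond.normal_modes_from_hessian(hess, model.masses, xm)


def vertical_excitations(model: ModelHamiltonian, coords: np.ndarray):
    """Vertical excitation energies (eV) and oscillator strengths at a point.

    Excitation energies are adiabatic gaps to the lowest state; oscillator
    strengths mix the diabatic state strengths through the squared
    diabatic->adiabatic rotation amplitudes (intensity borrowing).
    """
    ep = evaluate_adiabatic(model, coords)
    energies = ep.energies - ep.energies[0]
    if model.oscillator_strengths is None:
        f = np.zeros(model.n_states)
    else:
        f_diab = np.asarray(model.oscillator_strengths, dtype=float)
        f = (ep.rotation**2).T @ f_diab
        f[0] = 0.0
    return energies, f


def run_protocol(
    seed: int = 1,
    n_sample: int = 500,
    n_traj_max: int = 115,
    window_halfwidth: float = 0.13,
    settings: fssh.RunSettings | None = None,
    model: ModelHamiltonian | None = None,
    grid: np.ndarray | None = None,
    line_width: float = 0.05,
) -> ProtocolResult:
    """Run the full model photodynamics protocol.

    Samples ``n_sample`` Wigner points, computes the nuclear-ensemble
    spectrum, selects up to ``n_traj_max`` initial conditions from the
    excitation window centered on the band maximum, propagates the
    surface-hopping ensemble from the bright state and aggregates the
    kinetics and hop-puckering analyses.  Fully reproducible for a fixed
    seed.
    """
    model = model or build_thymine_model()
    modes = ground_state_modes(model)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    samples = initcond.wigner_sample(modes, n_sample, rng)
    points = []
    for coords, momenta in samples:
        energies, f = vertical_excitations(model, coords)
        points.append(
            initcond.InitialCondition(
                coords=coords, momenta=momenta, energies=energies, oscillator_strengths=f
            )
        )
    if grid is None:
        grid = np.linspace(3.5, 6.5, 601)
    spectrum = initcond.nea_spectrum(points, grid, width=line_width)
    band_max = spectrum.band_maximum_ev
    mean_bright = float(np.mean([p.energies[2] for p in points]))
    selected = initcond.filter_energy_window(
        points, center=band_max, half_width=window_halfwidth, target_state=2
    )
    n_selected = len(selected)
    selected = selected[:n_traj_max]
    if settings is None:
        settings = fssh.RunSettings(
            couple_ground=False, initial_state=2, seed=seed, t_max=1000.0
        )
    ics = [(p.coords, p.momenta / model.masses) for p in selected]
    ensemble = fssh.run_ensemble(model, ics, settings)
    occ = kinetics.aggregate_occupations(
        ensemble, times=np.arange(0.0, settings.t_max + settings.dt_nuclear / 2, settings.dt_nuclear)
    )
    try:
        fit = kinetics.fit_sequential_model(occ)
    except (RuntimeError, ValueError) as exc:
        logger.warning("kinetic fit failed: %s", exc)
        fit = None
    hop_events = [
        fssh.HopEvent(
            time=h.time,
            from_state=h.from_state,
            to_state=h.to_state,
            coords=h.coords,
            draw=h.draw,
            geometry=thymine_frame_geometry(h.coords)[1],
        )
        for traj in ensemble.trajectories
        for h in traj.hops
        if h.from_state == 2 and h.to_state == 1
    ]
    hop_map = pucker.hop_pucker_map(hop_events)
    return ProtocolResult(
        model=model,
        spectrum=spectrum,
        band_maximum_ev=band_max,
        mean_bright_vertical_ev=mean_bright,
        window_center_ev=band_max,
        window_halfwidth_ev=window_halfwidth,
        n_sampled=n_sample,
        n_selected=n_selected,
        ensemble=ensemble,
        occupations=occ,
        kinetic_fit=fit,
        hop_map=hop_map,
        settings=settings,
        seed=seed,
    )
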