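"""Fewest-switches surface hopping on model Hamiltonians.

Nuclei follow one adiabatic surface by velocity Verlet (0.5 fs default);
complex electronic amplitudes are integrated with Butcher's 5th-order
Runge-Kutta in substeps (0.025 fs default) on linearly interpolated
energies and couplings; hops are drawn once per nuclear step from the
fewest-switches probabilities built on time-derivative couplings obtained
from the overlap of adiabatic eigenvectors between consecutive steps
(the model-level analog of wave-function overlap TDNCs); the energy-based
decoherence correction damps inactive amplitudes with lifetime
tau = hbar/|dE| * (1 + alpha/E_kin), alpha = 0.1 Hartree by default.

Trajectories are stopped when the S1/S0 gap drops below a threshold
(0.15 eV by default) while the trajectory runs on S1 - the model-level
mirror of the practice of terminating where couplings to a multi-reference
ground state become untrustworthy - and the stop time is recorded as the
estimated S1/S0 crossing time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import EV_TO_AMU_AA_FS, HBAR_EV_FS, HARTREE_TO_EV
from .models import ElectronicPoint, ModelHamiltonian, evaluate_adiabatic

logger = logging.getLogger(__name__)

__all__ = [
    "RunSettings",
    "TrajectoryState",
    "HopEvent",
    "TrajectoryResult",
    "EnsembleResult",
    "IntegrationError",
    "nuclear_step",
    "electronic_step",
    "hop_probability",
    "apply_decoherence",
    "attempt_hop",
    "check_termination",
    "run_trajectory",
    "run_ensemble",
    "kinetic_energy",
]


class IntegrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class RunSettings:
    """Propagation parameters.

    dt_electronic must divide dt_nuclear; decoherence_alpha is in Hartree
    (the conventional unit for this parameter) and may be None to disable
    the correction; gap_stop is the S1/S0 termination threshold in eV.
    ``couple_ground`` switches the couplings to the lowest state on or off -
    the thymine protocol runs with them off, mirroring dynamics whose
    electronic-structure method cannot describe the S1/S0 seam.
    """

    dt_nuclear: float = 0.5  # fs
    dt_electronic: float = 0.025  # fs
    decoherence_alpha: float | None = 0.1  # Hartree
    gap_stop: float = 0.15  # eV
    t_max: float = 1000.0  # fs
    seed: int = 0
    couple_ground: bool = True
    initial_state: int = 1

    def __post_init__(self):
        if self.dt_nuclear <= 0 or self.dt_electronic <= 0:
            raise ValueError("time steps must be positive")
        n_sub = self.dt_nuclear / self.dt_electronic
        if abs(n_sub - round(n_sub)) > 1e-9:
            raise ValueError("dt_electronic must divide dt_nuclear")
        if self.gap_stop < 0 or self.t_max <= 0:
            raise ValueError("gap_stop must be >= 0 and t_max > 0")

    @property
    def n_substeps(self) -> int:
        return int(round(self.dt_nuclear / self.dt_electronic))

    @property
    def alpha_ev(self) -> float | None:
        if self.decoherence_alpha is None:
            return None
        return self.decoherence_alpha * HARTREE_TO_EV


@dataclass
class TrajectoryState:
    """Classical+quantum state of one trajectory."""

    time: float
    coords: np.ndarray
    velocities: np.ndarray
    amplitudes: np.ndarray
    active: int
    electronic: ElectronicPoint
    rng: np.random.Generator


@dataclass(frozen=True)
class HopEvent:
    time: float
    from_state: int
    to_state: int
    coords: np.ndarray
    draw: float
    geometry: np.ndarray | None = None


@dataclass
class TrajectoryResult:
    times: np.ndarray
    active: np.ndarray
    energies: np.ndarray  # (n_steps, n_states)
    populations: np.ndarray  # (n_steps, n_states)
    coords: np.ndarray  # (n_steps, n_coords)
    hops: list
    n_frustrated: int
    termination: str  # "t_max" | "s1s0_gap"
    crossing_time: float | None
    seed_index: int = 0


@dataclass
class EnsembleResult:
    trajectories: list
    failures: list
    settings: RunSettings
    n_states: int


def kinetic_energy(velocities: np.ndarray, masses: np.ndarray) -> float:
    """Kinetic energy in eV for velocities in Angstrom/fs and masses in amu."""
    return 0.5 * float(np.sum(masses * velocities**2)) / EV_TO_AMU_AA_FS


def nuclear_step(
    state: TrajectoryState, model: ModelHamiltonian, dt: float
) -> TrajectoryState:
    """One velocity-Verlet step on the active adiabatic surface.

    The returned state carries updated coordinates, velocities and a fresh
    ElectronicPoint whose eigenvector columns are sign-aligned with the
    previous step for continuity.
    """
    ep = state.electronic
    grad = ep.gradients[state.active]
    if not np.all(np.isfinite(grad)):
        raise IntegrationError(
            f"non-finite force on state {state.active} at t={state.time} fs, "
            f"coords={state.coords.tolist()}"
        )
    acc = -grad * EV_TO_AMU_AA_FS / model.masses
    new_coords = state.coords + state.velocities * dt + 0.5 * acc * dt**2
    ep_next = evaluate_adiabatic(model, new_coords)
    # sign-align eigenvectors to the previous step (state tracking)
    overlap_diag = np.einsum("sm,sm->m", ep.rotation, ep_next.rotation)
    signs = np.where(overlap_diag < 0.0, -1.0, 1.0)
    ep_next = ElectronicPoint(
        energies=ep_next.energies,
        gradients=ep_next.gradients,
        rotation=ep_next.rotation * signs[np.newaxis, :],
        coords=ep_next.coords,
    )
    acc_next = -ep_next.gradients[state.active] * EV_TO_AMU_AA_FS / model.masses
    new_vel = state.velocities + 0.5 * (acc + acc_next) * dt
    return replace(
        state,
        time=state.time + dt,
        coords=new_coords,
        velocities=new_vel,
        electronic=ep_next,
    )


def _substep_kernel_py(a, g0, g1, sig_row0, dsig_row, active, h, n_sub):
    """Butcher 5th-order RK over n_sub substeps with hazard accumulation.

    a' = (g0 + tau*g1) a; hazard_m += int 2 sig_row(tau)_m Re(a_k^* a_m)/|a_k|^2.
    ``active`` < 0 disables the hazard integral.
    """
    hazard = np.zeros(a.shape[0])
    tau = 0.0

    def f(t, y):
        return (g0 + t * g1) @ y

    def flux(t, y):
        pop = (y[active].real ** 2 + y[active].imag ** 2)
        if pop < 1e-12:
            return np.zeros(y.shape[0])
        row = sig_row0 + t * dsig_row
        return 2.0 * row * (np.conj(y[active]) * y).real / pop

    for _ in range(n_sub):
        if active >= 0:
            f0 = flux(tau, a)
        k1 = f(tau, a)
        k2 = f(tau + h / 4, a + h * k1 / 4)
        k3 = f(tau + h / 4, a + h * (k1 + k2) / 8)
        k4 = f(tau + h / 2, a - h * k2 / 2 + h * k3)
        k5 = f(tau + 3 * h / 4, a + h * (3 * k1 + 9 * k4) / 16)
        k6 = f(tau + h, a + h * (-3 * k1 + 2 * k2 + 12 * k3 - 12 * k4 + 8 * k5) / 7)
        a = a + h * (7 * k1 + 32 * k3 + 12 * k4 + 32 * k5 + 7 * k6) / 90
        tau += h
        if active >= 0:
            hazard += 0.5 * h * (f0 + flux(tau, a))
    return a, hazard


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _substep_kernel = njit(cache=False)(_substep_kernel_py)
except Exception:  # pragma: no cover
    _substep_kernel = _substep_kernel_py


def electronic_step(
    amplitudes: np.ndarray,
    energies_t: np.ndarray,
    energies_next: np.ndarray,
    sigma_t: np.ndarray,
    sigma_next: np.ndarray,
    dt_nuclear: float,
    dt_electronic: float,
    active: int | None = None,
) -> np.ndarray:
    """Advance the electronic amplitudes through one nuclear step.

    Integrates i*hbar da/dt = E(t) a - i*hbar sigma(t) a with Butcher's
    six-stage 5th-order Runge-Kutta in substeps of ``dt_electronic``;
    energies and coupling matrices are interpolated linearly between their
    values at the ends of the nuclear step.  Raises IntegrationError when
    the norm drifts by more than 1e-6 within the step.

    With ``active`` given, also returns the fewest-switches hazard vector
    accumulated over the substeps,
    h_m = integral 2 sigma_{k m} Re(a_k^* a_m) / |a_k|^2 dtau (k = active),
    the substep-resolved generalization of the per-step hop-probability
    formula.
    """
    n_sub = int(round(dt_nuclear / dt_electronic))
    if abs(n_sub * dt_electronic - dt_nuclear) > 1e-9:
        raise ValueError("dt_electronic must divide dt_nuclear")
    de = (energies_next - energies_t) / dt_nuclear
    ds = (sigma_next - sigma_t) / dt_nuclear
    # propagate in a gauge shifted by the mean energy (the stiff common
    # phase is restored analytically below); only energy differences then
    # enter the integrator, which sharpens its accuracy considerably
    eref0 = float(np.mean(energies_t))
    deref = float(np.mean(de))
    # fused complex generators: da/dtau = (g0 + tau*g1) a
    g0 = np.diag(-1j / HBAR_EV_FS * (energies_t - eref0)).astype(np.complex128) - sigma_t
    g1 = np.diag(-1j / HBAR_EV_FS * (de - deref)).astype(np.complex128) - ds
    a0 = np.ascontiguousarray(amplitudes, dtype=np.complex128)
    norm0 = float(np.vdot(a0, a0).real)
    act = -1 if active is None else int(active)
    sig_row0 = np.ascontiguousarray(sigma_t[act], dtype=float)
    dsig_row = np.ascontiguousarray(ds[act], dtype=float)
    g0c = np.ascontiguousarray(g0)
    g1c = np.ascontiguousarray(g1)
    # sharply peaked couplings (near-degeneracy passages) can exceed the
    # accuracy of the nominal substep; refine it until the norm is conserved
    drift = None
    for refine in range(4):
        sub = n_sub * 4**refine
        a, hazard = _substep_kernel(
            a0, g0c, g1c, sig_row0, dsig_row, act, dt_nuclear / sub, sub
        )
        drift = abs(float(np.vdot(a, a).real) - norm0)
        if drift <= 1e-6:
            if refine:
                logger.info(
                    "electronic_step: refined substep %dx to hold norm (drift %.1e)",
                    4**refine, drift,
                )
            break
    else:
        raise IntegrationError(
            f"electronic norm drifted by {drift:.2e} in one nuclear step "
            "despite substep refinement"
        )
    # restore the exact global phase of the mean-energy gauge
    phase = -(eref0 * dt_nuclear + 0.5 * deref * dt_nuclear**2) / HBAR_EV_FS
    a = a * complex(math.cos(phase), math.sin(phase))
    if active is not None:
        return a, hazard
    return a


def hop_probability(
    amplitudes: np.ndarray, sigma: np.ndarray, active: int, dt: float
) -> np.ndarray:
    """Fewest-switches hop probabilities out of the active state.

    g_m = max(0, 2 dt sigma_km Re(a_k^* a_m) / |a_k|^2) with k the active
    state (Hammes-Schiffer/Tully with the TDNC replacing F.v); negative
    entries are clipped to zero and the vector is rescaled if its sum
    exceeds one.  A depleted active amplitude (|a_k|^2 < 1e-12) yields all
    zeros with a warning.
    """
    pop = float(np.abs(amplitudes[active]) ** 2)
    g = np.zeros(len(amplitudes))
    if pop < 1e-12:
        logger.warning("hop_probability: active-state population depleted; no hops")
        return g
    flux = 2.0 * dt * sigma[active] * np.real(np.conj(amplitudes[active]) * amplitudes)
    g = np.maximum(flux / pop, 0.0)
    g[active] = 0.0
    total = g.sum()
    if total > 1.0:
        g /= total
    return g


def apply_decoherence(
    amplitudes: np.ndarray,
    energies: np.ndarray,
    kinetic: float,
    active: int,
    dt: float,
    alpha_ev: float,
) -> np.ndarray:
    """Energy-based decoherence damping of inactive amplitudes.

    Inactive state m decays as exp(-dt/tau_m) with
    tau_m = hbar/|E_m - E_active| * (1 + alpha/E_kin); the active amplitude
    is rescaled to restore unit norm.  Zero kinetic energy means infinite
    lifetimes (no damping).
    """
    if kinetic < 0:
        raise ValueError("kinetic energy must be >= 0")
    a = amplitudes.astype(complex).copy()
    if kinetic == 0.0:
        logger.info("apply_decoherence: zero kinetic energy, no damping applied")
        return a
    for m in range(len(a)):
        if m == active:
            continue
        gap = abs(energies[m] - energies[active])
        if gap == 0.0:
            continue  # tau -> infinity
        tau = HBAR_EV_FS / gap * (1.0 + alpha_ev / kinetic)
        a[m] *= math.exp(-dt / tau)
    inactive_pop = float(np.sum(np.abs(np.delete(a, active)) ** 2))
    active_pop = float(np.abs(a[active]) ** 2)
    if active_pop > 0.0:
        a[active] *= math.sqrt(max(0.0, 1.0 - inactive_pop) / active_pop)
    return a


def attempt_hop(
    state: TrajectoryState,
    model: ModelHamiltonian,
    probabilities: np.ndarray,
    draw: float,
) -> tuple[TrajectoryState, HopEvent | None, bool]:
    """Stochastic hop attempt with uniform velocity rescaling.

    The uniform draw selects the target state from the cumulative hop
    probabilities.  An accepted hop rescales the velocities along the
    velocity direction so total energy is conserved; if the kinetic energy
    cannot pay for an upward hop the attempt is frustrated (active state and
    velocities unchanged).  Returns (state, hop event or None, frustrated).
    """
    cum = np.cumsum(probabilities)
    if cum[-1] <= 0.0 or draw >= cum[-1]:
        return state, None, False
    target = int(np.searchsorted(cum, draw, side="right"))
    if target == state.active:
        return state, None, False
    ekin = kinetic_energy(state.velocities, model.masses)
    de = state.electronic.energies[target] - state.electronic.energies[state.active]
    if ekin + 1e-15 < de:
        return state, None, True  # frustrated
    scale = math.sqrt(max(0.0, 1.0 - de / ekin)) if ekin > 0 else 0.0
    new_state = replace(
        state, velocities=state.velocities * scale, active=target
    )
    event = HopEvent(
        time=state.time,
        from_state=state.active,
        to_state=target,
        coords=state.coords.copy(),
        draw=draw,
    )
    return new_state, event, False


@dataclass(frozen=True)
class TerminationStatus:
    terminated: bool
    reason: str | None = None
    crossing_time: float | None = None


def check_termination(state: TrajectoryState, settings: RunSettings) -> TerminationStatus:
    """Gap-based and time-based stop criteria.

    While the trajectory runs on S1 (index 1) and the S1/S0 gap drops below
    ``gap_stop`` the run is terminated with reason "s1s0_gap" and the
    current time recorded as the estimated crossing time; any trajectory
    stops with reason "t_max" at ``t_max``.
    """
    e = state.electronic.energies
    if state.active == 1 and len(e) >= 2 and (e[1] - e[0]) < settings.gap_stop:
        return TerminationStatus(True, "s1s0_gap", state.time)
    if state.time >= settings.t_max - 1e-9:
        return TerminationStatus(True, "t_max", None)
    return TerminationStatus(False)


def _coupling_matrix(
    rot_t: np.ndarray, rot_next: np.ndarray, dt: float, couple_ground: bool
) -> np.ndarray:
    """Antisymmetrized TDNC matrix from eigenvector overlaps (midpoint value)."""
    w = rot_t.T @ rot_next
    sigma = (w - w.T) / (2.0 * dt)
    if not couple_ground:
        sigma[0, :] = 0.0
        sigma[:, 0] = 0.0
    return sigma


def run_trajectory(
    model: ModelHamiltonian,
    coords: np.ndarray,
    velocities: np.ndarray,
    settings: RunSettings,
    rng: np.random.Generator,
    seed_index: int = 0,
) -> TrajectoryResult:
    """Propagate a single surface-hopping trajectory.

    Starts on ``settings.initial_state`` with all electronic population on
    it.  Records per-step active state, adiabatic energies, populations and
    coordinates; hop events; frustrated-hop count; and the termination
    reason with the S1/S0 crossing-time estimate when applicable.
    """
    n_states = model.n_states
    dt = settings.dt_nuclear
    amps = np.zeros(n_states, dtype=complex)
    amps[settings.initial_state] = 1.0
    ep = evaluate_adiabatic(model, coords)
    state = TrajectoryState(
        time=0.0,
        coords=np.asarray(coords, dtype=float).copy(),
        velocities=np.asarray(velocities, dtype=float).copy(),
        amplitudes=amps,
        active=settings.initial_state,
        electronic=ep,
        rng=rng,
    )
    n_steps = int(round(settings.t_max / dt))
    times = [0.0]
    actives = [state.active]
    energies = [ep.energies.copy()]
    pops = [np.abs(amps) ** 2]
    coords_log = [state.coords.copy()]
    hops: list[HopEvent] = []
    n_frustrated = 0
    sigma_prev: np.ndarray | None = None
    termination = "t_max"
    crossing_time = None

    status = check_termination(state, settings)
    if status.terminated and status.reason == "s1s0_gap":
        termination, crossing_time = status.reason, status.crossing_time
        n_steps = 0

    for _ in range(n_steps):
        prev_ep = state.electronic
        state = nuclear_step(state, model, dt)
        sigma_now = _coupling_matrix(
            prev_ep.rotation, state.electronic.rotation, dt, settings.couple_ground
        )
        if sigma_prev is None:
            sigma_prev = sigma_now
        # sigma_now is the midpoint value of the step; reconstruct end-point
        # values of the linear interpolant through the two midpoints
        sigma_start = 0.5 * (sigma_prev + sigma_now)
        sigma_end = 1.5 * sigma_now - 0.5 * sigma_prev
        new_amps, hazard = electronic_step(
            state.amplitudes,
            prev_ep.energies,
            state.electronic.energies,
            sigma_start,
            sigma_end,
            dt,
            settings.dt_electronic,
            active=state.active,
        )
        state = replace(state, amplitudes=new_amps)
        g = np.maximum(hazard, 0.0)
        g[state.active] = 0.0
        if g.sum() > 1.0:
            g /= g.sum()
        draw = float(state.rng.uniform())
        state, event, frustrated = attempt_hop(state, model, g, draw)
        if event is not None:
            hops.append(event)
        if frustrated:
            n_frustrated += 1
        if settings.alpha_ev is not None:
            ekin = kinetic_energy(state.velocities, model.masses)
            state = replace(
                state,
                amplitudes=apply_decoherence(
                    state.amplitudes,
                    state.electronic.energies,
                    ekin,
                    state.active,
                    dt,
                    settings.alpha_ev,
                ),
            )
        sigma_prev = sigma_now
        times.append(state.time)
        actives.append(state.active)
        energies.append(state.electronic.energies.copy())
        pops.append(np.abs(state.amplitudes) ** 2)
        coords_log.append(state.coords.copy())
        status = check_termination(state, settings)
        if status.terminated:
            if status.reason == "s1s0_gap":
                termination = "s1s0_gap"
                crossing_time = status.crossing_time
            else:
                termination = "t_max"
            break

    return TrajectoryResult(
        times=np.array(times),
        active=np.array(actives, dtype=int),
        energies=np.array(energies),
        populations=np.array(pops),
        coords=np.array(coords_log),
        hops=hops,
        n_frustrated=n_frustrated,
        termination=termination,
        crossing_time=crossing_time,
        seed_index=seed_index,
    )


def run_ensemble(
    model: ModelHamiltonian,
    initial_conditions,
    settings: RunSettings,
) -> EnsembleResult:
    """Propagate an ensemble of independent trajectories.

    ``initial_conditions`` is a sequence of (coords, velocities) pairs.
    Per-trajectory generators are spawned deterministically from the master
    seed with the trajectory index as spawn key, so results are reproducible
    bit for bit under a fixed seed regardless of ordering.  Individual
    trajectory failures are quarantined and reported, not fatal.
    """
    trajectories = []
    failures = []
    for k, (coords, velocities) in enumerate(initial_conditions):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=settings.seed, spawn_key=(k,))
        )
        try:
            trajectories.append(
                run_trajectory(model, coords, velocities, settings, rng, seed_index=k)
            )
        except (IntegrationError, FloatingPointError, ValueError) as exc:
            logger.warning("trajectory %d failed: %s", k, exc)
            failures.append({"index": k, "error": str(exc)})
    return EnsembleResult(
        trajectories=trajectories,
        failures=failures,
        settings=settings,
        n_states=model.n_states,
    )
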