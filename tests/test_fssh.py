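"""Surface-hopping engine: nuclear and electronic integrators, hop logic,
decoherence, termination and ensemble behavior."""

import math

import numpy as np
import pytest

from surfhop import fssh, models
from surfhop.constants import EV_TO_AMU_AA_FS, HBAR_EV_FS


def _flat_model(n_states=2, energies=(0.0, 1.0)):
    e = np.array(energies[:n_states])

    def diabatic(x):
        return np.diag(e)

    def gradient(x):
        return np.zeros((1, n_states, n_states))

    return models.ModelHamiltonian(
        name="flat", n_states=n_states, n_coords=1,
        diabatic=diabatic, diabatic_gradient=gradient,
        masses=[12.0], labels=tuple("s" * n_states),
    )


def _harmonic_model(k=1.0, n_states=1):
    def diabatic(x):
        x0 = float(np.atleast_1d(x)[0])
        return np.array([[0.5 * k * x0**2]])

    def gradient(x):
        x0 = float(np.atleast_1d(x)[0])
        return np.array([[[k * x0]]])

    return models.ModelHamiltonian(
        name="harm", n_states=1, n_coords=1,
        diabatic=diabatic, diabatic_gradient=gradient,
        masses=[12.0], labels=("s0",),
    )


def _make_state(model, coords, velocities, active=0, amps=None):
    ep = models.evaluate_adiabatic(model, coords)
    n = model.n_states
    if amps is None:
        amps = np.zeros(n, dtype=complex)
        amps[active] = 1.0
    return fssh.TrajectoryState(
        time=0.0, coords=np.array(coords, dtype=float),
        velocities=np.array(velocities, dtype=float),
        amplitudes=np.asarray(amps, dtype=complex), active=active,
        electronic=ep, rng=np.random.default_rng(0),
    )


class TestNuclearStep:
    def test_zero_force_free_flight(self):
        m = _flat_model()
        s = _make_state(m, [0.0], [0.3])
        s2 = fssh.nuclear_step(s, m, 0.5)
        assert s2.coords[0] == pytest.approx(0.15, abs=1e-15)
        assert s2.velocities[0] == pytest.approx(0.3, abs=1e-15)

    def test_harmonic_energy_drift_small(self):
        """Secular total-energy drift below 1e-6 of the initial energy over
        1e4 velocity-Verlet steps at 0.5 fs."""
        m = _harmonic_model(k=1.0)
        s = _make_state(m, [0.4], [0.0])
        energies = []
        times = []
        for step in range(10000):
            e_pot = s.electronic.energies[0]
            e_kin = fssh.kinetic_energy(s.velocities, m.masses)
            energies.append(e_pot + e_kin)
            times.append(s.time)
            s = fssh.nuclear_step(s, m, 0.5)
        energies = np.array(energies)
        slope = np.polyfit(times, energies, 1)[0]  # eV/fs
        drift = abs(slope) * (times[-1] - times[0])
        assert drift < 1e-6 * energies[0]

    def test_harmonic_period_matches_closed_form(self):
        k, mass = 1.0, 12.0
        m = _harmonic_model(k=k)
        omega = math.sqrt(k * EV_TO_AMU_AA_FS / mass)
        period = 2 * math.pi / omega
        s = _make_state(m, [0.3], [0.0])
        crossings = []
        prev_x = s.coords[0]
        while len(crossings) < 21 and s.time < 40 * period:
            s = fssh.nuclear_step(s, m, 0.5)
            if prev_x > 0 >= s.coords[0]:
                # linear interpolation of the downward zero crossing
                frac = prev_x / (prev_x - s.coords[0])
                crossings.append(s.time - 0.5 + frac * 0.5)
            prev_x = s.coords[0]
        measured = (crossings[20] - crossings[0]) / 20.0
        assert measured == pytest.approx(period, rel=1e-3)

    def test_nonfinite_force_aborts(self):
        def diabatic(x):
            return np.array([[float(np.atleast_1d(x)[0])]])

        m = models.ModelHamiltonian(
            name="badgrad", n_states=1, n_coords=1, diabatic=diabatic,
            diabatic_gradient=lambda x: np.array([[[np.inf]]]),
            masses=[1.0], labels=("s",),
        )
        s = _make_state(m, [0.0], [0.0])
        with pytest.raises(fssh.IntegrationError, match="non-finite force"):
            fssh.nuclear_step(s, m, 0.5)


class TestElectronicStep:
    def test_zero_coupling_pure_phases(self):
        e = np.array([0.0, 2.0])
        amps = np.array([math.sqrt(0.5), math.sqrt(0.5)], dtype=complex)
        sigma = np.zeros((2, 2))
        out = fssh.electronic_step(amps, e, e, sigma, sigma, 0.5, 0.025)
        expected = amps * np.exp(-1j * e * 0.5 / HBAR_EV_FS)
        np.testing.assert_allclose(out, expected, atol=1e-8)
        np.testing.assert_allclose(np.abs(out) ** 2, np.abs(amps) ** 2, atol=1e-12)

    def test_constant_coupling_rabi_rotation(self):
        """Degenerate energies and constant sigma give the closed-form
        rotation exp(-sigma*t) of the amplitude vector."""
        sigma12 = 0.08  # 1/fs
        sigma = np.array([[0.0, sigma12], [-sigma12, 0.0]])
        e = np.zeros(2)
        amps = np.array([1.0, 0.0], dtype=complex)
        t_total = 10.0
        out = amps
        for _ in range(int(t_total / 0.5)):
            out = fssh.electronic_step(out, e, e, sigma, sigma, 0.5, 0.025)
        angle = sigma12 * t_total
        expected = np.array([math.cos(angle), math.sin(angle)], dtype=complex)
        np.testing.assert_allclose(out, expected, atol=1e-8)

    def test_fifth_order_self_convergence(self):
        rng = np.random.default_rng(5)
        e0 = rng.uniform(0, 2, 3)
        e1 = e0 + rng.uniform(-0.1, 0.1, 3)
        a = rng.standard_normal((3, 3))
        s0 = (a - a.T) * 0.05
        s1 = s0 * 1.2
        amps = np.array([0.8, 0.6j, 0.0], dtype=complex)
        coarse = fssh.electronic_step(amps, e0, e1, s0, s1, 0.5, 0.025)
        fine = fssh.electronic_step(amps, e0, e1, s0, s1, 0.5, 0.0125)
        finest = fssh.electronic_step(amps, e0, e1, s0, s1, 0.5, 0.00625)
        d1 = np.max(np.abs(coarse - fine))
        d2 = np.max(np.abs(fine - finest))
        assert d1 < 1e-9
        # global 5th-order: halving the substep shrinks the change ~32x
        assert d1 / max(d2, 1e-16) > 16.0

    def test_norm_conserved_each_step(self):
        """Per-nuclear-step norm drift below 1e-8 (the production loop
        restores unit norm each step through the decoherence rescaling)."""
        rng = np.random.default_rng(6)
        e = rng.uniform(0, 5, 3)
        a = rng.standard_normal((3, 3))
        sigma = (a - a.T) * 0.1
        amps = np.array([0.6, 0.48 + 0.36j, 0.4 - 0.34j], dtype=complex)
        amps /= np.linalg.norm(amps)
        for _ in range(200):
            norm_in = np.vdot(amps, amps).real
            amps = fssh.electronic_step(amps, e, e, sigma, sigma, 0.5, 0.025)
            assert abs(np.vdot(amps, amps).real - norm_in) < 1e-8
            amps /= np.linalg.norm(amps)


class TestHopProbability:
    def test_zero_coupling_zero_probability(self):
        amps = np.array([0.8, 0.6], dtype=complex)
        g = fssh.hop_probability(amps, np.zeros((2, 2)), 0, 0.5)
        np.testing.assert_array_equal(g, 0.0)

    def test_all_population_on_active_zero_probability(self):
        amps = np.array([1.0, 0.0], dtype=complex)
        sigma = np.array([[0.0, 0.3], [-0.3, 0.0]])
        g = fssh.hop_probability(amps, sigma, 0, 0.5)
        np.testing.assert_allclose(g, 0.0, atol=1e-15)

    def test_hand_evaluation_of_formula(self):
        amps = np.array([0.8, 0.6j], dtype=complex)
        s12 = 0.01
        sigma = np.array([[0.0, s12], [-s12, 0.0]])
        dt = 0.5
        g = fssh.hop_probability(amps, sigma, 0, dt)
        expected = max(
            0.0, 2 * dt * s12 * np.real(np.conj(amps[0]) * amps[1])
        ) / abs(amps[0]) ** 2
        assert g[1] == pytest.approx(expected, abs=1e-15)
        assert g[0] == 0.0

    def test_depleted_active_state_gives_zeros(self):
        amps = np.array([1e-9, 1.0], dtype=complex)
        sigma = np.array([[0.0, 1.0], [-1.0, 0.0]])
        g = fssh.hop_probability(amps, sigma, 0, 0.5)
        np.testing.assert_array_equal(g, 0.0)


class TestDecoherence:
    def test_all_population_on_active_unchanged(self):
        amps = np.array([1.0, 0.0], dtype=complex)
        out = fssh.apply_decoherence(amps, np.array([0.0, 1.0]), 0.5, 0, 0.5, 2.72)
        np.testing.assert_allclose(out, amps, atol=1e-15)

    def test_degenerate_state_undamped(self):
        amps = np.array([math.sqrt(0.5), math.sqrt(0.5)], dtype=complex)
        out = fssh.apply_decoherence(amps, np.array([1.0, 1.0]), 0.5, 0, 0.5, 2.72)
        np.testing.assert_allclose(out, amps, atol=1e-15)

    def test_hand_evaluation(self):
        """Direct evaluation of the damping formula for a 50/50 state,
        1 eV gap, 1 eV kinetic energy, alpha = 0.1 Hartree, dt = 0.5 fs."""
        from surfhop.constants import HARTREE_TO_EV

        alpha_ev = 0.1 * HARTREE_TO_EV
        amps = np.array([math.sqrt(0.5), math.sqrt(0.5)], dtype=complex)
        energies = np.array([0.0, 1.0])
        ekin, dt = 1.0, 0.5
        out = fssh.apply_decoherence(amps, energies, ekin, 0, dt, alpha_ev)
        tau = HBAR_EV_FS / 1.0 * (1.0 + alpha_ev / ekin)
        a1 = math.sqrt(0.5) * math.exp(-dt / tau)
        a0 = math.sqrt(1.0 - a1**2)
        assert abs(out[1] - a1) < 1e-12
        assert abs(out[0] - a0) < 1e-12
        assert np.vdot(out, out).real == pytest.approx(1.0, abs=1e-12)

    def test_zero_kinetic_energy_no_damping(self):
        amps = np.array([0.8, 0.6], dtype=complex)
        out = fssh.apply_decoherence(amps, np.array([0.0, 1.0]), 0.0, 0, 0.5, 2.72)
        np.testing.assert_allclose(out, amps, atol=1e-15)


class TestAttemptHop:
    def test_draw_above_total_probability_no_hop(self):
        m = _flat_model()
        s = _make_state(m, [0.0], [0.1])
        g = np.array([0.0, 0.2])
        out, event, frustrated = fssh.attempt_hop(s, m, g, 0.9)
        assert out.active == 0 and event is None and not frustrated

    def test_upward_hop_without_kinetic_energy_frustrated(self):
        m = _flat_model(energies=(0.0, 5.0))
        s = _make_state(m, [0.0], [0.01])  # tiny kinetic energy
        g = np.array([0.0, 1.0])
        out, event, frustrated = fssh.attempt_hop(s, m, g, 0.1)
        assert frustrated and out.active == 0
        np.testing.assert_array_equal(out.velocities, s.velocities)

    def test_downward_hop_conserves_total_energy(self):
        m = _flat_model(energies=(0.0, 1.0))
        s = _make_state(m, [0.0], [0.05], active=1)
        e_tot_before = (
            s.electronic.energies[1] + fssh.kinetic_energy(s.velocities, m.masses)
        )
        g = np.array([1.0, 0.0])
        out, event, frustrated = fssh.attempt_hop(s, m, g, 0.1)
        assert out.active == 0 and event is not None and not frustrated
        e_tot_after = (
            out.electronic.energies[0] + fssh.kinetic_energy(out.velocities, m.masses)
        )
        assert e_tot_after == pytest.approx(e_tot_before, abs=1e-10)
        assert event.from_state == 1 and event.to_state == 0


class TestTermination:
    def _gap_model(self, gap):
        return _flat_model(n_states=2, energies=(0.0, gap))

    def test_small_gap_terminates_with_crossing_time(self):
        m = self._gap_model(0.10)
        s = _make_state(m, [0.0], [0.0], active=1)
        s.time = 123.5
        status = fssh.check_termination(s, fssh.RunSettings())
        assert status.terminated and status.reason == "s1s0_gap"
        assert status.crossing_time == 123.5

    def test_large_gap_continues(self):
        m = self._gap_model(0.20)
        s = _make_state(m, [0.0], [0.0], active=1)
        assert not fssh.check_termination(s, fssh.RunSettings()).terminated

    def test_t_max_reached(self):
        m = self._gap_model(1.0)
        s = _make_state(m, [0.0], [0.0], active=0)
        s.time = 1000.0
        status = fssh.check_termination(s, fssh.RunSettings())
        assert status.terminated and status.reason == "t_max"

    def test_raising_threshold_shortens_crossing_times(self, thymine_model):
        """Doubling the S1/S0 stop gap from 0.15 to 0.30 eV can only shorten
        each trajectory's crossing-time estimate."""
        from surfhop import initcond, protocol

        modes = protocol.ground_state_modes(thymine_model)
        rng = np.random.default_rng(11)
        samples = initcond.wigner_sample(modes, 12, rng)
        crossing = {}
        for gap in (0.15, 0.30):
            settings = fssh.RunSettings(
                couple_ground=False, initial_state=2, seed=4, t_max=400.0, gap_stop=gap
            )
            ens = fssh.run_ensemble(
                thymine_model,
                [(c, p / thymine_model.masses) for c, p in samples],
                settings,
            )
            crossing[gap] = [
                t.crossing_time for t in ens.trajectories if t.crossing_time is not None
            ]
        assert len(crossing[0.30]) >= len(crossing[0.15])
        assert np.mean(crossing[0.30]) <= np.mean(crossing[0.15])


class TestEnsemble:
    def test_same_seed_identical_occupations(self, thymine_model):
        from surfhop import kinetics

        ics = [(np.array([-0.1, 0.05]), np.array([0.01, -0.005]))] * 4
        settings = fssh.RunSettings(couple_ground=False, initial_state=2, seed=7, t_max=100.0)
        occ = []
        for _ in range(2):
            ens = fssh.run_ensemble(thymine_model, ics, settings)
            occ.append(kinetics.aggregate_occupations(ens).fractions)
        np.testing.assert_array_equal(occ[0], occ[1])

    def test_single_state_model_never_hops(self):
        m = _harmonic_model()
        settings = fssh.RunSettings(seed=1, t_max=50.0, initial_state=0)
        ens = fssh.run_ensemble(m, [([0.3], [0.0]), ([0.1], [0.02])], settings)
        for traj in ens.trajectories:
            assert not traj.hops
            assert traj.termination == "t_max"

    def test_zero_coupling_population_stays_put(self):
        """With no diabatic coupling anywhere the initial state keeps exactly
        unit population."""
        m = models.build_single_crossing(coupling=0.0)
        settings = fssh.RunSettings(seed=2, t_max=100.0, initial_state=1,
                                    decoherence_alpha=None)
        ens = fssh.run_ensemble(m, [([-1.0], [0.02])], settings)
        traj = ens.trajectories[0]
        assert not traj.hops
        np.testing.assert_allclose(traj.populations[:, 1], 1.0, atol=1e-10)

    def test_failures_are_quarantined(self):
        def diabatic(x):
            x0 = float(np.atleast_1d(x)[0])
            if abs(x0) > 0.5:
                return np.array([[np.nan]])
            return np.array([[0.0]])

        m = models.ModelHamiltonian(
            name="exploding", n_states=1, n_coords=1, diabatic=diabatic,
            masses=[1.0], labels=("s",),
        )
        settings = fssh.RunSettings(seed=3, t_max=50.0, initial_state=0)
        ens = fssh.run_ensemble(m, [([0.0], [0.1]), ([0.0], [0.0])], settings)
        assert len(ens.failures) == 1
        assert len(ens.trajectories) == 1

    def test_single_surface_total_energy_drift(self, thymine_model):
        """Propagation pinned to one surface of thymine3s conserves total
        energy to better than 1e-5 eV/ps."""
        settings = fssh.RunSettings(seed=1, t_max=1000.0, initial_state=0,
                                    decoherence_alpha=None, couple_ground=False)
        ep = models.evaluate_adiabatic(thymine_model, [-0.1, 0.1])
        s = fssh.TrajectoryState(
            time=0.0, coords=np.array([-0.1, 0.1]), velocities=np.zeros(2),
            amplitudes=np.array([1.0, 0.0, 0.0], dtype=complex), active=0,
            electronic=ep, rng=np.random.default_rng(0),
        )
        times, energies = [], []
        for _ in range(2000):
            times.append(s.time)
            energies.append(
                s.electronic.energies[0]
                + fssh.kinetic_energy(s.velocities, thymine_model.masses)
            )
            s = fssh.nuclear_step(s, thymine_model, 0.5)
        slope = np.polyfit(times, energies, 1)[0]  # eV/fs
        assert abs(slope) * 1000.0 < 1e-5  # eV per ps


class TestInternalConsistency:
    def test_active_fractions_track_populations(self, single_crossing_model):
        """After a single passage through the avoided crossing, the ensemble
        fraction on each surface agrees with the mean quantum populations to
        within 5 percentage points (500 trajectories, production decoherence
        setting).  The surviving-population check against the Landau-Zener
        estimate guards against the agreement being vacuous."""
        m = single_crossing_model
        settings = fssh.RunSettings(
            seed=42, t_max=150.0, initial_state=0,
            gap_stop=0.0,  # no S1/S0 stop on this generic two-state model
        )
        v0 = math.sqrt(2 * 1.0 * EV_TO_AMU_AA_FS / 12.0)  # 1 eV of kinetic energy
        ics = [(np.array([-2.5]), np.array([v0]))] * 500
        ens = fssh.run_ensemble(m, ics, settings)
        assert not ens.failures
        final_active = np.array([t.active[-1] for t in ens.trajectories])
        frac_upper = float(np.mean(final_active == 1))
        pop_upper = float(np.mean([t.populations[-1, 1] for t in ens.trajectories]))
        assert 0.02 < pop_upper < 0.98  # the crossing actually mixes
        assert abs(frac_upper - pop_upper) < 0.05
        # Landau-Zener diabatic-passage estimate for this crossing is ~0.74;
        # the hopping fraction should land in its neighborhood
        assert 0.6 < frac_upper < 0.9
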