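"""Deterministic fixture generators.

Three generators, addressable by name through :func:`make_fixture`:

* ``random_cis`` - seeded random orthonormal orbital pairs plus CIS states
  connected by a small orthogonal rotation, the workhorse instances for
  OD/DD coupling comparisons;
* ``synthetic_occupations`` - closed-form occupation curves of the
  sequential kinetic model, optionally with per-trajectory binomial
  sampling noise;
* ``ring_conformers`` - ideal XYZ geometries of the 38 canonical Boeyens
  conformers plus the planar ring.

The same spec and seed always produce identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from . import tdnc
from .kinetics import sequential_model_curves

__all__ = ["FixtureSpec", "make_fixture", "random_cis_pair", "sample_hop_times"]


@dataclass(frozen=True)
class FixtureSpec:
    generator: str
    parameters: dict = field(default_factory=dict)
    seed: int = 0


def random_cis_pair(
    rng: np.random.Generator,
    n_occ: int,
    n_virt: int,
    rotation_magnitude: float = 1e-3,
    state_rotation: float | None = None,
):
    """A pair of consecutive-step CIS snapshots.

    Orbitals at t are a random orthonormal set; orbitals at t+dt are rotated
    by exp(A) with ||A|| = rotation_magnitude.  Two Frobenius-orthonormal CI
    states at t are rotated among themselves by ``state_rotation`` (drawn at
    the same magnitude when None) to produce the t+dt states.  Requires
    n_occ*n_virt >= 2 so that two independent CIS states exist.

    Returns (orbitals_t, orbitals_next, states_t, states_next).
    """
    if n_occ * n_virt < 2:
        raise ValueError("need n_occ * n_virt >= 2 for two CIS states")
    n_orb = n_occ + n_virt
    q, _ = np.linalg.qr(rng.standard_normal((n_orb, n_orb)))
    a = rng.standard_normal((n_orb, n_orb))
    a = (a - a.T) / 2.0
    a *= rotation_magnitude / max(np.linalg.norm(a), 1e-300)
    q_next = q @ expm(a)
    orbitals_t = tdnc.OrbitalSet(q, n_occ, n_virt)
    orbitals_next = tdnc.OrbitalSet(q_next, n_occ, n_virt)

    c1 = rng.standard_normal((n_occ, n_virt))
    c1 /= np.linalg.norm(c1)
    c2 = rng.standard_normal((n_occ, n_virt))
    c2 -= np.sum(c2 * c1) * c1
    c2 /= np.linalg.norm(c2)
    delta = state_rotation if state_rotation is not None else rotation_magnitude * rng.standard_normal()
    c1n = math.cos(delta) * c1 + math.sin(delta) * c2
    c2n = -math.sin(delta) * c1 + math.cos(delta) * c2
    states_t = [tdnc.CISState(c1, 0), tdnc.CISState(c2, 1)]
    states_next = [
        tdnc.CISState(c1n / np.linalg.norm(c1n), 0),
        tdnc.CISState(c2n / np.linalg.norm(c2n), 1),
    ]
    return orbitals_t, orbitals_next, states_t, states_next


def sample_hop_times(
    rng: np.random.Generator,
    n_traj: int,
    f21: float,
    tau21: float,
    f10: float,
    tau10: float,
):
    """Per-trajectory (S2->S1 time, S1->S0 time) samples from the sequential
    model; trapped channels are represented by infinite times."""
    t21 = np.where(
        rng.uniform(size=n_traj) < f21,
        rng.exponential(tau21, size=n_traj),
        np.inf,
    )
    t10 = np.where(
        rng.uniform(size=n_traj) < f10,
        t21 + rng.exponential(tau10, size=n_traj),
        np.inf,
    )
    return t21, t10


def _synthetic_occupations(params: dict, seed: int):
    f21 = params.get("f21", 0.84)
    tau21 = params.get("tau21", 253.0)
    f10 = params.get("f10", 0.70)
    tau10 = params.get("tau10", 391.0)
    t_max = params.get("t_max", 1000.0)
    dt = params.get("dt", 0.5)
    n_traj = params.get("n_traj", 0)
    times = np.arange(0.0, t_max + dt / 2, dt)
    if n_traj <= 0:
        fractions = sequential_model_curves(times, f21, tau21, f10, tau10)
    else:
        rng = np.random.default_rng(seed)
        t21, t10 = sample_hop_times(rng, n_traj, f21, tau21, f10, tau10)
        fractions = np.empty((len(times), 3))
        for k, t in enumerate(times):
            in_s0 = np.sum(t10 <= t)
            in_s1 = np.sum((t21 <= t) & (t10 > t))
            fractions[k] = [in_s0 / n_traj, in_s1 / n_traj, 1.0 - (in_s0 + in_s1) / n_traj]
    return times, fractions


def make_fixture(spec: FixtureSpec, outdir=None):
    """Generate a named fixture, optionally writing files under ``outdir``.

    Returns the in-memory fixture; when ``outdir`` is given the files
    written are deterministic for a given spec and seed.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.generator == "random_cis":
        p = spec.parameters
        n = p.get("n_instances", 1)
        instances = [
            random_cis_pair(
                rng,
                p.get("n_occ", 3),
                p.get("n_virt", 3),
                p.get("rotation_magnitude", 1e-3),
            )
            for _ in range(n)
        ]
        if outdir is not None:
            import os

            os.makedirs(outdir, exist_ok=True)
            for k, (ot, on, st, sn) in enumerate(instances):
                np.savetxt(f"{outdir}/orbitals_t_{k:03d}.txt", ot.coefficients)
                np.savetxt(f"{outdir}/orbitals_next_{k:03d}.txt", on.coefficients)
                for s in st:
                    np.savetxt(f"{outdir}/ci_t_{k:03d}_state{s.label}.txt", s.coefficients)
                for s in sn:
                    np.savetxt(f"{outdir}/ci_next_{k:03d}_state{s.label}.txt", s.coefficients)
        return instances
    if spec.generator == "synthetic_occupations":
        times, fractions = _synthetic_occupations(spec.parameters, spec.seed)
        if outdir is not None:
            import os

            os.makedirs(outdir, exist_ok=True)
            np.savetxt(
                f"{outdir}/occupations.csv",
                np.column_stack([times, fractions]),
                delimiter=",",
                header="time_fs,S0,S1,S2",
                comments="",
            )
        return times, fractions
    if spec.generator == "ring_conformers":
        from .pucker import PuckerParams, canonical_conformers, cremer_pople_inverse
        from .xyzio import Frame, write_xyz

        q = spec.parameters.get("Q", 0.5)
        radius = spec.parameters.get("base_radius", 1.39)
        geoms = {"planar": cremer_pople_inverse(PuckerParams(0.0, 0.0, 0.0, "planar"), radius)}
        for theta, phi, label in canonical_conformers():
            geoms[label] = cremer_pople_inverse(PuckerParams(q, theta, phi, label), radius)
        if outdir is not None:
            import os

            os.makedirs(outdir, exist_ok=True)
            for label, pos in geoms.items():
                safe = label.replace(",", "_")
                write_xyz(
                    Frame(elements=["C"] * 6, positions=pos, comment=label),
                    f"{outdir}/{safe}.xyz",
                )
        return geoms
    raise KeyError(f"unknown fixture generator '{spec.generator}'")
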