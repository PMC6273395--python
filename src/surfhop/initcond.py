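"""Initial conditions and nuclear-ensemble spectroscopy.

Harmonic-oscillator Wigner sampling of the vibrational ground state gives
uncorrelated Gaussian coordinates and momenta per normal mode, with
variances sigma_q^2 = hbar/(2 mu omega) and sigma_p^2 = hbar mu omega / 2
(minimum-uncertainty product).  The nuclear-ensemble absorption spectrum is
the oscillator-strength-weighted sum of Gaussian lines at the vertical
excitation energies of the sampled geometries; initial conditions for
dynamics are filtered from an excitation-energy window around the band
maximum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .constants import HBAR_AMU_AA_FS, wavenumber_to_angular_fs

logger = logging.getLogger(__name__)

__all__ = [
    "NormalModeSet",
    "InitialCondition",
    "SpectrumCurve",
    "wigner_sample",
    "nea_spectrum",
    "filter_energy_window",
    "normal_modes_from_hessian",
]


@dataclass(frozen=True)
class NormalModeSet:
    """Ground-state normal modes for Wigner sampling.

    frequencies in cm^-1 (> 0 for sampled modes), reduced masses in amu,
    displacement vectors as rows (mode, coordinate) in the same coordinate
    space as ``equilibrium`` (Angstrom).
    """

    frequencies: np.ndarray
    reduced_masses: np.ndarray
    displacements: np.ndarray
    equilibrium: np.ndarray
    coord_masses: np.ndarray | None = None  # per-coordinate masses (amu)

    def __post_init__(self):
        freq = np.asarray(self.frequencies, dtype=float)
        for name, arr in (
            ("frequencies", freq),
            ("reduced_masses", np.asarray(self.reduced_masses, dtype=float)),
        ):
            if arr.ndim != 1 or len(arr) != len(freq):
                raise ValueError(f"{name} must be 1D with one entry per mode")
        bad = np.nonzero(freq <= 0.0)[0]
        if bad.size:
            raise ValueError(
                f"mode {bad[0]} has non-positive frequency {freq[bad[0]]} cm^-1; "
                "only bound modes can be Wigner sampled"
            )


@dataclass(frozen=True)
class InitialCondition:
    """A sampled geometry with vertical excitation data."""

    coords: np.ndarray  # Angstrom
    momenta: np.ndarray  # amu * Angstrom / fs
    energies: np.ndarray  # per-state vertical excitation energy, eV
    oscillator_strengths: np.ndarray
    selected_state: int | None = None

    def __post_init__(self):
        if np.any(np.asarray(self.oscillator_strengths) < 0):
            raise ValueError("oscillator strengths must be >= 0")


@dataclass(frozen=True)
class SpectrumCurve:
    energy_ev: np.ndarray
    intensity: np.ndarray
    width_ev: float

    @property
    def band_maximum_ev(self) -> float:
        return float(self.energy_ev[int(np.argmax(self.intensity))])


def wigner_sample(
    modes: NormalModeSet, n: int, seed: int | np.random.Generator = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Draw n (coords, momenta) pairs from the ground-state Wigner function.

    Per mode, the coordinate and momentum are independent Gaussians with
    sigma_q = sqrt(hbar/(2 mu omega)) and sigma_p = sqrt(hbar mu omega/2);
    mode-space displacements are mapped to coordinates through the
    displacement vectors.  Momenta are returned in amu*Angstrom/fs.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    omega = np.array([wavenumber_to_angular_fs(f) for f in modes.frequencies])
    mu = np.asarray(modes.reduced_masses, dtype=float)
    sigma_q = np.sqrt(HBAR_AMU_AA_FS / (2.0 * mu * omega))
    sigma_p = np.sqrt(HBAR_AMU_AA_FS * mu * omega / 2.0)
    disp = np.asarray(modes.displacements, dtype=float)
    out = []
    for _ in range(n):
        q = rng.normal(0.0, sigma_q)
        p = rng.normal(0.0, sigma_p)
        coords = modes.equilibrium + q @ disp
        if modes.coord_masses is not None:
            # true cartesian momenta: pi_i = m_i * sum_k d_ki * (p_k / mu_k)
            momenta = ((p / mu) @ disp) * np.asarray(modes.coord_masses, dtype=float)
        else:
            momenta = p @ disp
        out.append((coords, momenta))
    return out


def nea_spectrum(
    ensemble,
    grid: np.ndarray,
    width: float = 0.05,
    normalize: bool = True,
) -> SpectrumCurve:
    """Nuclear-ensemble absorption spectrum.

    I(E) = (1/n) sum_points sum_states f * g(E - dE; width), with g a
    unit-area Gaussian of standard deviation ``width`` (eV).  With
    ``normalize`` the curve is scaled to unit band maximum (arbitrary
    units); without it the energy integral equals the ensemble-mean total
    oscillator strength, which is the sum rule used in testing.
    """
    ensemble = list(ensemble)
    if not ensemble:
        raise ValueError("empty ensemble")
    grid = np.asarray(grid, dtype=float)
    intensity = np.zeros_like(grid)
    norm = 1.0 / (width * np.sqrt(2.0 * np.pi))
    for point in ensemble:
        for de, f in zip(point.energies, point.oscillator_strengths):
            if f == 0.0:
                continue
            intensity += f * norm * np.exp(-0.5 * ((grid - de) / width) ** 2)
    intensity /= len(ensemble)
    if normalize and intensity.max() > 0:
        intensity = intensity / intensity.max()
    return SpectrumCurve(energy_ev=grid, intensity=intensity, width_ev=width)


def filter_energy_window(
    ensemble,
    center: float,
    half_width: float,
    target_state: int,
    f_weighted: bool = False,
    rng: np.random.Generator | None = None,
) -> list[InitialCondition]:
    """Keep initial conditions whose target-state vertical energy lies within
    center +- half_width (boundary inclusive).

    By default every qualifying point is kept with its ``selected_state``
    set; with ``f_weighted`` the qualifying points are resampled with
    probability proportional to oscillator strength (points with zero
    strength are then never selected).  An empty result triggers a warning.
    """
    selected = []
    for point in ensemble:
        de = point.energies[target_state]
        if abs(de - center) <= half_width:
            selected.append(
                InitialCondition(
                    coords=point.coords,
                    momenta=point.momenta,
                    energies=point.energies,
                    oscillator_strengths=point.oscillator_strengths,
                    selected_state=target_state,
                )
            )
    if f_weighted and selected:
        weights = np.array(
            [p.oscillator_strengths[target_state] for p in selected], dtype=float
        )
        if weights.sum() <= 0:
            logger.warning("filter_energy_window: all selected oscillator strengths zero")
            return []
        weights /= weights.sum()
        rng = rng or np.random.default_rng(0)
        keep = rng.choice(len(selected), size=len(selected), replace=True, p=weights)
        selected = [selected[k] for k in keep]
    if not selected:
        logger.warning(
            "filter_energy_window: no points within %.3f +- %.3f eV", center, half_width
        )
    return selected


def normal_modes_from_hessian(
    hessian: np.ndarray, masses: np.ndarray, equilibrium: np.ndarray
) -> NormalModeSet:
    """Normal modes of a (small) Hessian in eV/Angstrom^2 with masses in amu.

    Mass-weighted diagonalization; only modes with positive curvature are
    returned (imaginary frequencies are excluded with a log message).
    Displacement rows are the mass-unweighted Cartesian mode vectors,
    normalized so that a unit mode-space displacement moves the coordinates
    by the mass-weighted eigenvector scaled back by 1/sqrt(mass); the
    reduced mass per mode follows from that normalization.
    """
    from .constants import EV_TO_AMU_AA_FS, C_CM_FS

    h = np.asarray(hessian, dtype=float)
    m = np.asarray(masses, dtype=float)
    mw = h * EV_TO_AMU_AA_FS / np.sqrt(np.outer(m, m))  # amu-weighted, 1/fs^2
    w2, vecs = np.linalg.eigh(mw)
    keep = w2 > 1e-12
    if not np.all(keep):
        logger.info("normal_modes_from_hessian: dropping %d non-bound modes", (~keep).sum())
    w = np.sqrt(w2[keep])
    vecs = vecs[:, keep]
    wavenumbers = w / (2.0 * np.pi * C_CM_FS)
    # cartesian displacement of mode k: vecs[:,k]/sqrt(m); normalize rows and
    # fold the norm into the reduced mass
    disp = (vecs / np.sqrt(m)[:, None]).T  # (mode, coord)
    norms = np.linalg.norm(disp, axis=1)
    disp = disp / norms[:, None]
    mu = 1.0 / norms**2
    return NormalModeSet(
        frequencies=wavenumbers,
        reduced_masses=mu,
        displacements=disp,
        equilibrium=np.asarray(equilibrium, dtype=float),
        coord_masses=m,
    )
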