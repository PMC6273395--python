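"""Ensemble occupation statistics, sequential kinetic fitting, binomial
confidence half-widths, LIIC reaction paths and bond-distance series.

The kinetic model is a minimal sequential branching scheme: starting with
all population in S2, a fraction f decays to S1 with time constant tau21
(the remainder is trapped in S2); of the population arriving in S1, a
fraction g drains to the ground state with time constant tau10 (the
remainder is trapped in S1).  In closed form, with k1 = 1/tau21 and
k2 = 1/tau10,

    S2(t) = f exp(-k1 t) + (1 - f)
    S1(t) = (1-g) f (1 - exp(-k1 t)) + g f k1 (exp(-k1 t) - exp(-k2 t))/(k2 - k1)
    S0(t) = 1 - S2(t) - S1(t)

(the k1 = k2 limit is handled by the usual t*exp(-k t) form).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "OccupationSeries",
    "KineticFit",
    "PathSpec",
    "sequential_model_curves",
    "aggregate_occupations",
    "fit_sequential_model",
    "confidence_halfwidth",
    "liic_path",
    "bond_distance_series",
]


@dataclass
class OccupationSeries:
    """Per-state trajectory fractions on a common time grid.

    ``fractions`` has shape (n_times, n_states); terminated trajectories
    are pooled into state 0 from their crossing time onward, so the rows
    sum to one exactly.
    """

    times: np.ndarray
    fractions: np.ndarray
    n_trajectories: int


@dataclass
class KineticFit:
    f21: float
    tau21: float
    f10: float
    tau10: float
    residual_norm: float
    covariance: np.ndarray | None


@dataclass(frozen=True)
class PathSpec:
    """Endpoints and image count for a linearly interpolated path."""

    start: np.ndarray
    end: np.ndarray
    n_images: int
    coordinate_system: str = "internal"  # "internal" | "cartesian"

    def __post_init__(self):
        if self.n_images < 2:
            raise ValueError("a path needs at least 2 images")


def sequential_model_curves(
    times: np.ndarray, f21: float, tau21: float, f10: float, tau10: float
) -> np.ndarray:
    """Closed-form occupations (S0, S1, S2) of the sequential branching model."""
    t = np.asarray(times, dtype=float)
    k1 = 1.0 / tau21
    k2 = 1.0 / tau10
    e1 = np.exp(-k1 * t)
    s2 = f21 * e1 + (1.0 - f21)
    if abs(k1 - k2) < 1e-12 * max(k1, k2):
        transfer = f10 * f21 * k1 * t * e1
    else:
        transfer = f10 * f21 * k1 * (e1 - np.exp(-k2 * t)) / (k2 - k1)
    s1 = (1.0 - f10) * f21 * (1.0 - e1) + transfer
    s0 = 1.0 - s2 - s1
    return np.column_stack([s0, s1, s2])


def aggregate_occupations(ensemble, times: np.ndarray | None = None) -> OccupationSeries:
    """Fraction of trajectories in each state at every grid time.

    Trajectories terminated by the S1/S0 gap criterion count as
    ground-state population from their crossing time onward.  When no
    common grid is given, the grid of the longest trajectory is used and
    shorter logs are extended with their terminal pool; trajectories on
    inconsistent grids are regridded to the nearest recorded step with a
    warning.
    """
    trajs = getattr(ensemble, "trajectories", ensemble)
    if not trajs:
        raise ValueError("empty ensemble")
    n_states = max(int(t.active.max()) for t in trajs) + 1
    n_states = max(n_states, getattr(ensemble, "n_states", n_states))
    if times is None:
        times = max((t.times for t in trajs), key=len)
    times = np.asarray(times, dtype=float)
    counts = np.zeros((len(times), n_states))
    for traj in trajs:
        tt = traj.times
        dt = tt[1] - tt[0] if len(tt) > 1 else 1.0
        idx = np.clip(np.round((times - tt[0]) / dt).astype(int), 0, len(tt) - 1)
        if len(tt) > 1 and not np.allclose(
            tt, tt[0] + dt * np.arange(len(tt)), atol=1e-9
        ):
            logger.warning("aggregate_occupations: non-uniform grid, regridding")
            idx = np.searchsorted(tt, times, side="right") - 1
            idx = np.clip(idx, 0, len(tt) - 1)
        states = traj.active[idx]
        if traj.termination == "s1s0_gap" and traj.crossing_time is not None:
            states = np.where(times >= traj.crossing_time - 1e-9, 0, states)
        else:
            # past the end of a t_max trajectory the last state persists
            pass
        counts[np.arange(len(times)), states] += 1.0
    fractions = counts / len(trajs)
    return OccupationSeries(times=times, fractions=fractions, n_trajectories=len(trajs))


def fit_sequential_model(
    occ: OccupationSeries,
    p0: tuple[float, float, float, float] = (0.8, 200.0, 0.7, 400.0),
) -> KineticFit:
    """Least-squares fit of the sequential branching model to S2/S1/S0 pools.

    Fits (f21, tau21, f10, tau10) jointly to all three occupation curves.
    A non-decaying S2 occupation (fitted tau hitting the upper bound) is
    flagged and the fit rejected.
    """
    if occ.fractions.shape[1] < 3:
        raise ValueError("sequential fit needs S0, S1 and S2 occupation pools")
    t = occ.times
    y = occ.fractions[:, :3].ravel()

    def model(tt, f21, tau21, f10, tau10):
        return sequential_model_curves(tt, f21, tau21, f10, tau10).ravel()

    t_span = max(t[-1] - t[0], 1.0)
    tau_hi = 1e4 * t_span
    bounds = ([0.0, 1e-6, 0.0, 1e-6], [1.0, tau_hi, 1.0, tau_hi])
    popt, pcov = curve_fit(model, t, y, p0=list(p0), bounds=bounds, maxfev=20000)
    resid = model(t, *popt) - y
    # a non-decaying S2 pool shows up either as tau21 at the bound or as a
    # vanishing decaying fraction over the observed window
    decayed = popt[0] * (1.0 - math.exp(-(t[-1] - t[0]) / popt[1]))
    if popt[1] > 0.99 * tau_hi or decayed < 1e-3:
        raise RuntimeError(
            "fit_sequential_model: S2 occupation does not decay over the "
            "fitted window (unbounded tau21 or zero decaying fraction)"
        )
    return KineticFit(
        f21=float(popt[0]),
        tau21=float(popt[1]),
        f10=float(popt[2]),
        tau10=float(popt[3]),
        residual_norm=float(np.linalg.norm(resid)),
        covariance=pcov,
    )


def confidence_halfwidth(n: int, level: float = 0.90) -> float:
    """Worst-case binomial confidence half-width for a fraction, in percent.

    max over p of z_{(1+level)/2} * sqrt(p(1-p)/n), attained at p = 1/2.
    For 115 trajectories at the 90% level this evaluates to 7.7% (i.e.,
    fractions determined to within about +-8 points).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 < level < 1.0):
        raise ValueError("confidence level must be in (0, 1)")
    z = norm.ppf(0.5 * (1.0 + level))
    return 100.0 * z * 0.5 / math.sqrt(n)


# ---------------------------------------------------------------------------
# LIIC paths


def _zmatrix(coords: np.ndarray):
    """Chain z-matrix (bond to i-1, angle to i-2, torsion to i-3)."""
    n = len(coords)
    bonds = np.zeros(n)
    angles = np.zeros(n)
    torsions = np.zeros(n)
    for i in range(1, n):
        bonds[i] = np.linalg.norm(coords[i] - coords[i - 1])
        if i >= 2:
            v1 = coords[i - 2] - coords[i - 1]
            v2 = coords[i] - coords[i - 1]
            cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angles[i] = math.acos(max(-1.0, min(1.0, cosang)))
        if i >= 3:
            b0 = coords[i - 2] - coords[i - 3]
            b1 = coords[i - 1] - coords[i - 2]
            b2 = coords[i] - coords[i - 1]
            n1 = np.cross(b0, b1)
            n2 = np.cross(b1, b2)
            m1 = np.cross(n1, b1 / np.linalg.norm(b1))
            torsions[i] = math.atan2(m1 @ n2, n1 @ n2)
    return bonds, angles, torsions


def _from_zmatrix(bonds, angles, torsions):
    n = len(bonds)
    coords = np.zeros((n, 3))
    if n > 1:
        coords[1] = [bonds[1], 0.0, 0.0]
    if n > 2:
        ang = angles[2]
        coords[2] = coords[1] + bonds[2] * np.array([-math.cos(ang), math.sin(ang), 0.0])
    for i in range(3, n):
        b, a, d = bonds[i], angles[i], torsions[i]
        p1, p2, p3 = coords[i - 3], coords[i - 2], coords[i - 1]
        e1 = p3 - p2
        e1 /= np.linalg.norm(e1)
        v = p1 - p2
        nrm = np.cross(v, e1)
        nn = np.linalg.norm(nrm)
        if nn < 1e-10:
            raise ValueError("collinear reference atoms in z-matrix rebuild")
        nrm /= nn
        m = np.cross(nrm, e1)
        d2 = np.array(
            [-b * math.cos(a), b * math.sin(a) * math.cos(d), b * math.sin(a) * math.sin(d)]
        )
        coords[i] = p3 + d2[0] * e1 + d2[1] * m + d2[2] * nrm
    return coords


def liic_path(spec: PathSpec) -> list[np.ndarray]:
    """Linearly interpolated path between two geometries.

    ``cartesian`` interpolates positions directly; ``internal`` interpolates
    chain z-matrix primitives (bonds, angles, torsions with torsions taken
    along the shortest arc) and rebuilds the geometries, preserving bond
    lengths when only torsions differ.  Endpoints are reproduced exactly
    (for the internal mode, up to a rigid-body alignment of the rebuilt
    frames onto the originals).  Falls back to cartesian with a warning
    when the internal set cannot be rebuilt.
    """
    a = np.asarray(spec.start, dtype=float)
    b = np.asarray(spec.end, dtype=float)
    if a.shape != b.shape:
        raise ValueError("endpoint geometries have mismatched atom lists")
    fracs = np.linspace(0.0, 1.0, spec.n_images)
    if spec.coordinate_system == "cartesian" or a.ndim == 1 or len(a) < 4:
        return [(1 - f) * a + f * b for f in fracs]
    if spec.coordinate_system != "internal":
        raise ValueError(f"unknown coordinate system '{spec.coordinate_system}'")
    try:
        ba_, an_a, to_a = _zmatrix(a)
        bb_, an_b, to_b = _zmatrix(b)
        to_b_arc = to_a + (((to_b - to_a) + math.pi) % (2 * math.pi) - math.pi)
        images = []
        for f in fracs:
            bonds = (1 - f) * ba_ + f * bb_
            angles = (1 - f) * an_a + f * an_b
            torsions = (1 - f) * to_a + f * to_b_arc
            geom = _from_zmatrix(bonds, angles, torsions)
            images.append(_align(geom, (1 - f) * a + f * b))
        # pin the endpoints exactly
        images[0] = a.copy()
        images[-1] = b.copy()
        return images
    except ValueError as exc:
        logger.warning("liic_path: internal rebuild failed (%s); cartesian fallback", exc)
        return [(1 - f) * a + f * b for f in fracs]


def _align(geom: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rigid-body (Kabsch) alignment of geom onto reference."""
    gc = geom - geom.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    u, _, vt = np.linalg.svd(gc.T @ rc)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return gc @ rot + reference.mean(axis=0)


def bond_distance_series(
    ensemble, atom_pair: tuple[int, int], frame_geometry=None
):
    """Mean and population standard deviation of an interatomic distance
    across surviving trajectories at every time.

    Trajectory coordinates are mapped to atomic positions through
    ``frame_geometry(coords) -> (elements, positions)`` when given (model
    trajectories), otherwise the coordinates themselves are taken as an
    (n_atoms, 3) array.  Returns (times, mean, sd); sd divides by the
    number of surviving trajectories (population convention).
    """
    trajs = getattr(ensemble, "trajectories", ensemble)
    if not trajs:
        raise ValueError("empty ensemble")
    i, j = atom_pair
    times = max((t.times for t in trajs), key=len)
    sums = np.zeros(len(times))
    sq = np.zeros(len(times))
    cnt = np.zeros(len(times))
    for traj in trajs:
        n = len(traj.times)
        for k in range(min(n, len(times))):
            c = traj.coords[k]
            if frame_geometry is not None:
                _, pos = frame_geometry(c)
            else:
                pos = np.asarray(c, dtype=float).reshape(-1, 3)
            if max(i, j) >= len(pos):
                raise IndexError(f"atom pair {atom_pair} outside geometry of {len(pos)} atoms")
            d = float(np.linalg.norm(pos[i] - pos[j]))
            sums[k] += d
            sq[k] += d * d
            cnt[k] += 1.0
    valid = cnt > 0
    mean = np.full(len(times), np.nan)
    sd = np.full(len(times), np.nan)
    mean[valid] = sums[valid] / cnt[valid]
    var = np.zeros(len(times))
    var[valid] = sq[valid] / cnt[valid] - mean[valid] ** 2
    sd[valid] = np.sqrt(np.maximum(var[valid], 0.0))
    return times[valid], mean[valid], sd[valid]
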