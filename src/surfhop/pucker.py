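"""Cremer-Pople puckering analysis for six-membered rings.

Forward map (ring coordinates -> Q, theta, phi), inverse construction on a
regular hexagon, classification into the canonical Boeyens conformers by
nearest vertex on the (theta, phi) sphere, and the hop-geometry polar-map
table used to characterize surface-hopping events.

Conventions: atoms are indexed 1..6 in ring order (N1 C2 N3 C4 C5 C6 for a
thymine-like ring); the mean plane follows the original Cremer-Pople
prescription (geometric-center origin, plane normal from the two
trigonometric sum vectors, right-handed with respect to ring traversal);
the phase uses the negative-sine convention, which places the boat with
atoms 3 and 6 above the plane at (theta, phi) = (90 deg, 120 deg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RingCoords",
    "PuckerParams",
    "cremer_pople",
    "cremer_pople_inverse",
    "boeyens_classify",
    "canonical_conformers",
    "hop_pucker_map",
]

_N = 6
_J = np.arange(_N)


@dataclass(frozen=True)
class PuckerParams:
    """Total puckering amplitude Q (Angstrom), polar angle theta (deg,
    0-180), phase phi (deg, 0-360) and the Boeyens conformer label."""

    Q: float
    theta: float
    phi: float
    conformer: str
    degenerate: bool = False  # True when Q ~ 0 and theta/phi are undefined


class RingCoords:
    """Six labeled 3D positions (Angstrom) in fixed ring order."""

    def __init__(self, positions, labels=("N1", "C2", "N3", "C4", "C5", "C6")):
        pos = np.asarray(positions, dtype=float)
        if pos.shape != (_N, 3):
            raise ValueError("a six-membered ring needs exactly six 3D positions")
        rel = pos - pos.mean(axis=0)
        if np.linalg.matrix_rank(rel, tol=1e-8) < 2:
            raise ValueError("ring atoms are collinear")
        self.positions = pos
        self.labels = tuple(labels)


def _displacements(positions: np.ndarray) -> np.ndarray:
    """Out-of-plane displacements z_j w.r.t. the Cremer-Pople mean plane."""
    rel = positions - positions.mean(axis=0)
    rp = np.sum(rel * np.sin(2.0 * math.pi * _J / _N)[:, None], axis=0)
    rpp = np.sum(rel * np.cos(2.0 * math.pi * _J / _N)[:, None], axis=0)
    # right-handed with respect to the ring traversal (counterclockwise
    # traversal -> +z normal); this orientation places the 3,6-boat at
    # (theta, phi) = (90, 120) deg.
    normal = np.cross(rpp, rp)
    nrm = np.linalg.norm(normal)
    if nrm < 1e-12:
        raise ValueError("degenerate ring geometry: undefined mean plane")
    return rel @ (normal / nrm)


def cremer_pople(ring: RingCoords | np.ndarray) -> PuckerParams:
    """Cremer-Pople (Q, theta, phi) of a six-membered ring.

    q2 and phi2 come from the m=2 trigonometric sums (negative-sine
    convention), q3 from the alternating sum; Q = sqrt(q2^2 + q3^2) and
    cos(theta) = q3/Q.  For near-planar rings (Q < 1e-6 Angstrom) theta and
    phi are undefined and flagged.
    """
    pos = ring.positions if isinstance(ring, RingCoords) else RingCoords(ring).positions
    z = _displacements(pos)
    ang = 4.0 * math.pi * _J / _N
    q2cos = math.sqrt(1.0 / 3.0) * float(np.sum(z * np.cos(ang)))
    q2sin = -math.sqrt(1.0 / 3.0) * float(np.sum(z * np.sin(ang)))
    q3 = math.sqrt(1.0 / 6.0) * float(np.sum(z * (-1.0) ** _J))
    q2 = math.hypot(q2cos, q2sin)
    big_q = math.hypot(q2, q3)
    if big_q < 1e-6:
        return PuckerParams(Q=big_q, theta=float("nan"), phi=float("nan"),
                            conformer="planar", degenerate=True)
    theta = math.degrees(math.acos(max(-1.0, min(1.0, q3 / big_q))))
    phi = math.degrees(math.atan2(q2sin, q2cos)) % 360.0
    return PuckerParams(Q=big_q, theta=theta, phi=phi,
                        conformer=boeyens_classify(theta, phi))


def cremer_pople_inverse(params: PuckerParams, base_radius: float = 1.39) -> np.ndarray:
    """Ring coordinates realizing given (Q, theta, phi) on a regular hexagon.

    In-plane positions are a regular hexagon of radius ``base_radius``
    traversed counterclockwise (right-handed +z normal); out-of-plane
    displacements are synthesized from (q2, phi2, q3).  The round trip
    through :func:`cremer_pople` recovers the parameters.
    """
    if params.Q < 0:
        raise ValueError("Q must be non-negative")
    th = math.radians(params.theta) if params.Q > 0 else 0.0
    ph = math.radians(params.phi) if params.Q > 0 else 0.0
    q2 = params.Q * math.sin(th)
    q3 = params.Q * math.cos(th)
    ang = 2.0 * math.pi * _J / _N
    z = (
        math.sqrt(1.0 / 3.0) * q2 * np.cos(ph + 2.0 * ang)
        + math.sqrt(1.0 / 6.0) * q3 * (-1.0) ** _J
    )
    xy_ang = ang
    pos = np.column_stack(
        [base_radius * np.cos(xy_ang), base_radius * np.sin(xy_ang), z]
    )
    return pos


# ---------------------------------------------------------------------------
# Boeyens classification

_THETA_E = math.degrees(math.atan(math.sqrt(2.0)))  # 54.74 deg, envelopes
_THETA_H = 50.84  # deg, half-chairs


def _pattern_label(theta: float, phi: float) -> str:
    """Systematic conformer label from the ideal displacement pattern.

    Atoms with |z| within 10% of the per-side maximum are listed, atoms above
    the plane as prefix and below as suffix around the type letter.  Chairs
    use the conventional four-atom reference-plane labels 1C4 / 4C1.
    """
    if theta < 1e-9:
        return "1C4"
    if theta > 180.0 - 1e-9:
        return "4C1"
    band = {90.0: ("B", "S"), _THETA_E: ("E", "E"), _THETA_H: ("H", "H"),
            180.0 - _THETA_E: ("E", "E"), 180.0 - _THETA_H: ("H", "H")}
    # letter: boats/skews distinguished by phi multiple of 60 at the equator
    for th0, (even_letter, odd_letter) in band.items():
        if abs(theta - th0) < 0.5:
            letter = even_letter if abs((phi / 30.0) % 2.0) < 0.5 else odd_letter
            break
    else:
        raise ValueError(f"no canonical band at theta={theta}")
    z = _ideal_pattern(theta, phi)
    zmax = np.max(np.abs(z))
    ups = [str(j + 1) for j in range(_N) if z[j] > 0.9 * zmax]
    downs = [str(j + 1) for j in range(_N) if z[j] < -0.9 * zmax]
    return ",".join(ups) + letter + ",".join(downs)


def _ideal_pattern(theta: float, phi: float) -> np.ndarray:
    th, ph = math.radians(theta), math.radians(phi)
    ang = 2.0 * math.pi * _J / _N
    return (
        math.sqrt(1.0 / 3.0) * math.sin(th) * np.cos(ph + 2.0 * ang)
        + math.sqrt(1.0 / 6.0) * math.cos(th) * (-1.0) ** _J
    )


def canonical_conformers() -> list[tuple[float, float, str]]:
    """The 38 canonical Boeyens vertices as (theta deg, phi deg, label).

    2 chairs at the poles, 6 boats and 6 twist-boats on the equator
    (alternating every 30 deg of phi), and 6 envelopes + 6 half-chairs in
    each hemisphere at theta = 54.7 / 50.8 deg (and supplements).
    """
    verts: list[tuple[float, float, str]] = [(0.0, 0.0, "1C4"), (180.0, 0.0, "4C1")]
    for phi in range(0, 360, 30):
        verts.append((90.0, float(phi), _pattern_label(90.0, float(phi))))
    for theta in (_THETA_E, 180.0 - _THETA_E):
        for phi in range(0, 360, 60):
            verts.append((theta, float(phi), _pattern_label(theta, float(phi))))
    for theta in (_THETA_H, 180.0 - _THETA_H):
        for phi in range(30, 360, 60):
            verts.append((theta, float(phi), _pattern_label(theta, float(phi))))
    return verts


_CANONICAL = None


def _canonical_cache():
    global _CANONICAL
    if _CANONICAL is None:
        verts = canonical_conformers()
        thetas = np.radians([v[0] for v in verts])
        phis = np.radians([v[1] for v in verts])
        labels = [v[2] for v in verts]
        # unit vectors on the puckering sphere
        xyz = np.column_stack(
            [np.sin(thetas) * np.cos(phis), np.sin(thetas) * np.sin(phis), np.cos(thetas)]
        )
        _CANONICAL = (xyz, labels, [(v[0], v[1]) for v in verts])
    return _CANONICAL


def boeyens_classify(theta: float, phi: float) -> str:
    """Nearest canonical Boeyens conformer on the (theta, phi) sphere.

    Great-circle distance metric; exact ties are broken deterministically in
    favor of the vertex with lower phi (then lower theta).  Undefined angles
    (planar ring) return "planar".
    """
    if math.isnan(theta) or math.isnan(phi):
        return "planar"
    if not (0.0 <= theta <= 180.0):
        raise ValueError("theta must be in [0, 180] degrees")
    xyz, labels, angles = _canonical_cache()
    th, ph = math.radians(theta), math.radians(phi % 360.0)
    p = np.array([math.sin(th) * math.cos(ph), math.sin(th) * math.sin(ph), math.cos(th)])
    dots = xyz @ p
    best = np.max(dots)
    candidates = [k for k in range(len(labels)) if dots[k] > best - 1e-12]
    if len(candidates) > 1:
        candidates.sort(key=lambda k: (angles[k][1], angles[k][0]))
    return labels[candidates[0]]


# ---------------------------------------------------------------------------
# hop-geometry polar maps


def hop_pucker_map(hops, ring_indices=tuple(range(6))):
    """Tabulate Cremer-Pople parameters at hop geometries.

    ``hops`` is an iterable of objects (or mappings) exposing ``time`` and a
    coordinate snapshot with at least six ring atoms; ``ring_indices`` picks
    the ring atoms out of the snapshot.  Each hop contributes one row
    (time, Q, theta, phi, conformer), with phi >= 180 deg reflected into the
    phi < 180 half-plane by the map's mirror symmetry (phi -> 360 - phi).
    Hops without usable ring coordinates are skipped and counted.  The
    returned DataFrame carries the number of skipped hops and the
    correlation between phi and hop time in ``attrs``.
    """
    import pandas as pd

    rows = []
    skipped = 0
    for hop in hops:
        geom = getattr(hop, "geometry", None)
        if geom is None and isinstance(hop, dict):
            geom = hop.get("geometry")
        time = getattr(hop, "time", None)
        if time is None and isinstance(hop, dict):
            time = hop.get("time")
        if geom is None:
            skipped += 1
            continue
        geom = np.asarray(geom, dtype=float)
        if geom.ndim != 2 or geom.shape[0] < max(ring_indices) + 1:
            skipped += 1
            continue
        try:
            params = cremer_pople(geom[list(ring_indices)])
        except ValueError:
            skipped += 1
            continue
        phi = params.phi
        if not params.degenerate and phi >= 180.0:
            phi = 360.0 - phi
        rows.append(
            {
                "time_fs": float(time) if time is not None else float("nan"),
                "Q_A": params.Q,
                "theta_deg": params.theta,
                "phi_deg": phi,
                "conformer": params.conformer,
            }
        )
    df = pd.DataFrame(rows, columns=["time_fs", "Q_A", "theta_deg", "phi_deg", "conformer"])
    df.attrs["skipped"] = skipped
    if len(df) > 2 and df["phi_deg"].std() > 0 and df["time_fs"].std() > 0:
        df.attrs["phi_time_correlation"] = float(df["phi_deg"].corr(df["time_fs"]))
    else:
        df.attrs["phi_time_correlation"] = float("nan")
    return df
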