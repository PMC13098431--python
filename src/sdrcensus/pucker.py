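"""Cremer-Pople puckering for six-membered rings.

Ring atoms are ordered O5, C1, C2, C3, C4, C5 with the phase origin at O5
(atom j = 1).  Under that carbohydrate convention the 4C1 chair of an
alpha-D-pyranose maps to the north pole theta = 0 and 1C4 to theta = 180.
The module provides the forward transform (coordinates -> Q, theta, phi), the
inverse construction used by the synthetic generator, and nearest-reference
IUPAC conformer assignment over the 38 canonical conformers (2 chairs, 6
boats, 6 twist-boats, 12 envelopes, 12 half-chairs).

Reference positions on the puckering sphere: chairs at the poles; boats and
twist-boats alternating every 30 deg in phi on the equator; envelopes and
half-chairs alternating every 30 deg in phi on the theta = 54.74 / 125.26 deg
circles (the magic-angle tropics, where the reference z-patterns of ideal E
and H forms fall under the phase convention above).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, EmptySelectionError, PlanarRingError
from .model_io import Frame, Selection, Trajectory

__all__ = [
    "PuckerCoordinates",
    "ConformerLabel",
    "CANONICAL_CONFORMERS",
    "cremer_pople",
    "build_ring",
    "assign_conformer",
    "pucker_series",
    "PuckerSeriesResult",
]

#: planarity threshold (Angstrom): below this Q, phi is numerically unstable
PLANARITY_THRESHOLD = 0.1

#: default circle radius (Angstrom) for ring construction; the mean in-plane
#: bond projection of a pyranose ring
DEFAULT_RING_RADIUS = 1.43

# magic-angle tropic: theta of ideal envelope/half-chair references
_TROPIC = float(np.degrees(np.arctan(np.sqrt(2.0))))  # 54.7356...

_J = np.arange(6)
_ANG2 = 4.0 * np.pi * _J / 6.0  # second-order Fourier angles, phase origin O5
_SIGNS = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])  # (-1)^(j-1)


def _reference_table() -> dict[str, tuple[float, float]]:
    """Canonical conformer name -> (theta, phi) in degrees.

    Derived analytically from the inverse z-displacement formula with the
    O5-first phase convention (superscript atoms lie above the mean plane).
    Exact phi ties in assignment are broken lexicographically by name.
    """
    table: dict[str, tuple[float, float]] = {
        "4C1": (0.0, 0.0),
        "1C4": (180.0, 0.0),
    }
    # equator: boats at phi = 0 mod 60, twist-boats at phi = 30 mod 60
    boats = {0: "3,0B", 60: "B1,4", 120: "2,5B", 180: "B3,0", 240: "1,4B", 300: "B2,5"}
    skews = {30: "3S1", 90: "5S1", 150: "2S0", 210: "1S3", 270: "1S5", 330: "0S2"}
    for phi, name in {**boats, **skews}.items():
        table[name] = (90.0, float(phi))
    # northern tropic: envelopes at phi = 0 mod 60, half-chairs at 30 mod 60
    north = {
        0: "0E", 30: "0H1", 60: "E1", 90: "2H1", 120: "2E", 150: "2H3",
        180: "E3", 210: "4H3", 240: "4E", 270: "4H5", 300: "E5", 330: "0H5",
    }
    for phi, name in north.items():
        table[name] = (_TROPIC, float(phi))
        # the southern reference at phi + 180 is the ring-inverted form:
        # superscript and subscript atoms swap sides of the mean plane
        south_phi = (phi + 180) % 360
        table[_invert_name(name)] = (180.0 - _TROPIC, float(south_phi))
    return table


def _invert_name(name: str) -> str:
    """Swap above/below-plane atoms of an envelope or half-chair label."""
    if name.startswith("E"):
        return name[1:] + "E"
    if name.endswith("E"):
        return "E" + name[:-1]
    sup, sub = name.split("H")
    return sub + "H" + sup


CANONICAL_CONFORMERS: dict[str, tuple[float, float]] = _reference_table()
assert len(CANONICAL_CONFORMERS) == 38


@dataclass(frozen=True)
class PuckerCoordinates:
    """Total amplitude Q (A), spherical angles theta/phi (deg), and the
    second- and third-order amplitudes q2 (A, >= 0) and q3 (A, signed)."""

    Q: float
    theta: float
    phi: float
    q2: float
    q3: float

    @property
    def is_planar(self) -> bool:
        return self.Q < PLANARITY_THRESHOLD


@dataclass(frozen=True)
class ConformerLabel:
    name: str
    angular_distance: float  # great-circle distance (deg) on the pucker sphere


def _ring_coords(frame: Frame, ring: list[int]) -> np.ndarray:
    if len(ring) != 6 or len(set(ring)) != 6:
        raise ValueError("ring must be 6 distinct atom indices (O5,C1..C5)")
    return frame.coordinates[list(ring)]


def cremer_pople(frame: Frame, ring: list[int]) -> PuckerCoordinates:
    """Puckering coordinates of a 6-ring given in O5, C1..C5 order.

    The mean plane passes through the geometric center with normal direction
    from the two weighted lattice vectors R' and R''; out-of-plane
    displacements are combined into the second-order Fourier pair (q2, phi)
    and the alternating third-order amplitude q3, with Q^2 = q2^2 + q3^2 and
    cos(theta) = q3 / Q.
    """
    r = _ring_coords(frame, ring)
    r = r - r.mean(axis=0)
    rp = (r * np.sin(2.0 * np.pi * _J / 6.0)[:, None]).sum(axis=0)
    rpp = (r * np.cos(2.0 * np.pi * _J / 6.0)[:, None]).sum(axis=0)
    # orientation chosen so an O5-up ideal chair lands on theta = 0 (4C1)
    normal = np.cross(rpp, rp)
    norm = np.linalg.norm(normal)
    if norm < 1e-12:
        raise DegenerateGeometryError("degenerate ring: no mean plane")
    n = normal / norm
    z = r @ n
    a_c = float((z * np.cos(_ANG2)).sum())
    a_s = float((z * np.sin(_ANG2)).sum())
    q2 = np.sqrt(a_c**2 + a_s**2) / np.sqrt(3.0)
    phi = float(np.degrees(np.arctan2(-a_s, a_c))) % 360.0
    q3 = float((_SIGNS * z).sum()) / np.sqrt(6.0)
    Q = float(np.hypot(q2, q3))
    theta = float(np.degrees(np.arccos(np.clip(q3 / Q, -1.0, 1.0)))) if Q > 0 else 0.0
    return PuckerCoordinates(Q=Q, theta=theta, phi=phi, q2=float(q2), q3=q3)


def build_ring(
    Q: float, theta: float, phi: float, radius: float = DEFAULT_RING_RADIUS
) -> np.ndarray:
    """Inverse transform: 6x3 coordinates realizing (Q, theta, phi).

    Atoms are placed on a circle of the given radius in O5, C1..C5 order with
    out-of-plane displacements

        z_j = sqrt(1/3) q2 cos(phi + 4 pi (j-1)/6) + sqrt(1/6) q3 (-1)^(j-1)

    where q2 = Q sin(theta), q3 = Q cos(theta); sum(z_j) = 0 by construction.
    """
    if Q < 0:
        raise ValueError("Q must be non-negative")
    if radius <= 0:
        raise ValueError("radius must be positive")
    th, ph = np.radians(theta), np.radians(phi)
    q2 = Q * np.sin(th)
    q3 = Q * np.cos(th)
    z = np.sqrt(1.0 / 3.0) * q2 * np.cos(ph + _ANG2) + np.sqrt(1.0 / 6.0) * q3 * _SIGNS
    ang = 2.0 * np.pi * _J / 6.0
    xy = radius * np.column_stack([np.cos(ang), np.sin(ang)])
    return np.column_stack([xy, z])


def _great_circle(theta1, phi1, theta2, phi2) -> float:
    t1, p1, t2, p2 = np.radians([theta1, phi1, theta2, phi2])
    c = np.sin(t1) * np.sin(t2) * np.cos(p1 - p2) + np.cos(t1) * np.cos(t2)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def assign_conformer(p: PuckerCoordinates) -> ConformerLabel:
    """Nearest canonical conformer by great-circle distance on (theta, phi).

    Raises :class:`PlanarRingError` below the planarity threshold; exact
    distance ties break lexicographically by name.
    """
    if p.is_planar:
        raise PlanarRingError(
            f"Q = {p.Q:.3f} A below planarity threshold {PLANARITY_THRESHOLD} A"
        )
    best_name, best_d = None, np.inf
    for name in sorted(CANONICAL_CONFORMERS):
        t_ref, p_ref = CANONICAL_CONFORMERS[name]
        d = _great_circle(p.theta, p.phi, t_ref, p_ref)
        if d < best_d - 1e-12:
            best_name, best_d = name, d
    return ConformerLabel(name=best_name, angular_distance=best_d)


@dataclass
class PuckerSeriesResult:
    """Per-frame pucker table and conformer populations.

    ``populations`` are fractions over assigned (non-planar) frames and sum
    to 1 when any frame was assignable; planar frames are counted separately.
    """

    table: pd.DataFrame  # frame, Q, theta, phi, conformer
    populations: pd.Series
    n_planar: int


def pucker_series(traj: Trajectory, ring: Selection | list[int]) -> PuckerSeriesResult:
    """Pucker every frame of a trajectory and tabulate conformer populations."""
    if isinstance(ring, Selection):
        indices = traj.topology.select(ring)
    else:
        indices = list(ring)
    if len(indices) != 6:
        raise EmptySelectionError(
            f"ring selection must resolve to 6 atoms, got {len(indices)}"
        )
    rows = []
    n_planar = 0
    for frame in traj:
        p = cremer_pople(frame, indices)
        if p.is_planar:
            n_planar += 1
            label = None
        else:
            label = assign_conformer(p).name
        rows.append(
            {"frame": frame.index, "Q": p.Q, "theta": p.theta, "phi": p.phi,
             "conformer": label}
        )
    table = pd.DataFrame(rows)
    assigned = table["conformer"].dropna()
    if len(assigned):
        populations = assigned.value_counts(normalize=True).sort_index()
    else:
        populations = pd.Series(dtype=float)
    return PuckerSeriesResult(table=table, populations=populations, n_planar=n_planar)
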