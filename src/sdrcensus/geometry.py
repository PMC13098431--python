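"""Exact geometric kernels.

Distances, bond angles and torsions over trajectory frames, least-squares
rigid superposition (Kabsch, reflections excluded) and per-residue
displacement profiles between two structures.  Angles are degrees at the
interface; torsions follow the IUPAC sign convention (clockwise positive
viewed from j toward k) on ``(-180, 180]`` with the trans boundary mapped to
``+180``.  No periodic-boundary wrapping is applied anywhere: active-site
distances are short-range and input frames must be pre-imaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, EmptySelectionError
from .model_io import Frame, Selection, Topology

__all__ = [
    "distance",
    "angle",
    "dihedral",
    "kabsch_superpose",
    "SuperpositionResult",
    "residue_displacement",
    "DisplacementProfile",
]

_EPS = 1e-12


def _vec(frame: Frame, i: int, j: int) -> np.ndarray:
    coords = frame.coordinates
    return coords[j] - coords[i]


def distance(frame: Frame, i: int, j: int) -> float:
    """Euclidean distance (Angstrom) between atoms i and j."""
    if i == j:
        raise ValueError("distance requires two distinct atom indices")
    return float(np.linalg.norm(_vec(frame, i, j)))


def angle(frame: Frame, i: int, j: int, k: int) -> float:
    """Angle at vertex j (degrees in [0, 180])."""
    if j in (i, k):
        raise ValueError("angle vertex must differ from the arm atoms")
    u = _vec(frame, j, i)
    v = _vec(frame, j, k)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _EPS or nv < _EPS:
        raise DegenerateGeometryError("zero-length arm in angle computation")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral(frame: Frame, i: int, j: int, k: int, l: int) -> float:
    """Torsion i-j-k-l in degrees on (-180, 180]; cis = 0, trans = 180."""
    if j == k:
        raise ValueError("central dihedral atoms must be distinct")
    b1 = _vec(frame, i, j)
    b2 = _vec(frame, j, k)
    b3 = _vec(frame, k, l)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _EPS or np.linalg.norm(n2) < _EPS:
        raise DegenerateGeometryError("collinear atoms: dihedral undefined")
    b2n = b2 / np.linalg.norm(b2)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2n)
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:  # single representation of trans
        ang += 360.0
    return ang


@dataclass
class SuperpositionResult:
    """Optimal rigid transform: y ~ rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(moving: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-RMSD proper rotation + translation mapping moving onto reference.

    Reflections are excluded (det = +1), so mirror-image point sets retain a
    non-zero residual.  Requires at least 3 non-collinear points.
    """
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape:
        raise ValueError(
            f"shape mismatch: {moving.shape} vs {reference.shape}"
        )
    n = moving.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    mu_m = moving.mean(axis=0)
    mu_r = reference.mean(axis=0)
    a = moving - mu_m
    b = reference - mu_r
    # align_vectors solves the orthogonal Procrustes problem restricted to
    # proper rotations (Kabsch with the reflection branch removed)
    rot, _ = Rotation.align_vectors(b, a)
    R = rot.as_matrix()
    t = mu_r - R @ mu_m
    resid = moving @ R.T + t - reference
    rmsd = float(np.sqrt((resid**2).sum() / n))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms=n)


@dataclass
class DisplacementProfile:
    """Per-residue displacement of selected atoms after superposition.

    ``table`` has one row per residue present in both structures
    (chain, resid, resname, displacement in Angstrom); residues missing from
    either structure are listed in ``absent`` rather than reported as zero.
    """

    table: pd.DataFrame
    absent: list[tuple[str, int]]
    superposition: SuperpositionResult


def _selected_by_residue(topology: Topology, indices: list[int]):
    groups: dict[tuple[str, int], list[int]] = {}
    resnames: dict[tuple[str, int], str] = {}
    for i in indices:
        a = topology.atoms[i]
        groups.setdefault((a.chain, a.resid), []).append(i)
        resnames[(a.chain, a.resid)] = a.resname
    return groups, resnames


def residue_displacement(
    topology_a: Topology,
    frame_a: Frame,
    topology_b: Topology,
    frame_b: Frame,
    selection: Selection,
    superpose_on: Selection,
) -> DisplacementProfile:
    """Superpose B onto A and profile per-residue displacements.

    The fit uses atoms matched by (chain, resid, name) within ``superpose_on``;
    displacements are the mean over each residue's ``selection`` atoms that
    exist in both structures.
    """
    fit_a = topology_a.select(superpose_on)
    pairs = []
    for ia in fit_a:
        atom = topology_a.atoms[ia]
        try:
            ib = topology_b.index_of(atom.chain, atom.resid, atom.name)
        except KeyError:
            continue
        pairs.append((ia, ib))
    if len(pairs) < 3:
        raise EmptySelectionError(
            "fewer than 3 atoms of the superposition selection are shared"
        )
    ia_fit, ib_fit = map(list, zip(*pairs))
    sup = kabsch_superpose(
        frame_b.coordinates[ib_fit], frame_a.coordinates[ia_fit]
    )
    b_transformed = sup.apply(frame_b.coordinates)

    sel_a = topology_a.select(selection)
    groups_a, resnames = _selected_by_residue(topology_a, sel_a)
    try:
        sel_b = topology_b.select(selection)
        groups_b, _ = _selected_by_residue(topology_b, sel_b)
    except EmptySelectionError:
        groups_b = {}
    rows, absent = [], []
    for (chain, resid), idx_a in groups_a.items():
        matched_a, matched_b = [], []
        for ia in idx_a:
            name = topology_a.atoms[ia].name
            try:
                ib = topology_b.index_of(chain, resid, name)
            except KeyError:
                continue
            matched_a.append(ia)
            matched_b.append(ib)
        if not matched_a:
            absent.append((chain, resid))
            continue
        d = np.linalg.norm(
            frame_a.coordinates[matched_a] - b_transformed[matched_b], axis=1
        ).mean()
        rows.append(
            {
                "chain": chain,
                "resid": resid,
                "resname": resnames[(chain, resid)],
                "displacement": float(d),
            }
        )
    for key in groups_b:
        if key not in groups_a:
            absent.append(key)
    table = pd.DataFrame(rows, columns=["chain", "resid", "resname", "displacement"])
    return DisplacementProfile(table=table, absent=absent, superposition=sup)
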