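"""Synthetic conformational ensembles with exact ground truth.

The generator emits a minimal pseudo-active-site topology (catalytic triad
atoms, nicotinamide-ribose hydroxyls, nicotinamide C4, the reactive sugar
atoms with an explicit H2, contact-probe atoms, a four-atom pyrophosphate
chain, and a detached six-atom pyranose ring) and constructs per-frame
coordinates so that every frame *exactly* realizes its sampled class:

* plausible frames satisfy all four canonical SDR distance criteria, with
  distances drawn from a truncated normal below the cutoff;
* unproductive frames violate at least one designated criterion (truncated
  above the cutoff with a safety margin, so classification is a hard
  guarantee, not a statistical one);
* the pyrophosphate O1-P1-O12-P2 torsion realizes a von Mises mixture draw;
* the hydride C2-H2-C4 angle realizes a truncated normal draw;
* contact probes are placed inside/outside their cutoff with planted
  per-frame indicators, independent of the plausibility class;
* the pyranose ring is built from the canonical (theta, phi) of a conformer
  drawn from a stated menu, plus isotropic coordinate noise.

Criterion partners are placed along fixed, mutually distant unit directions
from their anchor atoms, which decouples the criteria so classes can be
planted exactly.  This is deliberately non-physical plumbing for testability;
it reproduces the statistical structure of an epimerase MD ensemble, not its
chemistry.  Everything is reproducible bitwise from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InfeasibleGeometryError
from .model_io import AtomRecord, Frame, Selection, Topology, Trajectory
from .pucker import CANONICAL_CONFORMERS, build_ring

__all__ = [
    "DistanceDistribution",
    "VonMisesComponent",
    "ContactPlant",
    "SyntheticEnsembleConfig",
    "GroundTruth",
    "generate_ensemble",
    "sample_dihedrals",
    "generate_ring_trajectory",
    "PRESETS",
    "preset",
    "active_site_bindings",
    "default_contact_specs",
]

_CRITERIA = ("tyr_oh-sugar_o2", "thr_og-sugar_o2", "lys_nz-ribose_oh", "nad_c4-sugar_c2")


@dataclass(frozen=True)
class DistanceDistribution:
    """Truncated normal over (lo, hi] sampled by bounded rejection."""

    mean: float
    sd: float
    lo: float
    hi: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.sd < 0 or self.hi <= self.lo:
            raise ValueError("invalid distance distribution")
        out = np.empty(n)
        filled = 0
        for _ in range(1000):  # bounded retries
            draw = rng.normal(self.mean, self.sd, size=2 * (n - filled) + 8)
            ok = draw[(draw > self.lo) & (draw <= self.hi)]
            take = min(len(ok), n - filled)
            out[filled : filled + take] = ok[:take]
            filled += take
            if filled == n:
                return out
        raise InfeasibleGeometryError(
            f"rejection sampling failed for {self} (acceptance region too small)"
        )


@dataclass(frozen=True)
class VonMisesComponent:
    mean: float      # degrees
    kappa: float     # concentration, > 0
    weight: float


@dataclass(frozen=True)
class ContactPlant:
    """A planted probe contact: True with probability p each frame."""

    label: str
    probe_atom: str           # atom name in the probe residue layout below
    target_atom: str          # "O3" or "O4" of the sugar
    probability: float
    cutoff: float = 4.0


# distances for the plausible class: hydrogen-bond-like, below the 3.5 A
# cutoff; for the unproductive class: clearly above it (margin 0.2 A keeps
# the class guarantee exact under float arithmetic)
_PLAUSIBLE_DIST = DistanceDistribution(mean=3.0, sd=0.25, lo=2.5, hi=3.5)
_UNPRODUCTIVE_DIST = DistanceDistribution(mean=4.8, sd=0.8, lo=3.7, hi=9.0)


def _default_dihedral_mixture():
    return (VonMisesComponent(mean=130.0, kappa=8.0, weight=1.0),)


def _default_pucker_menu():
    # dominant 4C1 chair with the distorted minor states seen for the
    # manno-configured substrate
    return (("4C1", 0.80), ("1H0", 0.07), ("1E", 0.05), ("1H2", 0.05), ("0S2", 0.03))


def _default_contacts():
    return (
        ContactPlant("asn_cg-c3o", "CG", "O3", 0.0018, cutoff=4.0),
        ContactPlant("gln_cd-c3o", "CD", "O3", 0.0033, cutoff=4.0),
        ContactPlant("val_o-c3o", "OV", "O3", 0.0313, cutoff=3.5),
        ContactPlant("met_o-c4o", "OM", "O4", 0.0008, cutoff=3.5),
    )


@dataclass(frozen=True)
class SyntheticEnsembleConfig:
    """Generative model of the ensemble statistics the analysis assumes.

    Defaults mirror the manno-configured study conditions: a 4.18% plausible
    fraction over 24e3 frames, a single pyrophosphate-torsion mode near
    130 deg, a 4C1-dominant pucker menu with half-chair/envelope/skew minors,
    and a hydride angle distribution centered between 130 and 140 deg with a
    162 deg ceiling.
    """

    n_frames: int = 24000
    fraction_plausible: float = 0.0418
    plausible_distances: DistanceDistribution = _PLAUSIBLE_DIST
    unproductive_distances: DistanceDistribution = _UNPRODUCTIVE_DIST
    fail_probability: float = 0.75  # per-criterion failure odds in unproductive frames
    contacts: tuple[ContactPlant, ...] = field(default_factory=_default_contacts)
    dihedral_mixture: tuple[VonMisesComponent, ...] = field(
        default_factory=_default_dihedral_mixture
    )
    pucker_menu: tuple[tuple[str, float], ...] = field(default_factory=_default_pucker_menu)
    pucker_Q: float = 0.57
    pucker_noise_sd: float = 0.02
    hydride_angle_mean: float = 135.0
    hydride_angle_sd: float = 8.0
    hydride_angle_bounds: tuple[float, float] = (100.0, 162.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames <= 0:
            raise ConfigurationError("n_frames must be positive")
        if not 0.0 <= self.fraction_plausible <= 1.0:
            raise ConfigurationError("fraction_plausible must lie in [0, 1]")
        w = sum(c.weight for c in self.dihedral_mixture)
        if abs(w - 1.0) > 1e-9:
            raise ConfigurationError("dihedral mixture weights must sum to 1")
        if any(c.kappa <= 0 for c in self.dihedral_mixture):
            raise ConfigurationError("von Mises concentration must be positive")
        p = sum(p for _, p in self.pucker_menu)
        if abs(p - 1.0) > 1e-9:
            raise ConfigurationError("pucker menu probabilities must sum to 1")
        for name, _ in self.pucker_menu:
            if name not in CANONICAL_CONFORMERS:
                raise ConfigurationError(f"unknown conformer {name!r}")
        for c in self.contacts:
            if not 0.0 <= c.probability <= 1.0:
                raise ConfigurationError(f"contact {c.label}: bad probability")
        probes = [c.probe_atom for c in self.contacts]
        if len(set(probes)) != len(probes):
            raise ConfigurationError(
                "each probe atom may carry only one planted contact "
                "(a shared probe cannot realize two independent indicators)"
            )


#: paper-mimicking study presets
PRESETS: dict[str, SyntheticEnsembleConfig] = {
    "cdp-glc-like": SyntheticEnsembleConfig(
        fraction_plausible=0.016,
        dihedral_mixture=(VonMisesComponent(170.0, 8.0, 1.0),),
        pucker_menu=(("4C1", 0.97), ("1H0", 0.01), ("1E", 0.01), ("1H2", 0.01)),
        # Asn CG is planted against the C3 oxygen only; its distance to the
        # C4 oxygen is then geometrically above the cutoff in every frame
        # (no C4-O contact), matching the glc-like contact pattern
        contacts=(ContactPlant("asn_cg-c3o", "CG", "O3", 0.0018, cutoff=4.0),),
    ),
    "cdp-man-like": SyntheticEnsembleConfig(),
}


def preset(name: str, **overrides) -> SyntheticEnsembleConfig:
    """A named study preset, optionally with field overrides."""
    try:
        cfg = PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# topology layout
# ---------------------------------------------------------------------------

# anchors (Angstrom); criterion partners move along fixed unit directions
# from these points, so the four criteria never interfere
_SUGAR_O2 = np.array([0.0, 0.0, 0.0])
_SUGAR_C2 = np.array([1.43, 0.0, 0.0])
_RIBOSE_O2D = np.array([-4.0, 4.0, 0.0])
_RIBOSE_O3D = np.array([-4.0, 1.5, 0.0])   # 2.5 A below O2D
_SUGAR_O3 = np.array([0.0, 6.0, 4.0])
_SUGAR_O4 = np.array([4.0, 6.0, 4.0])
_PYRO_O1 = np.array([0.0, -8.0, -6.0])
_PYRO_P1 = _PYRO_O1 + np.array([1.6, 0.0, 0.0])
_RING_OFFSET = np.array([14.0, 14.0, 14.0])

_DIR_TYR = np.array([0.0, 1.0, 0.0])
_DIR_THR = np.array([0.0, -1.0, 0.0])
_DIR_LYS = np.array([0.0, 1.0, 0.0])       # from O2D, away from O3D
_DIR_H2 = np.array([0.0, 0.0, 1.0])
_H2_BOND = 1.09

_CONTACT_DIRS = {
    "CG": np.array([0.0, 1.0, 0.0]),
    "CD": np.array([0.0, 0.0, 1.0]),
    "OV": np.array([-1.0, 0.0, 0.0]),
    "OM": np.array([0.0, 0.0, -1.0]),
}

_CONTACT_RESIDUES = {
    "CG": ("ASN", 125),
    "CD": ("GLN", 205),
    "OV": ("VAL", 83),
    "OM": ("MET", 85),
}

_RING_ATOMS = ("O5", "C1", "C2", "C3", "C4", "C5")


def _build_topology(contacts: tuple[ContactPlant, ...]) -> tuple[Topology, dict[str, int]]:
    atoms: list[AtomRecord] = []
    order: dict[str, int] = {}

    def add(name, resname, resid, element):
        order[f"{resname}{resid}:{name}"] = len(atoms)
        atoms.append(
            AtomRecord(
                serial=len(atoms) + 1,
                name=name,
                resname=resname,
                resid=resid,
                chain="A",
                element=element,
            )
        )

    add("OH", "TYR", 164, "O")
    add("OG1", "THR", 124, "O")
    add("NZ", "LYS", 168, "N")
    add("O2D", "NAD", 401, "O")
    add("O3D", "NAD", 401, "O")
    add("C4N", "NAD", 401, "C")
    add("C2", "SUG", 402, "C")
    add("H2", "SUG", 402, "H")
    add("O2", "SUG", 402, "O")
    add("O3", "SUG", 402, "O")
    add("O4", "SUG", 402, "O")
    add("O1", "SUG", 402, "O")
    add("P1", "SUG", 402, "P")
    add("O12", "SUG", 402, "O")
    add("P2", "SUG", 402, "P")
    probe_names = sorted({c.probe_atom for c in contacts})
    for pname in probe_names:
        resname, resid = _CONTACT_RESIDUES[pname]
        name = "O" if pname in ("OV", "OM") else pname
        add(name, resname, resid, name[0])
        order[f"probe:{pname}"] = len(atoms) - 1
    for rname in _RING_ATOMS:
        add(rname, "PYR", 403, rname[0])
    return Topology(atoms), order


def active_site_bindings(topology: Topology) -> dict[str, Selection]:
    """Role -> Selection map for ``census.default_sdr_criteria`` on the
    generated pseudo-active-site topology."""
    return {
        "tyr_oh": Selection(resid=164, name="OH"),
        "thr_og": Selection(resid=124, name="OG1"),
        "lys_nz": Selection(resid=168, name="NZ"),
        "ribose_oh": Selection(resname="NAD", name="O?D"),
        "nad_c4": Selection(resname="NAD", name="C4N"),
        "sugar_c2": Selection(resname="SUG", name="C2"),
        "sugar_o2": Selection(resname="SUG", name="O2"),
    }


def default_contact_specs(cfg: SyntheticEnsembleConfig):
    """ContactSpec list matching the planted contacts of a config."""
    from .census import ContactSpec

    specs = []
    for c in cfg.contacts:
        resname, resid = _CONTACT_RESIDUES[c.probe_atom]
        name = "O" if c.probe_atom in ("OV", "OM") else c.probe_atom
        specs.append(
            ContactSpec(
                label=c.label,
                probe=Selection(resname=resname, resid=resid, name=name),
                target=Selection(resname="SUG", name=c.target_atom),
                cutoff=c.cutoff,
            )
        )
    return specs


@dataclass
class GroundTruth:
    """Planted per-frame labels, consistent with the coordinates by
    construction."""

    plausible: np.ndarray                 # bool (n_frames,)
    criterion_distances: pd.DataFrame     # one column per criterion label
    contacts: pd.DataFrame                # bool, one column per contact label
    dihedral: np.ndarray                  # degrees (-180, 180]
    dihedral_component: np.ndarray        # mixture component index
    conformer: np.ndarray                 # conformer name per frame
    hydride_angle: np.ndarray             # degrees

    @property
    def fraction_plausible(self) -> float:
        return float(self.plausible.mean())


def _place_by_internal(a, b, c, bond, angle_deg, torsion_deg) -> np.ndarray:
    """Place atom d at (bond, angle at c, torsion a-b-c-d), NeRF style."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _place_torsion_batch(a, b, c, bond, angle_deg, torsion_deg) -> np.ndarray:
    """Vectorized internal-coordinate placement over a torsion array."""
    ang = np.radians(angle_deg)
    tor = np.radians(np.asarray(torsion_deg, dtype=float))
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    nvec = np.cross(ab, bc)
    nvec = nvec / np.linalg.norm(nvec)
    m = np.cross(nvec, bc)
    d0 = -bond * np.cos(ang)
    d1 = bond * np.sin(ang) * np.cos(tor)
    d2 = bond * np.sin(ang) * np.sin(tor)
    return c + d0 * bc + d1[:, None] * m + d2[:, None] * nvec


def _build_ring_batch(Q: float, theta_deg, phi_deg, radius: float = None) -> np.ndarray:
    """Vectorized ``build_ring`` over per-frame (theta, phi) arrays."""
    from .pucker import DEFAULT_RING_RADIUS, _ANG2, _J, _SIGNS

    radius = DEFAULT_RING_RADIUS if radius is None else radius
    th = np.radians(np.asarray(theta_deg, dtype=float))[:, None]
    ph = np.radians(np.asarray(phi_deg, dtype=float))[:, None]
    q2 = Q * np.sin(th)
    q3 = Q * np.cos(th)
    z = np.sqrt(1.0 / 3.0) * q2 * np.cos(ph + _ANG2) + np.sqrt(1.0 / 6.0) * q3 * _SIGNS
    ang = 2.0 * np.pi * _J / 6.0
    out = np.empty((th.shape[0], 6, 3))
    out[:, :, 0] = radius * np.cos(ang)
    out[:, :, 1] = radius * np.sin(ang)
    out[:, :, 2] = z
    return out


def sample_dihedrals(
    mixture: tuple[VonMisesComponent, ...],
    n: int,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Wrapped von Mises mixture draws (degrees) plus component labels."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    weights = np.array([c.weight for c in mixture])
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ConfigurationError("mixture weights must sum to 1")
    if any(c.kappa <= 0 for c in mixture):
        raise ConfigurationError("kappa must be positive")
    comp = rng.choice(len(mixture), size=n, p=weights)
    out = np.empty(n)
    for k, c in enumerate(mixture):
        m = comp == k
        out[m] = rng.vonmises(np.radians(c.mean), c.kappa, size=int(m.sum()))
    deg = np.degrees(out)
    deg[deg <= -180.0] += 360.0
    return deg, comp


def _sample_hydride_angles(cfg, rng, n) -> np.ndarray:
    lo, hi = cfg.hydride_angle_bounds
    dist = DistanceDistribution(cfg.hydride_angle_mean, cfg.hydride_angle_sd, lo, hi)
    return dist.sample(rng, n)


def generate_ensemble(
    cfg: SyntheticEnsembleConfig | None = None, seed: int | None = None
) -> tuple[Trajectory, GroundTruth]:
    """Generate a pseudo-active-site trajectory realizing the config exactly."""
    cfg = cfg or SyntheticEnsembleConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_frames
    topo, order = _build_topology(cfg.contacts)

    plausible = rng.random(n) < cfg.fraction_plausible

    # per-criterion distances: start from the plausible distribution and
    # overwrite the designated failing criteria of unproductive frames
    dist = {
        label: cfg.plausible_distances.sample(rng, n) for label in _CRITERIA
    }
    n_unprod = int((~plausible).sum())
    if n_unprod:
        fail = rng.random((n_unprod, len(_CRITERIA))) < cfg.fail_probability
        none_failing = ~fail.any(axis=1)
        # force at least one designated failing criterion
        fail[none_failing, rng.integers(0, len(_CRITERIA), int(none_failing.sum()))] = True
        unprod_rows = np.flatnonzero(~plausible)
        for j, label in enumerate(_CRITERIA):
            rows = unprod_rows[fail[:, j]]
            dist[label][rows] = cfg.unproductive_distances.sample(rng, len(rows))

    hydride = _sample_hydride_angles(cfg, rng, n)
    dihedral, dihedral_comp = sample_dihedrals(cfg.dihedral_mixture, n, rng)

    contact_flags = {
        c.label: rng.random(n) < c.probability for c in cfg.contacts
    }
    contact_dist = {}
    for c in cfg.contacts:
        hit = contact_flags[c.label]
        d = np.empty(n)
        d[hit] = rng.uniform(2.8, c.cutoff, int(hit.sum()))
        d[~hit] = rng.uniform(c.cutoff + 0.5, c.cutoff + 3.0, int((~hit).sum()))
        contact_dist[c.label] = d

    menu_names = [name for name, _ in cfg.pucker_menu]
    menu_p = np.array([p for _, p in cfg.pucker_menu])
    conf_idx = rng.choice(len(menu_names), size=n, p=menu_p)
    conformer = np.array([menu_names[i] for i in conf_idx])
    ring_noise = rng.normal(0.0, cfg.pucker_noise_sd, size=(n, 6, 3)) if cfg.pucker_noise_sd > 0 else np.zeros((n, 6, 3))

    # assemble all frame coordinates vectorized over the frame axis
    n_atoms = topo.n_atoms
    xyz = np.zeros((n, n_atoms, 3))
    xyz[:, order["SUG402:O2"]] = _SUGAR_O2
    xyz[:, order["SUG402:C2"]] = _SUGAR_C2
    xyz[:, order["NAD401:O2D"]] = _RIBOSE_O2D
    xyz[:, order["NAD401:O3D"]] = _RIBOSE_O3D
    xyz[:, order["SUG402:O3"]] = _SUGAR_O3
    xyz[:, order["SUG402:O4"]] = _SUGAR_O4

    xyz[:, order["TYR164:OH"]] = _SUGAR_O2 + dist["tyr_oh-sugar_o2"][:, None] * _DIR_TYR
    xyz[:, order["THR124:OG1"]] = _SUGAR_O2 + dist["thr_og-sugar_o2"][:, None] * _DIR_THR
    xyz[:, order["LYS168:NZ"]] = _RIBOSE_O2D + dist["lys_nz-ribose_oh"][:, None] * _DIR_LYS

    # H2 fixed on C2; the nicotinamide C4 placed so that both the
    # donor-acceptor distance and the C2-H2-C4 angle are realized
    h2 = _SUGAR_C2 + _H2_BOND * _DIR_H2
    xyz[:, order["SUG402:H2"]] = h2
    alpha = np.radians(hydride)
    d4 = dist["nad_c4-sugar_c2"]
    disc = d4**2 - (_H2_BOND * np.sin(alpha)) ** 2
    if np.any(disc <= 0):
        f_bad = int(np.argmax(disc <= 0))
        raise InfeasibleGeometryError(
            f"frame {f_bad}: hydride distance {d4[f_bad]:.2f} below the "
            f"geometric minimum for angle {hydride[f_bad]:.1f} deg"
        )
    t = _H2_BOND * np.cos(alpha) + np.sqrt(disc)
    w = np.column_stack([np.sin(alpha), np.zeros(n), -np.cos(alpha)])
    xyz[:, order["NAD401:C4N"]] = h2 + t[:, None] * w

    # pyrophosphate: O1 and P1 fixed, O12 at a 130 deg bond angle,
    # P2 closes the O1-P1-O12-P2 torsion frame by frame
    o1, p1 = _PYRO_O1, _PYRO_P1
    o12 = _place_by_internal(p1 + np.array([0.0, 1.0, 0.0]), o1, p1, 1.6, 130.0, 0.0)
    xyz[:, order["SUG402:O1"]] = o1
    xyz[:, order["SUG402:P1"]] = p1
    xyz[:, order["SUG402:O12"]] = o12
    xyz[:, order["SUG402:P2"]] = _place_torsion_batch(o1, p1, o12, 1.6, 130.0, dihedral)

    for c in cfg.contacts:
        anchor = _SUGAR_O3 if c.target_atom == "O3" else _SUGAR_O4
        xyz[:, order[f"probe:{c.probe_atom}"]] = (
            anchor + contact_dist[c.label][:, None] * _CONTACT_DIRS[c.probe_atom]
        )

    thetas = np.array([CANONICAL_CONFORMERS[c][0] for c in conformer])
    phis = np.array([CANONICAL_CONFORMERS[c][1] for c in conformer])
    ring = _build_ring_batch(cfg.pucker_Q, thetas, phis) + _RING_OFFSET + ring_noise
    for k, rname in enumerate(_RING_ATOMS):
        xyz[:, order[f"PYR403:{rname}"]] = ring[:, k]

    frames = [Frame(f, xyz[f]) for f in range(n)]

    truth = GroundTruth(
        plausible=plausible,
        criterion_distances=pd.DataFrame(dist),
        contacts=pd.DataFrame(contact_flags),
        dihedral=dihedral,
        dihedral_component=dihedral_comp,
        conformer=conformer,
        hydride_angle=hydride,
    )
    return Trajectory(topo, frames), truth


def generate_ring_trajectory(
    pucker_menu,
    n: int,
    noise_sd: float = 0.02,
    seed: int = 0,
    Q: float = 0.57,
) -> tuple[Trajectory, np.ndarray]:
    """Trajectory of a bare six-atom ring sampled from a conformer menu.

    Returns the trajectory and the planted per-frame conformer labels.
    """
    menu = list(pucker_menu.items()) if isinstance(pucker_menu, dict) else list(pucker_menu)
    names = [m[0] for m in menu]
    probs = np.array([m[1] for m in menu], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ConfigurationError("menu probabilities must sum to 1")
    for name in names:
        if name not in CANONICAL_CONFORMERS:
            raise ConfigurationError(f"unknown conformer {name!r}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(names), size=n, p=probs)
    labels = np.array([names[i] for i in idx])
    atoms = [
        AtomRecord(serial=k + 1, name=rname, resname="PYR", resid=1, chain="A",
                   element=rname[0])
        for k, rname in enumerate(_RING_ATOMS)
    ]
    topo = Topology(atoms)
    frames = []
    for f in range(n):
        theta, phi = CANONICAL_CONFORMERS[labels[f]]
        xyz = build_ring(Q, theta, phi)
        if noise_sd > 0:
            xyz = xyz + rng.normal(0.0, noise_sd, size=(6, 3))
        frames.append(Frame(f, xyz))
    return Trajectory(topo, frames), labels
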