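"""Catalytic-plausibility census over conformational ensembles.

The canonical SDR alcohol-oxidation geometry is screened frame by frame with
four heavy-atom distance criteria (default cutoff 3.5 A each):

1. catalytic-base Tyr phenolic O  -- sugar C2-O   (specific pair)
2. Thr side-chain O               -- sugar C2-O   (specific pair)
3. Lys NZ -- nicotinamide-ribose hydroxyl oxygens (min over pairs: either
   hydroxyl within the cutoff suffices; configurable)
4. nicotinamide C4 -- sugar C2 (hydride donor-acceptor, specific pair)

A frame is catalytically plausible when every criterion holds (boundary
d == cutoff passes).  The hydride-transfer C2-H2-C4 angle is reported as a
statistic of the ensemble but does not gate plausibility; an optional angle
gate can be enabled explicitly.  Contact sub-censuses (e.g. side-chain amide
carbons or backbone carbonyl oxygens against the sugar C3/C4 hydroxyl
oxygens) are computed under an explicit denominator: all frames or plausible
frames only, and both can be reported.

The module also carries the small activity-arithmetic helpers used alongside
the ensemble statistics: specific activity from a linear product time course,
fold changes between activities, and turnover numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats
from statsmodels.stats.proportion import proportion_confint

from . import geometry
from .errors import (
    ConfigurationError,
    EmptyInputError,
    EmptySelectionError,
    UndefinedFractionError,
)
from .model_io import Frame, Selection, Topology, Trajectory

__all__ = [
    "DistanceCriterion",
    "CriterionSet",
    "FrameVerdict",
    "CensusResult",
    "ContactSpec",
    "ContactCensusResult",
    "HydrideAngleStats",
    "ActivityResult",
    "FoldChange",
    "default_sdr_criteria",
    "evaluate_frame",
    "census",
    "contact_census",
    "hydride_angle_stats",
    "fold_change",
    "specific_activity",
    "turnover_number",
    "DEFAULT_CUTOFF",
]

#: heavy-atom criterion cutoff (Angstrom) of the canonical SDR screen
DEFAULT_CUTOFF = 3.5


@dataclass(frozen=True)
class DistanceCriterion:
    """One labelled distance rule: probe vs target under a cutoff.

    ``reduction`` is ``"specific-pair"`` (both selections must resolve to a
    single atom) or ``"min-over-pairs"`` (the minimum over all probe x target
    pairs is compared with the cutoff).
    """

    label: str
    probe: Selection
    target: Selection
    cutoff: float = DEFAULT_CUTOFF
    reduction: str = "specific-pair"

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.reduction not in ("specific-pair", "min-over-pairs", "max-over-pairs"):
            raise ValueError(f"unknown reduction {self.reduction!r}")

    def measure(self, frame: Frame, probe_idx: list[int], target_idx: list[int]) -> float:
        if self.reduction == "specific-pair":
            if len(probe_idx) != 1 or len(target_idx) != 1:
                raise ConfigurationError(
                    f"criterion {self.label!r}: specific-pair needs single atoms, "
                    f"got {len(probe_idx)} x {len(target_idx)}"
                )
            return geometry.distance(frame, probe_idx[0], target_idx[0])
        diffs = frame.coordinates[probe_idx][:, None, :] - frame.coordinates[target_idx][None, :, :]
        d = np.sqrt((diffs**2).sum(axis=-1))
        # max-over-pairs: the probe must reach every target atom, so the
        # governing distance is the farthest target's nearest approach
        if self.reduction == "max-over-pairs":
            return float(d.min(axis=0).max())
        return float(d.min())


@dataclass(frozen=True)
class CriterionSet:
    """An all-must-hold conjunction of labelled distance criteria."""

    name: str
    criteria: tuple[DistanceCriterion, ...]

    def __post_init__(self):
        if not self.criteria:
            raise ValueError("a criterion set needs at least one criterion")
        labels = [c.label for c in self.criteria]
        if len(set(labels)) != len(labels):
            raise ValueError("criterion labels must be unique")

    def resolve(self, topology: Topology) -> list[tuple[DistanceCriterion, list[int], list[int]]]:
        out = []
        for c in self.criteria:
            out.append((c, topology.select(c.probe), topology.select(c.target)))
        return out


@dataclass(frozen=True)
class FrameVerdict:
    frame: int
    distances: dict[str, float]
    passes: dict[str, bool]
    plausible: bool  # conjunction of the per-criterion pass flags


@dataclass
class CensusResult:
    """Ensemble fractions with a Wilson 95% CI and per-criterion marginals."""

    criterion_set: CriterionSet
    n_frames: int
    n_plausible: int
    fraction: float
    ci_low: float
    ci_high: float
    marginals: dict[str, float]
    verdicts: pd.DataFrame  # frame, <label>..., plausible

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


_DEFAULT_ROLES = {
    "tyr_oh": "phenolic oxygen of the catalytic Tyr base",
    "thr_og": "Thr side-chain oxygen",
    "lys_nz": "Lys NZ",
    "ribose_oh": "nicotinamide-ribose hydroxyl oxygens of NAD+",
    "nad_c4": "nicotinamide C4 of NAD+",
    "sugar_c2": "sugar C2",
    "sugar_o2": "reactive sugar C2 oxygen",
}


def default_sdr_criteria(
    bindings: dict[str, Selection],
    cutoffs: dict[str, float] | None = None,
    lys_requires_both: bool = False,
) -> CriterionSet:
    """Build the canonical four-criterion SDR screen from named atom bindings.

    ``bindings`` must provide a :class:`Selection` for every role in
    ``tyr_oh, thr_og, lys_nz, ribose_oh, nad_c4, sugar_c2, sugar_o2``.
    ``cutoffs`` overrides individual criterion cutoffs by label (the values
    used are echoed in the returned set).  ``lys_requires_both`` switches the
    Lys criterion from min-over-pairs (either ribose hydroxyl within the
    cutoff suffices, the default) to max-over-pairs (the NZ must be within
    the cutoff of both hydroxyl oxygens simultaneously).
    """
    missing = [role for role in _DEFAULT_ROLES if role not in bindings]
    if missing:
        raise ConfigurationError(
            "missing atom binding(s): "
            + ", ".join(f"{m} ({_DEFAULT_ROLES[m]})" for m in missing)
        )
    cutoffs = dict(cutoffs or {})

    def cut(label: str) -> float:
        return float(cutoffs.get(label, DEFAULT_CUTOFF))

    criteria = [
        DistanceCriterion(
            "tyr_oh-sugar_o2", bindings["tyr_oh"], bindings["sugar_o2"], cut("tyr_oh-sugar_o2")
        ),
        DistanceCriterion(
            "thr_og-sugar_o2", bindings["thr_og"], bindings["sugar_o2"], cut("thr_og-sugar_o2")
        ),
    ]
    if lys_requires_both:
        # stricter reading: the Lys NZ must reach both ribose hydroxyls
        criteria.append(
            DistanceCriterion(
                "lys_nz-ribose_oh",
                bindings["lys_nz"],
                bindings["ribose_oh"],
                cut("lys_nz-ribose_oh"),
                reduction="max-over-pairs",
            )
        )
    else:
        criteria.append(
            DistanceCriterion(
                "lys_nz-ribose_oh",
                bindings["lys_nz"],
                bindings["ribose_oh"],
                cut("lys_nz-ribose_oh"),
                reduction="min-over-pairs",
            )
        )
    criteria.append(
        DistanceCriterion(
            "nad_c4-sugar_c2", bindings["nad_c4"], bindings["sugar_c2"], cut("nad_c4-sugar_c2")
        )
    )
    return CriterionSet(name="canonical-sdr", criteria=tuple(criteria))


def evaluate_frame(
    frame: Frame,
    cs: CriterionSet,
    topology: Topology,
    resolved=None,
) -> FrameVerdict:
    """Evaluate all criteria on one frame; plausible is their conjunction.

    Boundary semantics: a measured distance exactly equal to the cutoff
    passes (<= comparison).
    """
    resolved = resolved if resolved is not None else cs.resolve(topology)
    distances, passes = {}, {}
    for criterion, probe_idx, target_idx in resolved:
        d = criterion.measure(frame, probe_idx, target_idx)
        distances[criterion.label] = d
        passes[criterion.label] = d <= criterion.cutoff
    return FrameVerdict(
        frame=frame.index,
        distances=distances,
        passes=passes,
        plausible=all(passes.values()),
    )


def census(traj: Trajectory, cs: CriterionSet, alpha: float = 0.05) -> CensusResult:
    """Fraction of catalytically plausible frames with a Wilson CI."""
    resolved = cs.resolve(traj.topology)
    rows = []
    for frame in traj:
        v = evaluate_frame(frame, cs, traj.topology, resolved)
        row = {"frame": v.frame}
        for label in v.distances:
            row[label] = v.distances[label]
            row[f"{label}_pass"] = v.passes[label]
        row["plausible"] = v.plausible
        rows.append(row)
    verdicts = pd.DataFrame(rows)
    n = len(verdicts)
    k = int(verdicts["plausible"].sum())
    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    marginals = {
        c.label: float(verdicts[f"{c.label}_pass"].mean()) for c in cs.criteria
    }
    return CensusResult(
        criterion_set=cs,
        n_frames=n,
        n_plausible=k,
        fraction=k / n,
        ci_low=float(lo),
        ci_high=float(hi),
        marginals=marginals,
        verdicts=verdicts,
    )


@dataclass(frozen=True)
class ContactSpec:
    """A labelled probe-target contact with an explicit denominator.

    ``cutoff`` defaults to 3.5 A; side-chain amide carbon probes (where the
    amide O/N orientation cannot be predefined) conventionally use 4.0 A.
    ``denominator`` is ``"all-frames"`` or ``"plausible-frames"``.
    """

    label: str
    probe: Selection
    target: Selection
    cutoff: float = DEFAULT_CUTOFF
    denominator: str = "all-frames"

    def __post_init__(self):
        if self.denominator not in ("all-frames", "plausible-frames"):
            raise ValueError(f"unknown denominator {self.denominator!r}")


@dataclass
class ContactCensusResult:
    spec: ContactSpec
    n_denominator: int
    n_contact: int
    fraction: float
    per_frame: np.ndarray  # bool, over the denominator frames (file order)

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


def contact_census(
    traj: Trajectory,
    contact: ContactSpec,
    verdicts: pd.DataFrame | np.ndarray | None = None,
) -> ContactCensusResult:
    """Fraction of denominator frames with min probe-target distance <= cutoff."""
    probe_idx = traj.topology.select(contact.probe)
    target_idx = traj.topology.select(contact.target)
    if contact.denominator == "plausible-frames":
        if verdicts is None:
            raise UndefinedFractionError(
                "plausible-frames denominator requires per-frame verdicts"
            )
        mask = (
            verdicts["plausible"].to_numpy()
            if isinstance(verdicts, pd.DataFrame)
            else np.asarray(verdicts, dtype=bool)
        )
    else:
        mask = np.ones(traj.n_frames, dtype=bool)
    if mask.sum() == 0:
        raise UndefinedFractionError(
            f"contact {contact.label!r}: empty denominator ({contact.denominator})"
        )
    hits = []
    for frame, keep in zip(traj, mask):
        if not keep:
            continue
        diffs = (
            frame.coordinates[probe_idx][:, None, :]
            - frame.coordinates[target_idx][None, :, :]
        )
        dmin = float(np.sqrt((diffs**2).sum(axis=-1)).min())
        hits.append(dmin <= contact.cutoff)
    per_frame = np.array(hits, dtype=bool)
    n_den = int(mask.sum())
    n_hit = int(per_frame.sum())
    return ContactCensusResult(
        spec=contact,
        n_denominator=n_den,
        n_contact=n_hit,
        fraction=n_hit / n_den,
        per_frame=per_frame,
    )


@dataclass
class HydrideAngleStats:
    mean: float
    sd: float
    max: float
    n: int
    series: np.ndarray  # degrees, over the evaluated frames


def hydride_angle_stats(
    traj: Trajectory,
    c2: Selection,
    h2: Selection,
    nad_c4: Selection,
    restrict_to: np.ndarray | pd.DataFrame | None = None,
) -> HydrideAngleStats:
    """C2-H2-C4 angle statistics (vertex at the explicit H2 hydrogen).

    ``restrict_to`` optionally limits the frames (e.g. to the plausible set).
    A missing H2 raises an explicit error; hydrogens are never reconstructed.
    """
    try:
        i_h2 = traj.topology.select(h2)
    except EmptySelectionError as exc:
        raise EmptySelectionError(
            f"explicit H2 hydrogen not found in topology ({exc}); "
            "hydrogen positions are not reconstructed"
        ) from exc
    i_c2 = traj.topology.select(c2)
    i_c4 = traj.topology.select(nad_c4)
    if len(i_c2) != 1 or len(i_h2) != 1 or len(i_c4) != 1:
        raise ConfigurationError("hydride-angle selections must be single atoms")
    if restrict_to is None:
        mask = np.ones(traj.n_frames, dtype=bool)
    elif isinstance(restrict_to, pd.DataFrame):
        mask = restrict_to["plausible"].to_numpy()
    else:
        mask = np.asarray(restrict_to, dtype=bool)
    values = [
        geometry.angle(frame, i_c2[0], i_h2[0], i_c4[0])
        for frame, keep in zip(traj, mask)
        if keep
    ]
    if not values:
        raise EmptyInputError("no frames selected for hydride-angle statistics")
    arr = np.array(values)
    return HydrideAngleStats(
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        max=float(arr.max()),
        n=len(arr),
        series=arr,
    )


# ---------------------------------------------------------------------------
# activity arithmetic
# ---------------------------------------------------------------------------


def _round_sig(x: float, sig: int = 2) -> float:
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


@dataclass(frozen=True)
class FoldChange:
    ratio: float           # raw a / b
    display: float         # rounded to 2 significant figures

    def __str__(self) -> str:
        d = self.display
        return f"{d:g}-fold"


def fold_change(a: float, b: float) -> FoldChange:
    """Activity ratio a / b, displayed to 2 significant figures.

    b = 0 has no defined ratio (report "ND" semantics upstream instead).
    """
    if b == 0:
        raise ZeroDivisionError("fold change undefined for zero reference (ND)")
    r = a / b
    return FoldChange(ratio=r, display=_round_sig(r, 2))


@dataclass(frozen=True)
class ActivityResult:
    """Specific activity from a linear product time course.

    slope: mM min^-1; enzyme_conc: mg ml^-1; specific_activity: mU mg^-1
    (1 U = 1 umol product min^-1); turnover: min^-1 when a molar mass was
    supplied.
    """

    slope: float
    enzyme_conc: float
    specific_activity: float
    r_squared: float
    turnover: float | None = None


def specific_activity(
    timecourse,
    enzyme_conc: float,
    linear_window: slice | tuple[int, int] | None = None,
    molar_mass: float | None = None,
) -> ActivityResult:
    """OLS slope of (t / min, product / mM) pairs over the linear window.

    Dividing the slope (mM min^-1) by the enzyme concentration (mg ml^-1)
    gives umol min^-1 mg^-1; the result is reported in mU mg^-1.  If a molar
    mass (g mol^-1) is given, the turnover number k (min^-1) is included.
    """
    if enzyme_conc <= 0:
        raise ValueError("enzyme concentration must be positive")
    arr = np.asarray(timecourse, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("timecourse must be (t, product) pairs")
    if linear_window is not None:
        if isinstance(linear_window, tuple):
            linear_window = slice(*linear_window)
        arr = arr[linear_window]
    if arr.shape[0] < 3:
        raise EmptyInputError("need at least 3 points in the linear window")
    fit = _scipy_stats.linregress(arr[:, 0], arr[:, 1])
    sa = fit.slope / enzyme_conc * 1000.0  # mM/min / (mg/ml) -> mU/mg
    k = turnover_number(sa, molar_mass) if molar_mass is not None else None
    return ActivityResult(
        slope=float(fit.slope),
        enzyme_conc=enzyme_conc,
        specific_activity=float(sa),
        r_squared=float(fit.rvalue**2),
        turnover=k,
    )


def turnover_number(specific_activity_mU_mg: float, molar_mass: float) -> float:
    """k (min^-1) = specific activity (mU mg^-1) x 1e-6 x molar mass (g mol^-1)."""
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    return float(specific_activity_mU_mg * 1e-6 * molar_mass)
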