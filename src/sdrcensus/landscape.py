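"""Histogram-based free-energy landscapes and circular torsion statistics.

Potentials of mean force are estimated as F = -kB T ln(n / n_max) over one-
or two-dimensional histograms of collective variables (a torsion and/or a
heavy-atom distance).  The reference is the most populated bin (F = 0 there);
empty bins are masked rather than assigned infinities or pseudo-counts, so no
barrier height is ever fabricated from unsampled space.  Default temperature
is 333 K, the production temperature of the simulations this analysis is
aimed at; default bin widths are 5 deg for torsion axes and 0.25 A for
distance axes.

Dihedral axes are periodic: samples are wrapped onto [-180, 180) and the bin
grid tiles the full circle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyInputError

__all__ = [
    "KB_KCAL",
    "DEFAULT_TEMPERATURE",
    "Histogram2D",
    "FreeEnergySurface",
    "Basin",
    "DihedralSeries",
    "histogram2d",
    "pmf",
    "pmf1d",
    "find_basins",
    "circular_mode",
    "circular_stats",
    "wrap_degrees",
]

#: Boltzmann constant, kcal mol^-1 K^-1
KB_KCAL = 0.0019872041

#: production temperature (K) of the target simulations
DEFAULT_TEMPERATURE = 333.0

DEFAULT_DIHEDRAL_BINWIDTH = 5.0   # deg
DEFAULT_DISTANCE_BINWIDTH = 0.25  # Angstrom


def wrap_degrees(x) -> np.ndarray:
    """Wrap angles onto [-180, 180)."""
    return (np.asarray(x, dtype=float) + 180.0) % 360.0 - 180.0


def _axis_edges(samples: np.ndarray, binwidth: float, periodic: bool) -> np.ndarray:
    if binwidth <= 0:
        raise ValueError("binwidth must be positive")
    if periodic:
        n = int(round(360.0 / binwidth))
        if abs(n * binwidth - 360.0) > 1e-9:
            raise ValueError("periodic binwidth must divide 360 degrees")
        return -180.0 + binwidth * np.arange(n + 1)
    lo = np.floor(samples.min() / binwidth) * binwidth
    # top edge strictly above the maximum, so a sample sitting exactly on an
    # interior grid line is counted in its upper (half-open) bin
    hi = np.floor(samples.max() / binwidth) * binwidth + binwidth
    n = int(round((hi - lo) / binwidth))
    return lo + binwidth * np.arange(n + 1)


@dataclass
class Histogram2D:
    """Binned sample counts; half-open bins [lo, hi), top edge closed."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray  # shape (nx, ny), integer

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())


def histogram2d(
    x,
    y,
    x_binwidth: float = DEFAULT_DIHEDRAL_BINWIDTH,
    y_binwidth: float = DEFAULT_DISTANCE_BINWIDTH,
    x_periodic: bool = False,
    y_periodic: bool = False,
) -> Histogram2D:
    """2D histogram of two equal-length CV series.

    Periodic (torsion) axes wrap samples at +/-180 deg and tile the circle.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise EmptyInputError("empty sample series")
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x_periodic:
        x = wrap_degrees(x)
    if y_periodic:
        y = wrap_degrees(y)
    xe = _axis_edges(x, x_binwidth, x_periodic)
    ye = _axis_edges(y, y_binwidth, y_periodic)
    counts, _, _ = np.histogram2d(x, y, bins=[xe, ye])
    return Histogram2D(x_edges=xe, y_edges=ye, counts=counts.astype(int))


@dataclass
class FreeEnergySurface:
    """F = -kB T ln(n / n_max), referenced to the most populated bin.

    ``mask`` is True on empty bins, which carry no F value.
    """

    x_centers: np.ndarray
    y_centers: np.ndarray
    F: np.ndarray          # kcal mol^-1; np.nan on masked bins
    mask: np.ndarray       # True where the bin is empty
    temperature: float

    def fmin(self) -> float:
        return float(np.nanmin(self.F))

    def fmax(self) -> float:
        return float(np.nanmax(self.F))


def pmf(h: Histogram2D, temperature: float = DEFAULT_TEMPERATURE) -> FreeEnergySurface:
    """Free-energy surface from a 2D histogram (kcal mol^-1)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    counts = h.counts
    nmax = counts.max()
    if nmax == 0:
        raise EmptyInputError("all-empty histogram")
    mask = counts == 0
    F = np.full(counts.shape, np.nan)
    with np.errstate(divide="ignore"):
        F[~mask] = -KB_KCAL * temperature * np.log(counts[~mask] / nmax)
    return FreeEnergySurface(
        x_centers=h.x_centers,
        y_centers=h.y_centers,
        F=F,
        mask=mask,
        temperature=temperature,
    )


def pmf1d(
    samples,
    binwidth: float = DEFAULT_DIHEDRAL_BINWIDTH,
    temperature: float = DEFAULT_TEMPERATURE,
    periodic: bool = True,
):
    """1D PMF convenience: returns (bin centers, F, counts)."""
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise EmptyInputError("empty sample series")
    if periodic:
        x = wrap_degrees(x)
    edges = _axis_edges(x, binwidth, periodic)
    counts, _ = np.histogram(x, bins=edges)
    nmax = counts.max()
    F = np.full(counts.shape, np.nan)
    nz = counts > 0
    F[nz] = -KB_KCAL * temperature * np.log(counts[nz] / nmax)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, F, counts


@dataclass(frozen=True)
class Basin:
    """A local minimum of a free-energy surface (bin-center resolution)."""

    x: float
    y: float
    F: float
    index: tuple[int, int]


def find_basins(s: FreeEnergySurface, max_F: float = np.inf) -> list[Basin]:
    """Unmasked local minima (8-neighborhood) with F <= max_F, ascending in F.

    Plateaus of equal F collapse to the lowest flat (row-major) bin index.
    Masked neighbors do not veto a minimum; they simply do not compete.
    """
    F = s.F
    nx, ny = F.shape
    candidates = []
    for i in range(nx):
        for j in range(ny):
            if s.mask[i, j] or F[i, j] > max_F:
                continue
            ok = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < nx and 0 <= jj < ny and not s.mask[ii, jj]:
                        if F[ii, jj] < F[i, j]:
                            ok = False
                            break
                if not ok:
                    break
            if ok:
                candidates.append((i, j))
    # collapse plateaus: connected candidates with equal F keep the lowest index
    kept: list[tuple[int, int]] = []
    used = set()
    cand = set(candidates)
    for start in sorted(candidates):
        if start in used:
            continue
        stack, comp = [start], []
        used.add(start)
        while stack:
            i, j = stack.pop()
            comp.append((i, j))
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    nb = (i + di, j + dj)
                    if nb in cand and nb not in used and np.isclose(F[nb], F[i, j]):
                        used.add(nb)
                        stack.append(nb)
        kept.append(min(comp))
    basins = [
        Basin(
            x=float(s.x_centers[i]),
            y=float(s.y_centers[j]),
            F=float(F[i, j]),
            index=(i, j),
        )
        for i, j in kept
    ]
    return sorted(basins, key=lambda b: (b.F, b.index))


@dataclass
class DihedralSeries:
    """Per-frame torsion values in degrees on (-180, 180]."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise EmptyInputError("empty dihedral series")


def circular_mode(d: DihedralSeries | np.ndarray, binwidth: float = 5.0) -> dict:
    """Most populated wrapped-histogram bin of a torsion series.

    Returns ``{"mode": center_deg, "half_width": binwidth/2, "count": n}``.
    Count ties break toward the bin center of smaller absolute angle.
    """
    values = d.values if isinstance(d, DihedralSeries) else np.asarray(d, dtype=float)
    if values.size == 0:
        raise EmptyInputError("empty dihedral series")
    x = wrap_degrees(values)
    edges = _axis_edges(x, binwidth, periodic=True)
    counts, _ = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    best = counts.max()
    tied = np.flatnonzero(counts == best)
    pick = tied[np.lexsort((centers[tied], np.abs(centers[tied])))[0]]
    return {
        "mode": float(centers[pick]),
        "half_width": binwidth / 2.0,
        "count": int(best),
    }


def circular_stats(d: DihedralSeries | np.ndarray) -> dict:
    """Circular mean (deg) and resultant length R in [0, 1].

    When R ~ 0 (e.g. an antipodal pair) the mean direction is undefined and
    flagged via ``mean_defined=False``.
    """
    values = d.values if isinstance(d, DihedralSeries) else np.asarray(d, dtype=float)
    if values.size == 0:
        raise EmptyInputError("empty dihedral series")
    rad = np.radians(values)
    c = np.cos(rad).mean()
    s = np.sin(rad).mean()
    r = float(np.hypot(c, s))
    defined = r > 1e-9
    mean = float(np.degrees(np.arctan2(s, c))) if defined else float("nan")
    return {"mean": mean, "resultant_length": r, "mean_defined": defined}
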