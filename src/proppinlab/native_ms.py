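"""Native-ESI charge-series assignment and oligomer intensity summaries.

A folded n-mer of monomer mass M appears as a series of peaks at
m/z = (n*M + z*proton)/z over consecutive charges z.  This module picks
peaks from an m/z-intensity list, assigns each peak to the (n, z) pair
minimizing ppm error, and reports per-order mass estimates and relative
intensities (percent of monomer).  Proton is the only adduct ion
considered; there is no isotope-resolved processing.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .chem import PROTON_MASS


@dataclass(frozen=True)
class PeakList:
    """An m/z-intensity list, ascending in m/z."""

    mz: np.ndarray  # Th
    intensity: np.ndarray  # a.u.

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.ndim != 1 or mz.shape != inten.shape:
            raise ValueError("mz and intensity must be 1-D of equal length")
        if mz.size == 0:
            raise ValueError("empty peak list")
        if not np.all(mz > 0):
            raise ValueError("m/z values must be > 0")
        if not np.all(np.diff(mz) > 0):
            raise ValueError("m/z values must be strictly ascending")
        if np.any(inten < 0):
            raise ValueError("intensities must be >= 0")


def mz_for(order: int, monomer_mass: float, charge: int) -> float:
    """m/z of an ``order``-mer at charge z: (n*M + z*proton)/z."""
    if order < 1 or charge < 1:
        raise ValueError("order and charge must be >= 1")
    if not monomer_mass > 0:
        raise ValueError("monomer_mass must be > 0")
    return (order * monomer_mass + charge * PROTON_MASS) / charge


def neutral_from_mz(mz: float, charge: int) -> float:
    """Neutral mass from an m/z at charge z (inverse of ``mz_for``)."""
    return charge * (mz - PROTON_MASS)


def pick_peaks(peaks: PeakList, rel_floor: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Local maxima above ``rel_floor`` of the base peak.

    Apex positions are refined by 3-point parabolic interpolation so that
    assignment errors are not limited by the sampling grid.  Returns
    (mz, height) arrays.
    """
    y = peaks.intensity
    x = peaks.mz
    if y.size < 3:
        idx = np.array([int(np.argmax(y))])
    else:
        idx = (
            np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:]))
            + 1
        )
    floor = rel_floor * y.max()
    idx = idx[y[idx] >= floor]
    mzs, heights = [], []
    for i in idx:
        if 0 < i < y.size - 1:
            denom = y[i - 1] - 2 * y[i] + y[i + 1]
            if denom != 0:
                shift = 0.5 * (y[i - 1] - y[i + 1]) / denom
                shift = float(np.clip(shift, -0.5, 0.5))
                mzs.append(x[i] + shift * (x[min(i + 1, y.size - 1)] - x[i - 1]) / 2)
                heights.append(y[i] - 0.25 * (y[i - 1] - y[i + 1]) * shift)
                continue
        mzs.append(x[i])
        heights.append(y[i])
    return np.asarray(mzs), np.asarray(heights)


@dataclass(frozen=True)
class PeakAssignment:
    mz: float
    intensity: float
    order: int
    charge: int
    ppm: float
    neutral_mass: float  # n * M estimate from this peak


@dataclass(frozen=True)
class Assignments:
    """Charge-series assignment of a picked peak set."""

    assigned: tuple  # PeakAssignment
    unassigned: tuple  # (mz, intensity)
    monomer_mass: float
    tol_ppm: float
    ambiguous: bool  # True when only even orders appear (2M-monomer degeneracy)

    @property
    def total_intensity(self) -> float:
        return float(
            sum(a.intensity for a in self.assigned)
            + sum(i for _, i in self.unassigned)
        )


def _assign_picked(
    mzs: np.ndarray,
    heights: np.ndarray,
    monomer_mass: float,
    n_max: int,
    charges: range,
    tol_ppm: float,
) -> tuple[list, list]:
    assigned, unassigned = [], []
    for mz, h in zip(mzs, heights):
        best = None
        for n in range(1, n_max + 1):  # ascending n: degenerate ties keep smallest n
            for z in charges:
                theo = mz_for(n, monomer_mass, z)
                ppm = (mz - theo) / theo * 1e6
                if abs(ppm) <= tol_ppm and (
                    best is None or abs(ppm) < abs(best[2]) - 1e-9
                ):
                    best = (n, z, ppm)
        if best is None:
            unassigned.append((float(mz), float(h)))
        else:
            n, z, ppm = best
            assigned.append(
                PeakAssignment(
                    mz=float(mz),
                    intensity=float(h),
                    order=n,
                    charge=z,
                    ppm=float(ppm),
                    neutral_mass=neutral_from_mz(mz, z),
                )
            )
    return assigned, unassigned


def assign_peaks(
    peaks: PeakList,
    monomer_mass: float | tuple,
    n_max: int = 4,
    charge_range: tuple = (10, 20),
    tol_ppm: float = 50.0,
    rel_floor: float = 0.01,
) -> Assignments:
    """Assign picked peaks to oligomer order / charge pairs.

    ``monomer_mass`` is either a known mass (Da) or a (low, high) search
    window; in the latter case the window is grid-searched for the mass
    maximizing total assigned intensity, then refined from the assigned
    peaks.  Degenerate (n, z) pairs with identical theoretical m/z are
    resolved toward the smallest n; if only even orders are then seen the
    result is flagged ambiguous (a monomer of mass 2M would fit equally).
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if not tol_ppm > 0:
        raise ValueError("tol_ppm must be > 0")
    charges = range(charge_range[0], charge_range[1] + 1)
    mzs, heights = pick_peaks(peaks, rel_floor=rel_floor)
    if mzs.size == 0:
        raise ValueError("no peaks above the picking floor")

    if isinstance(monomer_mass, (tuple, list)):
        lo, hi = monomer_mass
        grid = np.linspace(lo, hi, 2001)
        scores = []
        for m in grid:
            a, _ = _assign_picked(mzs, heights, m, n_max, charges, tol_ppm)
            scores.append(sum(x.intensity for x in a))
        m0 = float(grid[int(np.argmax(scores))])
        a, _ = _assign_picked(mzs, heights, m0, n_max, charges, tol_ppm)
        if a:  # refine: intensity-weighted monomer mass from assignments
            w = np.array([x.intensity for x in a])
            est = np.array([x.neutral_mass / x.order for x in a])
            monomer_mass = float(np.average(est, weights=w))
        else:
            monomer_mass = m0
    monomer_mass = float(monomer_mass)

    assigned, unassigned = _assign_picked(
        mzs, heights, monomer_mass, n_max, charges, tol_ppm
    )
    orders = {a.order for a in assigned}
    ambiguous = bool(orders) and all(n % 2 == 0 for n in orders) and n_max >= 2
    return Assignments(
        assigned=tuple(assigned),
        unassigned=tuple(unassigned),
        monomer_mass=monomer_mass,
        tol_ppm=tol_ppm,
        ambiguous=ambiguous,
    )


@dataclass(frozen=True)
class OligomerResult:
    """Per-order mass and intensity summary of a charge-series assignment."""

    order: int
    mass: float  # Da, intensity-weighted mean of per-peak neutral masses
    mass_sd: float  # Da, SD across charge states
    n_peaks: int
    total_intensity: float
    rel_intensity: float  # percent of monomer (or of the most abundant order)

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.rel_intensity < 0:
            raise ValueError("relative intensity must be >= 0")


def oligomer_intensities(assignments: Assignments) -> list[OligomerResult]:
    """Summarize assignments per oligomer order.

    Relative intensities are percentages of the monomer; if no monomer
    peaks were assigned, the most abundant order is used as the 100%
    reference and a warning is emitted.
    """
    if not assignments.assigned:
        raise ValueError("no assigned peaks to summarize")
    by_order: dict[int, list[PeakAssignment]] = {}
    for a in assignments.assigned:
        by_order.setdefault(a.order, []).append(a)
    totals = {n: sum(a.intensity for a in v) for n, v in by_order.items()}
    if 1 in totals:
        ref = totals[1]
    else:
        ref = max(totals.values())
        warnings.warn(
            "monomer absent from assignments; relative intensities are "
            "normalized to the most abundant order",
            UserWarning,
            stacklevel=2,
        )
    out = []
    for n in sorted(by_order):
        grp = by_order[n]
        masses = np.array([a.neutral_mass for a in grp])
        weights = np.array([a.intensity for a in grp])
        out.append(
            OligomerResult(
                order=n,
                mass=float(np.average(masses, weights=weights)),
                mass_sd=float(np.std(masses)),
                n_peaks=len(grp),
                total_intensity=float(totals[n]),
                rel_intensity=float(100.0 * totals[n] / ref),
            )
        )
    return out
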