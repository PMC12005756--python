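"""EIC-based relative quantification of Fc/2 proteoforms.

Quantification follows the intact-subunit scheme: for every species an
extracted ion chromatogram (EIC) is built from exactly three consecutive
charge states, with m/z borders derived from the base peak and a TOF
resolving power of 15000; peak areas are integrated by the trapezoid
rule; all reported quantities are relative (glycoform profiles per
allotype, allotype and subclass abundances, PTM levels against the
unmodified H3N4F1 anchor, and Cₕ3-site occupancy of IgG3 via the doubly
glycosylated H5N2,H3N4F1 glycoform).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np

from .proteoforms import PROTON_MASS, ProteoformSpecies
from .signal import SpectrumRun

__all__ = [
    "EICDefinition",
    "Chromatogram",
    "build_eic",
    "integrate_peak",
    "find_apex",
    "glycoform_profile",
    "subclass_average",
    "allotype_ratio",
    "ch3_occupancy",
    "intact_occupancy",
    "ptm_level",
]

# default triangular charge envelope used to rank candidate charge triplets
DEFAULT_CHARGES = (18, 19, 20, 21, 22)
DEFAULT_CHARGE_WEIGHTS = (1.0, 2.0, 3.0, 2.0, 1.0)


def _mz_for(mass: float, z: int) -> float:
    return (mass + z * PROTON_MASS) / z


@dataclass(frozen=True)
class EICDefinition:
    """Three consecutive charge states and their m/z integration windows."""

    species: ProteoformSpecies
    charges: Tuple[int, int, int]
    mz_windows: Tuple[Tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.charges) != 3 or len(self.mz_windows) != 3:
            raise ValueError("an EIC uses exactly 3 charge states")
        if tuple(sorted(self.charges)) != tuple(range(min(self.charges), min(self.charges) + 3)):
            raise ValueError("charge states must be consecutive")

    @classmethod
    def for_species(
        cls,
        species: ProteoformSpecies,
        charges: Optional[Tuple[int, int, int]] = None,
        charge_pool: Sequence[int] = DEFAULT_CHARGES,
        charge_weights: Sequence[float] = DEFAULT_CHARGE_WEIGHTS,
        resolution: float = 15000.0,
        w: float = 2.0,
        mz_window: Tuple[float, float] = (1000.0, 1600.0),
    ) -> "EICDefinition":
        """Build an EIC definition for a species.

        If ``charges`` is omitted, the 3 consecutive charges from the
        pool with the largest summed envelope weight whose windows fall
        inside ``mz_window`` are chosen.  Passing explicit ``charges``
        (e.g. the triplet fixed for an allotype from its reference
        glycoform) keeps windows of all glycoforms of that allotype
        internally consistent.
        """
        mass = species.mass_avg
        if charges is None:
            pool = list(charge_pool)
            wts = dict(zip(pool, charge_weights))
            best, best_score = None, -1.0
            for i in range(len(pool) - 2):
                triplet = tuple(pool[i : i + 3])
                lo = _mz_for(mass, max(triplet))
                hi = _mz_for(mass, min(triplet))
                if lo < mz_window[0] or hi > mz_window[1]:
                    continue
                score = sum(wts[z] for z in triplet)
                if score > best_score:
                    best, best_score = triplet, score
            if best is None:
                raise ValueError(
                    f"no 3 consecutive charges place {mass:.1f} Da inside m/z "
                    f"{mz_window[0]:.0f}-{mz_window[1]:.0f}"
                )
            charges = best  # type: ignore[assignment]
        windows = []
        for z in charges:
            mz0 = _mz_for(mass, z)
            fwhm = mz0 / resolution
            windows.append((mz0 - w * fwhm, mz0 + w * fwhm))
        return cls(species, tuple(charges), tuple(windows))


@dataclass
class Chromatogram:
    rts: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.rts = np.asarray(self.rts, float)
        self.values = np.asarray(self.values, float)


def build_eic(run: SpectrumRun, definition: EICDefinition) -> Chromatogram:
    """Sum intensities within the 3 m/z windows, per scan."""
    in_range = [
        w for w in definition.mz_windows if w[1] >= run.mz[0] and w[0] <= run.mz[-1]
    ]
    if not in_range:
        raise ValueError(
            f"all EIC windows of {definition.species.label} fall outside the "
            "acquired m/z range"
        )
    values = np.zeros(run.n_scans)
    for lo, hi in in_range:
        i0 = int(np.searchsorted(run.mz, lo, side="left"))
        i1 = int(np.searchsorted(run.mz, hi, side="right"))
        if i1 > i0:
            values += run.intensity[:, i0:i1].sum(axis=1)
    return Chromatogram(run.rts, values)


def integrate_peak(chrom: Chromatogram, rt_window: Tuple[float, float]) -> float:
    """Trapezoidal area of the chromatogram above zero within ``rt_window``."""
    lo, hi = rt_window
    sel = (chrom.rts >= lo) & (chrom.rts <= hi)
    if sel.sum() < 2:
        warnings.warn("empty or single-point integration window; area set to 0")
        return 0.0
    return float(np.trapezoid(np.clip(chrom.values[sel], 0.0, None), chrom.rts[sel]))


def find_apex(chrom: Chromatogram) -> Tuple[float, float]:
    """Apex retention time and height, with 3-point parabolic refinement."""
    if chrom.values.size == 0:
        return math.nan, 0.0
    i = int(np.argmax(chrom.values))
    rt, h = float(chrom.rts[i]), float(chrom.values[i])
    if 0 < i < chrom.values.size - 1:
        y0, y1, y2 = chrom.values[i - 1 : i + 2]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            delta = 0.5 * (y0 - y2) / denom
            step = (chrom.rts[i + 1] - chrom.rts[i - 1]) / 2.0
            rt = float(chrom.rts[i] + delta * step)
    return rt, h


def glycoform_profile(areas: Mapping[str, float]) -> Optional[Dict[str, float]]:
    """Relative glycoform abundances (percent) within one allotype.

    The caller passes only the unmodified glycan-bearing species of the
    allotype (PTM variants are excluded from this denominator).  Returns
    ``None`` (NA) when nothing was detected.
    """
    total = float(sum(areas.values()))
    if total <= 0:
        return None
    return {k: 100.0 * v / total for k, v in areas.items()}


def subclass_average(
    profiles: Mapping[str, Mapping[str, float]],
    allotype_abundances: Mapping[str, float],
) -> Dict[str, float]:
    """Abundance-weighted mean glycoform profile over 1-2 allotypes."""
    names = [n for n in profiles if profiles[n] is not None]
    if not names:
        return {}
    weights = np.array([allotype_abundances.get(n, 0.0) for n in names], float)
    if weights.sum() <= 0:
        weights = np.ones(len(names))
    weights = weights / weights.sum()
    keys = sorted({k for n in names for k in profiles[n]})
    return {
        k: float(sum(w * profiles[n].get(k, 0.0) for w, n in zip(weights, names)))
        for k in keys
    }


def allotype_ratio(a1_area: float, a2_area: float) -> float:
    """Fraction of the first allotype, a1/(a1+a2), over all glycoforms."""
    total = a1_area + a2_area
    if total <= 0:
        return math.nan
    return a1_area / total


def ch3_occupancy(
    area_double_anchor: float,
    rel_abund_anchor_among_double: float,
    area_single_total: float,
) -> float:
    """Cₕ3-site occupancy of IgG3 Fc/2 from the doubly glycosylated anchor.

    The anchor is the doubly glycosylated species carrying H3N4F1 on Cₕ2
    and H5N2 on Cₕ3.  Its EIC peak area divided by its relative
    abundance among all doubly glycosylated glycoforms (from the
    deconvoluted mass spectrum) gives the total doubly glycosylated
    area; occupancy is that total against total-plus-singly.
    """
    if not (0.0 < rel_abund_anchor_among_double <= 1.0):
        return math.nan
    total_double = area_double_anchor / rel_abund_anchor_among_double
    denom = total_double + area_single_total
    if denom <= 0:
        return math.nan
    return total_double / denom


def intact_occupancy(p: float) -> float:
    """Convert Fc/2 (single-chain) occupancy to the intact-IgG3 level.

    Assuming heavy-chain pairing is independent of site occupancy, the
    fraction of intact molecules carrying at least one Cₕ3 glycan is
    1 - (1-p)^2.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("occupancy must lie in [0, 1]")
    return 1.0 - (1.0 - p) ** 2


def ptm_level(
    area_modified: float, area_unmodified: float, bounded: bool = True
) -> float:
    """PTM level from the modified vs non-modified H3N4F1 glycoform pair.

    ``bounded`` (default) returns 100*mod/(mod+unmod) so the value is a
    percentage of the anchor pool; ``bounded=False`` returns the plain
    ratio 100*mod/unmod.
    """
    if area_unmodified <= 0 and area_modified <= 0:
        return math.nan
    if bounded:
        return 100.0 * area_modified / (area_modified + area_unmodified)
    if area_unmodified <= 0:
        return math.nan
    return 100.0 * area_modified / area_unmodified
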