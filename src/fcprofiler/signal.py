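"""Spectrum preprocessing and zero-charge deconvolution.

The chain mirrors a typical intact-subunit LC-MS workflow: per-spectrum
Gaussian smoothing, morphological (tophat) baseline subtraction,
anchor-based retention-time alignment across runs, and deconvolution of
the multiply charged m/z domain onto a 1 Da zero-charge mass grid.

Deconvolution is a direct charge-assignment summation: for every
candidate mass M the intensities interpolated at (M + z*mp)/z are
combined over the charge list.  A charge-support filter (a real species
shows coherent signal on several charge states, a harmonic ghost on only
one) and a robust median combination are provided to suppress
wrong-charge artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .proteoforms import PROTON_MASS

__all__ = [
    "SpectrumRun",
    "DeconvolvedSpectrum",
    "smooth_scan",
    "smooth_run",
    "baseline_tophat_scan",
    "baseline_tophat_run",
    "preprocess_run",
    "deconvolve",
    "align_runs",
]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class SpectrumRun:
    """Time-ordered MS1 spectra of one LC-MS run on a shared m/z grid.

    ``intensity`` has shape (n_scans, n_mz); ``rts`` is strictly
    increasing in seconds.
    """

    rts: np.ndarray
    mz: np.ndarray
    intensity: np.ndarray
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rts = np.asarray(self.rts, dtype=float)
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (self.rts.size, self.mz.size):
            raise ValueError("intensity shape must be (n_scans, n_mz)")
        if self.rts.size > 1 and not np.all(np.diff(self.rts) > 0):
            raise ValueError("retention times must be strictly increasing")

    @property
    def n_scans(self) -> int:
        return self.rts.size

    def scan(self, i: int) -> Tuple[float, np.ndarray, np.ndarray]:
        return float(self.rts[i]), self.mz, self.intensity[i]

    def summed_spectrum(self, rt_range: Optional[Tuple[float, float]] = None) -> np.ndarray:
        if rt_range is None:
            sel = slice(None)
        else:
            lo, hi = rt_range
            sel = (self.rts >= lo) & (self.rts <= hi)
        return self.intensity[sel].sum(axis=0)


def _mz_step(mz: np.ndarray) -> float:
    if mz.size < 2:
        return 1.0
    return float(np.median(np.diff(mz)))


def smooth_scan(mz: np.ndarray, intensity: np.ndarray, width_mz: float = 1.0) -> np.ndarray:
    """Gaussian smoothing of one profile spectrum (FWHM ``width_mz``)."""
    if intensity.size == 0:
        return intensity.copy()
    sigma_pts = width_mz / _FWHM_TO_SIGMA / _mz_step(mz)
    return ndimage.gaussian_filter1d(np.asarray(intensity, float), sigma_pts, mode="reflect")


def baseline_tophat_scan(mz: np.ndarray, intensity: np.ndarray, width_mz: float = 1.0) -> np.ndarray:
    """Morphological tophat baseline subtraction (structuring width ``width_mz``).

    The grey opening (erosion then dilation) estimates the baseline;
    subtracting it preserves peaks narrower than the structuring element
    and yields non-negative output.
    """
    if intensity.size == 0:
        return intensity.copy()
    size = max(3, int(round(width_mz / _mz_step(mz))) | 1)  # odd: opening <= input
    x = np.asarray(intensity, float)
    opened = ndimage.maximum_filter1d(ndimage.minimum_filter1d(x, size), size)
    return x - opened


def smooth_run(run: SpectrumRun, width_mz: float = 1.0) -> SpectrumRun:
    sigma_pts = width_mz / _FWHM_TO_SIGMA / _mz_step(run.mz)
    out = ndimage.gaussian_filter1d(run.intensity, sigma_pts, axis=1, mode="reflect")
    return SpectrumRun(run.rts.copy(), run.mz, out, dict(run.metadata))


def baseline_tophat_run(run: SpectrumRun, width_mz: float = 1.0) -> SpectrumRun:
    size = max(3, int(round(width_mz / _mz_step(run.mz))) | 1)
    eroded = ndimage.minimum_filter1d(run.intensity, size, axis=1)
    opened = ndimage.maximum_filter1d(eroded, size, axis=1)
    return SpectrumRun(run.rts.copy(), run.mz, run.intensity - opened, dict(run.metadata))


def preprocess_run(
    run: SpectrumRun, smooth_width_mz: float = 1.0, tophat_width_mz: float = 1.0
) -> SpectrumRun:
    """Standard per-spectrum chain: Gaussian smoothing then tophat baseline."""
    return baseline_tophat_run(smooth_run(run, smooth_width_mz), tophat_width_mz)


@dataclass
class DeconvolvedSpectrum:
    """Zero-charge mass spectrum on a uniform grid with picked peaks."""

    masses: np.ndarray
    intensity: np.ndarray
    picked_peaks: List[Tuple[float, float]]
    per_charge: Optional[np.ndarray] = None  # (n_charges, n_masses)
    charges: Optional[Tuple[int, ...]] = None

    def peak_area(self, mass: float, half_width: float = 4.0) -> float:
        """Integrated intensity of the mass spectrum within ``mass`` ± ``half_width``."""
        sel = np.abs(self.masses - mass) <= half_width
        if not sel.any():
            return 0.0
        step = float(np.median(np.diff(self.masses))) if self.masses.size > 1 else 1.0
        return float(np.clip(self.intensity[sel], 0.0, None).sum() * step)

    def nearest_peak(self, mass: float) -> Optional[Tuple[float, float]]:
        if not self.picked_peaks:
            return None
        return min(self.picked_peaks, key=lambda p: abs(p[0] - mass))


def deconvolve(
    run: SpectrumRun,
    rt_range: Optional[Tuple[float, float]] = None,
    charges: Sequence[int] = (18, 19, 20, 21, 22),
    mass_range: Tuple[float, float] = (23000.0, 28000.0),
    grid_spacing: float = 1.0,
    threshold_k: float = 8.0,
    min_charges: int = 3,
    combine: str = "sum",
    mz_window: Optional[Tuple[float, float]] = None,
) -> DeconvolvedSpectrum:
    """Charge-assignment summation deconvolution of a summed spectrum.

    Parameters
    ----------
    rt_range
        Retention-time window over which scans are summed (whole run if
        omitted); an empty window yields an empty result.
    charges
        Candidate charge states.
    combine
        ``"sum"`` adds the per-charge traces; ``"median"`` takes the
        median across charges (scaled by the charge count), which is
        robust against single-charge harmonic ghosts and is used for
        relative quantification of the doubly glycosylated region.
    threshold_k
        Peaks are picked as 3-point local maxima above
        ``median + threshold_k * MAD`` of the combined trace.  The
        default (8) was calibrated on the pure-noise null so that runs
        without signal rarely yield any pick.
    min_charges
        A peak is retained only if at least this many charges carry
        >=5% of the strongest per-charge signal at that mass
        (charge-coherence support).
    """
    summed = run.summed_spectrum(rt_range)
    masses = np.arange(mass_range[0], mass_range[1] + 0.5 * grid_spacing, grid_spacing)
    if summed.sum() == 0 or masses.size == 0:
        return DeconvolvedSpectrum(masses, np.zeros_like(masses), [], None, tuple(charges))
    if mz_window is None:
        mz_window = (float(run.mz[0]), float(run.mz[-1]))

    per_charge = np.zeros((len(charges), masses.size))
    for i, z in enumerate(charges):
        mzc = (masses + z * PROTON_MASS) / z
        v = np.interp(mzc, run.mz, summed, left=0.0, right=0.0)
        v[(mzc < mz_window[0]) | (mzc > mz_window[1])] = 0.0
        per_charge[i] = v

    if combine == "median":
        intensity = np.median(per_charge, axis=0) * len(charges)
    elif combine == "sum":
        intensity = per_charge.sum(axis=0)
    else:
        raise ValueError(f"unknown combine mode: {combine!r}")

    med = float(np.median(intensity))
    mad = float(np.median(np.abs(intensity - med)))
    threshold = med + threshold_k * mad

    picked: List[Tuple[float, float]] = []
    c = intensity
    for i in range(1, c.size - 1):
        # plateau tie-break to the lower mass: >= left, > right
        if c[i] <= threshold or c[i] <= 0:
            continue
        if c[i] >= c[i - 1] and c[i] > c[i + 1]:
            col = per_charge[:, i]
            support = int((col >= 0.05 * col.max()).sum()) if col.max() > 0 else 0
            if support >= min_charges:
                picked.append((float(masses[i]), float(c[i])))

    return DeconvolvedSpectrum(masses, intensity, picked, per_charge, tuple(charges))


def align_runs(
    runs: Sequence[SpectrumRun],
    anchors: Sequence[Tuple[object, float]],
    resolution: float = 15000.0,
    window_scale: float = 2.0,
    min_snr: float = 5.0,
) -> List[SpectrumRun]:
    """Piecewise-linear retention-time alignment on shared anchor species.

    ``anchors`` is a list of ``(species, expected_rt)`` pairs; each
    species must be a high-abundance proteoform detectable in every run
    (typically the G0F glycoform of an abundant allotype).  The apex of
    each anchor's EIC is located per run and a piecewise-linear warp
    maps observed apexes onto the expected retention times.  Runs in
    which an anchor cannot be detected (apex below ``min_snr`` times the
    chromatographic median) are flagged in their metadata and returned
    unwarped.
    """
    from .quantify import EICDefinition, build_eic, find_apex  # local: avoids cycle

    aligned: List[SpectrumRun] = []
    for run in runs:
        obs: List[float] = []
        exp: List[float] = []
        ok = True
        for species, expected_rt in anchors:
            definition = EICDefinition.for_species(
                species,
                resolution=resolution,
                w=window_scale,
                mz_window=(float(run.mz[0]), float(run.mz[-1])),
            )
            chrom = build_eic(run, definition)
            apex_rt, apex_h = find_apex(chrom)
            baseline = float(np.median(chrom.values))
            if apex_h <= 0 or apex_h < min_snr * max(baseline, 1e-12):
                ok = False
                break
            obs.append(apex_rt)
            exp.append(expected_rt)
        meta = dict(run.metadata)
        if not ok or not obs:
            meta["alignment_flagged"] = True
            aligned.append(SpectrumRun(run.rts.copy(), run.mz, run.intensity, meta))
            continue
        order = np.argsort(obs)
        obs_a = np.asarray(obs)[order]
        exp_a = np.asarray(exp)[order]
        shift = exp_a - obs_a
        # constant extrapolation of the shift outside the anchor span
        new_rts = run.rts + np.interp(run.rts, obs_a, shift)
        meta["alignment_flagged"] = False
        meta["alignment_shift_s"] = [float(s) for s in shift]
        aligned.append(SpectrumRun(new_rts, run.mz, run.intensity, meta))
    return aligned
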