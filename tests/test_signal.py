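"""Preprocessing and zero-charge deconvolution."""

from dataclasses import replace

import numpy as np
import pytest

from fcprofiler.proteoforms import Allotype, GlycanComposition, ProteoformSpecies
from fcprofiler.signal import (
    SpectrumRun,
    baseline_tophat_scan,
    deconvolve,
    preprocess_run,
    smooth_scan,
    align_runs,
)
from fcprofiler.simulate import render_run

from conftest import single_species_profile

MZ = np.arange(1000.0, 1100.0, 0.02)


class TestSmoothing:
    def test_flat_unchanged(self):
        flat = np.full(MZ.size, 7.0)
        out = smooth_scan(MZ, flat, 1.0)
        assert np.allclose(out, 7.0)

    def test_impulse_response_fwhm(self):
        x = np.zeros(MZ.size)
        x[MZ.size // 2] = 1.0
        out = smooth_scan(MZ, x, 1.0)
        half = out.max() / 2
        width = MZ[out >= half][-1] - MZ[out >= half][0]
        assert width == pytest.approx(1.0, rel=0.05)

    def test_intensity_conserved(self):
        rng = np.random.default_rng(0)
        x = rng.random(MZ.size) * 100
        out = smooth_scan(MZ, x, 1.0)
        interior = slice(200, -200)
        assert out[interior].sum() == pytest.approx(x[interior].sum(), rel=1e-3)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, MZ.size)
        assert smooth_scan(MZ, x, 1.0).var() < x.var()

    def test_empty_scan_identity(self):
        out = smooth_scan(np.array([]), np.array([]), 1.0)
        assert out.size == 0


class TestTophat:
    def test_constant_removed(self):
        out = baseline_tophat_scan(MZ, np.full(MZ.size, 11.0), 1.0)
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_narrow_peak_on_ramp_preserved(self):
        ramp = np.linspace(0, 50, MZ.size)
        peak = 100 * np.exp(-0.5 * ((MZ - 1050) / 0.04) ** 2)
        out = baseline_tophat_scan(MZ, ramp + peak, 1.0)
        sel = np.abs(MZ - 1050) < 0.5
        assert out[sel].sum() == pytest.approx(peak[sel].sum(), rel=0.05)

    def test_zeros(self):
        out = baseline_tophat_scan(MZ, np.zeros(MZ.size), 1.0)
        assert np.all(out == 0)

    def test_output_nonnegative_for_nonnegative_input(self):
        rng = np.random.default_rng(2)
        x = np.abs(rng.normal(5, 2, MZ.size))
        assert baseline_tophat_scan(MZ, x, 1.0).min() >= -1e-9


def test_preprocess_homogeneous_in_scale(single_species_run):
    """Smoothing + baseline commute with intensity scaling (degree 1)."""
    a = preprocess_run(single_species_run, 0.1, 1.0)
    scaled = SpectrumRun(
        single_species_run.rts, single_species_run.mz,
        3.0 * single_species_run.intensity,
    )
    b = preprocess_run(scaled, 0.1, 1.0)
    assert np.allclose(b.intensity, 3.0 * a.intensity, rtol=1e-9, atol=1e-6)


def _render_single(mass, small_runspec, abundance=1.0, noise=0.0, seed=1,
                   glycan="H3N4F1"):
    allo = Allotype("IGHG1*01", "IgG1", mass - GlycanComposition.from_string(glycan).mass())
    spec = replace(small_runspec, noise_sd=noise, seed=seed)
    profile = single_species_profile(allo, glycan=glycan)
    return render_run(profile, spec, {allo.name: allo}), allo


class TestDeconvolve:
    @pytest.mark.parametrize("mass", [23000.0, 24000.0, 25000.0, 26000.0, 27000.0])
    def test_single_species_mass_recovery(self, mass, small_runspec):
        run, _ = _render_single(mass, small_runspec)
        d = deconvolve(run, mass_range=(mass - 500, mass + 500))
        assert len(d.picked_peaks) == 1
        assert abs(d.picked_peaks[0][0] - mass) <= 1.0

    def test_two_species_resolved(self, small_runspec):
        r1, _ = _render_single(25000.0, small_runspec)
        r2, _ = _render_single(26200.0, small_runspec)
        run = SpectrumRun(r1.rts, r1.mz, r1.intensity + r2.intensity)
        d = deconvolve(run, mass_range=(24500, 26700))
        masses = sorted(p[0] for p in d.picked_peaks)
        assert len(masses) == 2
        assert abs(masses[0] - 25000.0) <= 1.0
        assert abs(masses[1] - 26200.0) <= 1.0

    @pytest.mark.parametrize("ratio", [0.05, 0.5, 1.0, 5.0, 20.0])
    def test_intensity_ratio_recovery(self, ratio, small_runspec):
        r1, _ = _render_single(25000.0, small_runspec, seed=3, noise=0.0)
        r2, _ = _render_single(26200.0, small_runspec, seed=4, noise=0.0)
        run = SpectrumRun(
            r1.rts, r1.mz, ratio * r1.intensity + r2.intensity
        )
        # default simulator noise level on top
        rng = np.random.default_rng(9)
        noisy = np.clip(run.intensity + rng.normal(0, 20.0, run.intensity.shape), 0, None)
        run = preprocess_run(SpectrumRun(run.rts, run.mz, noisy), 0.1, 1.0)
        d = deconvolve(run, mass_range=(24500, 26700))
        i1 = d.peak_area(25000.0, 4.0)
        i2 = d.peak_area(26200.0, 4.0)
        assert i1 / i2 == pytest.approx(ratio, rel=0.10)

    def test_empty_rt_range(self, single_species_run):
        d = deconvolve(single_species_run, rt_range=(100.0, 110.0))
        assert d.picked_peaks == []
        assert np.all(d.intensity == 0)

    def test_pure_noise_rarely_picks_peaks(self, small_runspec):
        """Noise-only runs yield zero picked peaks in >=95% of seeds."""
        clean = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            mz = np.arange(1000.0, 1600.0, 0.02)
            rts = np.arange(600.0, 700.0, 2.0)
            intensity = np.clip(rng.normal(0, 20.0, (rts.size, mz.size)), 0, None)
            run = preprocess_run(SpectrumRun(rts, mz, intensity), 0.1, 1.0)
            d = deconvolve(run, mass_range=(23000, 28000))
            clean += not d.picked_peaks
        assert clean >= 0.95 * n_seeds

    def test_scaling_invariance_of_picks(self, single_species_run):
        d1 = deconvolve(single_species_run, mass_range=(24800, 25800))
        scaled = SpectrumRun(
            single_species_run.rts, single_species_run.mz,
            10.0 * single_species_run.intensity,
        )
        d2 = deconvolve(scaled, mass_range=(24800, 25800))
        assert [p[0] for p in d1.picked_peaks] == [p[0] for p in d2.picked_peaks]


class TestAlignRuns:
    def _shifted_runs(self, small_runspec, shifts):
        allo = Allotype("IGHG1*01", "IgG1", 23788.0)
        spec = replace(small_runspec, rt_window=(600.0, 800.0))
        runs = []
        for i, shift in enumerate(shifts):
            profile = single_species_profile(allo, rt=700.0)
            runs.append(
                render_run(profile, replace(spec, seed=i), {allo.name: allo},
                           rt_shift=shift)
            )
        anchor = ProteoformSpecies(allo, GlycanComposition.from_string("H3N4F1"))
        return runs, [(anchor, 700.0)], allo

    def test_global_shift_removed(self, small_runspec):
        runs, anchors, allo = self._shifted_runs(small_runspec, [0.0, 10.0])
        aligned = align_runs(runs, anchors)
        from fcprofiler.quantify import EICDefinition, build_eic, find_apex

        for run in aligned:
            d = EICDefinition.for_species(anchors[0][0], mz_window=(1000, 1600))
            apex, _ = find_apex(build_eic(run, d))
            assert abs(apex - 700.0) < 1.0
            assert run.metadata["alignment_flagged"] is False

    def test_identity_for_identical_runs(self, small_runspec):
        runs, anchors, _ = self._shifted_runs(small_runspec, [0.0, 0.0])
        aligned = align_runs(runs, anchors)
        for run, orig in zip(aligned, runs):
            assert np.allclose(run.rts, orig.rts, atol=0.5)

    def test_missing_anchor_flags_run(self, small_runspec):
        runs, anchors, allo = self._shifted_runs(small_runspec, [0.0])
        blank = SpectrumRun(runs[0].rts, runs[0].mz, np.zeros_like(runs[0].intensity))
        aligned = align_runs([blank], anchors)
        assert aligned[0].metadata["alignment_flagged"] is True
        assert np.array_equal(aligned[0].rts, blank.rts)
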