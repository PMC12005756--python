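"""EIC definitions, integration and the relative-quantification formulas."""

import math

import numpy as np
import pytest

from fcprofiler.proteoforms import Allotype, GlycanComposition, ProteoformSpecies
from fcprofiler.quantify import (
    Chromatogram,
    EICDefinition,
    allotype_ratio,
    build_eic,
    ch3_occupancy,
    find_apex,
    glycoform_profile,
    integrate_peak,
    intact_occupancy,
    ptm_level,
    subclass_average,
)


def _species(mass):
    g0f = GlycanComposition.from_string("H3N4F1")
    return ProteoformSpecies(Allotype("IGHG1*01", "IgG1", mass - g0f.mass()), g0f)


class TestEICDefinition:
    def test_window_borders_from_resolution(self):
        """m/z 1278.66 at R=15000: FWHM 0.0852, default window +- 0.1704."""
        sp = _species(25553.0)
        d = EICDefinition.for_species(sp, charges=(19, 20, 21))
        lo, hi = d.mz_windows[1]  # z = 20
        mz0 = (25553.0 + 20 * 1.00728) / 20
        fwhm = mz0 / 15000.0
        assert fwhm == pytest.approx(0.0852, abs=2e-4)
        assert lo == pytest.approx(mz0 - 2 * fwhm, abs=1e-6)
        assert hi == pytest.approx(mz0 + 2 * fwhm, abs=1e-6)

    def test_charge_selection_inside_window(self):
        """Auto selection picks the heaviest-weighted triplet fitting m/z 1000-1600."""
        d = EICDefinition.for_species(_species(25553.0))
        assert d.charges == (19, 20, 21)
        # heavier species: low charges fall above m/z 1600, selection shifts up
        d2 = EICDefinition.for_species(_species(30000.0))
        assert min(d2.charges) >= 19

    def test_requires_three_consecutive(self):
        sp = _species(25553.0)
        with pytest.raises(ValueError):
            EICDefinition.for_species(sp, charges=(18, 20, 22))
        with pytest.raises(ValueError):
            EICDefinition.for_species(sp, mz_window=(1000.0, 1010.0))


class TestIntegration:
    def test_gaussian_area(self):
        """Unit-height Gaussian, sigma = 5 s: area = sigma * sqrt(2*pi)."""
        rts = np.arange(600.0, 700.0, 0.5)
        chrom = Chromatogram(rts, np.exp(-0.5 * ((rts - 650) / 5.0) ** 2))
        assert integrate_peak(chrom, (600, 700)) == pytest.approx(
            5.0 * math.sqrt(2 * math.pi), rel=1e-3
        )

    def test_zero_and_linearity(self):
        rts = np.arange(0, 100.0, 1.0)
        zero = Chromatogram(rts, np.zeros_like(rts))
        assert integrate_peak(zero, (0, 100)) == 0.0
        vals = np.random.default_rng(0).random(rts.size)
        a1 = integrate_peak(Chromatogram(rts, vals), (10, 90))
        a2 = integrate_peak(Chromatogram(rts, 2 * vals), (10, 90))
        assert a2 == pytest.approx(2 * a1, rel=1e-12)

    def test_empty_window_warns(self):
        chrom = Chromatogram(np.arange(10.0), np.ones(10))
        with pytest.warns(UserWarning):
            assert integrate_peak(chrom, (100.0, 110.0)) == 0.0

    def test_build_eic_outside_range_errors(self, single_species_run):
        sp = _species(60000.0)
        d = EICDefinition.for_species(sp, charges=(19, 20, 21), mz_window=(2000, 4000))
        with pytest.raises(ValueError):
            build_eic(single_species_run, d)

    def test_find_apex_parabolic(self):
        rts = np.arange(0.0, 50.0, 2.0)
        chrom = Chromatogram(rts, np.exp(-0.5 * ((rts - 25.3) / 5) ** 2))
        apex, height = find_apex(chrom)
        assert apex == pytest.approx(25.3, abs=0.2)


class TestProfiles:
    def test_normalisation(self):
        prof = glycoform_profile({"G0F": 50.0, "G1F": 30.0, "G2F": 20.0})
        assert prof == {"G0F": 50.0, "G1F": 30.0, "G2F": 20.0}
        assert sum(prof.values()) == pytest.approx(100.0)

    def test_single_species_and_equal(self):
        assert glycoform_profile({"G0F": 7.0}) == {"G0F": 100.0}
        prof = glycoform_profile(dict.fromkeys("abcd", 3.0))
        assert all(v == pytest.approx(25.0) for v in prof.values())

    def test_empty_is_na(self):
        assert glycoform_profile({}) is None
        assert glycoform_profile({"G0F": 0.0}) is None

    def test_subclass_average(self):
        p = {"G0F": 60.0, "G1F": 40.0}
        q = {"G0F": 20.0, "G1F": 80.0}
        assert subclass_average({"a1": p}, {"a1": 1.0}) == pytest.approx(p)
        half = subclass_average({"a1": p, "a2": q}, {"a1": 1.0, "a2": 1.0})
        assert half["G0F"] == pytest.approx(40.0)
        weighted = subclass_average({"a1": p, "a2": q}, {"a1": 0.75, "a2": 0.25})
        # hand computation: 0.75*60 + 0.25*20 / 0.75*40 + 0.25*80
        assert weighted["G0F"] == pytest.approx(50.0)
        assert weighted["G1F"] == pytest.approx(50.0)


class TestRatiosAndOccupancy:
    def test_allotype_ratio(self):
        assert allotype_ratio(5.0, 5.0) == pytest.approx(0.5)
        assert allotype_ratio(3.0, 0.0) == 1.0
        assert math.isnan(allotype_ratio(0.0, 0.0))

    def test_ch3_occupancy_worked_examples(self):
        # anchor area 30 at 25% of the doubly glycosylated pool, singles 900:
        # doubly total 120 -> occupancy 120/1020
        assert ch3_occupancy(30.0, 0.25, 900.0) == pytest.approx(0.1176, abs=1e-4)
        assert ch3_occupancy(30.0, 1.0, 900.0) == pytest.approx(30.0 / 930.0, abs=1e-9)
        assert math.isnan(ch3_occupancy(30.0, 0.0, 900.0))

    def test_intact_occupancy_reported_range(self):
        """Fc/2 occupancies 13.7% and 24.1% map to 25.5% and 42.4% of
        intact IgG3 carrying at least one C_H3 glycan."""
        assert round(100 * intact_occupancy(0.137), 1) == 25.5
        assert round(100 * intact_occupancy(0.241), 1) == 42.4

    def test_intact_occupancy_bounds_and_shape(self):
        assert intact_occupancy(0.0) == 0.0
        assert intact_occupancy(1.0) == 1.0
        grid = np.linspace(0, 1, 101)
        vals = np.array([intact_occupancy(p) for p in grid])
        assert np.all(np.diff(vals) >= 0)  # monotone
        assert np.all(np.diff(np.diff(vals)) <= 1e-12)  # concave
        with pytest.raises(ValueError):
            intact_occupancy(1.5)

    def test_ptm_level(self):
        assert ptm_level(5.0, 95.0) == pytest.approx(5.0)
        assert ptm_level(0.0, 50.0) == 0.0
        assert math.isnan(ptm_level(0.0, 0.0))
        assert ptm_level(5.0, 95.0, bounded=False) == pytest.approx(100 * 5 / 95)

    def test_eic_area_proportional_to_abundance(self, reference):
        """Noiseless single species: EIC area scales linearly with abundance."""
        from dataclasses import replace

        from fcprofiler.reference import allotypes_by_name
        from fcprofiler.simulate import RunSpec, render_run
        from conftest import single_species_profile

        allo = allotypes_by_name(reference)["IGHG1*01"]
        spec = RunSpec(rt_window=(600.0, 700.0), scan_interval=2.0, noise_sd=0.0, seed=0)
        areas = []
        for scale in (1.0, 0.5):
            run = render_run(
                single_species_profile(allo), replace(spec, total_ion_area=1e8 * scale),
                {allo.name: allo},
            )
            sp = ProteoformSpecies(allo, GlycanComposition.from_string("H3N4F1"))
            d = EICDefinition.for_species(sp)
            areas.append(integrate_peak(build_eic(run, d), (620, 680)))
        assert areas[0] / areas[1] == pytest.approx(2.0, rel=1e-3)
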