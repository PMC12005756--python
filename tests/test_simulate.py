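"""Synthetic-data generator: distributions, determinism, rendering."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fcprofiler.proteoforms import PROTON_MASS, Allotype
from fcprofiler.simulate import (
    FractionProfile,
    SimulationConfig,
    glycoform_distribution,
    render_run,
    sample_patient,
)
from fcprofiler.traits import derive_traits

from conftest import single_species_profile


class TestGlycoformDistribution:
    @given(
        gal=st.floats(0.1, 0.9),
        sia_frac=st.floats(0.0, 1.0),
        afuc=st.floats(0.0, 0.4),
        bis=st.floats(0.0, 0.4),
        hm=st.floats(0.0, 0.2),
    )
    @settings(deadline=None, max_examples=40)
    def test_targets_reproduced(self, gal, sia_frac, afuc, bis, hm):
        """The derived traits of the constructed profile equal the targets."""
        sia = gal * sia_frac
        dist = glycoform_distribution(gal, sia, afuc, bis, hm)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)
        traits = derive_traits({k: 100 * v for k, v in dist.items()})
        assert traits["galactosylation"] == pytest.approx(100 * gal, abs=1e-6)
        assert traits["sialylation"] == pytest.approx(100 * sia, abs=1e-6)
        assert traits["afucosylation"] == pytest.approx(100 * afuc, abs=1e-6)
        assert traits["bisection"] == pytest.approx(100 * bis, abs=1e-6)
        assert traits["high_mannose"] == pytest.approx(100 * hm, abs=1e-6)

    def test_invalid_targets(self):
        with pytest.raises(ValueError):
            glycoform_distribution(0.5, 0.6, 0.1, 0.1, 0.0)  # sia > gal
        with pytest.raises(ValueError):
            glycoform_distribution(1.5, 0.1, 0.1, 0.1, 0.0)


class TestSamplePatient:
    def test_deterministic(self):
        a = sample_patient(SimulationConfig(), seed=11)
        b = sample_patient(SimulationConfig(), seed=11)
        assert a.profiles["total_plasma"].glycoform_dists == b.profiles["total_plasma"].glycoform_dists
        assert a.truth.equals(b.truth)
        assert a.run_seeds == b.run_seeds

    def test_fraction_effect_directions(self):
        """ACPA IgG has lower afucosylation/bisection; ACPA SF lower
        galactosylation/sialylation than ACPA plasma."""
        s = sample_patient(SimulationConfig(), seed=5)
        t = s.truth
        sub = t[(t.level == "subclass") & (t.name == "IgG1")]

        def val(fraction, trait):
            return sub[(sub.fraction == fraction) & (sub.trait == trait)]["value"].iloc[0]

        for trait in ("afucosylation", "bisection"):
            assert val("ACPA_plasma", trait) < val("total_plasma", trait)
        for trait in ("galactosylation", "sialylation"):
            assert val("ACPA_SF", trait) < val("ACPA_plasma", trait)

    def test_plusk_only_in_sf(self):
        s = sample_patient(SimulationConfig(), seed=5)
        t = s.truth
        plusk = t[t.trait == "plusK"]
        plasma = plusk[plusk.fraction.str.endswith("plasma")]["value"]
        sf = plusk[plusk.fraction.str.endswith("SF")]["value"]
        assert (plasma == 0).all()
        assert (sf > 0).all()

    def test_zero_occupancy_suppresses_double_species(self, igg3_allotype):
        profile = FractionProfile(
            fraction="total_plasma",
            allotype_abundances={igg3_allotype.name: 1.0},
            glycoform_dists={igg3_allotype.name: {"H3N4F1": 1.0}},
            ch3_dists={igg3_allotype.name: {"H5N2": 1.0}},
            ch3_occupancy={igg3_allotype.name: 0.0},
        )
        species = profile.species_abundances({igg3_allotype.name: igg3_allotype})
        assert all(sp.ch3_glycan is None for sp, _, _ in species)

    def test_profile_validation(self, allotype):
        bad = FractionProfile(
            fraction="total_plasma",
            allotype_abundances={allotype.name: 1.0},
            glycoform_dists={allotype.name: {"H3N4F1": 0.7}},
        )
        with pytest.raises(ValueError):
            bad.validate()


class TestRenderRun:
    def test_deterministic(self, allotype, small_runspec):
        from dataclasses import replace

        spec = replace(small_runspec, noise_sd=5.0, seed=42)
        profile = single_species_profile(allotype)
        r1 = render_run(profile, spec, {allotype.name: allotype})
        r2 = render_run(profile, spec, {allotype.name: allotype})
        assert np.array_equal(r1.intensity, r2.intensity)

    def test_total_ion_current_conservation(self, allotype, single_species_run, small_runspec):
        """Noiseless: integrated ion current equals the configured area."""
        total = (
            single_species_run.intensity.sum()
            * small_runspec.mz_step
            * small_runspec.scan_interval
        )
        assert total == pytest.approx(small_runspec.total_ion_area, rel=1e-3)

    def test_peak_positions(self, small_runspec):
        """A 25553.0 Da species at z=20 produces a peak at m/z 1278.66."""
        from dataclasses import replace

        allo = Allotype("IGHG1*01", "IgG1", 25553.0 - 1445.3325)
        spec = replace(small_runspec, charges=(20,), charge_weights=(1.0,))
        run = render_run(single_species_profile(allo), spec, {allo.name: allo})
        summed = run.intensity.sum(axis=0)
        apex = run.mz[np.argmax(summed)]
        assert apex == pytest.approx((25553.0 + 20 * PROTON_MASS) / 20, abs=0.02)
        assert apex == pytest.approx(1278.66, abs=0.05)

    def test_two_allotypes_two_rt_maxima(self, small_runspec):
        from dataclasses import replace

        a1 = Allotype("IGHG1*01", "IgG1", 23788.0)
        a2 = Allotype("IGHG1*03", "IgG1", 23816.1)
        spec = replace(small_runspec, rt_window=(600.0, 800.0))
        profile = FractionProfile(
            fraction="total_plasma",
            allotype_abundances={a1.name: 0.5, a2.name: 0.5},
            glycoform_dists={a1.name: {"H3N4F1": 1.0}, a2.name: {"H3N4F1": 1.0}},
            rt_centers={a1.name: 650.0, a2.name: 750.0},
        )
        run = render_run(profile, spec, {a1.name: a1, a2.name: a2})
        tic = run.intensity.sum(axis=1)
        assert abs(run.rts[np.argmax(tic * (run.rts < 700))] - 650.0) < 5
        assert abs(run.rts[np.argmax(tic * (run.rts >= 700))] - 750.0) < 5

    def test_species_outside_window_warns(self, small_runspec):
        from dataclasses import replace

        allo = Allotype("IGHG1*01", "IgG1", 60000.0)  # all charges beyond m/z 1600
        spec = replace(small_runspec, charges=(20,), charge_weights=(1.0,))
        with pytest.warns(UserWarning, match="outside"):
            run = render_run(single_species_profile(allo), spec, {allo.name: allo})
        assert run.intensity.sum() == 0
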