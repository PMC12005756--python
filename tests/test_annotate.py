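"""Allotype calling and combinatorial glycan-pair annotation."""

import itertools

import numpy as np
import pytest

from fcprofiler.annotate import (
    annotate_double_glyc,
    call_allotypes,
    call_allotypes_windowed,
)
from fcprofiler.proteoforms import (
    COMMON_CH2_GLYCANS,
    COMMON_CH3_GLYCANS,
    GlycanComposition,
    glycan_mass,
)
from fcprofiler.signal import DeconvolvedSpectrum


def _spectrum_with_peaks(peaks):
    masses = np.arange(23000.0, 28000.0)
    intensity = np.zeros_like(masses)
    picked = [(float(round(m)), float(i)) for m, i in peaks]
    for m, i in picked:
        intensity[int(m - 23000)] = i
    return DeconvolvedSpectrum(masses, intensity, picked)


def _ladder(backbone, height=100.0):
    return [(backbone + glycan_mass(g), height) for g in ("H3N4F1", "H4N4F1", "H5N4F1")]


class TestCallAllotypes:
    def test_empty_spectrum_empty_call(self, reference):
        call = call_allotypes(_spectrum_with_peaks([]), reference)
        assert call.allotypes == []

    def test_single_allotype_ladder(self, reference):
        backbone = float(reference.loc[reference["name"] == "IGHG1*01",
                                       "backbone_mass_avg"].iloc[0])
        call = call_allotypes(_spectrum_with_peaks(_ladder(backbone)), reference)
        assert call.names == ["IGHG1*01"]
        assert len(call.evidence["IGHG1*01"]) >= 2

    def test_single_peak_not_called(self, reference):
        backbone = float(reference.loc[reference["name"] == "IGHG1*01",
                                       "backbone_mass_avg"].iloc[0])
        spectrum = _spectrum_with_peaks([(backbone + glycan_mass("H3N4F1"), 100.0)])
        assert call_allotypes(spectrum, reference).allotypes == []

    def test_intensity_scaling_invariance(self, reference):
        backbone = float(reference.loc[reference["name"] == "IGHG2*01",
                                       "backbone_mass_avg"].iloc[0])
        p1 = _spectrum_with_peaks(_ladder(backbone, 10.0))
        p2 = _spectrum_with_peaks(_ladder(backbone, 1e6))
        assert call_allotypes(p1, reference).names == call_allotypes(p2, reference).names

    def test_at_most_two_per_subclass(self, reference):
        peaks = []
        for name in ("IGHG1*01", "IGHG1*03"):
            backbone = float(reference.loc[reference["name"] == name,
                                           "backbone_mass_avg"].iloc[0])
            peaks += _ladder(backbone)
        call = call_allotypes(_spectrum_with_peaks(peaks), reference)
        assert sorted(call.names) == ["IGHG1*01", "IGHG1*03"]

    def test_isobaric_allotypes_flagged(self, reference):
        """Two reference allotypes within tolerance are co-reported as ambiguous."""
        import pandas as pd

        rows = reference.copy()
        clone = rows[rows["name"] == "IGHG1*01"].copy()
        clone["name"] = "IGHG1*99"
        clone["backbone_mass_avg"] += 0.5  # isobaric within 2 Da
        ref2 = pd.concat([rows, clone], ignore_index=True)
        backbone = float(reference.loc[reference["name"] == "IGHG1*01",
                                       "backbone_mass_avg"].iloc[0])
        call = call_allotypes(_spectrum_with_peaks(_ladder(backbone)), ref2)
        assert sorted(call.names) == ["IGHG1*01", "IGHG1*99"]
        assert "IGHG1*99" in call.ambiguous.get("IGHG1*01", [])


def test_windowed_calling_matches_constitution(reference):
    """Windowed calling on a rendered two-allotype run finds exactly those two."""
    from dataclasses import replace

    from fcprofiler.reference import allotypes_by_name
    from fcprofiler.simulate import FractionProfile, RunSpec, render_run

    by_name = allotypes_by_name(reference)
    names = ["IGHG1*01", "IGHG4*03"]
    spec = RunSpec(rt_window=(600.0, 800.0), scan_interval=2.0, noise_sd=10.0, seed=6)
    profile = FractionProfile(
        fraction="total_plasma",
        allotype_abundances={names[0]: 0.7, names[1]: 0.3},
        glycoform_dists={
            n: {"H3N4F1": 0.5, "H4N4F1": 0.3, "H5N4F1": 0.2} for n in names
        },
        rt_centers={names[0]: 650.0, names[1]: 740.0},
    )
    run = render_run(profile, spec, by_name)
    call = call_allotypes_windowed(run, reference)
    assert call.names == sorted(names)


class TestAnnotateDoubleGlyc:
    BACKBONE = 24206.5

    def test_exact_identity(self):
        g0f = GlycanComposition.from_string("H3N4F1")
        m5 = GlycanComposition.from_string("H5N2")
        observed = self.BACKBONE + g0f.mass() + m5.mass()
        res = annotate_double_glyc(
            observed, self.BACKBONE, COMMON_CH2_GLYCANS, COMMON_CH3_GLYCANS
        )
        top_c2, top_c3, delta = res.candidates[0]
        assert (top_c2, top_c3) == (g0f, m5)
        assert delta == pytest.approx(0.0, abs=1e-9)

    def test_hexose_shift_adds_one_hexose(self):
        g0f = GlycanComposition.from_string("H3N4F1")
        m5 = GlycanComposition.from_string("H5N2")
        observed = self.BACKBONE + g0f.mass() + m5.mass() + 162.1406
        res = annotate_double_glyc(
            observed, self.BACKBONE, COMMON_CH2_GLYCANS, COMMON_CH3_GLYCANS, tol=0.01
        )
        base_hex = g0f.H + m5.H
        assert res.candidates, "one-hexose-shifted mass must be annotatable"
        for c2, c3, _ in res.candidates:
            assert c2.N + c3.N == g0f.N + m5.N
            assert c2.H + c3.H == base_hex + 1

    def test_zero_tolerance(self):
        res = annotate_double_glyc(
            self.BACKBONE + 2662.42 + 0.5, self.BACKBONE,
            COMMON_CH2_GLYCANS, COMMON_CH3_GLYCANS, tol=0.0,
        )
        assert res.candidates == []
        assert res.nearest_miss is not None

    def test_matches_brute_force_enumeration(self):
        """Optimised search agrees exactly with the literal product oracle."""
        rng = np.random.default_rng(12)
        for _ in range(100):
            observed = self.BACKBONE + rng.uniform(2400.0, 4200.0)
            tol = rng.uniform(0.5, 3.0)
            res = annotate_double_glyc(
                observed, self.BACKBONE, COMMON_CH2_GLYCANS, COMMON_CH3_GLYCANS, tol
            )
            oracle = set()
            for c2, c3 in itertools.product(COMMON_CH2_GLYCANS, COMMON_CH3_GLYCANS):
                if abs(observed - (self.BACKBONE + c2.mass() + c3.mass())) <= tol:
                    oracle.add((c2, c3))
            assert {(c2, c3) for c2, c3, _ in res.candidates} == oracle
            deltas = [abs(d) for _, _, d in res.candidates]
            assert deltas == sorted(deltas)

    def test_isobaric_pairs_co_reported(self):
        """Pairs identical in total composition (isobaric) are never collapsed."""
        c2s = (GlycanComposition.from_string("H3N4F1"), GlycanComposition.from_string("H4N4F1"))
        c3s = (GlycanComposition.from_string("H5N2"), GlycanComposition.from_string("H6N2"))
        observed = 24206.5 + c2s[0].mass() + c3s[1].mass()  # == c2s[1] + c3s[0]
        res = annotate_double_glyc(observed, 24206.5, c2s, c3s, tol=0.1)
        assert len(res.candidates) == 2
        assert res.ambiguous
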