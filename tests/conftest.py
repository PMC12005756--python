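import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from fcprofiler.proteoforms import Allotype
from fcprofiler.reference import load_allotype_reference
from fcprofiler.simulate import FractionProfile, RunSpec


@pytest.fixture(scope="session")
def reference():
    return load_allotype_reference()


@pytest.fixture
def allotype():
    return Allotype("IGHG1*01", "IgG1", 23788.0, 1, -2453.6)


@pytest.fixture
def igg3_allotype():
    return Allotype("IGHG3*11", "IgG3", 24206.5, 2, -2512.3)


@pytest.fixture
def small_runspec():
    """Narrow, fast acquisition window for single-species tests."""
    return RunSpec(
        rt_window=(600.0, 700.0),
        mz_window=(1000.0, 1600.0),
        scan_interval=2.0,
        mz_step=0.02,
        noise_sd=0.0,
        seed=1,
    )


def single_species_profile(allo: Allotype, glycan: str = "H3N4F1", rt: float = 650.0,
                           fraction: str = "total_plasma") -> FractionProfile:
    return FractionProfile(
        fraction=fraction,
        allotype_abundances={allo.name: 1.0},
        glycoform_dists={allo.name: {glycan: 1.0}},
        rt_centers={allo.name: rt},
    )


@pytest.fixture
def single_species_run(allotype, small_runspec):
    from fcprofiler.simulate import render_run

    profile = single_species_profile(allotype)
    return render_run(profile, small_runspec, {allotype.name: allotype})
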