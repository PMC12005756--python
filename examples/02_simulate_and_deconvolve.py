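"""Simulate one LC-MS run and recover the masses by deconvolution.

A patient fraction is sampled, rendered into MS1 profile spectra
(charge envelopes in m/z 1000-1600, Gaussian elution peaks), smoothed
and baseline-subtracted, then deconvoluted onto a 1 Da zero-charge mass
grid; finally the allotype constitution is called by intact mass
matching of the glycoform ladders.
"""

import warnings

from fcprofiler import SimulationConfig, preprocess_run, render_run, sample_patient
from fcprofiler.annotate import call_allotypes_windowed
from fcprofiler.reference import load_allotype_reference

cfg = SimulationConfig()
patient = sample_patient(cfg, seed=7)
print(f"simulated patient {patient.patient_id} with allotypes:",
      ", ".join(sorted(patient.allotypes)))

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    run = render_run(patient.profiles["total_plasma"], cfg.run, patient.allotypes,
                     metadata={"fraction": "total_plasma"})
print(f"rendered run: {run.n_scans} scans x {run.mz.size} m/z points")

run = preprocess_run(run, smooth_width_mz=0.1, tophat_width_mz=1.0)
call = call_allotypes_windowed(run, load_allotype_reference())
print("called allotypes (>=2 glycoform-ladder masses each):")
for allo in call.allotypes:
    hits = call.evidence[allo.name]
    print(f"  {allo.name} ({allo.subclass}): "
          + ", ".join(f"{g}@{m:.0f} Da" for g, m, _ in hits))
# every simulated allotype should be recovered, and never more than
# two per subclass (a diploid patient carries at most eight in total)
assert call.names == sorted(patient.allotypes)
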