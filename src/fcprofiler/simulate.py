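"""Synthetic LC-MS runs of IdeS-released IgG Fc/2 subunits.

The generator emulates the four IgG fractions studied per rheumatoid
arthritis patient -- total and ACPA (anti-citrullinated protein
antibody) IgG, each from plasma and synovial fluid (SF) -- so that the
whole downstream pipeline is testable without raw data:

* up to two allotypes per subclass (heterozygosity) with patient- and
  fraction-specific abundances,
* per-allotype complex-type glycoform distributions built from target
  trait levels (galactosylation, sialylation, afucosylation, bisection,
  high mannose),
* doubly glycosylated IgG3 species for Cₕ3-carrying allotypes with a
  configurable site occupancy,
* the additional PTM set (retained C-terminal Lys -- synovial fluid
  only, GK loss, +2 Da open disulfides plus their N-terminally
  truncated form, cysteinylation) and non-glycosylated backbones,
* charge envelopes in m/z 1000-1600 at TOF resolving power 15000,
  Gaussian elution peaks in RT 600-1320 s, and additive Gaussian noise.

Fraction effect directions follow the study design: ACPA fractions have
lower afucosylation and bisection than total IgG; within ACPA, the SF
fraction has lower galactosylation and sialylation than plasma; ACPA
carries more high-mannose Cₕ3 glycans; retained Lys occurs only in SF.

The generator also emits the exact ground-truth trait table implied by
its parameters (computed with the same formulas the quantification and
trait modules use), which downstream recovery tests compare against.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .proteoforms import (
    PROTON_MASS,
    Allotype,
    GlycanComposition,
    ProteoformSpecies,
    PTMVariant,
    PTM_NONE,
    endos2_stub,
)
from .quantify import subclass_average
from .reference import allotypes_by_name, load_allotype_reference
from .signal import SpectrumRun
from .traits import derive_traits

__all__ = [
    "RunSpec",
    "FractionProfile",
    "SimulationConfig",
    "PatientSample",
    "glycoform_distribution",
    "sample_patient",
    "simulate_cohort",
    "render_run",
    "ground_truth_traits",
    "FRACTIONS",
]

FRACTIONS = ("total_plasma", "total_SF", "ACPA_plasma", "ACPA_SF")

_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # FWHM / sigma


@dataclass(frozen=True)
class RunSpec:
    """Acquisition settings of one simulated run; the seed fixes the output."""

    rt_window: Tuple[float, float] = (600.0, 1320.0)
    mz_window: Tuple[float, float] = (1000.0, 1600.0)
    resolution: float = 15000.0
    charges: Tuple[int, ...] = (18, 19, 20, 21, 22)
    charge_weights: Tuple[float, ...] = (1.0, 2.0, 3.0, 2.0, 1.0)
    rt_sigma: float = 6.0
    scan_interval: float = 3.0
    mz_step: float = 0.02
    noise_sd: float = 20.0
    total_ion_area: float = 1.0e8
    seed: int = 0


@dataclass
class FractionProfile:
    """Ground-truth composition of one IgG fraction of one patient."""

    fraction: str
    allotype_abundances: Dict[str, float]
    glycoform_dists: Dict[str, Dict[str, float]]  # allotype -> CH2 composition -> frac
    ch3_dists: Dict[str, Dict[str, float]] = field(default_factory=dict)
    ch3_occupancy: Dict[str, float] = field(default_factory=dict)
    ptm_pools: Dict[str, Dict[str, float]] = field(default_factory=dict)
    nonglyc_frac: Dict[str, float] = field(default_factory=dict)
    rt_centers: Dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for name, dist in self.glycoform_dists.items():
            s = sum(dist.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"glycoform distribution of {name} sums to {s}, not 1")
            if any(v < 0 for v in dist.values()):
                raise ValueError(f"negative glycoform fraction for {name}")
        for name, dist in self.ch3_dists.items():
            if dist and abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"CH3 distribution of {name} does not sum to 1")
        for name, pools in self.ptm_pools.items():
            if any(not 0.0 <= v <= 1.0 for v in pools.values()) or sum(pools.values()) > 1.0:
                raise ValueError(f"invalid PTM pool fractions for {name}")
        for name, p in self.ch3_occupancy.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"occupancy of {name} outside [0, 1]")
        for name, q in self.nonglyc_frac.items():
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"non-glycosylated fraction of {name} outside [0, 1]")

    def species_abundances(
        self, allotypes: Mapping[str, Allotype], endos2: bool = False
    ) -> List[Tuple[ProteoformSpecies, float, float]]:
        """Enumerate (species, abundance, retention time) triples.

        Abundances are fractions of the run's total ion area.  PTM
        variants are attached to singly glycosylated species; open-
        disulfide species (+2 Da and the truncated form) elute 15 s
        later than the parent.  ``endos2`` truncates every Cₕ2 glycan
        to its chitobiose stub.
        """
        self.validate()
        out: List[Tuple[ProteoformSpecies, float, float]] = []
        for name, a in self.allotype_abundances.items():
            if a <= 0:
                continue
            allo = allotypes[name]
            rt = self.rt_centers.get(name, 900.0)
            q = self.nonglyc_frac.get(name, 0.0)
            p = self.ch3_occupancy.get(name, 0.0) if allo.n_glyc_sites == 2 else 0.0
            pools = self.ptm_pools.get(name, {})
            p_none = 1.0 - sum(pools.values())
            glyc = a * (1.0 - q)

            def ch2_of(comp_str: str) -> GlycanComposition:
                c = GlycanComposition.from_string(comp_str)
                return endos2_stub(c) if endos2 else c

            for comp_str, fg in self.glycoform_dists[name].items():
                base = glyc * (1.0 - p) * fg
                if base <= 0:
                    continue
                ch2 = ch2_of(comp_str)
                for kind, frac in [("none", p_none)] + list(pools.items()):
                    w = base * frac
                    if w <= 0:
                        continue
                    ptm = PTM_NONE if kind == "none" else PTMVariant.standard(kind, allo)
                    rt_k = rt + (15.0 if kind in ("open_disulfide", "openSS_truncation") else 0.0)
                    out.append((ProteoformSpecies(allo, ch2, None, ptm), w, rt_k))
            if p > 0:
                ch3_dist = self.ch3_dists.get(name, {})
                for comp_str, fg in self.glycoform_dists[name].items():
                    for c3_str, f3 in ch3_dist.items():
                        w = glyc * p * fg * f3
                        if w <= 0:
                            continue
                        out.append(
                            (
                                ProteoformSpecies(
                                    allo,
                                    ch2_of(comp_str),
                                    GlycanComposition.from_string(c3_str),
                                ),
                                w,
                                rt,
                            )
                        )
            if q > 0:
                out.append((ProteoformSpecies(allo, None, None), a * q, rt))
        return out


def glycoform_distribution(
    gal: float, sia: float, afuc: float, bis: float, high_mannose: float
) -> Dict[str, float]:
    """Build a biantennary glycoform distribution from target trait levels.

    Galactosylation per arm is Bernoulli(``gal``); each galactose
    carries a sialic acid with probability ``sia/gal``; fucosylation,
    bisection and the high-mannose share are independent.  The derived
    traits of the resulting profile equal the targets by construction.
    """
    for nm, v in (("gal", gal), ("afuc", afuc), ("bis", bis), ("high_mannose", high_mannose)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{nm} target outside [0, 1]: {v}")
    if sia < 0 or sia > gal + 1e-12:
        raise ValueError("sialylation target must lie in [0, gal]")
    r = 0.0 if gal <= 0 else sia / gal
    dist: Dict[str, float] = {}
    p_gal = {0: (1 - gal) ** 2, 1: 2 * gal * (1 - gal), 2: gal**2}
    for f, pf in ((0, afuc), (1, 1 - afuc)):
        for b, pb in ((0, 1 - bis), (1, bis)):
            for ngal, pg in p_gal.items():
                for nsia in range(ngal + 1):
                    ps = (
                        math.comb(ngal, nsia)
                        * r**nsia
                        * (1 - r) ** (ngal - nsia)
                    )
                    w = (1 - high_mannose) * pf * pb * pg * ps
                    if w <= 0:
                        continue
                    comp = GlycanComposition(H=3 + ngal, N=4 + b, F=f, S=nsia)
                    key = str(comp)
                    dist[key] = dist.get(key, 0.0) + w
    if high_mannose > 0:
        dist["H5N2"] = dist.get("H5N2", 0.0) + 0.8 * high_mannose
        dist["H6N2"] = dist.get("H6N2", 0.0) + 0.2 * high_mannose
    return dist


# ---------------------------------------------------------------------------
# cohort-level sampling


@dataclass
class SimulationConfig:
    """Study conditions of the simulated cohort (defaults = the emulated design)."""

    run: RunSpec = field(default_factory=RunSpec)
    reference: Optional[pd.DataFrame] = None
    het_prob: Mapping[str, float] = field(
        default_factory=lambda: {"IgG1": 0.7, "IgG2": 0.6, "IgG3": 0.6, "IgG4": 0.6}
    )
    total_subclass_means: Mapping[str, float] = field(
        default_factory=lambda: {"IgG1": 0.60, "IgG2": 0.25, "IgG3": 0.08, "IgG4": 0.07}
    )
    acpa_subclass_means: Mapping[str, float] = field(
        default_factory=lambda: {"IgG1": 0.66, "IgG2": 0.10, "IgG3": 0.05, "IgG4": 0.19}
    )
    base_traits: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "IgG1": dict(gal=0.50, sia=0.11, afuc=0.06, bis=0.12, hm=0.020),
            "IgG2": dict(gal=0.42, sia=0.10, afuc=0.04, bis=0.10, hm=0.015),
            "IgG3": dict(gal=0.48, sia=0.12, afuc=0.08, bis=0.10, hm=0.020),
            "IgG4": dict(gal=0.44, sia=0.10, afuc=0.05, bis=0.12, hm=0.015),
        }
    )
    # ACPA fractions: lower afucosylation and bisection than total IgG
    acpa_afuc_scale: float = 0.40
    acpa_bis_scale: float = 0.60
    # SF: lower galactosylation/sialylation than plasma (strongest in ACPA)
    sf_gal_shift_total: float = -0.03
    sf_gal_shift_acpa: float = -0.10
    sf_sia_scale_total: float = 0.90
    sf_sia_scale_acpa: float = 0.65
    # C_H3 occupancy of 2-site IgG3 allotypes
    occupancy_range: Tuple[float, float] = (0.10, 0.42)
    occupancy_fraction_scale: Mapping[str, float] = field(
        default_factory=lambda: {
            "total_plasma": 1.0,
            "total_SF": 0.95,
            "ACPA_plasma": 1.15,
            "ACPA_SF": 0.80,
        }
    )
    occupancy_clip: Tuple[float, float] = (0.07, 0.45)
    ch3_base: Mapping[str, float] = field(
        default_factory=lambda: {"H5N2": 0.35, "H3N4": 0.28, "H4N4": 0.22, "H4N4S1": 0.15}
    )
    ch3_hm_acpa: float = 0.50  # H5N2 share in ACPA fractions (renormalised)
    # PTM pool fractions (of the singly glycosylated pool)
    plusK_SF_total: float = 0.016
    plusK_SF_acpa: float = 0.032
    minusGK_IgG4_plasma: float = 0.05
    minusGK_IgG4_SF: float = 0.03
    cysteinylation: float = 0.02
    open_disulfide: float = 0.010
    openss_truncation: float = 0.015
    nonglyc_total: float = 0.003
    nonglyc_acpa: float = 0.0005
    # per-patient between-subject spread of trait targets
    jitter_sd: Mapping[str, float] = field(
        default_factory=lambda: {"gal": 0.04, "sia": 0.015, "afuc": 0.012, "bis": 0.025}
    )
    allotype_trait_offsets: Mapping[str, float] = field(
        default_factory=lambda: {"bis": 0.03, "afuc": 0.010}
    )
    rt_first: float = 660.0
    rt_spacing: float = 75.0
    rt_run_jitter_sd: float = 3.0


@dataclass
class PatientSample:
    patient_id: str
    allotypes: Dict[str, Allotype]
    profiles: Dict[str, FractionProfile]
    truth: pd.DataFrame
    clinical: Dict[str, float]
    run_seeds: Dict[str, int]
    rt_shifts: Dict[str, float]


def _clip01(x: float, lo: float = 0.0, hi: float = 1.0) -> float:
    return float(min(hi, max(lo, x)))


def sample_patient(
    config: SimulationConfig, seed: int, patient_id: Optional[str] = None
) -> PatientSample:
    """Draw one patient: allotype constitution, four fraction profiles, truth.

    Deterministic in ``seed``.  Profiles are internally consistent and
    the returned ground-truth table holds exactly the trait values the
    quantification formulas imply for them.
    """
    rng = np.random.default_rng(seed)
    patient_id = patient_id or f"P{seed}"
    reference = config.reference if config.reference is not None else load_allotype_reference()
    by_name = allotypes_by_name(reference)
    by_subclass: Dict[str, List[str]] = {}
    for name, allo in by_name.items():
        by_subclass.setdefault(allo.subclass, []).append(name)
    for names in by_subclass.values():
        names.sort()

    # allotype constitution: heterozygous subclasses carry both reference
    # allotypes (2-site IgG3 allotypes are listed second by name order)
    present: Dict[str, List[str]] = {}
    for subclass in ("IgG1", "IgG2", "IgG3", "IgG4"):
        names = by_subclass.get(subclass, [])
        if len(names) >= 2 and rng.random() < config.het_prob.get(subclass, 0.5):
            present[subclass] = names[:2]
        elif names:
            present[subclass] = [names[rng.integers(len(names))]]
    allotypes = {n: by_name[n] for names in present.values() for n in names}

    rt_centers = {
        name: config.rt_first + i * config.rt_spacing
        for i, name in enumerate(sorted(allotypes))
    }

    # patient-level latents shared across fractions (pairing structure)
    jit = {k: float(rng.normal(0.0, sd)) for k, sd in config.jitter_sd.items()}
    occ_base = float(rng.uniform(*config.occupancy_range))
    ratio_total = {sc: float(rng.uniform(0.30, 0.70)) for sc in present}
    ratio_acpa = {
        sc: _clip01(r + float(rng.normal(0.0, 0.08)), 0.05, 0.95)
        for sc, r in ratio_total.items()
    }
    subclass_jitter = {sc: float(rng.normal(0.0, 0.15)) for sc in present}

    profiles: Dict[str, FractionProfile] = {}
    for fraction in FRACTIONS:
        is_acpa = fraction.startswith("ACPA")
        is_sf = fraction.endswith("SF")
        means = config.acpa_subclass_means if is_acpa else config.total_subclass_means
        raw = {
            sc: max(0.005, means[sc] * math.exp(subclass_jitter[sc] + rng.normal(0.0, 0.05)))
            for sc in present
        }
        tot = sum(raw.values())
        subclass_abund = {sc: v / tot for sc, v in raw.items()}

        abund: Dict[str, float] = {}
        dists: Dict[str, Dict[str, float]] = {}
        ch3_dists: Dict[str, Dict[str, float]] = {}
        occupancy: Dict[str, float] = {}
        ptm_pools: Dict[str, Dict[str, float]] = {}
        nonglyc: Dict[str, float] = {}
        for sc, names in present.items():
            ratio = ratio_acpa[sc] if is_acpa else ratio_total[sc]
            weights = [ratio, 1.0 - ratio] if len(names) == 2 else [1.0]
            base = config.base_traits[sc]
            for idx, name in enumerate(names):
                abund[name] = subclass_abund[sc] * weights[idx]
                gal = base["gal"] + jit["gal"]
                sia = base["sia"] + jit["sia"]
                afuc = base["afuc"] + jit["afuc"]
                bis = base["bis"] + jit["bis"]
                if idx == 1:
                    bis += config.allotype_trait_offsets.get("bis", 0.0)
                    afuc += config.allotype_trait_offsets.get("afuc", 0.0)
                if is_acpa:
                    afuc *= config.acpa_afuc_scale
                    bis *= config.acpa_bis_scale
                if is_sf:
                    gal += config.sf_gal_shift_acpa if is_acpa else config.sf_gal_shift_total
                    sia *= config.sf_sia_scale_acpa if is_acpa else config.sf_sia_scale_total
                gal = _clip01(gal, 0.05, 0.95)
                afuc = _clip01(afuc, 0.005, 0.5)
                bis = _clip01(bis, 0.01, 0.5)
                sia = _clip01(sia, 0.0, gal)
                dists[name] = glycoform_distribution(gal, sia, afuc, bis, base["hm"])

                allo = allotypes[name]
                if allo.n_glyc_sites == 2:
                    p = occ_base * config.occupancy_fraction_scale[fraction]
                    occupancy[name] = _clip01(p, *config.occupancy_clip)
                    ch3 = dict(config.ch3_base)
                    if is_acpa:
                        rest = 1.0 - config.ch3_hm_acpa
                        others = {k: v for k, v in ch3.items() if k != "H5N2"}
                        s = sum(others.values())
                        ch3 = {"H5N2": config.ch3_hm_acpa}
                        ch3.update({k: rest * v / s for k, v in others.items()})
                    ch3_dists[name] = ch3

                pools: Dict[str, float] = {
                    "cysteinylation": config.cysteinylation,
                    "open_disulfide": config.open_disulfide,
                    "openSS_truncation": config.openss_truncation,
                }
                if is_sf:
                    pools["plusK"] = config.plusK_SF_acpa if is_acpa else config.plusK_SF_total
                if sc == "IgG4":
                    pools["minusGK"] = (
                        config.minusGK_IgG4_SF if is_sf else config.minusGK_IgG4_plasma
                    )
                ptm_pools[name] = pools
                nonglyc[name] = config.nonglyc_acpa if is_acpa else config.nonglyc_total

        profiles[fraction] = FractionProfile(
            fraction=fraction,
            allotype_abundances=abund,
            glycoform_dists=dists,
            ch3_dists=ch3_dists,
            ch3_occupancy=occupancy,
            ptm_pools=ptm_pools,
            nonglyc_frac=nonglyc,
            rt_centers=rt_centers,
        )

    truth = ground_truth_traits(patient_id, profiles, allotypes)

    u = float(rng.normal())
    clinical = {
        "ACPA_IgG_level": float(np.exp(4.0 + 0.8 * rng.normal())),
        "DAS28": _clip01(4.5 + 1.1 * u, 0.5, 9.0),
        "ESR": _clip01(30.0 + 14.0 * u + float(rng.normal(0.0, 6.0)), 2.0, 95.0),
    }
    run_seeds = {f: int(rng.integers(2**31)) for f in FRACTIONS}
    rt_shifts = {f: float(rng.normal(0.0, config.rt_run_jitter_sd)) for f in FRACTIONS}
    return PatientSample(patient_id, allotypes, profiles, truth, clinical, run_seeds, rt_shifts)


def simulate_cohort(
    n_patients: int, config: Optional[SimulationConfig] = None, seed: int = 0
) -> List[PatientSample]:
    """Draw a cohort of patients; patient i uses a sub-seed derived from ``seed``."""
    config = config or SimulationConfig()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_patients)
    return [
        sample_patient(config, int(child.generate_state(1)[0] % (2**31)), f"P{i + 1:02d}")
        for i, child in enumerate(children)
    ]


def ground_truth_traits(
    patient_id: str,
    profiles: Mapping[str, FractionProfile],
    allotypes: Mapping[str, Allotype],
) -> pd.DataFrame:
    """Exact trait table implied by the profiles (the recovery target).

    Tidy rows: patient, fraction, level (allotype/subclass), name,
    trait, value -- computed with the same derived-trait and weighting
    formulas the measurement pipeline uses.
    """
    rows: List[Dict] = []

    def add(fraction: str, level: str, name: str, trait: str, value: float) -> None:
        rows.append(
            dict(patient=patient_id, fraction=fraction, level=level, name=name,
                 trait=trait, value=value)
        )

    for fraction, prof in profiles.items():
        by_subclass: Dict[str, List[str]] = {}
        for name in prof.allotype_abundances:
            by_subclass.setdefault(allotypes[name].subclass, []).append(name)
        for names in by_subclass.values():
            names.sort()

        for name, a in prof.allotype_abundances.items():
            profile_pct = {k: 100.0 * v for k, v in prof.glycoform_dists[name].items()}
            for trait, value in derive_traits(profile_pct).items():
                add(fraction, "allotype", name, trait, value)
            for comp, v in profile_pct.items():
                add(fraction, "allotype", name, f"glycoform:{comp}", v)
            add(fraction, "allotype", name, "non_glycosylated",
                100.0 * prof.nonglyc_frac.get(name, 0.0))
            pools = prof.ptm_pools.get(name, {})
            p_none = 1.0 - sum(pools.values())
            for kind in ("plusK", "minusGK", "open_disulfide", "cysteinylation"):
                pk = pools.get(kind, 0.0)
                # open disulfides are quantified through the truncated form
                if kind == "open_disulfide":
                    pk = pools.get("openSS_truncation", pk)
                add(fraction, "allotype", name, kind, 100.0 * pk / (pk + p_none))
            if name in prof.ch3_occupancy:
                add(fraction, "allotype", name, "ch3_occupancy", prof.ch3_occupancy[name])
            add(fraction, "allotype", name, "allotype_abundance", 100.0 * a)

        for sc, names in by_subclass.items():
            sub_profiles = {
                n: {k: 100.0 * v for k, v in prof.glycoform_dists[n].items()} for n in names
            }
            avg = subclass_average(sub_profiles, prof.allotype_abundances)
            for trait, value in derive_traits(avg).items():
                add(fraction, "subclass", sc, trait, value)
            total = sum(prof.allotype_abundances[n] for n in names)
            add(fraction, "subclass", sc, "subclass_abundance", 100.0 * total)
            if len(names) == 2:
                a1 = prof.allotype_abundances[names[0]]
                a2 = prof.allotype_abundances[names[1]]
                add(fraction, "subclass", sc, "allotype_ratio", a1 / (a1 + a2))
    return pd.DataFrame(rows)


def render_run(
    profile: FractionProfile,
    spec: RunSpec,
    allotypes: Mapping[str, Allotype],
    rt_shift: float = 0.0,
    endos2: bool = False,
    metadata: Optional[Dict] = None,
) -> SpectrumRun:
    """Render a fraction profile into profile-mode MS1 spectra.

    Every species contributes, per charge state within the m/z window,
    a separable Gaussian (elution peak of width ``rt_sigma`` times an
    m/z peak of FWHM m/z / resolution) whose integrated ion current is
    proportional to the configured abundance.  Species entirely outside
    the m/z window are skipped with a warning.  Gaussian noise of
    standard deviation ``noise_sd`` is added and intensities clipped at
    zero.  Output is fully determined by ``spec.seed``.
    """
    rt0, rt1 = spec.rt_window
    mz0, mz1 = spec.mz_window
    rts = np.arange(rt0, rt1, spec.scan_interval)
    mz = np.arange(mz0, mz1 + spec.mz_step / 2, spec.mz_step)
    intensity = np.zeros((rts.size, mz.size))
    wsum = sum(spec.charge_weights)
    weights = [w / wsum for w in spec.charge_weights]
    sig_rt = spec.rt_sigma

    for species, a, rt_c in profile.species_abundances(allotypes, endos2=endos2):
        if a <= 0:
            continue
        mass = species.mass_avg
        rt_c = rt_c + rt_shift
        placed = False
        j0 = int(np.searchsorted(rts, rt_c - 5 * sig_rt))
        j1 = int(np.searchsorted(rts, rt_c + 5 * sig_rt))
        if j1 <= j0:
            continue
        g_rt = np.exp(-0.5 * ((rts[j0:j1] - rt_c) / sig_rt) ** 2)
        s = g_rt.sum() * spec.scan_interval
        if s <= 0:
            continue
        g_rt /= s
        for z, w in zip(spec.charges, weights):
            mzc = (mass + z * PROTON_MASS) / z
            if not mz0 <= mzc <= mz1:
                continue
            placed = True
            sig_mz = mzc / spec.resolution / _SIGMA
            i0 = int(np.searchsorted(mz, mzc - 6 * sig_mz))
            i1 = int(np.searchsorted(mz, mzc + 6 * sig_mz))
            if i1 <= i0:
                continue
            g_mz = np.exp(-0.5 * ((mz[i0:i1] - mzc) / sig_mz) ** 2)
            g_mz /= g_mz.sum() * spec.mz_step
            intensity[j0:j1, i0:i1] += (
                a * spec.total_ion_area * w * g_rt[:, None] * g_mz[None, :]
            )
        if not placed:
            warnings.warn(
                f"species {species.label} ({mass:.1f} Da) falls entirely outside "
                f"m/z {mz0:.0f}-{mz1:.0f}; skipped"
            )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        intensity += rng.normal(0.0, spec.noise_sd, intensity.shape)
        np.clip(intensity, 0.0, None, out=intensity)

    meta = dict(metadata or {})
    meta.setdefault("fraction", profile.fraction)
    meta.setdefault("seed", spec.seed)
    return SpectrumRun(rts, mz, intensity, meta)
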