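"""Allotype calling and combinatorial glycan-pair annotation.

Allotypes are identified by intact mass matching of deconvoluted Fc/2
masses against a reference table: an allotype is called when the
zero-charge spectrum shows at least two members of its expected
glycoform ladder (backbone + G0F/G1F/G2F by default) within tolerance.
A diploid patient carries at most two allotypes per subclass, hence at
most eight in total.

Doubly glycosylated IgG3 masses are assigned site-wise glycan pairs by
exhaustive enumeration over candidate Cₕ2 x Cₕ3 compositions, keeping
every combination within tolerance (isobaric assignments are always
co-reported, never collapsed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .proteoforms import Allotype, GlycanComposition, glycan_mass
from .reference import allotypes_by_name
from .signal import DeconvolvedSpectrum

__all__ = [
    "DEFAULT_EVIDENCE_GLYCANS",
    "AllotypeCall",
    "call_allotypes",
    "call_allotypes_windowed",
    "AnnotationResult",
    "annotate_double_glyc",
]

# evidence ladder: the ubiquitous fucosylated biantennary glycoforms
DEFAULT_EVIDENCE_GLYCANS = ("H3N4F1", "H4N4F1", "H5N4F1")


@dataclass
class AllotypeCall:
    """Allotypes supported by the deconvoluted spectrum of one patient/run."""

    allotypes: List[Allotype]
    evidence: Dict[str, List[Tuple[str, float, float]]]  # name -> (glycan, mass, intensity)
    ambiguous: Dict[str, List[str]] = field(default_factory=dict)
    patient: Optional[str] = None

    @property
    def names(self) -> List[str]:
        return [a.name for a in self.allotypes]


def call_allotypes(
    deconv: DeconvolvedSpectrum,
    reference: pd.DataFrame,
    tol: float = 2.0,
    evidence_glycans: Sequence[str] = DEFAULT_EVIDENCE_GLYCANS,
    min_evidence: int = 2,
    patient: Optional[str] = None,
) -> AllotypeCall:
    """Call allotypes from picked zero-charge masses.

    An allotype needs ``min_evidence`` of its expected glycoform masses
    (backbone + each evidence glycan) matched by picked peaks within
    ``tol`` Da; per subclass only the two best-supported calls are
    retained.  Allotypes whose expected ladders are isobaric within
    ``tol`` are co-reported with an ambiguity flag.
    """
    candidates = allotypes_by_name(reference)
    glycan_masses = {g: glycan_mass(g) for g in evidence_glycans}

    support: Dict[str, float] = {}
    evidence: Dict[str, List[Tuple[str, float, float]]] = {}
    expected: Dict[str, List[float]] = {}
    for name, allo in candidates.items():
        exp = {g: allo.backbone_mass_avg + m for g, m in glycan_masses.items()}
        expected[name] = list(exp.values())
        hits: List[Tuple[str, float, float]] = []
        total = 0.0
        for g, m in exp.items():
            peak = deconv.nearest_peak(m)
            if peak is not None and abs(peak[0] - m) <= tol:
                hits.append((g, peak[0], peak[1]))
                total += peak[1]
        if len(hits) >= min_evidence:
            support[name] = total
            evidence[name] = hits

    # keep at most the 2 best-supported allotypes per subclass
    called: List[Allotype] = []
    for subclass in sorted({candidates[n].subclass for n in support}):
        names = [n for n in support if candidates[n].subclass == subclass]
        names.sort(key=lambda n: -support[n])
        called.extend(candidates[n] for n in names[:2])
    called.sort(key=lambda a: a.name)

    ambiguous: Dict[str, List[str]] = {}
    called_names = [a.name for a in called]
    for i, a in enumerate(called_names):
        for b in called_names[i + 1 :]:
            if all(
                any(abs(ma - mb) <= tol for mb in expected[b]) for ma in expected[a]
            ):
                ambiguous.setdefault(a, []).append(b)
                ambiguous.setdefault(b, []).append(a)

    return AllotypeCall(called, {n: evidence[n] for n in called_names},
                        ambiguous, patient)


def call_allotypes_windowed(
    run,
    reference: pd.DataFrame,
    tol: float = 2.0,
    rt_window_width: float = 60.0,
    rt_step: float = 30.0,
    evidence_glycans: Sequence[str] = DEFAULT_EVIDENCE_GLYCANS,
    min_evidence: int = 2,
    rel_support_floor: float = 0.08,
    patient: Optional[str] = None,
    **deconv_kwargs,
) -> AllotypeCall:
    """Allotype calling over sliding retention-time windows.

    Allotypes elute at distinct retention times, so deconvoluting the
    spectrum summed over short chromatographic segments (instead of the
    whole run) keeps near-isobaric glycoforms of different allotypes
    from merging into shifted peaks.  Each window is deconvoluted and
    called separately; per allotype the best-supported window wins, and
    per subclass the two best-supported allotypes are retained.

    ``rel_support_floor`` discards calls whose summed evidence intensity
    is below that fraction of the strongest call in the same window:
    low-stoichiometry PTM satellites of an abundant allotype (e.g. a
    retained-lysine ladder at a few percent) can mimic another
    allotype's glycoform ladder, but a genuine allotype dominates its
    own elution window.
    """
    from .signal import deconvolve  # local import avoids a module cycle

    candidates = allotypes_by_name(reference)
    rts = run.rts
    starts = np.arange(float(rts[0]), float(rts[-1]), rt_step)
    best: Dict[str, Tuple[float, List[Tuple[str, float, float]]]] = {}
    ambiguous: Dict[str, List[str]] = {}
    for start in starts:
        window_call = call_allotypes(
            deconvolve(run, rt_range=(start, start + rt_window_width), **deconv_kwargs),
            reference,
            tol=tol,
            evidence_glycans=evidence_glycans,
            min_evidence=min_evidence,
        )
        supports = {
            name: sum(h[2] for h in hits)
            for name, hits in window_call.evidence.items()
        }
        floor = rel_support_floor * max(supports.values(), default=0.0)
        for name, hits in window_call.evidence.items():
            support = supports[name]
            if support < floor:
                continue
            if name not in best or support > best[name][0]:
                best[name] = (support, hits)
        for name, others in window_call.ambiguous.items():
            seen = ambiguous.setdefault(name, [])
            seen.extend(o for o in others if o not in seen)

    called: List[Allotype] = []
    for subclass in sorted({candidates[n].subclass for n in best}):
        names = [n for n in best if candidates[n].subclass == subclass]
        names.sort(key=lambda n: -best[n][0])
        called.extend(candidates[n] for n in names[:2])
    called.sort(key=lambda a: a.name)
    names = [a.name for a in called]
    return AllotypeCall(
        called,
        {n: best[n][1] for n in names},
        {n: v for n, v in ambiguous.items() if n in names},
        patient,
    )


@dataclass
class AnnotationResult:
    """Ranked site-wise glycan-pair assignments for one observed mass."""

    observed_mass: float
    tolerance: float
    candidates: List[Tuple[GlycanComposition, GlycanComposition, float]]
    # (ch2, ch3, delta = observed - theoretical), ranked by |delta|
    nearest_miss: Optional[Tuple[GlycanComposition, GlycanComposition, float]] = None

    @property
    def ambiguous(self) -> bool:
        return len(self.candidates) > 1

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "observed_mass": self.observed_mass,
                "rank": i + 1,
                "ch2": str(c2),
                "ch3": str(c3),
                "delta_mass": d,
                "ambiguity_flag": self.ambiguous,
            }
            for i, (c2, c3, d) in enumerate(self.candidates)
        ]
        return pd.DataFrame(rows)


def annotate_double_glyc(
    observed_mass: float,
    backbone_mass: float,
    ch2_candidates: Iterable[GlycanComposition],
    ch3_candidates: Iterable[GlycanComposition],
    tol: float = 1.5,
) -> AnnotationResult:
    """Exhaustively assign (Cₕ2, Cₕ3) glycan pairs to an observed mass.

    Every pair whose theoretical mass (backbone + both glycans) lies
    within ``tol`` Da of the observation is kept, ranked by absolute
    mass error; with no hit, the nearest miss is reported.
    """
    hits: List[Tuple[GlycanComposition, GlycanComposition, float]] = []
    nearest: Optional[Tuple[GlycanComposition, GlycanComposition, float]] = None
    for c2 in ch2_candidates:
        m2 = backbone_mass + c2.mass()
        for c3 in ch3_candidates:
            delta = observed_mass - (m2 + c3.mass())
            if abs(delta) <= tol:
                hits.append((c2, c3, delta))
            if nearest is None or abs(delta) < abs(nearest[2]):
                nearest = (c2, c3, delta)
    hits.sort(key=lambda h: (abs(h[2]), str(h[0]), str(h[1])))
    return AnnotationResult(
        observed_mass=observed_mass,
        tolerance=tol,
        candidates=hits,
        nearest_miss=None if hits else nearest,
    )
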