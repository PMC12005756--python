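"""Molecular model of IgG Fc/2 proteoform species.

An Fc/2 subunit is the single-chain ~25 kDa fragment released from IgG by
IdeS proteolysis below the hinge.  A species is fully described by

* an *allotype* -- the inherited constant-region sequence variant
  (IMGT ``IGHG<subclass>*<nn>`` nomenclature), which fixes the
  unglycosylated backbone mass,
* the *N*-glycan on the Cₕ2 domain (may be absent),
* for the IgG3 allotypes that carry a second site (Asn392), an optional
  *N*-glycan on the Cₕ3 domain,
* one of a small set of additional PTMs (C-terminal lysine retention,
  C-terminal GK loss, open Cₕ2 disulfides at +2 Da, the N-terminally
  truncated open-disulfide form, and cysteinylation).

Masses are additive: backbone + glycan residues + PTM delta.  Average
masses are the working currency throughout the pipeline because isotopes
are unresolved for 25 kDa species at TOF resolving power ~15000;
monoisotopic values are kept for bookkeeping only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Union

__all__ = [
    "GLYCAN_RESIDUE_AVG",
    "GLYCAN_RESIDUE_MONO",
    "PROTON_MASS",
    "PTM_DELTA_AVG",
    "GlycanComposition",
    "GlycanType",
    "GlycanClass",
    "classify_glycan",
    "glycan_mass",
    "Allotype",
    "PTMVariant",
    "PTM_NONE",
    "ProteoformSpecies",
    "species_mass",
    "COMMON_CH2_GLYCANS",
    "COMMON_CH3_GLYCANS",
    "GLYCAN_SHORTHAND",
    "endos2_stub",
]

# Residue (dehydrated monosaccharide) masses in Da.
# H = hexose, N = HexNAc, F = deoxyhexose (fucose), S = Neu5Ac.
GLYCAN_RESIDUE_AVG = {"H": 162.1406, "N": 203.1925, "F": 146.1412, "S": 291.2546}
GLYCAN_RESIDUE_MONO = {"H": 162.05282, "N": 203.07937, "F": 146.05791, "S": 291.09542}

PROTON_MASS = 1.00728  # Da, charge-carrier mass for positive ESI

# Average-mass deltas of the fixed PTM set. ``openSS_truncation`` is
# allotype-specific (loss of the N-terminal stretch upstream of the DP
# hydrolysis site when the C_H2 disulfide is open) and lives on Allotype.
PTM_DELTA_AVG = {
    "none": 0.0,
    "plusK": 128.1741,           # retained C-terminal lysine
    "minusGK": -185.2254,        # loss of C-terminal Gly-Lys
    "cysteinylation": 119.1442,  # free cysteine via disulfide
    "open_disulfide": 2.0159,    # reduced C_H2 disulfide, +2 H
}

_COMP_RE = re.compile(r"([HNFS])(\d+)")


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """An N-glycan composition HxNyFzSw (counts of monosaccharide classes)."""

    H: int = 0
    N: int = 0
    F: int = 0
    S: int = 0

    def __post_init__(self) -> None:
        for key in ("H", "N", "F", "S"):
            v = getattr(self, key)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"negative or non-integer {key} count: {v!r}")

    @classmethod
    def from_string(cls, text: str) -> "GlycanComposition":
        """Parse ``"H3N4F1"`` style composition strings.

        Zero counts may be omitted; the empty string is the empty
        composition.
        """
        text = text.strip()
        counts = {"H": 0, "N": 0, "F": 0, "S": 0}
        consumed = 0
        for m in _COMP_RE.finditer(text):
            counts[m.group(1)] += int(m.group(2))
            consumed += len(m.group(0))
        if consumed != len(text):
            raise ValueError(f"unparsable glycan composition: {text!r}")
        return cls(**counts)

    def __str__(self) -> str:
        parts = [f"{k}{getattr(self, k)}" for k in ("H", "N", "F", "S") if getattr(self, k)]
        return "".join(parts)

    def mass(self, monoisotopic: bool = False) -> float:
        table = GLYCAN_RESIDUE_MONO if monoisotopic else GLYCAN_RESIDUE_AVG
        return sum(getattr(self, k) * table[k] for k in ("H", "N", "F", "S"))


GlycanLike = Union[GlycanComposition, str]


def _as_composition(g: GlycanLike) -> GlycanComposition:
    if isinstance(g, GlycanComposition):
        return g
    return GlycanComposition.from_string(g)


def glycan_mass(g: GlycanLike, monoisotopic: bool = False) -> float:
    """Residue mass of a glycan composition in Da."""
    return _as_composition(g).mass(monoisotopic=monoisotopic)


class GlycanType(str, Enum):
    COMPLEX = "complex"
    HIGH_MANNOSE = "high_mannose"
    STUB = "stub"


@dataclass(frozen=True)
class GlycanClass:
    """Structural reading of a composition under the biantennary IgG-Fc convention.

    Galactose count is inferred as H-3 on complex glycans (Man3 core),
    bisection as a fifth HexNAc.
    """

    type: GlycanType
    n_gal: int = 0
    bisecting: bool = False
    fucosylated: bool = False
    n_sia: int = 0


def classify_glycan(g: GlycanLike) -> GlycanClass:
    """Classify a composition as complex / high-mannose / chitobiose stub.

    High-mannose requires N=2 with at least 4 hexoses; a stub (EndoS2
    remnant) has at most one HexNAc; everything else is treated as a
    complex-type biantennary glycan.
    """
    c = _as_composition(g)
    if c.N <= 1:
        return GlycanClass(GlycanType.STUB, fucosylated=c.F >= 1)
    if c.N == 2 and c.H >= 4:
        return GlycanClass(GlycanType.HIGH_MANNOSE)
    return GlycanClass(
        GlycanType.COMPLEX,
        n_gal=min(2, max(0, c.H - 3)),
        bisecting=c.N >= 5,
        fucosylated=c.F >= 1,
        n_sia=min(2, c.S),
    )


_SUBCLASS_RE = re.compile(r"^IGHG([1-4])\*\d+")


@dataclass(frozen=True)
class Allotype:
    """One IgG constant-region allotype and its Fc/2 backbone mass."""

    name: str
    subclass: str  # "IgG1" .. "IgG4"
    backbone_mass_avg: float
    n_glyc_sites: int = 1
    openss_truncation_delta: Optional[float] = None

    def __post_init__(self) -> None:
        if self.backbone_mass_avg <= 0:
            raise ValueError("backbone_mass_avg must be positive")
        if self.n_glyc_sites not in (1, 2):
            raise ValueError("n_glyc_sites must be 1 or 2")
        m = _SUBCLASS_RE.match(self.name)
        if m and f"IgG{m.group(1)}" != self.subclass:
            raise ValueError(
                f"subclass {self.subclass!r} inconsistent with allotype name {self.name!r}"
            )


@dataclass(frozen=True)
class PTMVariant:
    """A single additional PTM with its average-mass delta."""

    kind: str = "none"
    delta_mass_avg: float = 0.0

    @classmethod
    def standard(cls, kind: str, allotype: Optional[Allotype] = None) -> "PTMVariant":
        """Construct one of the fixed PTM variants.

        ``openSS_truncation`` needs the allotype because the lost
        N-terminal stretch is sequence-dependent.
        """
        if kind in PTM_DELTA_AVG:
            return cls(kind, PTM_DELTA_AVG[kind])
        if kind == "openSS_truncation":
            if allotype is None or allotype.openss_truncation_delta is None:
                raise ValueError(
                    "openSS_truncation requires an allotype with a truncation delta"
                )
            return cls(kind, allotype.openss_truncation_delta)
        raise ValueError(f"unknown PTM kind: {kind!r}")


PTM_NONE = PTMVariant()


@dataclass(frozen=True)
class ProteoformSpecies:
    """One molecular Fc/2 species: allotype + site-wise glycans + PTM."""

    allotype: Allotype
    ch2_glycan: Optional[GlycanComposition] = None
    ch3_glycan: Optional[GlycanComposition] = None
    ptm: PTMVariant = PTM_NONE

    def __post_init__(self) -> None:
        if self.ch3_glycan is not None and self.allotype.n_glyc_sites != 2:
            raise ValueError(
                f"{self.allotype.name} has a single glycosylation site; "
                "ch3_glycan must be absent"
            )

    @property
    def mass_avg(self) -> float:
        m = self.allotype.backbone_mass_avg + self.ptm.delta_mass_avg
        if self.ch2_glycan is not None:
            m += self.ch2_glycan.mass()
        if self.ch3_glycan is not None:
            m += self.ch3_glycan.mass()
        return m

    @property
    def label(self) -> str:
        g2 = str(self.ch2_glycan) if self.ch2_glycan is not None else "nonglyc"
        parts = [self.allotype.name, g2]
        if self.ch3_glycan is not None:
            parts.append(f"CH3:{self.ch3_glycan}")
        if self.ptm.kind != "none":
            parts.append(self.ptm.kind)
        return "|".join(parts)


def species_mass(s: ProteoformSpecies) -> float:
    """Average mass of a proteoform species in Da (additive bookkeeping)."""
    return s.mass_avg


def endos2_stub(g: GlycanLike) -> GlycanComposition:
    """Truncate a glycan to its EndoS2 chitobiose remnant.

    EndoS2 hydrolyses between the two core GlcNAcs, leaving a single
    GlcNAc that retains the core fucose if present.
    """
    c = _as_composition(g)
    if c.N == 0:
        return GlycanComposition()
    return GlycanComposition(N=1, F=min(c.F, 1))


# Widely used shorthand for biantennary IgG-Fc glycans; used as the default
# candidate library for annotation and EIC quantification.
GLYCAN_SHORTHAND = {
    "G0": "H3N4",
    "G1": "H4N4",
    "G2": "H5N4",
    "G0F": "H3N4F1",
    "G1F": "H4N4F1",
    "G2F": "H5N4F1",
    "G0FN": "H3N5F1",
    "G1FN": "H4N5F1",
    "G2FN": "H5N5F1",
    "G1S1": "H4N4S1",
    "G2S1": "H5N4S1",
    "G1FS1": "H4N4F1S1",
    "G2FS1": "H5N4F1S1",
    "G2FS2": "H5N4F1S2",
    "G1FNS1": "H4N5F1S1",
    "G2FNS1": "H5N5F1S1",
    "G2FNS2": "H5N5F1S2",
    "M5": "H5N2",
    "M6": "H6N2",
}

COMMON_CH2_GLYCANS = tuple(
    GlycanComposition.from_string(s)
    for s in (
        "H3N4", "H4N4", "H5N4",
        "H3N4F1", "H4N4F1", "H5N4F1",
        "H3N5F1", "H4N5F1", "H5N5F1",
        "H3N5", "H4N5", "H5N5",
        "H4N4S1", "H5N4S1", "H5N4S2",
        "H4N4F1S1", "H5N4F1S1", "H5N4F1S2",
        "H4N5S1", "H5N5S1",
        "H4N5F1S1", "H5N5F1S1", "H5N5F1S2", "H5N5S2",
        "H5N2", "H6N2",
    )
)

# C_H3-domain glycans observed on doubly glycosylated IgG3 are dominated by
# high-mannose and afucosylated complex types.
COMMON_CH3_GLYCANS = tuple(
    GlycanComposition.from_string(s)
    for s in ("H5N2", "H6N2", "H3N4", "H4N4", "H5N4", "H4N4S1", "H5N4S1")
)
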