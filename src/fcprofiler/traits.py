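"""Derived glycosylation traits.

A glycoform profile (composition -> percent) is condensed into summary
traits.  Arm-counted traits use the "weighted twice" rule: a
digalactosylated glycan contributes twice as much galactosylation as a
monogalactosylated one, and likewise for sialylation, so a profile that
is 100% digalactosylated scores exactly 100%.

Denominators: traits describing the complex-type repertoire
(galactosylation, agalactosylation, sialylation, afucosylation,
bisection, and the mono/di sub-traits) are normalised to the
complex-type fraction of the profile; ``high_mannose`` is reported
against the full glycan profile, and ``non_glycosylated`` (handled at
the species level, not here) against the full species total.
"""

from __future__ import annotations

import math
from typing import Dict, Mapping, Optional

from .proteoforms import GlycanType, classify_glycan

__all__ = ["derive_traits", "TRAIT_NAMES"]

TRAIT_NAMES = (
    "galactosylation",
    "agalactosylation",
    "sialylation",
    "afucosylation",
    "bisection",
    "high_mannose",
)

_SUBTRAIT_NAMES = (
    "mono_galactosylation",
    "di_galactosylation",
    "mono_sialylation",
    "di_sialylation",
)


def derive_traits(
    profile: Optional[Mapping[str, float]],
    include_subtraits: bool = False,
) -> Dict[str, float]:
    """Summary traits (percent) of a glycoform profile.

    ``profile`` maps composition strings (``"H3N4F1"``) to relative
    abundances; it need not be normalised.  An empty or missing profile
    yields NaN for every trait.
    """
    names = TRAIT_NAMES + (_SUBTRAIT_NAMES if include_subtraits else ())
    if not profile:
        return {t: math.nan for t in names}

    total = float(sum(profile.values()))
    if total <= 0:
        return {t: math.nan for t in names}

    complex_total = 0.0
    gal = sia = afuc = bis = agal = hm = 0.0
    mono_gal = di_gal = mono_sia = di_sia = 0.0
    for comp, a in profile.items():
        cls = classify_glycan(comp)
        if cls.type is GlycanType.HIGH_MANNOSE:
            hm += a
        elif cls.type is GlycanType.COMPLEX:
            complex_total += a
            gal += a * cls.n_gal / 2.0
            sia += a * cls.n_sia / 2.0
            if not cls.fucosylated:
                afuc += a
            if cls.bisecting:
                bis += a
            if cls.n_gal == 0:
                agal += a
            elif cls.n_gal == 1:
                mono_gal += a
            else:
                di_gal += a
            if cls.n_sia == 1:
                mono_sia += a
            elif cls.n_sia >= 2:
                di_sia += a
        # stubs (EndoS2 remnants) enter no trait numerator

    out: Dict[str, float] = {}
    if complex_total > 0:
        out["galactosylation"] = 100.0 * gal / complex_total
        out["agalactosylation"] = 100.0 * agal / complex_total
        out["sialylation"] = 100.0 * sia / complex_total
        out["afucosylation"] = 100.0 * afuc / complex_total
        out["bisection"] = 100.0 * bis / complex_total
        if include_subtraits:
            out["mono_galactosylation"] = 100.0 * mono_gal / complex_total
            out["di_galactosylation"] = 100.0 * di_gal / complex_total
            out["mono_sialylation"] = 100.0 * mono_sia / complex_total
            out["di_sialylation"] = 100.0 * di_sia / complex_total
    else:
        for t in names:
            out[t] = math.nan
    out["high_mannose"] = 100.0 * hm / total
    return out
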