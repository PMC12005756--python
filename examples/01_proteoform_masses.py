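"""Build Fc/2 proteoform species and inspect their masses and glycan classes.

An Fc/2 subunit is the ~25 kDa single-chain fragment IdeS releases from
IgG below the hinge.  Its mass is the allotype backbone plus glycan
residues plus any PTM delta.
"""

from fcprofiler import (
    GlycanComposition,
    ProteoformSpecies,
    PTMVariant,
    classify_glycan,
    glycan_mass,
)
from fcprofiler.reference import allotypes_by_name, load_allotype_reference

reference = load_allotype_reference()
allotypes = allotypes_by_name(reference)
allo = allotypes["IGHG1*01"]

g0f = GlycanComposition.from_string("H3N4F1")  # agalactosylated core-fucosylated
print(f"G0F residue mass: {glycan_mass(g0f):.3f} Da (avg), "
      f"{glycan_mass(g0f, monoisotopic=True):.3f} Da (mono)")

species = ProteoformSpecies(allo, g0f)
print(f"{species.label}: {species.mass_avg:.2f} Da")
# backbone + glycan; at z=20 this species appears near m/z (M + 20*1.00728)/20
print(f"  -> m/z at z=20: {(species.mass_avg + 20 * 1.00728) / 20:.3f}")

plus_k = ProteoformSpecies(allo, g0f, ptm=PTMVariant.standard("plusK"))
print(f"with retained C-terminal Lys: +{plus_k.mass_avg - species.mass_avg:.2f} Da")

for comp in ("H3N4F1", "H5N4F1S1", "H5N2", "H5N5F1"):
    cls = classify_glycan(comp)
    print(f"{comp:10s} type={cls.type.value:12s} gal={cls.n_gal} "
          f"bisecting={cls.bisecting} fucosylated={cls.fucosylated} sia={cls.n_sia}")

# a doubly glycosylated IgG3 Fc/2 (C_H2 + C_H3 site)
igg3 = allotypes["IGHG3*11"]
double = ProteoformSpecies(igg3, g0f, GlycanComposition.from_string("H5N2"))
print(f"{double.label}: {double.mass_avg:.2f} Da "
      "(the anchor species for C_H3 occupancy)")
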