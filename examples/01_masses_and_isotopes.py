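"""Mass bookkeeping for a glycopeptide: backbone, Y ladder, isotopes.

Computes the neutral mass of a deglycopeptide backbone, the theoretical
Y0-Y5 ladder used to augment library spectra, and the theoretical isotope
pattern + idotp check used to vet precursor assignments.
"""

from glycosearch import (
    ModifiedPeptide,
    glyco_y_ladder,
    glycopeptide_composition,
    idotp,
    isotope_distribution,
    peptide_mono_mass,
)

peptide = ModifiedPeptide("LNGTASLHFK")
backbone = peptide_mono_mass(peptide)
print(f"backbone neutral mass      : {backbone:.4f} Da")

# Y ions: peptide + 0..5 core sugars (HexNAc2Hex3), singly protonated
print("Y0-Y5 ladder (1+), m/z     :",
      " ".join(f"{mz:.3f}" for i, z, mz in glyco_y_ladder(backbone, (1,))))

# elemental composition of the intact glycopeptide with a biantennary glycan
comp = glycopeptide_composition(peptide, {"Hex": 5, "HexNAc": 4, "NeuAc": 2})
print("intact glycopeptide formula:",
      " ".join(f"{el}{n}" for el, n in sorted(comp.items())))
print(f"intact glycopeptide mass   : {comp.mono_mass():.4f} Da")

# first six isotopologue abundances and a perfect-observation idotp
pattern = isotope_distribution(comp, 6)
print("isotope pattern M0..M5     :",
      " ".join(f"{a:.4f}" for a in pattern.abundances))
print(f"idotp vs itself            : {idotp(pattern.as_array(), pattern):.4f}")
print("(1.0 means the observed envelope matches the theoretical one exactly)")
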