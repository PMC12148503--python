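"""Cysteinylation mass arithmetic.

A free cysteine attaching to a protein thiol through a disulfide adds
the mass of cysteine minus two hydrogens (the linkage releases 2 H).
This is the +119 Da shift that intact-mass spectrometry reports for
cysteinylated monomers, which disappears on reduction.
"""

from ssbond import cysteinylation_mass_shift

avg = cysteinylation_mass_shift("average")
mono = cysteinylation_mass_shift("monoisotopic")
print(f"average mass shift      : {avg:.3f} Da  (rounds to {round(avg)} Da)")
print(f"monoisotopic mass shift : {mono:.3f} Da")
print("A +119 Da adduct that vanishes with TCEP is the signature of a "
      "cysteinylated free cysteine.")
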