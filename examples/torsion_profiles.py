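"""AMBER torsion strain across the cystine dihedrals.

Evaluates the three cosine-series torsion terms and prints the
landmarks of the χ3 (Cβ-S-S′-Cβ′) curve: relaxed disulfides sit near
χ3 = ±90° (0.6 kcal/mol), while an eclipsed syn-periplanar bond at
χ3 = 0° pays the full 8.2 kcal/mol — the torsional-strain ceiling.
"""

from ssbond import e_chi1, e_chi2, e_chi3, energy_profile

for chi3 in (0.0, 90.0, -90.0, 180.0):
    print(f"E(chi3 = {chi3:6.1f} deg) = {float(e_chi3(chi3)):.2f} kcal/mol")

prof = energy_profile("chi3", step=1.0)
print(f"chi3 global maximum at {prof.argmax:.0f} deg "
      f"({prof.values.max():.1f} kcal/mol) -> syn-periplanar is the most "
      "strained disulfide conformation")

chi1_bonded = -120.3  # a disulfide-bonded χ1 rotamer between canonical wells
print(f"E(chi1 = {chi1_bonded} deg) = {float(e_chi1(chi1_bonded)):.3f} kcal/mol "
      "(near the top of the chi1 barrier: an uncommon, high-energy rotamer)")
print(f"E(chi2 = -80 deg) = {float(e_chi2(-80.0)):.3f} kcal/mol")
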