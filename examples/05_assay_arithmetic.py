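"""Cofactor and quinone quantification arithmetic.

Beer–Lambert flavin concentration, occupancy per protein monomer, and the
internal-standard recovery correction that calibrates analyte losses during
lipid extraction.
"""

from chokepoint.assaycalc import (
    AssayReading,
    EPSILON_FAD_450,
    cofactor_occupancy,
    concentration_from_absorbance,
    internal_standard_correction,
)

c = concentration_from_absorbance(AssayReading(0.113), EPSILON_FAD_450)
print(f"A450 = 0.113, eps = 11300 /M/cm -> flavin = {c * 1e6:.1f} uM")

occ = cofactor_occupancy(8.5e-6, 10e-6)
print(f"flavin 8.5 uM on protein 10 uM -> occupancy {occ:.0%} per monomer")

corrected, recovery = internal_standard_correction(
    measured_analyte=40.0, standard_added=100.0, standard_recovered=80.0)
print(f"standard recovery {recovery:.0%}: measured 40 pmol -> corrected "
      f"{corrected:.0f} pmol")
print("\nThe spiked standard's recovery fraction rescales the analyte, "
      "exactly inverting proportional extraction losses.")
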