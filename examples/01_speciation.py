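"""Henderson-Hasselbalch speciation: from intrinsic solubility to S(pH).

Builds a weak base (pKa 9), evaluates its solubility two pH units below the
pKa, and inverts the map to recover the intrinsic solubility.
"""

from intrisol import (
    IonizationModel,
    intrinsic_from_measured,
    ionization_factor,
    solubility_at_ph,
)

base = IonizationModel(basic_pkas=(9.0,))

log_phi = ionization_factor(base, 7.0).log_phi
print(f"log10 Phi at pH 7 for a base with pKa 9: {log_phi:.5f}")
# ~2.004: at two pH units below the pKa the compound is ~99% protonated,
# so total solubility is ~100x the intrinsic value.

log_s = solubility_at_ph(-6.0, base, 7.0)
print(f"log10 S(pH 7) for log10 S0 = -6:        {log_s:.5f}")

back = intrinsic_from_measured(log_s, base, 7.0)
print(f"inverted back to intrinsic S0:          {back:.5f}")
# the forward and inverse maps are exact inverses of each other.
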