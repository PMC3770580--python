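"""Calibrating microscopic reaction rates from measured rate constants.

A bimolecular rate constant measured in bulk (macroscopic, nm^3/us or
1/(M s)) mixes diffusional encounter formation with the intrinsic
reactivity of the encounter pair. A particle simulation resolves the
encounters explicitly, so it needs the intrinsic (microscopic) rate
lambda: the inversion interpolates between the reaction-limited regime
(k = lambda * encounter volume) and the diffusion-limited Smoluchowski
ceiling 4 pi D R.
"""

import numpy as np

from rdx import (
    erban_macroscopic_rate,
    invert_erban,
    molar_rate_conversion,
    smoluchowski_encounter_rate,
)

d_sum = 143.1 + 71.6  # A + B mutual diffusion, nm^2/us
radius = 1.5 + 3.0  # summed reaction radii, nm

k_enc = smoluchowski_encounter_rate(143.1, 71.6, radius)
print(f"diffusion-limited encounter rate: {k_enc:.4g} nm^3/us "
      f"({molar_rate_conversion(k_enc):.3g} 1/(M s))")

for k_macro in (6.0, 60.0, 600.0, 6000.0):
    lam = invert_erban(k_macro, d_sum, radius)
    back = erban_macroscopic_rate(lam, d_sum, radius)
    print(f"k_macro = {k_macro:7.1f} nm^3/us -> lambda = {lam:10.4g} 1/us "
          f"(round trip {back:.6g})")

# Far below the ceiling lambda grows linearly with k_macro; approaching the
# ceiling it diverges - no finite intrinsic rate can beat diffusion.
lam_grid = np.geomspace(1e-3, 1e4, 8)
print("\nlambda -> k_macro saturation:")
for lam in lam_grid:
    print(f"  lambda = {lam:9.3g} 1/us -> k = "
          f"{erban_macroscopic_rate(lam, d_sum, radius):9.4g} nm^3/us")
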