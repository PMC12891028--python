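"""Render A-band fluorescence profiles and measure their FWHM.

Compares a myosin-heavy-chain stain (all crowns) with phospho-RLC
occupancies confined to the C-zone or spilling into the D-zone.
"""

import numpy as np

from thickfil import imaging
from thickfil.geometry import build_half_filament

geom = build_half_filament()

# uniform MHC stain: every crown weighted by its head count
mhc = imaging.render_profile(geom, None)
print(f"MHC profile FWHM: {imaging.fwhm(mhc).fwhm_um:.3f} um")

# phospho-RLC confined to P+C crowns
occ = np.where(np.isin(geom.zones, ["P", "C"]), 1.0, 0.0)
czone = imaging.OccupancyMap(occ, float(occ.mean()))
print(f"C-zone-confined FWHM: "
      f"{imaging.fwhm(imaging.render_profile(geom, czone)).fwhm_um:.3f} um")

# sequential spillover at a global level of 0.6 mol Pi / mol RLC
for level in (0.2, 0.6, 0.9):
    omap = imaging.occupancy_from_level(geom, level, "sequential")
    w = imaging.fwhm(imaging.render_profile(geom, omap)).fwhm_um
    print(f"sequential occupancy, level {level:.1f}: FWHM = {w:.3f} um")

# The phospho-RLC width tracks where the phosphorylated heads sit: the
# C-zone doublet (~1.06 um) is narrower than the full A-band (~1.58 um),
# and the width grows as phosphorylation spills into the D-zone.
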