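"""Build the default rodent half thick filament and inspect its zones."""

from thickfil.geometry import build_half_filament, zone_extent

geom = build_half_filament()
frac = geom.zone_head_fractions()

print("crowns per half filament:", geom.n_crowns_half)
print("heads per half filament:", geom.n_heads_half)
print("zone head fractions:", {z: round(f, 3) for z, f in frac.items()})
print("C-zone axial extent (nm from M-line):",
      tuple(round(x, 2) for x in zone_extent(geom, "C")))
print("A-band doublet span (um):", round(geom.full_filament_span_nm() / 1000, 3))

# The C-zone fraction (~0.55) is the share of myosin motors lying in the
# cMyBP-C-containing region; the doublet span (~1.56 um) matches the
# A-band length of ventricular myofibrils.
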