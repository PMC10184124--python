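"""Protrusion extraction from an atomistic-style structure.

Builds a pseudo-atom bilayer in which the anchored molecule's linker sits
exactly 0.31 nm below its leaflet's headgroup plane, assigns leaflets by
the side of the bilayer midplane, and extracts the protrusion coordinate
z relative to the per-frame matrix-headgroup center of mass. Both leaflets
must report the same z = -0.31 nm: the sign convention is aqueous-positive
in either leaflet. For real trajectories the same call chain starts from
``lipidspring.load_structure`` with PDB/GRO + XTC/DCD files and MDAnalysis
selection expressions for the linker / headgroup / saccharide groups.
"""

import lipidspring as ls
from lipidspring.geometry import assign_leaflets, protrusion_series

frames = assign_leaflets(ls.make_toy_structure(n_lipids_per_leaflet=8, linker_offset=0.31))
anchors = sorted({int(r) for r, n in zip(frames.resids, frames.resnames) if n == "ANCH"})
for resid in anchors:
    series = protrusion_series(frames, resid)
    print(f"{series.label}: z = {series.z[0]:+.3f} nm over {series.n_frames} frames")
print("z < 0 means the linker sits below the headgroup plane, as for real")
print("glycolipid anchors; binding or pulling shifts z upward (toward water).")
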