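"""Peg-and-socket depth measurement and the morphological-closing contract.

A peg is the finger-like pericyte protrusion into an endothelial
invagination.  Depth is the maximum Euclidean distance-transform value
over the peg, measured from the abluminal endothelial surface after
closing the EC+peg+lumen mask with a 134 nm disk.  The closing seals a
thin basement-membrane cleft between peg and socket (a real feature of
these junctions), so the programmed 400 nm depth is recovered; a gap
wider than the element is preserved and the measured depth collapses.
"""

from dataclasses import replace

from pericytometry import peg_max_depths
from pericytometry.synthetic import SyntheticVesselSpec, generate_vessel

base = SyntheticVesselSpec(
    peg_count_per_section=1,
    peg_depth_nm=400.0,
    n_sections=1,
    grid_px=512,
    pixel_size_nm=20.0,
    seed=17,
)

for cleft in (0.0, 100.0, 300.0):
    stack, _ = generate_vessel(replace(base, peg_cleft_nm=cleft))
    (rec,) = peg_max_depths(stack.sections[0])
    sealed = "sealed by closing" if cleft <= 268 else "NOT sealed"
    print(
        f"cleft {cleft:5.0f} nm ({sealed}): "
        f"measured depth {rec.max_depth_nm:6.1f} nm, "
        f"area {rec.area_nm2/1e3:6.1f} x10^3 nm^2"
    )
print("programmed depth was 400 nm; an unsealed 300 nm gap breaks the")
print("depth continuity, which is exactly why the closing step exists")
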