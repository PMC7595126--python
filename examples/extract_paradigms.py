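"""Extract GCIPL over the 8×8 grid and the VF-based paradigms for one eye.

Shows the headline single-eye effect: the four central grid squares average
across the GC-poor foveal pit, while the displaced central VF locations
sample the GC-rich parafovea and read ~25 μm thicker.
"""

import numpy as np

from maculamap import (StimulusSpec, TopographyModel, build_vf_grid,
                       make_topography, process_volume, scan_topography)

topo = make_topography(TopographyModel(noise_sd_um=0.0, anisotropy=1.0))
vol = scan_topography(topo, tilt_deg=6.6, seed=0)
res = process_volume(vol)

v = res.grid_set.values_um.reshape(8, 8)
print("8x8 grid GCIPL means (um), superior-temporal first:")
print(np.array2string(v, precision=1, floatmode="fixed"))

central_sq = [v[3, 3], v[3, 4], v[4, 3], v[4, 4]]
print(f"\ncentral 4 squares: {np.mean(central_sq):.1f} um "
      "(pit pulls the average down)")

vfg = build_vf_grid(StimulusSpec.from_goldmann("GIII"))
cen = [i for i, l in enumerate(vfg.locations)
       if abs(l.field_deg[0]) == 1 and abs(l.field_deg[1]) == 1]
for g in ("GII", "GIII", "GV"):
    m = res.vf_sets[g].values_um[cen].mean()
    print(f"central 4 VF locations, {g}: {m:.1f} um")
print("\nGV < GIII < GII at the fovea: the larger stimulus disc encroaches")
print("on the pit.  All VF values exceed the grid squares by ~25 um.")

asg = res.assignments["GIII"]
n_assigned = sum(a is not None for a in asg)
print(f"\ngreatest-shared-area assignment: {n_assigned}/80 locations "
      f"assigned to a grid square under this eye's {res.tilt_deg:.1f}° tilt")
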