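"""Cohort-level comparison on the default synthetic study population.

Generates the default 40-eye cohort (tilts drawn from the reference
population, ~half stored left-eye), runs the full pipeline per eye, and
prints the pointwise statistics: Wilcoxon differences vs the 8×8 grid,
tilt correlations, and Friedman tests across stimulus sizes.

Takes ~1 minute.
"""

import numpy as np

from maculamap import (CohortSpec, StimulusSpec, analyze_cohort,
                       build_vf_grid, make_cohort, process_volume)

volumes, manifest = make_cohort(CohortSpec(n_participants=40))
tilts = [e["tilt_deg"] for e in manifest["participants"]]
print(f"cohort: n={len(volumes)}, tilt {np.mean(tilts):.2f} ± "
      f"{np.std(tilts):.2f}° (range {min(tilts):.1f} to {max(tilts):.1f})")

results = [process_volume(v) for v in volumes]
analysis = analyze_cohort(results)

tab = analysis["vs_grid"]["GIII"].table
print(f"\nGIII vs 8x8 grid, {len(tab)} locations:")
print(f"  significant (Wilcoxon p<0.05): {int(tab['significant'].sum())}")
print(f"  |median diff| > 3.9 um (axial resolution): "
      f"{int((tab['median_diff_um'].abs() > 3.9).sum())}")

vfg = build_vf_grid(StimulusSpec.from_goldmann("GIII"))
cen = [i for i, l in enumerate(vfg.locations)
       if abs(l.field_deg[0]) == 1 and abs(l.field_deg[1]) == 1]
cen_med = tab.loc[tab["location_id"].isin(cen), "median_diff_um"]
print(f"  central-4 median difference: {cen_med.median():.1f} um "
      "(VF-based values larger: the pit is excluded)")

ecc = np.array([np.hypot(*l.field_deg) for l in vfg.locations])
sig = tab["rho_significant"].to_numpy()
print(f"\ntilt sensitivity (Spearman p<0.05):")
print(f"  6°-8° annulus: {sig[(ecc >= 6) & (ecc <= 8)].mean():.0%} of locations")
print(f"  central 2°:    {sig[ecc <= 2].mean():.0%} of locations")

sizes = analysis["sizes"]
print(f"\nFriedman across GII/GIII/GV: {int(sizes['significant'].sum())} "
      f"of {len(sizes)} locations differ with stimulus size")
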