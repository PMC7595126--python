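# Methods

This note documents the models, conventions and numerical choices behind
`maculamap`, and what the synthetic phantom does and does not establish
about real data.

## Coordinate frames and conventions

All en-face coordinates are micrometres with the origin at the foveal
centre, in right-eye format: x increases toward the optic disc (nasal),
y toward superior retina. Two frames matter:

* the **field frame** (0° tilt), aligned with the perimetric/head frame;
* the **scan frame**, rotated to the fovea–optic-disc axis along which the
  scanner acquires.

The fovea–disc tilt is positive when the disc centre lies below the
horizontal through the fovea; with y pointing superior this makes the scan
frame a clockwise rotation of the field frame, so fixed points transform as
`p_scan = R(+tilt)·p_field`. Left-eye volumes are mirrored along the
a-scan axis into right-eye format; the mirror flips the tilt's sign (a
reflection conjugates rotations) and is an involution, which the tests
enforce bit-exactly. Field-to-retina mapping negates both axes (superior
field → inferior retina, nasal field → temporal retina).

Degrees convert to retinal micrometres through one global factor,
286.5 μm/deg. This value is back-derived from the published no-allowance
Goldmann projection areas: it is the unique factor (to 3 s.f.) reproducing
all three of 0.00298, 0.0119 and 0.191 mm² from subtenses 0.215°, 0.43° and
1.72°. Eccentricity-dependent magnification is deliberately not modelled;
the factor is configurable for other schematic eyes. The printed
with-allowance areas are not mutually consistent with any single disc
geometry under one factor, so with-allowance areas are reported from
geometry (disc of diameter subtense + 0.5°), with an optional override
table carrying the printed values.

## Data model and interchange format

A segmented volume is three real-valued boundary matrices
(`rnfl_gcl`, `gcl_ipl`, `ipl_inl`; axial pixels, 0-based from the B-scan
top, sub-pixel allowed, NaN for ungradeable samples) plus metadata (eye,
geometry, fovea position, tilt, quality). Serialisation is one JSON file
plus three CSVs — inspectable, diffable, language-neutral. Validation
enforces boundary ordering (depth non-decreasing through the three
interfaces, invalid samples exempt) with the offending (bscan, a-scan)
coordinate in the error. The 15 dB signal-quality gate is inclusive
(exactly 15 dB passes): "minimum" is read as an attainable minimum.

## Thickness maps

Thickness is `(bottom − top) × axial_um_per_px`; GCIPL is the GCL and IPL
thicknesses summed, identical (to float round-off) to the direct
RNFL/GCL→IPL/INL separation. The en-face map interpolates the sparse
B-scan lattice (61 rows × ~768 columns) with an interpolating bicubic
spline (`scipy` FITPACK, `kx=ky=3`, `s=0`): exact at the original nodes and
reproducing constants and planes, which the tests assert. Output pixels
are square; the column pitch is the scanned width over `target_px_x − 1`
(default 768 columns, ~11.2 μm/px) and the row pitch is forced equal. No
extrapolation beyond the scanned extent.

Invalid samples are excluded, not repaired: they are in-filled (nearest
neighbour) only so the spline is computable, and every output pixel whose
bicubic stencil could touch an invalid node (±2 lattice steps, applied
conservatively through a 5×5 maximum filter) is masked out. Region means
are therefore never contaminated by repaired data. A region is excluded
when fewer than 75% of its expected pixels (region area / pixel area —
so off-map portions count as invalid) are valid; the threshold is a
package default, configurable, since no fraction is prescribed for
"could not be adequately corrected" exclusions.

## Grids and assignment

The 8×8 grid (6880 μm span, 64 squares of 860 μm, row-major from
superior-temporal) is centred on the fovea and tilted to the individual
fovea–disc angle, as the acquisition protocol does; when grid tilt equals
scan tilt the grid is axis-aligned in map coordinates. The VF paradigms
stay at 0° tilt regardless of the eye's tilt.

The VF grid is the canonical 68-point HFA 10-2 (odd coordinates ±1..±9,
eccentricity ≤ 9.3°; any cutoff in (9.06°, 9.49°) gives the same 68 points)
plus the 12 paracentral 30-2 points not coincident with 10-2 locations:
(±9,±3), (±3,±9), (±9,±9). The total of 80 is pinned independently by the
percentages the comparison statistics are quoted against (41/80 = 51.25%,
30/80 = 37.5%).

Ganglion-cell displacement is applied radially along the meridian: the
angle is preserved and the eccentricity remapped through a monotone lookup
(packaged as JSON data, digitized from the published displacement curve;
identity at and beyond 12°). The lookup is data, not code; every test is
invariant to its exact values and asserts only monotonicity,
centrifugality (mapped ≥ original) and the cutoff identity.

Averaging regions are discs of diameter (subtense + 0.5° allowance),
realised as 256-gons whose radius is inflated by `sqrt((2π/n)/sin(2π/n))`
so the polygon area equals the true disc area exactly; the boundary then
deviates from the circle by ~4×10⁻⁵ of the radius, below every tolerance
used. Each location is assigned to the 8×8 square sharing the greatest
area (exact polygon clipping), under the individual tilt; ties (relative
area difference ≤ 1e-9) break to the square centre nearest the fovea, then
the lowest row-major index. Zero overlap yields an explicit "unassigned"
location.

The instrument-software surrogate (`extract_grid8x8_direct`) averages raw
B-scan samples falling inside each square — no interpolation — and rounds
to integer micrometres, mirroring the review software's display. Whether
the real software averages raw samples or its own resampled map is not
documented; the surrogate is validated only through the <1 μm
direct-vs-map agreement property on smooth phantoms.

## Statistics

* **Wilcoxon one-sample signed-rank** (two-sided, against 0): zeros are
  dropped before ranking (Wilcoxon's original rule, matching common
  commercial behaviour); midranks for ties. The null distribution is exact
  for n ≤ 25 via convolution over sign assignments with doubled (integer)
  midranks — this equals full 2ⁿ enumeration, ties included, which the
  tests verify — and a tie-corrected normal approximation with continuity
  correction beyond. Two-sided p is twice the smaller tail, capped at 1.
* **Median CI**: exact binomial order statistics at ≥ 95% nominal coverage,
  degenerating to the sample range at small n.
* **Spearman vs tilt**: tie-corrected (midranks); 95% CI by the Fisher
  transform with the Bonett–Wright standard error
  `sqrt((1 + ρ²/2)/(n − 3))`. Constant inputs flag the correlation as
  undefined rather than raising.
* **Linear vs quadratic tilt model**: ordinary least squares;
  `F = (RSS_lin − RSS_quad)/(RSS_quad/(n−3))`, quadratic chosen iff
  p < 0.05. A perfect quadratic fit reports F = +inf and selects the
  quadratic; a perfect *linear* fit selects the linear model. The chosen
  model predicts the difference between 0° and 15° tilt.
* **Friedman across GII/GIII/GV**: rows with any exclusion dropped;
  midrank tie correction. The null is exact for ≤ 12 complete rows via
  dynamic programming over within-row label permutations (equal to full
  (3!)ⁿ enumeration), chi-square beyond. Post-hoc: Dunn pairwise z tests
  on mean ranks, Bonferroni-adjusted over the 3 pairs.
* No multiple-testing correction across the 80 locations for
  Wilcoxon/Spearman (pointwise P < 0.05 flags, as is conventional for
  these location maps); both behaviours are arguments.
* Cohort differences default to full-precision map-based values on both
  sides; `use_direct_grid=True` substitutes the integer-rounded instrument
  surrogate as the grid side.

## The synthetic phantom and cohort

The phantom is an analytic GCIPL field
`t(x,y) = base + A·exp(−((r_a − e)/σ)²/2) − D·exp(−(r/ρ)⁴/2)`:
a flat plateau (base 52 μm), a parafoveal annulus (A = 45 μm at e = 3.5°,
σ = 1.8°) and a flat-floored super-Gaussian pit (D = 58 μm, ρ = 1.8°,
exponent 4 — the anatomical foveal depression has steep walls and a flat
floor, which a Gaussian pit cannot reproduce at this width without going
negative). The annulus radius `r_a` may be elliptically stretched
(default anisotropy 1.15, emulating the horizontally elongated parafoveal
ring); the pit stays round. With these defaults the pit floor is ~1 μm,
the ring peaks near 97 μm, and the central-4 VF-vs-grid contrast is
~24 μm — the scale of the foveal mismatch the method exists to expose.

The virtual scanner samples the field along a frame rotated by the tilt,
encodes GCIPL into boundary separations split 55:45 between GCL and IPL
(the split only exercises layer I/O), and adds seeded Gaussian noise
(default SD 2 μm) independently per boundary position, re-sorting to
preserve anatomical order; positions stay sub-pixel real-valued.
Artifact injection invalidates samples along wiggly vessel-like tracks or
random dropout blocks until a requested fraction is reached.

The default study cohort is 40 eyes: tilts from a truncated normal
matching the reference population (6.64° ± 3.33°, truncated to
[−5.6°, 16.4°]), mild (5% relative) per-participant jitter on plateau,
ring amplitude and ring geometry with the pit-floor thickness held fixed
(pits bottom at the same near-zero GCIPL; unconstrained jitter would make
some fields negative), and ~47% of eyes stored in left-eye format to
exercise the right-eye conversion. Everything is bit-reproducible from the
master seed; the cohort used throughout tests and the acceptance script is
the default one (master seed 1). n = 40 with 768-column maps keeps the
full cohort pipeline under a minute on one CPU while leaving the
directional effects far above measurement noise.

What the phantom does *not* emulate: OCT speckle, curvature/axial-length
remapping, realistic vessel trees, pathology (glaucomatous thinning), or
inter-individual variation in ganglion-cell displacement. Passing tests
establish the pipeline's geometry, averaging and statistics are correct
and calibrated — not that the displacement lookup or any particular eye
model is anatomically exact for a given patient.

## Calibration checks

Type-I error of the per-location Wilcoxon test is measured on 1000
replicates of directly simulated null paired differences (n = 30,
symmetric noise) — this probes the test's calibration, for which the full
image pipeline adds nothing — and must land in [0.03, 0.07] at α = 0.05.
The F test's quadratic-selection rate under a linear truth must be 5% ± 2%
over 1000 replicates. Both run inside the acceptance script with the
run's seed.

## Known limitations

* The displacement lookup is a digitization; individualized displacement
  (axial length, refraction) is out of scope by design.
* The with-allowance region geometry is a declared construction (disc of
  subtense + 0.5°), not a reverse-engineered reproduction of the printed
  areas, which no single geometry reproduces.
* The direct extractor is a surrogate for undocumented instrument
  behaviour; only its agreement envelope is claimed.
* Cohort-level numbers from the 478-eye clinical population (e.g. its
  exact median offsets or significant-location counts) are not
  reproducible from synthetic data; the package reproduces signs, spatial
  patterns and calibration properties at desk scale.
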