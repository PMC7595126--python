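"""Measurement-grid geometry in retinal coordinates.

Builds the instrument-style 8×8 macular averaging grid (6880 μm span, 64
squares of 860 μm) and the visual-field-based measurement paradigms: the HFA
10-2 test grid plus 12 paracentral 30-2 locations, projected onto the retina
with

* axis inversion (superior field → inferior retina, nasal field → temporal
  retina; everything in right-eye format),
* centrifugal ganglion-cell displacement applied radially along the
  meridian (Henle fibre elongation; lookup-table model),
* conversion from visual degrees to retinal μm by a single global factor
  (default 286.5 μm/deg, back-derived from the Goldmann stimulus projection
  areas), and
* rotation into the tilted scan frame of the individual eye, while the VF
  paradigms themselves stay at 0° tilt (head frame of perimetry).

The averaging region for a Goldmann stimulus is a disc of diameter
(stimulus subtense + 0.5° microsaccade allowance).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from shapely.geometry import Point, Polygon, box

from .errors import ValidationError
from .geometry import rotate_xy
from .thickness import ThicknessMap

__all__ = [
    "DEG_TO_UM_DEFAULT",
    "GOLDMANN_DIAMETER_DEG",
    "PRINTED_ALLOWANCE_AREA_MM2",
    "MICROSACCADE_ALLOWANCE_DEG",
    "deg_to_um",
    "um_to_deg",
    "StimulusSpec",
    "effective_region",
    "Grid8x8",
    "build_grid8x8",
    "DisplacementModel",
    "hfa_10_2_points",
    "hfa_30_2_paracentral_points",
    "VFLocation",
    "VFGrid",
    "build_vf_grid",
    "Assignment",
    "assign_to_square",
]

#: Global retinal-projection factor: μm of retina per degree of visual
#: angle.  Back-derived from the published no-allowance stimulus areas
#: (all three Goldmann sizes consistent at 3 s.f. with this single value).
DEG_TO_UM_DEFAULT = 286.5

#: Goldmann stimulus angular subtenses, stored exactly; the conventional
#: printed 0.22° for GII is the rounded form of 0.215°.
GOLDMANN_DIAMETER_DEG = {"GII": 0.215, "GIII": 0.43, "GV": 1.72}

#: Published with-allowance projection areas (mm²), available as an
#: override: they are not exactly reproducible from any single disc
#: geometry, so by default areas come from geometry instead.
PRINTED_ALLOWANCE_AREA_MM2 = {"GII": 0.0433, "GIII": 0.0691, "GV": 0.351}

#: Microsaccade fixation allowance: 30 min of arc = 0.5° of subtense.
MICROSACCADE_ALLOWANCE_DEG = 0.5

#: Number of segments per quarter circle in disc-polygon approximations
#: (256-gon).
_DISC_QUAD_SEGS = 64

#: Radius inflation making the inscribed 256-gon's area equal the true
#: disc area (boundary then oscillates ~±4e-5·r around the circle).
_DISC_AREA_CORRECTION = float(np.sqrt(
    (2 * np.pi / (4 * _DISC_QUAD_SEGS))
    / np.sin(2 * np.pi / (4 * _DISC_QUAD_SEGS))))


def disc_polygon(center, radius: float) -> Polygon:
    """Area-exact polygonal disc: a 256-gon whose area is π·radius²."""
    return Point(center).buffer(radius * _DISC_AREA_CORRECTION,
                                quad_segs=_DISC_QUAD_SEGS)


def deg_to_um(deg, factor: float = DEG_TO_UM_DEFAULT):
    """Visual degrees → retinal μm (linear small-angle projection)."""
    if not factor > 0:
        raise ValidationError("deg→μm factor must be positive")
    return np.multiply(deg, factor)


def um_to_deg(um, factor: float = DEG_TO_UM_DEFAULT):
    """Retinal μm → visual degrees; exact inverse of :func:`deg_to_um`."""
    if not factor > 0:
        raise ValidationError("deg→μm factor must be positive")
    return np.divide(um, factor)


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusSpec:
    """A Goldmann perimetric stimulus and its retinal averaging region."""

    goldmann: str
    diameter_deg: float
    allowance_deg: float = MICROSACCADE_ALLOWANCE_DEG
    region_shape: str = "disc"

    def __post_init__(self):
        if self.goldmann not in GOLDMANN_DIAMETER_DEG:
            raise ValidationError(f"unknown Goldmann size {self.goldmann!r}")
        if not self.diameter_deg > 0:
            raise ValidationError("diameter_deg must be positive")
        if self.allowance_deg < 0:
            raise ValidationError("allowance_deg must be >= 0")

    @classmethod
    def from_goldmann(cls, name: str,
                      allowance_deg: float = MICROSACCADE_ALLOWANCE_DEG) -> "StimulusSpec":
        return cls(name, GOLDMANN_DIAMETER_DEG[name], allowance_deg)

    @property
    def effective_area_mm2(self) -> float:
        """No-allowance projected disc area at the default factor (mm²)."""
        _, area = effective_region(self, with_allowance=False)
        return area


def effective_region(stimulus: StimulusSpec, with_allowance: bool = True,
                     deg_um_factor: float = DEG_TO_UM_DEFAULT,
                     area_override_mm2: float | None = None):
    """Averaging-disc radius (deg) and projected area (mm²).

    Without allowance the disc is the stimulus itself; with allowance its
    diameter grows by the 0.5° microsaccade allowance.  ``area_override_mm2``
    substitutes a published area for the geometric one while keeping the
    geometric radius.
    """
    d = stimulus.diameter_deg + (stimulus.allowance_deg if with_allowance else 0.0)
    radius_deg = d / 2.0
    radius_mm = deg_to_um(radius_deg, deg_um_factor) / 1000.0
    area = float(np.pi * radius_mm ** 2)
    if area_override_mm2 is not None:
        area = float(area_override_mm2)
    return radius_deg, area


# ---------------------------------------------------------------------------
# 8x8 grid
# ---------------------------------------------------------------------------

GRID_SPAN_UM = 6880.0
GRID_SQUARES_PER_SIDE = 8
GRID_SQUARE_UM = GRID_SPAN_UM / GRID_SQUARES_PER_SIDE  # 860 μm


@dataclass
class Grid8x8:
    """The 64-square instrument averaging grid, in map (scan-frame) μm.

    ``polygons`` are row-major from the superior-temporal corner: row 0 is
    superior, column 0 temporal.  ``tilt_deg`` is the grid tilt in the field
    frame; when it equals the scan tilt the grid is axis-aligned with the
    map.  ``in_map[i]`` is False for squares extending beyond the mapped
    extent (flagged, not fatal).
    """

    center_um: tuple[float, float]
    tilt_deg: float
    scan_tilt_deg: float
    polygons: list
    in_map: np.ndarray
    span_um: float = GRID_SPAN_UM
    squares_per_side: int = GRID_SQUARES_PER_SIDE
    square_um: float = GRID_SQUARE_UM

    def square_centers_um(self) -> np.ndarray:
        return np.array([np.asarray(p.centroid.coords[0]) for p in self.polygons])


def _map_extent_polygon(tmap: ThicknessMap) -> Polygon:
    xs, ys = tmap.x_um(), tmap.y_um()
    return box(min(xs), min(ys), max(xs), max(ys))


def build_grid8x8(tmap: ThicknessMap | None, tilt_deg: float | None = None,
                  center_um: tuple[float, float] = (0.0, 0.0)) -> Grid8x8:
    """Place the 8×8 grid over a thickness map, centred on the fovea.

    ``tilt_deg`` defaults to the map's scan tilt (the acquisition protocol
    aligns the grid with the fovea–disc axis), in which case the grid is
    axis-aligned in map coordinates.  Passing ``tmap=None`` builds the grid
    in a pure 0°-tilt frame with no extent flagging (useful for geometry
    checks).
    """
    scan_tilt = tmap.scan_tilt_deg if tmap is not None else 0.0
    if tilt_deg is None:
        tilt_deg = scan_tilt
    half = GRID_SPAN_UM / 2.0
    s = GRID_SQUARE_UM
    rot = scan_tilt - tilt_deg  # ccw rotation of grid-frame coords into map
    cx, cy = center_um
    polygons = []
    for i in range(GRID_SQUARES_PER_SIDE):        # rows, superior first
        y_top = half - i * s
        for j in range(GRID_SQUARES_PER_SIDE):    # cols, temporal first
            x_left = -half + j * s
            corners = np.array([
                [x_left, y_top - s],
                [x_left + s, y_top - s],
                [x_left + s, y_top],
                [x_left, y_top],
            ])
            corners = rotate_xy(corners, rot) + [cx, cy]
            polygons.append(Polygon(corners))
    if tmap is not None:
        extent = _map_extent_polygon(tmap)
        in_map = np.array([p.within(extent) for p in polygons])
    else:
        in_map = np.ones(64, dtype=bool)
    return Grid8x8(center_um=center_um, tilt_deg=float(tilt_deg),
                   scan_tilt_deg=float(scan_tilt), polygons=polygons, in_map=in_map)


# ---------------------------------------------------------------------------
# ganglion-cell displacement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DisplacementModel:
    """Monotone eccentricity remapping for centrifugal GC displacement.

    ``__call__`` maps stimulus eccentricity (deg) to ganglion-cell
    eccentricity (deg) along the same meridian; identity at and beyond
    ``cutoff_deg``.
    """

    stimulus_ecc_deg: tuple
    gc_ecc_deg: tuple
    cutoff_deg: float

    def __post_init__(self):
        e = np.asarray(self.stimulus_ecc_deg, float)
        g = np.asarray(self.gc_ecc_deg, float)
        if e.shape != g.shape or e.ndim != 1 or e.size < 2:
            raise ValidationError("displacement table must be two equal 1-D arrays")
        if (np.diff(e) <= 0).any() or (np.diff(g) < 0).any():
            raise ValidationError("displacement table must be monotone")
        if (g + 1e-12 < e).any():
            raise ValidationError("displacement must be centrifugal (gc >= stimulus)")

    def __call__(self, ecc_deg):
        ecc = np.asarray(ecc_deg, dtype=float)
        out = np.interp(ecc, self.stimulus_ecc_deg, self.gc_ecc_deg)
        out = np.where(ecc >= self.cutoff_deg, ecc, out)
        return out if out.ndim else float(out)

    @classmethod
    def drasdo(cls) -> "DisplacementModel":
        """The packaged lookup digitized from the published curve."""
        raw = json.loads(
            resources.files("maculamap.data")
            .joinpath("drasdo_displacement.json")
            .read_text()
        )
        return cls(tuple(raw["stimulus_ecc_deg"]), tuple(raw["gc_ecc_deg"]),
                   float(raw["cutoff_deg"]))

    @classmethod
    def identity(cls) -> "DisplacementModel":
        return cls((0.0, 1.0), (0.0, 1.0), 0.0)


# ---------------------------------------------------------------------------
# VF grids
# ---------------------------------------------------------------------------

#: 10-2 eccentricity cutoff: any value in (9.06°, 9.49°) yields the
#: canonical 68 points; the midpoint is used.
HFA_10_2_CUTOFF_DEG = 9.3


def hfa_10_2_points() -> np.ndarray:
    """The 68 HFA 10-2 test locations in VF degrees, sorted (y desc, x asc)."""
    coords = np.array([1, 3, 5, 7, 9])
    pts = []
    for x in np.concatenate([-coords, coords]):
        for y in np.concatenate([-coords, coords]):
            if np.hypot(x, y) <= HFA_10_2_CUTOFF_DEG:
                pts.append((float(x), float(y)))
    return _sort_vf(np.array(pts))


def hfa_30_2_paracentral_points() -> np.ndarray:
    """The 12 paracentral 30-2 additions: the nearest 30-2 points to
    fixation that do not coincide with 10-2 locations."""
    pts = [(x, y) for (x, y) in
           [(9, 3), (9, -3), (-9, 3), (-9, -3),
            (3, 9), (3, -9), (-3, 9), (-3, -9),
            (9, 9), (9, -9), (-9, 9), (-9, -9)]]
    return _sort_vf(np.array(pts, dtype=float))


def _sort_vf(pts: np.ndarray) -> np.ndarray:
    order = np.lexsort((pts[:, 0], -pts[:, 1]))  # y desc, then x asc
    return pts[order]


@dataclass
class VFLocation:
    """One measurement location of a VF-based paradigm."""

    loc_id: int
    field_deg: tuple[float, float]
    source: str  # "10-2" | "30-2"
    retina_deg: tuple[float, float]  # displaced, field-frame degrees
    center_um: tuple[float, float]   # map (scan-frame) μm
    region: Polygon                  # averaging disc, map μm
    measurable: bool = True


@dataclass
class VFGrid:
    """All 80 locations of one VF-based paradigm (tilt fixed at 0°)."""

    locations: list
    stimulus: StimulusSpec
    tilt_deg: float = 0.0

    def __len__(self):
        return len(self.locations)


def build_vf_grid(stimulus: StimulusSpec,
                  displacement: DisplacementModel | None = None,
                  tmap: ThicknessMap | None = None,
                  scan_tilt_deg: float | None = None,
                  deg_um_factor: float = DEG_TO_UM_DEFAULT) -> VFGrid:
    """Project the 10-2 + paracentral 30-2 grid onto the retina.

    Each field location is axis-inverted onto the retina, its eccentricity
    remapped outward by the displacement model along the same meridian,
    converted to μm in the 0° field frame, and rotated into the scan frame
    of the map.  The averaging region is the allowance-inflated stimulus
    disc; regions extending beyond the mapped extent are flagged
    unmeasurable.
    """
    if displacement is None:
        displacement = DisplacementModel.drasdo()
    if scan_tilt_deg is None:
        scan_tilt_deg = tmap.scan_tilt_deg if tmap is not None else 0.0
    radius_deg, _ = effective_region(stimulus, with_allowance=True,
                                     deg_um_factor=deg_um_factor)
    radius_um = float(deg_to_um(radius_deg, deg_um_factor))
    extent = _map_extent_polygon(tmap) if tmap is not None else None

    pts10 = hfa_10_2_points()
    pts30 = hfa_30_2_paracentral_points()
    locations = []
    for source, pts in (("10-2", pts10), ("30-2", pts30)):
        for x, y in pts:
            retina = np.array([-x, -y])  # field axes invert onto the retina
            ecc = float(np.hypot(*retina))
            if ecc > 0:
                retina = retina * (float(displacement(ecc)) / ecc)
            center_field_um = deg_to_um(retina, deg_um_factor)
            center_map = rotate_xy(center_field_um, +scan_tilt_deg)
            region = disc_polygon(center_map, radius_um)
            measurable = extent is None or region.within(extent)
            locations.append(VFLocation(
                loc_id=len(locations),
                field_deg=(float(x), float(y)),
                source=source,
                retina_deg=(float(retina[0]), float(retina[1])),
                center_um=(float(center_map[0]), float(center_map[1])),
                region=region,
                measurable=measurable,
            ))
    return VFGrid(locations=locations, stimulus=stimulus, tilt_deg=0.0)


# ---------------------------------------------------------------------------
# location -> grid-square assignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Assignment:
    """Result of greatest-shared-area assignment; ``square`` None when the
    region overlaps no grid square."""

    square: int | None
    fraction: float


#: Relative tolerance under which two overlap areas count as tied.
_TIE_RTOL = 1e-9


def assign_to_square(loc: VFLocation, grid: Grid8x8) -> Assignment:
    """Assign a VF location to the 8×8 square sharing the greatest area.

    Ties are broken deterministically: nearest square centre to the fovea,
    then lowest row-major index.
    """
    region = loc.region
    area = region.area
    cx, cy = np.asarray(region.centroid.coords[0])
    r_region = float(Point(cx, cy).hausdorff_distance(region))
    centers = grid.square_centers_um()
    half_diag = grid.square_um * np.sqrt(2) / 2
    d_centers = np.hypot(centers[:, 0] - cx, centers[:, 1] - cy)
    candidates = np.flatnonzero(d_centers <= r_region + half_diag + 1e-6)

    fovea_d = np.hypot(centers[:, 0] - grid.center_um[0],
                       centers[:, 1] - grid.center_um[1])
    overlaps = [(region.intersection(grid.polygons[idx]).area, idx)
                for idx in candidates]
    overlaps = [(a, idx) for a, idx in overlaps if a > 0]
    if not overlaps:
        return Assignment(None, 0.0)
    best_area = max(a for a, _ in overlaps)
    tied = [idx for a, idx in overlaps
            if abs(a - best_area) <= _TIE_RTOL * best_area]
    winner = min(tied, key=lambda idx: (fovea_d[idx], idx))
    return Assignment(int(winner), float(best_area / area))
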