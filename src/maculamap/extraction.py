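"""Region-averaged GCIPL measurements for the four paradigms.

Three extractors share one averaging primitive:

* ``extract_grid8x8`` — mean map thickness per 8×8 grid square (map-based,
  full precision);
* ``extract_grid8x8_direct`` — mean over *raw* B-scan samples per square,
  rounded to the nearest integer μm, mirroring what the instrument review
  software displays; used as the instrument surrogate in validation;
* ``extract_vf`` — mean over each VF location's allowance-inflated stimulus
  disc.

A location is excluded (value NaN, with a reason) when its region lies off
the mapped extent, when too few of its pixels are valid, or — for VF
locations — when no grid square shares area with it downstream.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely

from .retinotopy import Grid8x8, VFGrid
from .thickness import ThicknessMap
from .volume import OCTVolume
from .geometry import rotate_xy

__all__ = [
    "MeasurementSet",
    "average_region",
    "extract_grid8x8",
    "extract_grid8x8_direct",
    "extract_vf",
    "MIN_VALID_FRACTION_DEFAULT",
]

#: Exclude a location when more than 25% of its expected pixels are
#: masked or off-map.
MIN_VALID_FRACTION_DEFAULT = 0.75


@dataclass
class MeasurementSet:
    """Per-location averaged GCIPL values for one paradigm on one eye.

    ``values_um[i]`` is NaN exactly where ``excluded[i]`` carries a reason
    string (``"masked"``, ``"out-of-map"`` or ``"unassigned"``).
    """

    paradigm: str  # "grid8x8" | "grid8x8-direct" | "GII" | "GIII" | "GV"
    values_um: np.ndarray
    excluded: list  # reason str or None, same length
    tilt_deg: float
    provenance: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.values_um)

    def validate(self) -> "MeasurementSet":
        ok = np.array([r is None for r in self.excluded])
        vals = self.values_um[ok]
        if vals.size and not (np.isfinite(vals).all() and (vals >= 0).all()):
            raise ValueError("included values must be finite and >= 0")
        if not np.isnan(self.values_um[~ok]).all():
            raise ValueError("excluded locations must carry NaN")
        return self

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["location_id", "paradigm", "value_um", "excluded", "reason"])
            for i, (v, r) in enumerate(zip(self.values_um, self.excluded)):
                w.writerow([i, self.paradigm,
                            "" if r is not None else f"{v:.6g}",
                            r is not None, r or ""])
        return path


def average_region(tmap: ThicknessMap, region,
                   min_valid_fraction: float = MIN_VALID_FRACTION_DEFAULT):
    """Mean thickness over valid pixels inside ``region`` (map μm coords).

    A pixel belongs to the region when its centre is inside.  Returns
    ``(value_um, reason)`` with ``reason`` None on success; the value is the
    unweighted mean of valid member pixels.  The valid fraction is counted
    against the number of pixels the region *should* contain
    (area / pixel area), so parts off the map count as invalid.
    """
    xs, ys = tmap.x_um(), tmap.y_um()
    minx, miny, maxx, maxy = region.bounds
    csel = np.flatnonzero((xs >= minx) & (xs <= maxx))
    rsel = np.flatnonzero((ys >= miny) & (ys <= maxy))
    expected = region.area / (tmap.um_per_px_x * tmap.um_per_px_y)
    if expected <= 0:
        return np.nan, "out-of-map"
    if csel.size == 0 or rsel.size == 0:
        return np.nan, "out-of-map"
    xx, yy = np.meshgrid(xs[csel], ys[rsel])
    inside = shapely.contains_xy(region, xx.ravel(), yy.ravel()).reshape(xx.shape)
    if not inside.any():
        return np.nan, "out-of-map"
    sub_vals = tmap.values_um[np.ix_(rsel, csel)]
    sub_mask = tmap.mask[np.ix_(rsel, csel)]
    member_valid = inside & sub_mask
    n_valid = int(member_valid.sum())
    valid_fraction = min(n_valid / expected, 1.0)
    if valid_fraction < min_valid_fraction:
        return np.nan, "masked"
    return float(sub_vals[member_valid].mean()), None


def extract_grid8x8(tmap: ThicknessMap, grid: Grid8x8,
                    min_valid_fraction: float = MIN_VALID_FRACTION_DEFAULT,
                    provenance: dict | None = None) -> MeasurementSet:
    """Map-based mean GCIPL per 8×8 square, row-major superior-temporal first."""
    values = np.full(64, np.nan)
    excluded: list = [None] * 64
    for i, poly in enumerate(grid.polygons):
        if not grid.in_map[i]:
            excluded[i] = "out-of-map"
            continue
        v, reason = average_region(tmap, poly, min_valid_fraction)
        values[i], excluded[i] = v, reason
    return MeasurementSet("grid8x8", values, excluded, grid.tilt_deg,
                          provenance or {}).validate()


def extract_grid8x8_direct(vol: OCTVolume, grid: Grid8x8,
                           provenance: dict | None = None) -> MeasurementSet:
    """Instrument-surrogate extractor: mean over raw B-scan GCIPL samples.

    No interpolation — each raw sample is binned into the square containing
    it — and means are rounded to the nearest integer μm, as the review
    software displays them.  Squares containing no valid sample are
    excluded.
    """
    from .thickness import gcipl_thickness

    gci, valid = gcipl_thickness(vol)
    b_idx, a_idx = np.nonzero(valid)
    vals = gci[b_idx, a_idx]
    fb, fa = vol.fovea_px
    # raw sample positions in map μm (fovea origin, y superior)
    x = (a_idx - fa) * vol.lateral_um_per_px
    y = (fb - b_idx) * vol.bscan_spacing_um
    # into the grid frame: inverse of the grid->map rotation
    rot = grid.scan_tilt_deg - grid.tilt_deg
    q = rotate_xy(np.column_stack([x, y]) - np.asarray(grid.center_um), -rot)
    half, s = grid.span_um / 2.0, grid.square_um
    col = np.floor((q[:, 0] + half) / s).astype(int)
    row = np.floor((half - q[:, 1]) / s).astype(int)
    ok = (col >= 0) & (col < 8) & (row >= 0) & (row < 8)
    idx = row[ok] * 8 + col[ok]
    sums = np.bincount(idx, weights=vals[ok], minlength=64)
    counts = np.bincount(idx, minlength=64)

    values = np.full(64, np.nan)
    excluded: list = [None] * 64
    for i in range(64):
        if counts[i] == 0:
            excluded[i] = "out-of-map"
        else:
            values[i] = float(np.rint(sums[i] / counts[i]))
    return MeasurementSet("grid8x8-direct", values, excluded, grid.tilt_deg,
                          provenance or {}).validate()


def extract_vf(tmap: ThicknessMap, vfgrid: VFGrid,
               min_valid_fraction: float = MIN_VALID_FRACTION_DEFAULT,
               provenance: dict | None = None) -> MeasurementSet:
    """Mean GCIPL over each VF location's averaging disc (80 values)."""
    n = len(vfgrid)
    values = np.full(n, np.nan)
    excluded: list = [None] * n
    for i, loc in enumerate(vfgrid.locations):
        if not loc.measurable:
            excluded[i] = "out-of-map"
            continue
        v, reason = average_region(tmap, loc.region, min_valid_fraction)
        values[i], excluded[i] = v, reason
    return MeasurementSet(vfgrid.stimulus.goldmann, values, excluded,
                          vfgrid.tilt_deg, provenance or {}).validate()
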