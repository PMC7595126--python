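"""Per-layer thickness and the interpolated en-face GCIPL map.

Thickness at a sample is ``(bottom − top) × axial_um_per_px``; the GCIPL
(ganglion cell layer + inner plexiform layer) thickness is the GCL and IPL
thicknesses summed, which telescopes to the separation between the
``rnfl_gcl`` and ``ipl_inl`` interfaces.

The en-face map is built by bicubic (interpolating cubic spline)
interpolation of the sparse B-scan lattice onto a square-pixel grid,
emulating resampling to the fundus-image (SLO) resolution.  Samples that
could not be segmented are *excluded, not repaired*: any output pixel whose
bicubic stencil touches an invalid input sample is masked out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.interpolate import NearestNDInterpolator, RectBivariateSpline
from scipy.ndimage import maximum_filter

from .errors import UnsupportedInputError, ValidationError
from .volume import BOUNDARY_NAMES, OCTVolume

__all__ = [
    "ThicknessMap",
    "layer_thickness",
    "gcipl_thickness",
    "build_map",
    "mark_exclusions",
    "DEFAULT_TARGET_PX_X",
]

#: Default number of map columns across the scanned width (~SLO resolution).
DEFAULT_TARGET_PX_X = 768


@dataclass
class ThicknessMap:
    """En-face thickness image in μm, in the scan frame.

    Row 0 is the superior-most B-scan; columns follow the a-scan axis.
    μm coordinates place the origin at the fovea with x increasing along
    columns (toward the optic disc) and y increasing superiorly, so
    ``x = (col − fovea_col)·um_per_px_x`` and
    ``y = (fovea_row − row)·um_per_px_y``.
    """

    values_um: np.ndarray
    mask: np.ndarray  # True where the value is valid
    um_per_px_x: float
    um_per_px_y: float
    fovea_map_px: tuple[float, float]  # (row, col); sub-pixel allowed
    frame: str = "scan"
    scan_tilt_deg: float = 0.0

    def validate(self) -> "ThicknessMap":
        if self.values_um.shape != self.mask.shape:
            raise ValidationError("values_um and mask shapes differ")
        if not (self.um_per_px_x > 0 and self.um_per_px_y > 0):
            raise ValidationError("um_per_px scales must be positive")
        r, c = self.fovea_map_px
        nr, nc = self.values_um.shape
        if not (0 <= r < nr and 0 <= c < nc):
            raise ValidationError(f"fovea_map_px {self.fovea_map_px} out of bounds")
        vals = self.values_um[self.mask]
        if vals.size and not (np.isfinite(vals).all() and (vals >= -1e-9).all()):
            raise ValidationError("valid thickness values must be finite and >= 0")
        return self

    # μm coordinates of pixel centres (fovea origin, y up)
    def x_um(self) -> np.ndarray:
        cols = np.arange(self.values_um.shape[1])
        return (cols - self.fovea_map_px[1]) * self.um_per_px_x

    def y_um(self) -> np.ndarray:
        rows = np.arange(self.values_um.shape[0])
        return (self.fovea_map_px[0] - rows) * self.um_per_px_y

    def copy(self) -> "ThicknessMap":
        return replace(self, values_um=self.values_um.copy(), mask=self.mask.copy())

    # -- export ------------------------------------------------------------
    def to_csv(self, path: str | Path) -> Path:
        """Write the value matrix as CSV plus a JSON sidecar with geometry."""
        path = Path(path)
        out = np.where(self.mask, self.values_um, np.nan)
        np.savetxt(path, out, delimiter=",", fmt="%.6g")
        sidecar = {
            "um_per_px_x": self.um_per_px_x,
            "um_per_px_y": self.um_per_px_y,
            "fovea_map_px": list(self.fovea_map_px),
            "frame": self.frame,
            "scan_tilt_deg": self.scan_tilt_deg,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
        return path

    def to_png(self, path: str | Path) -> Path:
        """Render a heatmap for visual inspection (masked pixels blank)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        shown = np.where(self.mask, self.values_um, np.nan)
        extent = [self.x_um()[0], self.x_um()[-1], self.y_um()[-1], self.y_um()[0]]
        im = ax.imshow(shown, cmap="viridis", extent=extent, origin="upper")
        fig.colorbar(im, ax=ax, label="GCIPL thickness (μm)")
        ax.set_xlabel("x (μm, toward disc)")
        ax.set_ylabel("y (μm, superior)")
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return Path(path)


def layer_thickness(vol: OCTVolume, top: str, bottom: str):
    """Thickness matrix (μm) between two interfaces, with validity.

    ``top`` must be anatomically above ``bottom`` in the fixed interface
    order rnfl_gcl → gcl_ipl → ipl_inl.  Returns ``(values_um, valid)``;
    samples invalid (NaN) in either boundary are invalid in the result.
    """
    order = list(BOUNDARY_NAMES)
    if top not in order or bottom not in order:
        raise ValidationError(f"unknown boundary id in ({top!r}, {bottom!r})")
    if order.index(top) >= order.index(bottom):
        raise ValidationError(f"{top!r} is not above {bottom!r}")
    t = vol.boundaries[top]
    b = vol.boundaries[bottom]
    sep = b - t
    bad = sep < -1e-9  # NaN -> False: invalid samples are exempt
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"{top} below {bottom} at (bscan={i}, ascan={j})"
        )
    values = sep * vol.axial_um_per_px
    valid = np.isfinite(values)
    return values, valid


def gcipl_thickness(vol: OCTVolume):
    """GCIPL = GCL + IPL thickness per sample, ``(values_um, valid)``.

    Equals the direct rnfl_gcl→ipl_inl separation exactly (telescoping).
    """
    return layer_thickness(vol, "rnfl_gcl", "ipl_inl")


def _fill_invalid(values: np.ndarray, valid: np.ndarray,
                  rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Nearest-neighbour fill of invalid samples so the spline is computable.

    Filled values never reach the output: the mask removes every pixel whose
    stencil touches them.
    """
    if valid.all():
        return values
    if not valid.any():
        raise UnsupportedInputError("all samples invalid; cannot build a map")
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    interp = NearestNDInterpolator(
        np.column_stack([rr[valid], cc[valid]]), values[valid]
    )
    filled = values.copy()
    filled[~valid] = interp(rr[~valid], cc[~valid])
    return filled


def build_map(vol: OCTVolume, target_px_x: int = DEFAULT_TARGET_PX_X) -> ThicknessMap:
    """Interpolate the B-scan GCIPL profiles onto a square-pixel en-face map.

    The 61-row B-scan lattice is the sparse axis; interpolation is a true
    2-D bicubic spline on the regular (row, column) lattice, exact at the
    original nodes.  Output pixels are square in μm: the column pitch is the
    scanned width divided by ``target_px_x − 1`` and the row pitch is forced
    equal to it.  No extrapolation: the output grid stays inside the scanned
    extent.
    """
    if vol.n_bscans < 4 or vol.ascans_per_bscan < 4:
        raise UnsupportedInputError("bicubic interpolation needs >= 4 B-scans and a-scans")
    if target_px_x < 2:
        raise UnsupportedInputError("target_px_x must be >= 2")

    values, valid = gcipl_thickness(vol)
    rows_um = np.arange(vol.n_bscans) * vol.bscan_spacing_um
    cols_um = np.arange(vol.ascans_per_bscan) * vol.lateral_um_per_px
    filled = _fill_invalid(values, valid, rows_um, cols_um)

    width_um = cols_um[-1]
    height_um = rows_um[-1]
    pitch = width_um / (target_px_x - 1)
    out_cols = np.arange(target_px_x) * pitch
    n_rows = int(np.floor(height_um / pitch + 1e-9)) + 1
    out_rows = np.arange(n_rows) * pitch

    spline = RectBivariateSpline(rows_um, cols_um, filled, kx=3, ky=3, s=0)
    out = spline(out_rows, out_cols)

    if valid.all():
        mask = np.ones_like(out, dtype=bool)
    else:
        # conservative invalidity dilation: an output pixel is invalid when
        # any input node within +/-2 lattice steps (the bicubic stencil
        # support) of its nearest node is invalid
        invalid_dil = maximum_filter((~valid).astype(np.uint8), size=5)
        ri = np.clip(np.rint(out_rows / vol.bscan_spacing_um).astype(int), 0, vol.n_bscans - 1)
        ci = np.clip(np.rint(out_cols / vol.lateral_um_per_px).astype(int), 0,
                     vol.ascans_per_bscan - 1)
        mask = invalid_dil[np.ix_(ri, ci)] == 0

    out = np.where(out < 0, 0.0, out)  # spline overshoot below zero clipped
    fov_b, fov_a = vol.fovea_px
    fovea_map = (fov_b * vol.bscan_spacing_um / pitch,
                 fov_a * vol.lateral_um_per_px / pitch)
    return ThicknessMap(
        values_um=out,
        mask=mask,
        um_per_px_x=pitch,
        um_per_px_y=pitch,
        fovea_map_px=fovea_map,
        frame="scan",
        scan_tilt_deg=vol.fovea_disc_angle_deg,
    ).validate()


def mark_exclusions(tmap: ThicknessMap, regions) -> ThicknessMap:
    """Return a copy with the mask cleared inside the union of ``regions``.

    ``regions`` are shapely polygons in map μm coordinates (fovea origin,
    y superior).  Values are untouched; degenerate (zero-area) polygons are
    ignored with a warning.
    """
    import warnings

    import shapely

    out = tmap.copy()
    xs = tmap.x_um()
    ys = tmap.y_um()
    xx, yy = np.meshgrid(xs, ys)
    for poly in regions:
        if poly.area <= 0:
            warnings.warn("ignoring degenerate (zero-area) exclusion polygon")
            continue
        minx, miny, maxx, maxy = poly.bounds
        csel = (xs >= minx - tmap.um_per_px_x) & (xs <= maxx + tmap.um_per_px_x)
        rsel = (ys >= miny - tmap.um_per_px_y) & (ys <= maxy + tmap.um_per_px_y)
        if not (csel.any() and rsel.any()):
            continue
        sub = np.ix_(rsel, csel)
        inside = shapely.contains_xy(poly, xx[sub].ravel(), yy[sub].ravel())
        block = out.mask[sub]
        block[inside.reshape(block.shape)] = False
        out.mask[sub] = block
    return out
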