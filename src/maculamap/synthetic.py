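"""Synthetic GCIPL topographies and virtual OCT acquisitions.

The phantom reproduces the canonical macular GCIPL shape: a ganglion-cell-
poor foveal pit where thickness drops toward ~0, a parafoveal annulus
peaking a few degrees out, and a plateau toward the peripheral macula.  The
parafoveal ring may be elliptically stretched (``anisotropy``) to emulate
its horizontally elongated appearance; the pit itself stays round.

The virtual scanner samples the analytic field along a frame rotated by the
participant's fovea-to-disc tilt (as the acquisition protocol does), splits
the GCIPL between GCL and IPL at a fixed ratio so layer I/O is exercised,
adds seeded Gaussian segmentation noise on boundary positions, and emits an
interchange-format :class:`~maculamap.volume.OCTVolume`.  Everything is
bit-reproducible from a seed, and the analytic field remains available as a
ground-truth oracle.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np
import shapely

from .errors import ValidationError
from .geometry import rotate_xy, scan_to_field
from .retinotopy import DEG_TO_UM_DEFAULT
from .volume import AcquisitionDefaults, OCTVolume

__all__ = [
    "TopographyModel",
    "Topography",
    "make_topography",
    "scan_topography",
    "CohortSpec",
    "make_cohort",
    "inject_artifacts",
    "analytic_region_mean",
    "GCL_FRACTION",
]

#: GCL share of GCIPL thickness in generated boundaries (only the sum
#: matters downstream; the split exists so per-layer I/O is exercised).
GCL_FRACTION = 0.55

#: Axial pixel position of the RNFL/GCL interface in generated B-scans.
_RNFL_GCL_PX = 120.0


@dataclass(frozen=True)
class TopographyModel:
    """Parameters of the analytic pit + parafoveal-annulus GCIPL field.

    thickness(x, y) = base
                      + annulus_amp · exp(−((r_a − annulus_ecc)/σ)²/2)
                      − pit_depth  · exp(−((r/pit_radius)^pit_shape)/2)

    with r the (round) eccentricity in degrees and r_a an elliptical
    eccentricity for the annulus term (x compressed / y stretched by
    ``anisotropy``).  ``pit_shape`` = 2 gives a Gaussian pit; the default 4
    a flat-floored pit with steep walls, matching the anatomical foveal
    depression.  Defaults give a ~52 μm plateau, a ~97 μm ring near 3.5°
    and a pit bottoming near 1 μm — steep central gradients next to
    GC-rich parafovea.  ``noise_sd_um`` is the per-boundary segmentation
    noise used by the virtual scanner.
    """

    base_um: float = 52.0
    pit_depth_um: float = 58.0
    pit_radius_deg: float = 1.8
    pit_shape: float = 4.0
    annulus_amp_um: float = 45.0
    annulus_ecc_deg: float = 3.5
    annulus_sigma_deg: float = 1.8
    anisotropy: float = 1.15  # parafoveal ring horizontally elongated
    noise_sd_um: float = 2.0

    def __post_init__(self):
        if self.base_um <= 0 or self.pit_radius_deg <= 0 \
                or self.annulus_sigma_deg <= 0 or self.anisotropy <= 0 \
                or self.pit_shape <= 0:
            raise ValidationError("topography scale parameters must be positive")
        if self.pit_depth_um < 0 or self.annulus_amp_um < 0 or self.noise_sd_um < 0:
            raise ValidationError("amplitudes and noise sd must be >= 0")


class Topography:
    """Callable analytic GCIPL field, degrees (field frame) → μm."""

    def __init__(self, model: TopographyModel):
        self.model = model

    def __call__(self, x_deg, y_deg):
        m = self.model
        x = np.asarray(x_deg, dtype=float)
        y = np.asarray(y_deg, dtype=float)
        r = np.hypot(x, y)
        r_a = np.hypot(x / m.anisotropy, y * m.anisotropy)
        t = (m.base_um
             + m.annulus_amp_um * np.exp(-0.5 * ((r_a - m.annulus_ecc_deg)
                                                 / m.annulus_sigma_deg) ** 2)
             - m.pit_depth_um * np.exp(-0.5 * (r / m.pit_radius_deg) ** m.pit_shape))
        return t if t.ndim else float(t)


def make_topography(model: TopographyModel | None = None) -> Topography:
    """Build the analytic field and validate it is non-negative with the
    pit below the ring."""
    model = model or TopographyModel()
    topo = Topography(model)
    probe = np.linspace(0.0, 15.0, 601)
    along_x = topo(probe, np.zeros_like(probe))
    along_y = topo(np.zeros_like(probe), probe)
    if (np.minimum(along_x, along_y) < 0).any():
        raise ValidationError("topography yields negative thickness")
    # pit below ring (equality allowed only for the degenerate flat field)
    if topo(0.0, 0.0) > topo(model.annulus_ecc_deg, 0.0) + 1e-9:
        raise ValidationError("pit centre must be thinner than the annulus")
    if (model.pit_depth_um > 0 or model.annulus_amp_um > 0) \
            and not topo(0.0, 0.0) < topo(model.annulus_ecc_deg, 0.0):
        raise ValidationError("pit centre must be thinner than the annulus")
    return topo


def scan_topography(topo, tilt_deg: float,
                    acquisition: AcquisitionDefaults | None = None,
                    seed: int | None = None,
                    ascans_per_bscan: int = 768,
                    eye: str = "OD",
                    quality_db: float = 30.0,
                    deg_um_factor: float = DEG_TO_UM_DEFAULT,
                    noise_sd_um: float | None = None,
                    volume_id: str = "synthetic") -> OCTVolume:
    """Virtually acquire a posterior-pole volume of the analytic field.

    B-scan rows are sampled in a frame rotated by ``tilt_deg`` (the scan
    follows the fovea–disc axis); the GCIPL separation encodes the field,
    split 55:45 between GCL and IPL.  Seeded Gaussian noise (the model's
    ``noise_sd_um``) is added per boundary; boundary order is restored by
    sorting so the volume always validates.  ``eye="OS"`` stores the volume
    mirrored to left-eye format (the exact inverse of right-eye conversion).

    ``topo`` may be any ``(x_deg, y_deg) -> μm`` callable; ``noise_sd_um``
    overrides the model's noise (0 for a plain callable without a model).
    """
    acq = acquisition or AcquisitionDefaults()
    width_um = acq.field_deg[0] * deg_um_factor
    lateral = width_um / (ascans_per_bscan - 1)
    fb = (acq.n_bscans - 1) // 2
    fa = (ascans_per_bscan - 1) // 2

    a = np.arange(ascans_per_bscan)
    b = np.arange(acq.n_bscans)
    x_scan = (a - fa) * lateral
    y_scan = (fb - b) * acq.bscan_spacing_um
    xx, yy = np.meshgrid(x_scan, y_scan)
    pts_field = scan_to_field(np.stack([xx, yy], axis=-1), tilt_deg)
    t_um = topo(pts_field[..., 0] / deg_um_factor, pts_field[..., 1] / deg_um_factor)
    t_um = np.maximum(t_um, 0.0)

    ax = acq.axial_um_per_px
    rnfl_gcl = np.full_like(t_um, _RNFL_GCL_PX)
    gcl_ipl = rnfl_gcl + GCL_FRACTION * t_um / ax
    ipl_inl = rnfl_gcl + t_um / ax

    if noise_sd_um is None:
        noise_sd_um = getattr(getattr(topo, "model", None), "noise_sd_um", 0.0)
    sd_px = noise_sd_um / ax
    if sd_px > 0:
        rng = np.random.default_rng(seed)
        stack = np.stack([rnfl_gcl, gcl_ipl, ipl_inl])
        stack = stack + rng.normal(0.0, sd_px, stack.shape)
        stack = np.sort(stack, axis=0)  # restore anatomical ordering
        rnfl_gcl, gcl_ipl, ipl_inl = stack

    vol = OCTVolume(
        eye="OD",
        n_bscans=acq.n_bscans,
        bscan_spacing_um=acq.bscan_spacing_um,
        axial_um_per_px=ax,
        lateral_um_per_px=lateral,
        ascans_per_bscan=ascans_per_bscan,
        boundaries={"rnfl_gcl": rnfl_gcl, "gcl_ipl": gcl_ipl, "ipl_inl": ipl_inl},
        fovea_px=(fb, fa),
        fovea_disc_angle_deg=float(tilt_deg),
        quality_db=float(quality_db),
        volume_id=volume_id,
    )
    if eye == "OS":  # store mirrored; right-eye conversion recovers this exactly
        vol = replace(
            vol,
            eye="OS",
            boundaries={k: v[:, ::-1].copy() for k, v in vol.boundaries.items()},
            fovea_px=(fb, ascans_per_bscan - 1 - fa),
            fovea_disc_angle_deg=-float(tilt_deg),
        )
    return vol.validate()


@dataclass(frozen=True)
class CohortSpec:
    """A virtual study cohort.

    Tilts are drawn from a truncated normal matching the reference
    population (mean 6.64°, SD 3.33°, truncated to [−5.6°, 16.4°]);
    topography parameters get mild per-participant relative jitter; roughly
    half the eyes are stored left-eye to exercise right-eye conversion.
    """

    n_participants: int = 40
    tilt_mean_deg: float = 6.64
    tilt_sd_deg: float = 3.33
    tilt_range_deg: tuple[float, float] = (-5.6, 16.4)
    topography: TopographyModel = TopographyModel()
    jitter_rel_sd: float = 0.05
    os_fraction: float = 0.47
    master_seed: int = 1

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValidationError("n_participants must be >= 1")
        if not (0 <= self.os_fraction <= 1):
            raise ValidationError("os_fraction must be in [0, 1]")


def _draw_truncated_normal(rng, mean, sd, lo, hi):
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise ValidationError("truncation bounds reject essentially all draws")


def make_cohort(spec: CohortSpec | None = None):
    """Generate ``n`` volumes plus a ground-truth manifest.

    Returns ``(volumes, manifest)``; the manifest records every drawn
    parameter per participant and round-trips through JSON.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.master_seed)
    volumes, entries = [], []
    for i in range(spec.n_participants):
        tilt = _draw_truncated_normal(rng, spec.tilt_mean_deg, spec.tilt_sd_deg,
                                      *spec.tilt_range_deg)
        j = spec.jitter_rel_sd
        base = spec.topography
        jittered = replace(
            base,
            base_um=base.base_um * float(1 + j * rng.standard_normal()),
            annulus_amp_um=base.annulus_amp_um * float(1 + j * rng.standard_normal()),
            annulus_ecc_deg=base.annulus_ecc_deg * float(1 + j * rng.standard_normal()),
            annulus_sigma_deg=base.annulus_sigma_deg * float(1 + j * rng.standard_normal()),
        )
        # preserve the template's pit-floor thickness: pits bottom out at the
        # same near-zero GCIPL regardless of plateau/ring jitter
        floor0 = Topography(base)(0.0, 0.0)
        ann0 = (jittered.annulus_amp_um
                * np.exp(-0.5 * (jittered.annulus_ecc_deg
                                 / jittered.annulus_sigma_deg) ** 2))
        jittered = replace(jittered,
                           pit_depth_um=jittered.base_um + ann0 - floor0)
        eye = "OS" if rng.random() < spec.os_fraction else "OD"
        scan_seed = int(rng.integers(0, 2**31 - 1))
        topo = make_topography(jittered)
        vol = scan_topography(topo, tilt, seed=scan_seed, eye=eye,
                              volume_id=f"synthetic-{i:03d}")
        volumes.append(vol)
        entries.append({
            "volume_id": vol.volume_id,
            "tilt_deg": tilt,
            "eye": eye,
            "scan_seed": scan_seed,
            "topography": asdict(jittered),
        })
    manifest = {"master_seed": spec.master_seed,
                "n_participants": spec.n_participants,
                "participants": entries}
    return volumes, manifest


def inject_artifacts(vol: OCTVolume, kind: str = "vessel-shadow",
                     fraction: float = 0.02, seed: int | None = None):
    """Invalidate samples to emulate segmentation failures.

    ``vessel-shadow`` draws curvilinear tracks crossing the B-scan stack
    (like vessel shadowing); ``dropout`` invalidates random rectangular
    blocks.  Tracks/blocks are added until the invalidated fraction reaches
    the request; returns ``(volume, achieved_fraction)``.  ``fraction=0``
    returns an untouched copy.
    """
    if kind not in ("vessel-shadow", "dropout"):
        raise ValidationError(f"unknown artifact kind {kind!r}")
    if fraction < 0:
        raise ValidationError("fraction must be >= 0")
    out = vol.copy()
    if fraction == 0:
        return out, 0.0
    rng = np.random.default_rng(seed)
    nb, na = out.n_bscans, out.ascans_per_bscan
    invalid = np.zeros((nb, na), dtype=bool)
    guard = 0
    while invalid.mean() < fraction and guard < 10_000:
        guard += 1
        if kind == "dropout":
            h = int(rng.integers(2, 6))
            w = int(rng.integers(8, 24))
            r0 = int(rng.integers(0, max(nb - h, 1)))
            c0 = int(rng.integers(0, max(na - w, 1)))
            invalid[r0:r0 + h, c0:c0 + w] = True
        else:
            # a wiggly vertical track of ~2 a-scans width through all B-scans
            c = float(rng.integers(0, na))
            drift = rng.normal(0.0, 1.5, nb).cumsum()
            centers = np.clip(np.rint(c + drift).astype(int), 0, na - 1)
            for r, cc in enumerate(centers):
                invalid[r, max(cc - 1, 0):cc + 1] = True
    for name in out.boundaries:
        out.boundaries[name][invalid] = np.nan
    return out, float(invalid.mean())


def analytic_region_mean(topo: Topography, region, scan_tilt_deg: float,
                         deg_um_factor: float = DEG_TO_UM_DEFAULT,
                         px_um: float = 4.0) -> float:
    """High-resolution quadrature oracle for the field's mean over a region.

    ``region`` is a shapely polygon in map (scan-frame) μm; the field is
    evaluated on a dense pixel grid (``px_um`` pitch) restricted to the
    region.  Independent of the extraction pipeline.
    """
    minx, miny, maxx, maxy = region.bounds
    xs = np.arange(minx, maxx + px_um, px_um)
    ys = np.arange(miny, maxy + px_um, px_um)
    xx, yy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(region, xx.ravel(), yy.ravel())
    pts = np.column_stack([xx.ravel()[inside], yy.ravel()[inside]])
    pts_field = rotate_xy(pts, -scan_tilt_deg)  # scan -> field frame
    vals = topo(pts_field[:, 0] / deg_um_factor, pts_field[:, 1] / deg_um_factor)
    return float(np.maximum(vals, 0.0).mean())
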