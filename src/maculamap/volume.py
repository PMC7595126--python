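"""Segmented-OCT-volume data model and its open interchange format.

A volume is the output of macular posterior-pole OCT after layer
segmentation: for each of the three retinal interfaces bounding the ganglion
cell layer (GCL) and inner plexiform layer (IPL) —

* ``rnfl_gcl`` — retinal nerve fibre layer / GCL,
* ``gcl_ipl`` — GCL / IPL,
* ``ipl_inl`` — IPL / inner nuclear layer,

one real-valued matrix of axial boundary positions in pixels (0-based from
the top of each B-scan, sub-pixel values allowed), shaped
``(n_bscans, ascans_per_bscan)``.  Samples where segmentation failed carry
``NaN``.  The scan frame is tilted to the individual fovea–optic-disc axis;
the tilt angle travels with the volume so downstream grid placement can undo
it.

The interchange format is one JSON metadata file plus three CSV boundary
matrices (header row = a-scan index), chosen to be inspectable, diffable and
language-neutral.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import SchemaError, StructuralError, ValidationError

__all__ = [
    "BOUNDARY_NAMES",
    "OCTVolume",
    "AcquisitionDefaults",
    "QualityVerdict",
    "read_volume",
    "write_volume",
    "to_right_eye_format",
    "check_quality",
]

#: The three segmented interfaces, ordered from inner (vitread) to outer.
BOUNDARY_NAMES = ("rnfl_gcl", "gcl_ipl", "ipl_inl")

#: Tolerance (pixels) when checking anatomical boundary ordering; allows
#: touching boundaries (zero-thickness layers) and float round-off.
_ORDER_TOL = 1e-9


@dataclass(frozen=True)
class AcquisitionDefaults:
    """Posterior-pole volume-scan protocol constants.

    61 horizontal B-scans spaced 120 μm apart cover the central 30°
    (horizontal) × 25° (vertical), with an axial sampling of 3.87 μm per
    pixel; volumes below 15 dB signal quality are excluded.
    """

    n_bscans: int = 61
    bscan_spacing_um: float = 120.0
    axial_um_per_px: float = 3.87
    field_deg: tuple[float, float] = (30.0, 25.0)
    min_quality_db: float = 15.0

    def __post_init__(self):
        if self.n_bscans < 2:
            raise ValidationError("n_bscans must be >= 2")
        for name in ("bscan_spacing_um", "axial_um_per_px", "min_quality_db"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if not (self.field_deg[0] > 0 and self.field_deg[1] > 0):
            raise ValidationError("field_deg extents must be positive")


@dataclass
class OCTVolume:
    """A segmented macular OCT volume in the (tilted) scan frame.

    ``fovea_disc_angle_deg`` is positive when the optic-disc centre lies
    below the horizontal through the fovea in right-eye format.
    """

    eye: str  # "OD" | "OS"
    n_bscans: int
    bscan_spacing_um: float
    axial_um_per_px: float
    lateral_um_per_px: float
    ascans_per_bscan: int
    boundaries: dict[str, np.ndarray]
    fovea_px: tuple[int, int]  # (bscan index, a-scan index)
    fovea_disc_angle_deg: float
    quality_db: float
    volume_id: str = "volume"

    def validate(self) -> "OCTVolume":
        """Enforce every type invariant; raise on the first violation."""
        if self.eye not in ("OD", "OS"):
            raise ValidationError(f"eye must be 'OD' or 'OS', got {self.eye!r}")
        if self.n_bscans < 2:
            raise ValidationError("n_bscans must be >= 2")
        if not self.bscan_spacing_um > 0:
            raise ValidationError("bscan_spacing_um must be positive")
        if not self.axial_um_per_px > 0:
            raise ValidationError("axial_um_per_px must be positive")
        if not self.lateral_um_per_px > 0:
            raise ValidationError("lateral_um_per_px must be positive")
        missing = [b for b in BOUNDARY_NAMES if b not in self.boundaries]
        if missing:
            raise SchemaError(f"missing boundary matrices: {missing}")
        shape = (self.n_bscans, self.ascans_per_bscan)
        for name in BOUNDARY_NAMES:
            mat = np.asarray(self.boundaries[name], dtype=float)
            if mat.shape != shape:
                raise StructuralError(
                    f"boundary {name!r} has shape {mat.shape}, expected {shape}"
                )
            self.boundaries[name] = mat
        b, a = self.fovea_px
        if not (0 <= b < self.n_bscans and 0 <= a < self.ascans_per_bscan):
            raise ValidationError(f"fovea_px {self.fovea_px} outside matrix bounds")
        _check_boundary_order(self.boundaries)
        return self

    def copy(self) -> "OCTVolume":
        return replace(self, boundaries={k: v.copy() for k, v in self.boundaries.items()})


def _check_boundary_order(boundaries: dict[str, np.ndarray]) -> None:
    """Depth must not decrease across rnfl_gcl -> gcl_ipl -> ipl_inl."""
    for top, bottom in zip(BOUNDARY_NAMES[:-1], BOUNDARY_NAMES[1:]):
        t, b = boundaries[top], boundaries[bottom]
        bad = np.asarray(t - b > _ORDER_TOL)  # NaN compares False: invalid exempt
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"boundary order violated: {top} below {bottom} at "
                f"(bscan={i}, ascan={j})"
            )


@dataclass(frozen=True)
class QualityVerdict:
    passed: bool
    quality_db: float
    min_db: float

    def __bool__(self) -> bool:
        return self.passed


def check_quality(vol: OCTVolume, min_db: float | None = None) -> QualityVerdict:
    """Signal-quality gate: pass iff ``quality_db >= min_db`` (inclusive).

    The 15 dB default reads the protocol's "minimum quality score" as an
    attainable minimum.
    """
    if min_db is None:
        min_db = AcquisitionDefaults().min_quality_db
    if not np.isfinite(min_db):
        raise ValidationError("min_db must be finite")
    return QualityVerdict(vol.quality_db >= min_db, vol.quality_db, float(min_db))


def to_right_eye_format(vol: OCTVolume) -> OCTVolume:
    """Convert a volume to right-eye (OD) format.

    Left-eye volumes are mirrored along the a-scan axis, which moves the
    fovea a-scan index to ``W - 1 - k`` and reverses the sign of the
    fovea-to-disc tilt (a horizontal mirror flips rotations).  Right-eye
    volumes are returned unchanged (same object).
    """
    if vol.eye == "OD":
        return vol
    W = vol.ascans_per_bscan
    mirrored = {k: v[:, ::-1].copy() for k, v in vol.boundaries.items()}
    return replace(
        vol,
        eye="OD",
        boundaries=mirrored,
        fovea_px=(vol.fovea_px[0], W - 1 - vol.fovea_px[1]),
        fovea_disc_angle_deg=-vol.fovea_disc_angle_deg,
    )


# ---------------------------------------------------------------------------
# interchange I/O
# ---------------------------------------------------------------------------

_META_FIELDS = {
    "eye": str,
    "n_bscans": int,
    "bscan_spacing_um": (int, float),
    "axial_um_per_px": (int, float),
    "lateral_um_per_px": (int, float),
    "ascans_per_bscan": int,
    "fovea_px": dict,
    "fovea_disc_angle_deg": (int, float),
    "quality_db": (int, float),
    "boundary_files": dict,
}


def write_volume(vol: OCTVolume, path: str | Path) -> Path:
    """Write ``vol`` to ``path`` (the JSON metadata file).

    The three boundary CSVs are written next to it, named
    ``<stem>_<boundary>.csv``.  Floats are serialised in full precision
    (``repr`` round-trip), NaN as the string ``nan``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    vol.validate()
    boundary_files = {}
    for name in BOUNDARY_NAMES:
        csv_path = path.with_name(f"{path.stem}_{name}.csv")
        header = ",".join(str(j) for j in range(vol.ascans_per_bscan))
        np.savetxt(csv_path, vol.boundaries[name], delimiter=",",
                   header=header, comments="", fmt="%.17g")
        boundary_files[name] = csv_path.name
    meta = {
        "eye": vol.eye,
        "n_bscans": vol.n_bscans,
        "bscan_spacing_um": vol.bscan_spacing_um,
        "axial_um_per_px": vol.axial_um_per_px,
        "lateral_um_per_px": vol.lateral_um_per_px,
        "ascans_per_bscan": vol.ascans_per_bscan,
        "fovea_px": {"bscan": vol.fovea_px[0], "ascan": vol.fovea_px[1]},
        "fovea_disc_angle_deg": vol.fovea_disc_angle_deg,
        "quality_db": vol.quality_db,
        "volume_id": vol.volume_id,
        "boundary_files": boundary_files,
    }
    path.write_text(json.dumps(meta, indent=2))
    return path


def read_volume(path: str | Path) -> OCTVolume:
    """Read an interchange-format volume from its JSON metadata file.

    Raises :class:`SchemaError` for missing/ill-typed metadata fields,
    :class:`StructuralError` for shape mismatches between boundary matrices
    and :class:`ValidationError` for domain-invariant violations.
    """
    path = Path(path)
    try:
        meta = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise SchemaError(f"malformed metadata JSON in {path}: {e}") from e

    for key, typ in _META_FIELDS.items():
        if key not in meta:
            raise SchemaError(f"metadata missing required field {key!r}")
        if not isinstance(meta[key], typ) or isinstance(meta[key], bool):
            raise SchemaError(f"metadata field {key!r} has wrong type")
    for sub in ("bscan", "ascan"):
        if sub not in meta["fovea_px"]:
            raise SchemaError(f"metadata field 'fovea_px.{sub}' missing")

    boundaries = {}
    for name in BOUNDARY_NAMES:
        if name not in meta["boundary_files"]:
            raise SchemaError(f"metadata field 'boundary_files.{name}' missing")
        csv_path = path.with_name(meta["boundary_files"][name])
        if not csv_path.exists():
            raise SchemaError(f"boundary file {csv_path} does not exist")
        boundaries[name] = np.loadtxt(csv_path, delimiter=",", skiprows=1, ndmin=2)

    vol = OCTVolume(
        eye=meta["eye"],
        n_bscans=meta["n_bscans"],
        bscan_spacing_um=float(meta["bscan_spacing_um"]),
        axial_um_per_px=float(meta["axial_um_per_px"]),
        lateral_um_per_px=float(meta["lateral_um_per_px"]),
        ascans_per_bscan=meta["ascans_per_bscan"],
        boundaries=boundaries,
        fovea_px=(meta["fovea_px"]["bscan"], meta["fovea_px"]["ascan"]),
        fovea_disc_angle_deg=float(meta["fovea_disc_angle_deg"]),
        quality_db=float(meta["quality_db"]),
        volume_id=str(meta.get("volume_id", path.stem)),
    )
    return vol.validate()
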