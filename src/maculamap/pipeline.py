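"""End-to-end glue: volume → map → grids → measurements → cohort tables.

Nothing here adds behaviour; it wires the module-level operations together
in the order a study would run them, once per participant and then across
the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .extraction import (MIN_VALID_FRACTION_DEFAULT, MeasurementSet,
                         extract_grid8x8, extract_grid8x8_direct, extract_vf)
from .retinotopy import (DEG_TO_UM_DEFAULT, DisplacementModel, Grid8x8,
                         StimulusSpec, assign_to_square, build_grid8x8,
                         build_vf_grid)
from .stats import ComparisonTable, compare_stimulus_sizes, run_comparison
from .thickness import DEFAULT_TARGET_PX_X, ThicknessMap, build_map
from .volume import OCTVolume, check_quality, to_right_eye_format

__all__ = ["ParticipantResult", "process_volume", "analyze_cohort"]

_STIMULI = ("GII", "GIII", "GV")


@dataclass
class ParticipantResult:
    """Everything extracted from one participant's volume."""

    volume_id: str
    tilt_deg: float
    quality_passed: bool
    tmap: ThicknessMap
    grid: Grid8x8
    grid_set: MeasurementSet            # map-based 8x8
    direct_set: MeasurementSet          # instrument-surrogate 8x8
    vf_sets: dict = field(default_factory=dict)      # paradigm -> MeasurementSet
    assignments: dict = field(default_factory=dict)  # paradigm -> [square|None]*80


def process_volume(vol: OCTVolume,
                   stimuli=_STIMULI,
                   displacement: DisplacementModel | None = None,
                   target_px_x: int = DEFAULT_TARGET_PX_X,
                   min_valid_fraction: float = MIN_VALID_FRACTION_DEFAULT,
                   deg_um_factor: float = DEG_TO_UM_DEFAULT) -> ParticipantResult:
    """Run the full single-eye pipeline in right-eye format.

    The 8×8 grid is placed at the participant's fovea-to-disc tilt; the VF
    paradigms stay at 0° field tilt.  Assignments (greatest shared area,
    under the individual tilt) are computed per paradigm.
    """
    if displacement is None:
        displacement = DisplacementModel.drasdo()
    vol = to_right_eye_format(vol)
    verdict = check_quality(vol)
    tmap = build_map(vol, target_px_x)
    grid = build_grid8x8(tmap)
    grid_set = extract_grid8x8(tmap, grid, min_valid_fraction)
    direct_set = extract_grid8x8_direct(vol, grid)
    result = ParticipantResult(
        volume_id=vol.volume_id,
        tilt_deg=vol.fovea_disc_angle_deg,
        quality_passed=bool(verdict),
        tmap=tmap, grid=grid, grid_set=grid_set, direct_set=direct_set,
    )
    for name in stimuli:
        spec = StimulusSpec.from_goldmann(name)
        vfgrid = build_vf_grid(spec, displacement, tmap,
                               deg_um_factor=deg_um_factor)
        result.vf_sets[name] = extract_vf(tmap, vfgrid, min_valid_fraction)
        result.assignments[name] = [assign_to_square(loc, grid).square
                                    for loc in vfgrid.locations]
    return result


def analyze_cohort(results: list, use_direct_grid: bool = False,
                   alpha: float = 0.05) -> dict:
    """Cohort tables: per-paradigm VF-vs-grid comparisons + size Friedman.

    ``use_direct_grid=True`` compares against the integer-rounded
    instrument-surrogate 8×8 values instead of the full-precision map-based
    ones.  Returns ``{"vs_grid": {paradigm: ComparisonTable}, "sizes":
    DataFrame, "tilts": array}``.
    """
    results = [r for r in results if r.quality_passed]
    if not results:
        raise ValueError("no quality-passing participants")
    tilts = np.array([r.tilt_deg for r in results])
    grid_sets = [(r.direct_set if use_direct_grid else r.grid_set) for r in results]
    vs_grid: dict[str, ComparisonTable] = {}
    paradigms = list(results[0].vf_sets.keys())
    for name in paradigms:
        vs_grid[name] = run_comparison(
            [r.vf_sets[name] for r in results], grid_sets,
            [r.assignments[name] for r in results], tilts=tilts, alpha=alpha)
    sizes = None
    if len(paradigms) == 3:
        sizes = compare_stimulus_sizes(
            {name: [r.vf_sets[name] for r in results] for name in paradigms},
            alpha=alpha)
    return {"vs_grid": vs_grid, "sizes": sizes, "tilts": tilts}
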