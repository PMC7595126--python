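"""Shared fixtures: small hand-built volumes and the default synthetic cohort."""

import numpy as np
import pytest

from maculamap import (CohortSpec, OCTVolume, TopographyModel, build_map,
                       make_cohort, make_topography, process_volume,
                       scan_topography)


def toy_volume(n_bscans=6, ascans=8, gcipl_um=70.0, eye="OD", tilt=0.0,
               axial=3.87, spacing=120.0, lateral=100.0, quality=20.0):
    """A tiny constant-thickness volume for unit tests."""
    rnfl = np.full((n_bscans, ascans), 100.0)
    gcl_ipl = rnfl + 0.5 * gcipl_um / axial
    ipl_inl = rnfl + gcipl_um / axial
    return OCTVolume(
        eye=eye, n_bscans=n_bscans, bscan_spacing_um=spacing,
        axial_um_per_px=axial, lateral_um_per_px=lateral,
        ascans_per_bscan=ascans,
        boundaries={"rnfl_gcl": rnfl, "gcl_ipl": gcl_ipl, "ipl_inl": ipl_inl},
        fovea_px=(n_bscans // 2, ascans // 2),
        fovea_disc_angle_deg=tilt, quality_db=quality,
    ).validate()


@pytest.fixture
def const_volume():
    return toy_volume()


@pytest.fixture(scope="session")
def noiseless_topo():
    """Isotropic noiseless default phantom (ground-truth oracle available)."""
    return make_topography(TopographyModel(noise_sd_um=0.0, anisotropy=1.0))


@pytest.fixture(scope="session")
def noiseless_volume(noiseless_topo):
    return scan_topography(noiseless_topo, tilt_deg=6.0, seed=0)


@pytest.fixture(scope="session")
def noiseless_map(noiseless_volume):
    return build_map(noiseless_volume)


@pytest.fixture(scope="session")
def noiseless_result(noiseless_volume):
    return process_volume(noiseless_volume)


@pytest.fixture(scope="session")
def cohort40():
    """The default pit-annulus study cohort (n=40, fixed master seed)."""
    volumes, manifest = make_cohort(CohortSpec(n_participants=40, master_seed=1))
    results = [process_volume(v) for v in volumes]
    return {"volumes": volumes, "manifest": manifest, "results": results}
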