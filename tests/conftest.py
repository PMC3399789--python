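"""Shared fixtures: protocol metadata, a small phantom, and AIF curves."""

from __future__ import annotations

import numpy as np
import pytest

from mpmri.curves import DSC_DEFAULT_AIF, AifModel, ConcentrationCurve
from mpmri.io import AcquisitionMeta
from mpmri.phantom import default_truth, make_geometry


@pytest.fixture(scope="session")
def meta() -> AcquisitionMeta:
    """The study protocol: 10 b-values, 80-frame DCE/DSC, bolus after frame 20."""
    return AcquisitionMeta()


@pytest.fixture(scope="session")
def small_masks(meta):
    """Desk-scale phantom: 12 mm tumor with 2 mm rim, liver block, aorta."""
    spacing = (1.0, 1.0, meta.slice_extent)
    masks, counts = make_geometry(
        shape=(32, 32, 8),
        spacing=spacing,
        tumor_center=(18.0, 18.0, 8.8),
        tumor_radii=(6.0, 6.0, 6.0),
        rim_thickness=2.0,
        liver_box=((1.0, 1.0, 0.0), (31.0, 31.0, 17.6)),
        aorta_cylinder=(4.0, 4.0, 2.0),
    )
    return masks


@pytest.fixture(scope="session")
def noiseless_truth(small_masks):
    return default_truth(small_masks, noise_sigma=0.0, seed=7)


@pytest.fixture(scope="session")
def dce_aif_curve(meta) -> ConcentrationCurve:
    """Population biexponential AIF sampled on the DCE frame grid."""
    aif = AifModel()
    times = meta.frame_times("dce")
    return ConcentrationCurve(
        times=times,
        values=aif.plasma_concentration(times, meta.dce_frame_duration),
        baseline_frames=meta.baseline_frames,
    )


@pytest.fixture(scope="session")
def dsc_aif_curve(meta) -> ConcentrationCurve:
    """First-pass bolus AIF sampled on the DSC frame grid."""
    times = meta.frame_times("dsc")
    return ConcentrationCurve(
        times=times,
        values=DSC_DEFAULT_AIF.plasma_concentration(times, meta.dsc_frame_duration),
        baseline_frames=meta.baseline_frames,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
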