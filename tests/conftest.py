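import numpy as np
import pytest

from myoglyco import synthetic as syn


@pytest.fixture(scope="session")
def doublet_stack_240():
    """Noiseless terminal-cisternae doublet (240 nm) blurred to ~110 nm sigma.

    Exactly periodic geometry (2 µm period = 50 px of 40 nm; 5 repeats) so a
    periodic boundary model is exact for deconvolution.
    """
    params = syn.FiberImageParams(
        noise=None,
        psf_sigma=(110.0, 110.0, 300.0),
        bleedthrough=(0.0, 0.0),
        background=0.0,
        grid_shape=(24, 24, 250),
        voxel_size=(40.0, 120.0),
        structure_templates=[
            [syn.tc_doublet(100.0, separation_nm=240.0, center_um=1.0)],
            [syn.iband_band(0.0, fwhm_um=1.0)],
        ],
    )
    stack, truth = syn.simulate_fiber_stack(params, seed=1)
    stack.background_subtracted = True
    stack.unmixed = True
    return stack, truth


@pytest.fixture(scope="session")
def fwhm_stack():
    """Two bands with measured FWHM 1.26 / 0.85 µm in stretched (3 µm) sarcomeres."""
    params = syn.FiberImageParams(
        noise=None,
        psf_sigma=(106.0, 106.0, 300.0),
        bleedthrough=(0.0, 0.0),
        background=0.0,
        sarcomere_length=3.0,
        grid_shape=(24, 24, 150),
        voxel_size=(40.0, 120.0),
        structure_templates=[
            [syn.iband_band(60.0, fwhm_um=1.26, center_um=1.5)],
            [syn.iband_band(60.0, fwhm_um=0.85, center_um=1.5)],
        ],
    )
    stack, truth = syn.simulate_fiber_stack(params, seed=4)
    stack.background_subtracted = True
    stack.unmixed = True
    return stack, truth


@pytest.fixture(scope="session")
def phospho_scene():
    """Ground-truth phospho (doublet) and apo (narrow central band) fields
    with a clean shoulder, for B/C scale recovery."""
    params = syn.FiberImageParams(
        noise=None,
        psf_sigma=(106.0, 106.0, 300.0),
        bleedthrough=(0.0, 0.0),
        background=0.0,
        grid_shape=(16, 24, 200),
        voxel_size=(40.0, 120.0),
        structure_templates=[
            [syn.tc_doublet(60.0, separation_nm=240.0, center_um=1.0, line_fwhm_nm=120.0)],
            [syn.iband_band(40.0, fwhm_um=0.4, center_um=0.0)],
        ],
    )
    _, truth = syn.simulate_fiber_stack(params, seed=2)
    return truth.blurred[0], truth.blurred[1]  # (phospho, apo) blurred fields


@pytest.fixture()
def gelblot_two_loads():
    """Equal protein amounts loaded at 1x and 2x; noiseless, mild blur."""
    params = syn.GelBlotParams(
        n_lanes=2,
        band_amplitudes=(5.0e4, 5.0e4),
        loading_factors=(1.0, 2.0),
        blur_sigma=1.0,
    )
    return syn.simulate_gel_blot(params, seed=0)


def band_rois(fixture, lane):
    """ROI quadruple (band, band background, lane, lane background) for a lane."""
    from myoglyco.densitometry import RectROI

    return (
        RectROI(*fixture.band_roi(lane)),
        RectROI(*fixture.band_background_roi(lane), role="background"),
        RectROI(*fixture.lane_roi(lane), role="lane"),
        RectROI(*fixture.lane_background_roi(lane), role="lane_background"),
    )


def quantify_lane(fixture, lane):
    """Run the full densitometry chain on one simulated lane."""
    from myoglyco import densitometry as den

    band, bg, laneroi, lanebg = band_rois(fixture, lane)
    sig = den.band_mass(fixture.blot, band, bg)
    factor = den.lane_normalization(fixture.gel, laneroi, lanebg)
    return den.normalized_content(sig, factor)
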