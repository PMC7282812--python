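"""Background subtraction, spectral unmixing and deconvolution properties."""

import numpy as np
import pytest
from scipy.signal import fftconvolve, find_peaks

from myoglyco import restoration as rest
from myoglyco import synthetic as syn
from myoglyco.restoration import BleedThrough, PipelineOrderError, ZStack


def _stack(arr, **kw):
    return ZStack(np.asarray(arr, dtype=float), (36.0, 120.0), **kw)


class TestBackground:
    def test_constant_image_goes_to_zero(self):
        st = _stack(np.full((1, 4, 8, 8), 12.0))
        out = rest.subtract_background(st, [12.0])
        assert np.allclose(out.intensities, 0.0)
        assert out.background_subtracted
        assert out.background_levels == [12.0]

    def test_estimator_finds_known_background(self):
        params = syn.FiberImageParams(
            background=10.0,
            structure_templates=[
                [syn.tc_doublet(80.0, center_um=1.0)],
                [syn.iband_band(50.0, fwhm_um=0.4)],
            ],
            noise=syn.NoiseModel(poisson=True, read_sigma=2.0),
        )
        stack, _ = syn.simulate_fiber_stack(params, seed=9)
        for ch in range(2):
            assert rest.estimate_background(stack.channel(ch)) == pytest.approx(10.0, abs=1.0)

    def test_subtraction_idempotent_within_tolerance(self):
        params = syn.FiberImageParams(background=10.0)
        stack, _ = syn.simulate_fiber_stack(params, seed=9)
        once = rest.subtract_background(stack)
        twice = rest.subtract_background(once)
        assert abs(twice.background_levels[0]) < 1.0

    def test_excessive_background_rejected(self):
        st = _stack(np.full((1, 2, 4, 4), 5.0))
        with pytest.raises(ValueError, match="exceeds"):
            rest.subtract_background(st, [50.0])


class TestBleedThrough:
    def test_coefficient_recovered_from_single_marker_stack(self):
        params = syn.FiberImageParams(
            bleedthrough=(0.0, 0.10),
            background=10.0,
            structure_templates=[
                [syn.iband_band(0.0, 1.0)],           # marker 1 absent
                [syn.tc_doublet(120.0, center_um=1.0)],
            ],
        )
        stack, _ = syn.simulate_fiber_stack(params, seed=3)
        sub = rest.subtract_background(stack, [10.0, 10.0])
        b21 = rest.estimate_bleedthrough(sub, absent_channel_index=0)
        assert b21 == pytest.approx(0.10, abs=0.01)

    def test_zero_crosstalk_estimates_near_zero(self):
        params = syn.FiberImageParams(
            bleedthrough=(0.0, 0.0),
            background=10.0,
            structure_templates=[
                [syn.iband_band(0.0, 1.0)],
                [syn.tc_doublet(120.0, center_um=1.0)],
            ],
        )
        ests = []
        for seed in range(5):
            stack, _ = syn.simulate_fiber_stack(params, seed=seed)
            # keep signed residuals: clipping would bias the slope upward
            sub = rest.subtract_background(stack, [10.0, 10.0], clip_negatives=False)
            ests.append(rest.estimate_bleedthrough(sub, absent_channel_index=0))
        ests = np.asarray(ests)
        se = ests.std(ddof=1) / np.sqrt(len(ests)) + 1e-4
        assert abs(ests.mean()) < 3 * se

    def test_requires_background_subtraction_first(self):
        st = _stack(np.ones((2, 4, 8, 8)))
        with pytest.raises(PipelineOrderError):
            rest.estimate_bleedthrough(st, 0)

    def test_invalid_coefficients_rejected(self):
        with pytest.raises(ValueError):
            BleedThrough(b12=1.0, b21=0.2)
        with pytest.raises(ValueError):
            BleedThrough(b12=-0.1, b21=0.2)


class TestUnmixing:
    def test_identity_when_no_crosstalk(self):
        st = _stack(np.random.default_rng(0).uniform(0, 50, (2, 4, 8, 8)),
                    background_subtracted=True)
        out = rest.unmix_channels(st, BleedThrough(0.0, 0.0))
        assert np.array_equal(out.intensities, st.intensities)

    def test_hand_worked_inverse(self):
        # A1=10, A2=20 with b21=0.1, b12=0.2 gives F1=12, F2=22
        st = _stack([[[[12.0]]], [[[22.0]]]], background_subtracted=True)
        out = rest.unmix_channels(st, BleedThrough(b12=0.2, b21=0.1))
        assert out.intensities[0, 0, 0, 0] == pytest.approx(10.0)
        assert out.intensities[1, 0, 0, 0] == pytest.approx(20.0)

    def test_pure_crosstalk_channel_nulls(self):
        f2 = np.random.default_rng(1).uniform(10, 50, (1, 4, 8, 8))
        st = _stack(np.concatenate([0.1 * f2, f2]), background_subtracted=True)
        out = rest.unmix_channels(st, BleedThrough(b12=0.0, b21=0.1))
        assert np.allclose(out.intensities[0], 0.0, atol=1e-12)

    def test_round_trip_machine_precision(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 100, (2, 4, 8, 8))
        b12, b21 = 0.23, 0.11
        f1 = a[0] + b21 * a[1]
        f2 = a[1] + b12 * a[0]
        st = _stack(np.stack([f1, f2]), background_subtracted=True)
        out = rest.unmix_channels(st, BleedThrough(b12=b12, b21=b21))
        assert np.allclose(out.intensities, a, rtol=1e-10, atol=1e-10)

    def test_heavy_clipping_warns(self):
        rng = np.random.default_rng(3)
        st = _stack(rng.uniform(0, 1, (2, 4, 8, 8)), background_subtracted=True)
        with pytest.warns(UserWarning, match="negative"):
            rest.unmix_channels(st, BleedThrough(b12=0.9, b21=0.9))

    def test_order_contract_enforced(self):
        st = _stack(np.ones((2, 4, 8, 8)))
        with pytest.raises(PipelineOrderError):
            rest.unmix_channels(st, BleedThrough(0.1, 0.1))


class TestDeconvolution:
    def test_delta_psf_is_identity(self):
        rng = np.random.default_rng(0)
        st = _stack(rng.uniform(5, 20, (1, 6, 8, 16)))
        psf = rest.PSFKernel(np.ones((1, 1, 1)), (36.0, 120.0))
        out = rest.deconvolve(st, psf, iterations=10)
        assert np.allclose(out.intensities, st.intensities, rtol=1e-6)

    def test_point_source_sharpens_and_conserves(self):
        img = np.zeros((24, 32, 64))
        img[12, 16, 32] = 1000.0
        psf = rest.gaussian_psf((110.0, 110.0, 300.0), (40.0, 120.0))
        blurred = fftconvolve(img, psf.kernel, mode="same")
        st = ZStack(blurred[None], (40.0, 120.0), background_subtracted=True, unmixed=True)
        out = rest.deconvolve(st, psf, iterations=40, tol=1e-7)
        # total intensity conserved for a compact centered source
        assert out.intensities.sum() == pytest.approx(blurred.sum(), rel=0.01)
        # restored peak is sharper than the blurred input
        prof_in = blurred[12, 16]
        prof_out = out.intensities[0, 12, 16]
        def width(p):
            half = p.max() / 2
            return np.count_nonzero(p > half)
        assert width(prof_out) <= width(prof_in)
        assert prof_out.max() > prof_in.max()

    def test_doublet_reresolved_at_240nm(self, doublet_stack_240):
        stack, _ = doublet_stack_240
        psf = rest.gaussian_psf((110.0, 110.0, 300.0), stack.voxel_size)
        out = rest.deconvolve(stack, psf, iterations=60, tol=1e-7, boundary="wrap")
        before = stack.intensities[0].mean(axis=(0, 1))
        after = out.intensities[0].mean(axis=(0, 1))
        window = slice(13, 38)  # one repeat centered on the doublet (px 25)
        # blurred doublet is effectively unimodal: no dip at the center
        assert before[25] > 0.98 * before[window].max()
        # restored doublet is clearly bimodal with the correct line spacing
        pk_after, _ = find_peaks(after[window], prominence=0.3 * after[window].max())
        assert len(pk_after) == 2
        assert after[25] < 0.5 * after[window].max()
        sep_nm = np.diff(pk_after)[0] * stack.voxel_size[0]
        assert sep_nm == pytest.approx(240.0, abs=stack.voxel_size[0])

    def test_intensity_conserved_on_periodic_fixture(self, doublet_stack_240):
        stack, _ = doublet_stack_240
        psf = rest.gaussian_psf((110.0, 110.0, 300.0), stack.voxel_size)
        out = rest.deconvolve(stack, psf, iterations=30, tol=1e-6, boundary="wrap")
        assert out.intensities.sum() == pytest.approx(stack.intensities.sum(), rel=0.01)

    def test_van_cittert_alternative_runs(self, doublet_stack_240):
        stack, _ = doublet_stack_240
        psf = rest.gaussian_psf((110.0, 110.0, 300.0), stack.voxel_size)
        out = rest.deconvolve(stack, psf, iterations=15, method="van_cittert")
        assert np.all(out.intensities >= 0)

    def test_matches_reference_richardson_lucy(self):
        """Cross-check against the independent scikit-image implementation."""
        from skimage.restoration import richardson_lucy

        rng = np.random.default_rng(5)
        obj = np.zeros((1, 24, 32, 32))
        obj[0, 12, 12:20, 10:22] = rng.uniform(50, 100, (8, 12))
        psf = rest.gaussian_psf((80.0, 80.0, 240.0), (40.0, 120.0))
        blurred = fftconvolve(obj[0], psf.kernel, mode="same")
        st = ZStack(blurred[None], (40.0, 120.0), background_subtracted=True, unmixed=True)
        ours = rest.deconvolve(st, psf, iterations=20, tol=0).intensities[0]
        ref = richardson_lucy(blurred, psf.kernel, num_iter=20, clip=False)
        # same fixed point family: high voxelwise agreement away from edges
        core = (slice(8, 16), slice(8, 24), slice(8, 24))
        assert np.corrcoef(ours[core].ravel(), ref[core].ravel())[0, 1] > 0.99

    def test_psf_larger_than_stack_rejected(self):
        st = _stack(np.ones((1, 4, 8, 8)), background_subtracted=True, unmixed=True)
        psf = rest.gaussian_psf((110.0, 110.0, 300.0), (36.0, 120.0))
        with pytest.raises(ValueError, match="exceeds"):
            rest.deconvolve(st, psf)

    def test_requires_unmixing_for_two_channel_stacks(self):
        st = _stack(np.ones((2, 4, 8, 8)), background_subtracted=True)
        psf = rest.PSFKernel(np.ones((1, 3, 3)) / 9.0, (36.0, 120.0))
        with pytest.raises(PipelineOrderError):
            rest.deconvolve(st, psf)


def test_gaussian_psf_normalized_and_shaped():
    psf = rest.gaussian_psf((110.0, 110.0, 300.0), (36.0, 120.0))
    assert psf.kernel.sum() == pytest.approx(1.0)
    assert np.all(psf.kernel >= 0)
    nz, ny, nx = psf.kernel.shape
    assert nx == ny  # isotropic lateral sampling
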