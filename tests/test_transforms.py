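"""Multi-resolution transforms: length contracts, reconstruction, selectivity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from echocad.transforms import (
    FEATURE_LENGTHS,
    METHODS,
    block_average,
    collapse,
    correntropy_lag1,
    directional_filter_bank,
    dwt_decompose,
    dwt_features,
    ewt_decompose_1d,
    get_extractor,
    laplacian_pyramid,
    shearlet_system,
)
from echocad.transforms.cwt import DEFAULT_SCALES, cwt2d_response
from echocad.transforms.dtcwt import dtcwt_decompose, magnitude_features


@pytest.fixture(scope="module")
def image(rng_module):
    return rng_module.random((512, 512))


@pytest.fixture(scope="module")
def rng_module():
    return np.random.default_rng(1)


CONSTANT = np.full((512, 512), 0.5)


class TestContracts:
    @pytest.mark.parametrize("method", METHODS)
    def test_length_contract_and_determinism(self, method, image):
        ext = get_extractor(method)
        v1 = ext.extract(image)
        v2 = ext.extract(image)
        assert v1.shape == (FEATURE_LENGTHS[method],)
        assert np.array_equal(v1, v2)

    @pytest.mark.parametrize("method", ["cntlet", "dtcomwt", "cwt"])
    def test_constant_image_gives_zero_bandpass_features(self, method):
        v = get_extractor(method).extract(CONSTANT)
        assert np.abs(v).max() < 1e-8

    def test_constant_image_dwt_features(self):
        v = get_extractor("dwt").extract(CONSTANT)
        # 256 approximation features = c * (per-level 2-D scaling gain 2)^3
        approx, details = v[:256], v[256:]
        assert np.allclose(approx, 0.5 * 2**3)
        assert np.abs(details).max() < 1e-10

    def test_constant_image_shearlet_only_lowpass(self):
        v = get_extractor("shelet").extract(CONSTANT).reshape(31, 512)
        assert v[0].min() > 0
        assert np.abs(v[1:]).max() < 1e-8

    def test_constant_image_ewt_all_ones(self):
        v = get_extractor("ewt").extract(CONSTANT)
        assert np.allclose(v, 1.0)

    def test_curvelet_slot_not_implemented(self):
        with pytest.raises(NotImplementedError):
            get_extractor("crvlet")


class TestBlockAverage:
    def test_ones_stay_ones(self):
        assert np.array_equal(block_average(np.ones((4, 4)), (2, 2)), np.ones((2, 2)))

    def test_global_mean(self):
        assert block_average(np.array([[1.0, 2.0], [3.0, 4.0]]), (1, 1))[0, 0] == 2.5

    def test_non_divisible_shape_rejected(self):
        with pytest.raises(ValueError):
            block_average(np.ones((6, 6)), (4, 4))

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_mean_preservation(self, seed):
        m = np.random.default_rng(seed).random((64, 64))
        assert abs(block_average(m, (16, 16)).mean() - m.mean()) < 1e-12


class TestDWT:
    def test_constant_detail_bands_vanish(self):
        bands = dwt_decompose(CONSTANT, 3)
        for b in bands.subbands[1:]:
            assert np.abs(b.coeffs).max() < 1e-10

    def test_three_level_band_shapes(self, image):
        shapes = sorted(b.coeffs.shape[0] for b in dwt_decompose(image, 3))
        assert shapes == [64, 64, 64, 64, 128, 128, 128, 256, 256, 256]

    def test_parseval_on_orthonormal_level_one(self, rng):
        x = rng.random((64, 64))
        bands = dwt_decompose(x, 1)
        assert abs(sum((b.coeffs**2).sum() for b in bands) - (x**2).sum()) < 1e-9

    def test_too_deep_levels_rejected(self, rng):
        with pytest.raises(ValueError):
            dwt_decompose(rng.random((64, 64)), 8)

    def test_not_shift_invariant(self, image):
        shifted = np.roll(image, 8, axis=1)
        assert np.linalg.norm(dwt_features(image) - dwt_features(shifted)) > 0


class TestLaplacianPyramid:
    def test_perfect_reconstruction(self, image):
        pyr = laplacian_pyramid(image, 3)
        err = np.linalg.norm(collapse(pyr) - image) / np.linalg.norm(image)
        assert err < 1e-6

    def test_constant_bandpass_levels_vanish(self):
        pyr = laplacian_pyramid(CONSTANT, 3)
        for sub in pyr.subbands[1:]:
            assert np.abs(sub.coeffs).max() < 1e-8
        low = pyr.subbands[0].coeffs
        assert np.allclose(low, low.flat[0])

    def test_impulse_energy_not_lost(self):
        imp = np.zeros((256, 256))
        imp[128, 128] = 1.0
        pyr = laplacian_pyramid(imp, 2)
        assert sum((s.coeffs**2).sum() for s in pyr) >= 1.0 - 1e-12

    def test_invalid_levels_rejected(self, rng):
        with pytest.raises(ValueError):
            laplacian_pyramid(rng.random((100, 100)), 3)


class TestDirectionalFilterBank:
    def test_partition_of_unity(self, rng):
        band = rng.standard_normal((128, 128))
        comps = directional_filter_bank(band, 4)
        assert np.abs(sum(comps) - band).max() < 1e-6

    def test_vertical_bar_energy_concentrates_in_one_wedge(self):
        bar = np.zeros((256, 256))
        bar[:, 120:136] = 1.0  # varies along x only: energy on the w_x axis
        comps = directional_filter_bank(bar - bar.mean(), 4)
        energies = np.array([(c**2).sum() for c in comps])
        assert energies[0] / energies.sum() >= 0.6  # wedge 0 contains theta = 0

    def test_isotropic_blob_splits_evenly(self):
        r, c = np.mgrid[0:256, 0:256]
        blob = np.exp(-((r - 128) ** 2 + (c - 128) ** 2) / (2 * 10.0**2))
        comps = directional_filter_bank(blob - blob.mean(), 4)
        energies = [(x**2).sum() for x in comps]
        assert max(energies) / min(energies) < 1.5

    def test_invalid_direction_count_rejected(self, rng):
        with pytest.raises(ValueError):
            directional_filter_bank(rng.random((64, 64)), 3)


def test_contourlet_rotation_changes_dominant_orientation():
    from skimage.transform import rotate

    line = np.zeros((512, 512))
    line[:, 250:262] = 1.0
    rotated = rotate(line, 30, order=1)
    ext = get_extractor("cntlet")

    def argmax_band(img):
        return int(np.argmax(ext.extract(img).reshape(16, 256).sum(axis=1)))

    assert argmax_band(line) != argmax_band(rotated)


class TestDTCWT:
    def test_six_complex_bands_per_level(self, image):
        bands = dtcwt_decompose(image, 3)
        assert len(bands) == 18
        assert sorted({b.coeffs.shape[0] for b in bands}) == [64, 128, 256]

    def test_magnitudes_more_shift_stable_than_dwt(self, single_phantom):
        img = single_phantom.clean_image
        shifted = np.roll(img, 1, axis=1)
        m = magnitude_features(img)
        rel_dt = np.linalg.norm(m - magnitude_features(shifted)) / np.linalg.norm(m)
        d = dwt_features(img)
        rel_dwt = np.linalg.norm(d - dwt_features(shifted)) / np.linalg.norm(d)
        assert rel_dt < rel_dwt


class TestShearlet:
    def test_filter_count(self):
        assert shearlet_system(128).shape[0] == 31  # 1 + 3 * (2 * (2*2 + 1))

    def test_tight_frame(self):
        filters = shearlet_system(512)
        total = (filters**2).sum(axis=0)
        assert np.abs(total - 1.0).max() < 1e-6

    def test_directional_filters_confined_to_their_cone(self):
        filters = shearlet_system(128)
        f = np.fft.fftfreq(128)
        cone_h = np.abs(f[None, :]) >= np.abs(f[:, None])
        # scale 1, horizontal cone, all shears: filters 1..5
        for filt in filters[1:6]:
            energy = filt**2
            assert energy[~cone_h].sum() / energy.sum() < 0.01

    def test_transpose_flips_dominant_cone(self):
        line = np.zeros((512, 512))
        line[:, 250:262] = 1.0
        ext = get_extractor("shelet")

        def cone_energies(img):
            v = ext.extract(img).reshape(31, 512)[1:].reshape(3, 2, 5, 512)
            return (v[:, 0] ** 2).sum(), (v[:, 1] ** 2).sum()

        eh, ev = cone_energies(line)
        eh_t, ev_t = cone_energies(line.T)
        assert (eh > ev) != (eh_t > ev_t)

    def test_non_dyadic_size_rejected(self):
        with pytest.raises(ValueError):
            shearlet_system(300)


def test_cwt_blob_energy_peaks_near_matching_scale():
    r, c = np.mgrid[0:512, 0:512]
    blob = np.exp(-((r - 256) ** 2 + (c - 256) ** 2) / (2 * 8.0**2))
    energies = [(cwt2d_response(blob, s) ** 2).sum() for s in DEFAULT_SCALES]
    best = DEFAULT_SCALES[int(np.argmax(energies))]
    assert best in (4, 8, 16)  # scale 8 within one dyadic step


class TestEWT:
    def test_modes_sum_to_signal(self, rng):
        sig = rng.standard_normal(512)
        modes, _ = ewt_decompose_1d(sig, 4)
        assert np.abs(sum(modes) - sig).max() < 1e-6

    def test_two_tone_boundary_lies_between_the_peaks(self):
        t = np.arange(512)
        sig = np.sin(2 * np.pi * 10 * t / 512) + np.sin(2 * np.pi * 100 * t / 512)
        modes, bounds = ewt_decompose_1d(sig, 2)
        assert len(modes) == 2 and len(bounds) == 1
        assert 10 / 512 * 2 * np.pi < bounds[0] < 100 / 512 * 2 * np.pi

    def test_constant_signal_yields_single_trivial_mode(self):
        sig = np.full(512, 0.3)
        modes, bounds = ewt_decompose_1d(sig, 4)
        assert len(modes) == 1 and bounds.size == 0
        assert np.array_equal(modes[0], sig)

    def test_noise_features_below_smooth_gradient_features(self, rng):
        noise = rng.random((512, 512))
        grad = np.tile(np.linspace(0.2, 0.8, 512), (512, 1))
        ext = get_extractor("ewt")
        assert ext.extract(noise).mean() < ext.extract(grad).mean()


class TestCorrentropy:
    def test_constant_signal_is_one(self):
        assert correntropy_lag1(np.full(100, 3.0)) == 1.0

    def test_alternating_signal_matches_hand_computation(self):
        sig = np.array([-1.0, 1.0] * 16)  # z-scored alternating: diffs all +-2
        assert correntropy_lag1(sig, sigma=1.0) == pytest.approx(np.exp(-2), abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_bounded_in_unit_interval(self, seed):
        sig = np.random.default_rng(seed).standard_normal(64)
        v = correntropy_lag1(sig)
        assert 0 < v <= 1

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            correntropy_lag1(np.arange(10.0), sigma=0.0)
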