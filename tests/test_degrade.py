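"""Noise injection, blind noise estimation and photometric perturbation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import seedxray as sx
from seedxray.degrade import PhotometricParams, degrade_dataset
from seedxray.errors import ParameterError, SizeError


def smooth_scene(shape=(384, 384), lo=60.0, hi=200.0, seed=0):
    """A smooth mid-range test scene: blurred phantom page, offset from 0
    so clipping is negligible at sigma <= 25."""
    from skimage.filters import gaussian

    spec = sx.PhantomSpec(class_mix={"M": 2, "N": 2, "E": 2},
                          canvas=(shape[1], shape[0]),
                          seed_size_px=(40, 56), rng_seed=seed)
    from seedxray.phantoms import make_phantom_scene
    scene = make_phantom_scene(spec).astype(float)
    scene = gaussian(scene, sigma=4, preserve_range=True)
    scene = lo + scene / 255.0 * (hi - lo)
    return np.clip(np.round(scene), 0, 255).astype(np.uint8)


class TestAddGaussianNoise:
    def test_sigma_zero_identity(self):
        img = np.arange(256, dtype=np.uint8).reshape(16, 16)
        assert np.array_equal(sx.add_gaussian_noise(img, 0, 1), img)

    def test_midgray_sample_std(self):
        img = np.full((1000, 1000), 128, np.uint8)
        out = sx.add_gaussian_noise(img, 10, rng_seed=0)
        diff = out.astype(float) - 128
        assert 9.8 <= diff.std() <= 10.2
        assert abs(diff.mean()) < 0.05

    def test_floor_clipping_bias(self):
        # near-black input: negative tail clips at 0, raising the mean
        img = np.full((500, 500), 2, np.uint8)
        out = sx.add_gaussian_noise(img, 10, rng_seed=0)
        assert out.astype(float).mean() > 2.0

    def test_deterministic_and_shape_preserving(self):
        img = np.full((64, 64), 100, np.uint8)
        a = sx.add_gaussian_noise(img, 5, 42)
        b = sx.add_gaussian_noise(img, 5, 42)
        assert np.array_equal(a, b)
        assert a.shape == img.shape and a.dtype == np.uint8

    def test_negative_sigma_rejected(self):
        with pytest.raises(ParameterError):
            sx.add_gaussian_noise(np.zeros((4, 4), np.uint8), -1, 0)


class TestEstimateNoiseSigma:
    def test_constant_image_estimates_zero(self):
        assert sx.estimate_noise_sigma(np.full((50, 50), 99, np.uint8)) == 0.0

    def test_injection_recovery_at_sigma_15(self):
        scene = smooth_scene()
        noisy = sx.add_gaussian_noise(scene, 15, rng_seed=1)
        assert 13.5 <= sx.estimate_noise_sigma(noisy) <= 16.5

    def test_monotone_in_injected_sigma(self):
        scene = smooth_scene()
        estimates = [
            sx.estimate_noise_sigma(sx.add_gaussian_noise(scene, s, 2))
            for s in (5, 10, 15, 20, 25)
        ]
        assert all(a < b for a, b in zip(estimates, estimates[1:]))

    def test_agrees_with_wavelet_oracle(self):
        # independent blind estimator on the same noisy image
        from skimage.restoration import estimate_sigma as wavelet_sigma

        noisy = sx.add_gaussian_noise(smooth_scene(), 12, rng_seed=3)
        ours = sx.estimate_noise_sigma(noisy)
        theirs = float(wavelet_sigma(noisy))
        assert abs(ours - theirs) / theirs < 0.15

    def test_too_small_image_rejected(self):
        with pytest.raises(SizeError):
            sx.estimate_noise_sigma(np.zeros((2, 5), np.uint8))


class TestApplyPhotometric:
    def test_identity(self):
        img = np.arange(256, dtype=np.uint8).reshape(16, 16)
        out = sx.apply_photometric(img, PhotometricParams(1.0, 0.0))
        assert np.array_equal(out, img)

    def test_contrast_pivot_arithmetic(self):
        img = np.full((3, 3), 200, np.uint8)
        out = sx.apply_photometric(img, PhotometricParams(1.25, 0.0))
        assert out[0, 0] == 218  # round(1.25 * 72.5 + 127.5)

    @pytest.mark.parametrize("contrast", [0.8, 1.0])
    def test_full_brightness_saturates(self, contrast):
        # with contrast <= 1 the +255 offset dominates every pixel; at
        # contrast > 1 the darkest pixels stay below the ceiling
        img = np.arange(256, dtype=np.uint8).reshape(16, 16)
        out = sx.apply_photometric(img, PhotometricParams(contrast, 1.0))
        assert (out == 255).all()

    def test_monotone_pixelwise(self, rng):
        a = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        b = np.clip(a.astype(int) + rng.integers(0, 40, a.shape),
                    0, 255).astype(np.uint8)
        params = PhotometricParams(1.2, 0.1)
        assert (sx.apply_photometric(a, params)
                <= sx.apply_photometric(b, params)).all()


class TestDegradeDataset:
    def test_degenerate_config_is_byte_identical(self, phantom_dataset,
                                                 tmp_path):
        manifest = phantom_dataset["manifest"]
        out = degrade_dataset(manifest, phantom_dataset["dir"],
                              tmp_path / "deg", sigma_max=0.0,
                              contrast=(1.0, 1.0), brightness=(0.0, 0.0),
                              rng_seed=0)
        for src, dst in zip(manifest.itertuples(), out.itertuples()):
            assert (phantom_dataset["dir"] / src.image_path).read_bytes() \
                == (tmp_path / "deg" / dst.image_path).read_bytes()

    def test_annotation_geometry_untouched(self, phantom_dataset, tmp_path):
        manifest = phantom_dataset["manifest"]
        out = degrade_dataset(manifest, phantom_dataset["dir"],
                              tmp_path / "deg", sigma_max=20.0,
                              copies_per_image=2, rng_seed=5)
        assert len(out) == 2 * len(manifest)
        for src, dst in zip(manifest.itertuples(),
                            out.iloc[::2].itertuples()):
            a = sx.read_voc(phantom_dataset["dir"] / src.voc_path)
            b = sx.read_voc(tmp_path / "deg" / dst.voc_path)
            assert a.boxes == b.boxes

    def test_logged_sigmas_uniform(self, tmp_path, catalog):
        # 1000 degraded copies of one tiny image: logged sigma ~ U(0, 25)
        img = np.full((16, 16), 120, np.uint8)
        rec = sx.AnnotatedRadiograph(width=16, height=16,
                                     boxes=[sx.Box(2, 2, 14, 14, "M")],
                                     source_id="tiny", image=img)
        from seedxray.datasets import save_dataset
        manifest = save_dataset([rec], catalog, tmp_path / "in")
        out = degrade_dataset(manifest, tmp_path / "in", tmp_path / "deg",
                              sigma_max=25.0, copies_per_image=1000,
                              rng_seed=8)
        sigmas = out["sigma"].to_numpy()
        assert (sigmas >= 0).all() and (sigmas <= 25).all()
        pvalue = stats.kstest(sigmas / 25.0, "uniform").pvalue
        assert pvalue > 0.01
        log = pd.read_csv(tmp_path / "deg" / "degrade_log.csv")
        assert np.allclose(log["sigma"], sigmas)
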