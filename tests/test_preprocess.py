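"""Brain-extraction chain: standardization, Gaussian blur, Otsu threshold
(against a brute-force maximizer), component selection, gamma transform,
and the composed pipeline on phantoms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from PIL import Image

from neuronet19.phantoms import NOTUMOR, PhantomSpec, generate_phantom
from neuronet19.preprocess import (BinaryMask, PreprocessConfig, apply_mask_and_crop,
                                   brain_roi, gaussian_blur, gaussian_kernel,
                                   otsu_threshold, power_law, preprocess_pipeline,
                                   select_brain_component, standardize)


# ---------------------------------------------------------------- oracles
def otsu_bruteforce(image):
    """Exhaustive maximizer of w1 w2 (mu1 - mu2)^2 over all 256 thresholds.

    Scores are compared exactly (integer cross-multiplication), so the
    returned threshold is the smallest exact maximizer.
    """
    v = np.clip(np.rint(np.asarray(image)), 0, 255).astype(np.int64).ravel()
    n = len(v)
    best = None  # (num, den, t): score = num / (n^2 * den)
    for t in range(256):
        c1 = v[v <= t]
        c2 = v[v > t]
        n1, n2 = len(c1), len(c2)
        if n1 == 0 or n2 == 0:
            continue
        s1, s2 = int(c1.sum()), int(c2.sum())
        num = (s1 * n2 - s2 * n1) ** 2
        den = n1 * n2
        if best is None or num * best[1] > best[0] * den:
            best = (num, den, t)
    return None if best is None else best[2]


# ---------------------------------------------------------- standardize
def test_standardize_shapes_and_identity(tmp_path):
    rgb = np.random.default_rng(0).integers(0, 256, (512, 512, 3), dtype=np.int64)
    out = standardize(rgb.astype(np.uint8), 128)
    assert out.shape == (128, 128) and out.dtype == np.uint8

    gray = np.random.default_rng(1).integers(0, 256, (128, 128)).astype(np.uint8)
    assert np.array_equal(standardize(gray, 128), gray)

    rect = np.zeros((100, 200), dtype=np.uint8)
    assert standardize(rect, 128).shape == (128, 128)

    p = tmp_path / "img.png"
    Image.fromarray(gray).save(p)
    assert np.array_equal(standardize(p, 128), gray)


def test_standardize_rejects_corrupt_file(tmp_path):
    p = tmp_path / "bad.png"
    p.write_bytes(b"not an image")
    with pytest.raises(ValueError, match="decode"):
        standardize(p, 128)


# -------------------------------------------------------- gaussian blur
def test_gaussian_kernel_sigma_rule_and_normalization():
    k = gaussian_kernel(11)
    assert k.shape == (11, 11)
    assert k.sum() == pytest.approx(1.0, abs=1e-12)
    # sigma = (n-1)/6: ratio of adjacent samples fixes sigma
    sigma = 10 / 6
    ratio = k[5, 6] / k[5, 5]
    assert ratio == pytest.approx(np.exp(-1 / (2 * sigma ** 2)), rel=1e-12)


def test_blur_preserves_constant_image():
    img = np.full((32, 32), 77, dtype=np.uint8)
    out = gaussian_blur(img, 11)
    assert np.allclose(out, 77.0, atol=1e-9)


def test_blur_even_kernel_rejected():
    with pytest.raises(ValueError, match="odd"):
        gaussian_blur(np.zeros((8, 8)), 4)


def test_blur_impulse_reproduces_kernel():
    """A single bright pixel convolved with the kernel returns the kernel
    itself scaled by the pixel value (dense-convolution oracle)."""
    img = np.zeros((11, 11))
    img[5, 5] = 255.0
    out = gaussian_blur(img, 5)
    expected = np.zeros((11, 11))
    expected[3:8, 3:8] = gaussian_kernel(5) * 255.0
    assert np.allclose(out, expected, atol=1e-12)


# ------------------------------------------------------------------ otsu
def test_otsu_separates_two_populations_exactly():
    img = np.concatenate([np.zeros(50), np.full(50, 255)]).reshape(10, 10)
    mask = otsu_threshold(img)
    assert mask.threshold_used == otsu_bruteforce(img)
    assert mask.pixels.sum() == 50

    img2 = np.full((4, 4), 10)
    img2.ravel()[:4] = 200
    mask2 = otsu_threshold(img2)
    assert mask2.pixels.sum() == 4
    assert mask2.threshold_used == otsu_bruteforce(img2)


def test_otsu_constant_image_degenerate():
    mask = otsu_threshold(np.full((8, 8), 128))
    assert mask.degenerate and mask.threshold_used is None
    assert not mask.pixels.any()


def test_otsu_matches_bruteforce_on_random_images():
    rng = np.random.default_rng(42)
    for _ in range(200):
        img = rng.integers(0, 256, (16, 16))
        assert otsu_threshold(img).threshold_used == otsu_bruteforce(img)


def test_otsu_variance_decomposition_identity():
    """w1 w2 (mu1-mu2)^2 + (w1 var1 + w2 var2) == total variance, every T."""
    rng = np.random.default_rng(7)
    v = rng.integers(0, 256, 400).astype(np.float64)
    total_var = v.var()
    for t in range(256):
        c1, c2 = v[v <= t], v[v > t]
        if len(c1) == 0 or len(c2) == 0:
            continue
        w1, w2 = len(c1) / len(v), len(c2) / len(v)
        between = w1 * w2 * (c1.mean() - c2.mean()) ** 2
        within = w1 * c1.var() + w2 * c2.var()
        assert between + within == pytest.approx(total_var, abs=1e-9 * max(1, total_var))


# ------------------------------------------------------------- brain ROI
def _mask(arr):
    return BinaryMask(pixels=np.asarray(arr, dtype=bool), threshold_used=0)


def test_roi_selects_largest_component_above_min_area():
    m = np.zeros((60, 60), dtype=bool)
    m[5:35, 5:55] = True          # 30x50 = 1500
    m[50:55, 0:10] = True         # 50
    roi = brain_roi(_mask(m), min_area=1000)
    assert (roi.x, roi.y, roi.w, roi.h) == (5, 5, 50, 30)
    assert roi.area == 1500 and not roi.fallback


def test_roi_counts_filled_area_and_masks_holes():
    m = np.zeros((40, 40), dtype=bool)
    m[5:25, 5:25] = True
    m[10:20, 10:20] = False       # hole: raw area 300, filled 400
    filled, roi = select_brain_component(_mask(m), min_area=350)
    assert roi.area == 400 and not roi.fallback
    assert filled[12, 12]         # hole is part of the filled component


def test_roi_fallback_when_nothing_qualifies():
    m = np.zeros((30, 30), dtype=bool)
    m[0:5, 0:5] = True
    roi = brain_roi(_mask(m), min_area=1000)
    assert roi.fallback and (roi.x, roi.y, roi.w, roi.h) == (0, 0, 30, 30)


def test_roi_tie_break_is_row_major_first():
    m = np.zeros((20, 40), dtype=bool)
    m[10:14, 30:34] = True        # later in raster order, same area
    m[12:16, 2:6] = True          # first pixel (10, 30) vs (12, 2)
    roi = brain_roi(_mask(m), min_area=4)
    assert (roi.x, roi.y) == (30, 10)


def test_apply_mask_and_crop_identity_and_zeroing():
    img = np.arange(36, dtype=np.uint8).reshape(6, 6)
    full = np.ones((6, 6), dtype=bool)
    from neuronet19.preprocess import RegionOfInterest
    roi = RegionOfInterest(0, 0, 6, 6, area=36)
    assert np.array_equal(apply_mask_and_crop(img, full, roi), img)

    comp = np.zeros((6, 6), dtype=bool)
    comp[1:4, 2:5] = True
    roi = RegionOfInterest(2, 1, 3, 3, area=9)
    out = apply_mask_and_crop(img, comp, roi)
    assert out.shape == (3, 3)
    assert np.array_equal(out, img[1:4, 2:5])
    out2 = apply_mask_and_crop(img, comp,
                               RegionOfInterest(0, 0, 6, 6, area=36))
    assert (out2[~comp] == 0).all()


# ------------------------------------------------------------ power law
def test_power_law_hand_cases():
    assert power_law(np.array([[int(0.25 * 255)]]))[0, 0] in (31, 32)
    # exact quarter: Q=0.25 -> P=0.125 -> 31.875 -> 32
    q = np.array([[63.75]])
    assert power_law(q)[0, 0] == 32
    img = np.arange(256, dtype=np.uint8).reshape(16, 16)
    assert np.array_equal(power_law(img, k=1.0, beta=1.0), img)
    assert power_law(np.array([[255]]), beta=7.3)[0, 0] == 255


@settings(max_examples=50, deadline=None, derandomize=True, database=None)
@given(beta=st.floats(0.1, 5.0), k=st.floats(0.2, 3.0))
def test_power_law_monotone_in_gray_level(beta, k):
    ramp = np.arange(256, dtype=np.uint8)
    out = power_law(ramp, k=k, beta=beta).astype(int)
    assert (np.diff(out) >= 0).all()


# ------------------------------------------------------------- pipeline
def test_pipeline_output_shape_and_determinism(phantom_batch):
    cfg = PreprocessConfig()
    ph = phantom_batch[0]
    a = preprocess_pipeline(ph.pixels, cfg)
    b = preprocess_pipeline(ph.pixels, cfg)
    assert a.shape == (128, 128) and a.dtype == np.uint8
    assert np.array_equal(a, b)


def test_pipeline_roi_contains_lesion(phantom_batch):
    cfg = PreprocessConfig()
    for ph in phantom_batch:
        if ph.lesion_bbox is None:
            continue
        _, stages = preprocess_pipeline(ph.pixels, cfg, return_stages=True)
        roi = stages["roi"]
        lb = ph.lesion_bbox
        assert roi.x <= lb.x and roi.y <= lb.y
        assert lb.x + lb.w <= roi.x + roi.w and lb.y + lb.h <= roi.y + roi.h


def test_pipeline_constant_black_image_falls_back():
    out, stages = preprocess_pipeline(np.zeros((64, 64), dtype=np.uint8),
                                      PreprocessConfig(), return_stages=True)
    assert stages["roi"].fallback
    assert out.shape == (128, 128) and (out == 0).all()


def test_config_validation():
    with pytest.raises(ValueError):
        PreprocessConfig(blur_kernel_n=10).validate()
    with pytest.raises(ValueError):
        PreprocessConfig(gamma_beta=0).validate()
    with pytest.raises(ValueError):
        PreprocessConfig(target_size=16).validate()
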