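"""Edge detection: filter/threshold oracles, topmost rule, validity, smoothing."""

import numpy as np
import pytest
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
from skimage.filters import threshold_otsu as skimage_otsu

from corneadyn import (
    EdgeParams,
    ImageSequence,
    Map2D,
    extract_edge_canny,
    extract_edge_otsu,
    interpolate_missing,
    median_filter_3d,
    otsu_threshold,
    smooth_contour,
    validate_contour,
)
from corneadyn.io_sequences import ContourError, DegenerateInputError, DimensionError


def naive_median(arr: np.ndarray, size: int = 3) -> np.ndarray:
    """Brute-force sliding median with edge replication, any dimensionality."""
    pad = size // 2
    padded = np.pad(arr, pad, mode="edge")
    windows = sliding_window_view(padded, (size,) * arr.ndim)
    return np.median(windows.reshape(arr.shape + (-1,)), axis=-1)


# ---------------------------------------------------------------------------
# 3-D median filter
# ---------------------------------------------------------------------------


def test_median3d_constant_and_salt():
    const = ImageSequence(np.full((6, 6, 6), 0.4))
    assert np.array_equal(median_filter_3d(const).data, const.data)

    salt = np.zeros((7, 7, 7), dtype=np.float32)
    salt[3, 3, 3] = 1.0
    out = median_filter_3d(ImageSequence(salt))
    assert out.data[3, 3, 3] == 0.0


def test_median3d_equals_naive_oracle(rng):
    data = rng.random((5, 5, 5)).astype(np.float32)
    ours = median_filter_3d(ImageSequence(data)).data
    assert np.allclose(ours, naive_median(data.astype(float)), atol=1e-7)


def test_median3d_mask_too_large():
    with pytest.raises(DimensionError):
        median_filter_3d(ImageSequence(np.zeros((3, 3, 3))), mask=(5, 5, 5))


# ---------------------------------------------------------------------------
# Otsu threshold
# ---------------------------------------------------------------------------


def brute_force_otsu(values: np.ndarray) -> float:
    """Exhaustive 256-candidate between-class-variance maximiser."""
    hist, edges = np.histogram(values, bins=256, range=(0.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = hist.sum()
    best_t, best_sigma = 0, -1.0
    for t in range(255):
        n0, n1 = hist[: t + 1].sum(), hist[t + 1 :].sum()
        if n0 == 0 or n1 == 0:
            continue
        mu0 = (hist[: t + 1] * centers[: t + 1]).sum() / n0
        mu1 = (hist[t + 1 :] * centers[t + 1 :]).sum() / n1
        sigma = (n0 / total) * (n1 / total) * (mu0 - mu1) ** 2
        if sigma > best_sigma:
            best_sigma, best_t = sigma, t
    return float(edges[best_t + 1])


def test_otsu_two_level():
    thr = otsu_threshold(np.array([0, 0, 0, 1, 1, 1], dtype=float))
    assert 0.0 < thr < 1.0


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_otsu_equals_brute_force(seed):
    rng = np.random.default_rng(seed)
    values = np.clip(
        np.concatenate([rng.normal(0.25, 0.05, 300), rng.normal(0.75, 0.08, 200)]), 0, 1
    )
    assert otsu_threshold(values) == pytest.approx(brute_force_otsu(values))


def test_otsu_matches_skimage_within_a_bin(rng):
    values = np.clip(np.concatenate([rng.normal(0.3, 0.05, 500), rng.normal(0.8, 0.05, 500)]), 0, 1)
    assert abs(otsu_threshold(values) - skimage_otsu(values, nbins=256)) < 2.0 / 256


def test_otsu_outlier_and_degenerate():
    values = np.concatenate([np.full(100, 0.2) + np.linspace(0, 1e-3, 100), [0.99]])
    assert np.isfinite(otsu_threshold(values))
    with pytest.raises(DegenerateInputError):
        otsu_threshold(np.full(10, 0.5))


# ---------------------------------------------------------------------------
# edge extraction
# ---------------------------------------------------------------------------


def slab_sequence(top=50, bottom=60, m=80, n=12, i=3):
    data = np.zeros((m, n, i), dtype=np.float32)
    data[top : bottom + 1] = 1.0
    return ImageSequence(data)


def test_otsu_route_flat_slab():
    contour = extract_edge_otsu(slab_sequence())
    assert np.allclose(contour.values, 50.0, atol=1e-6)


def test_canny_route_flat_slab():
    contour = extract_edge_canny(slab_sequence())
    assert np.all(np.abs(contour.values - 50.0) <= 1.0)


def test_topmost_rule_ignores_bright_band_below():
    """A bright iris-like band deeper in the image must not steal the contour."""
    seq = slab_sequence(top=20, bottom=30, m=80)
    with_band = seq.data.copy()
    with_band[60:70] = 1.0
    contour_plain = extract_edge_otsu(ImageSequence(seq.data))
    contour_band = extract_edge_otsu(ImageSequence(with_band))
    assert np.allclose(contour_band.values, contour_plain.values, atol=1e-6)
    assert np.all(contour_band.values < 31)


def test_both_detectors_recover_phantom_contour(quiet_phantom):
    """Noiseless phantom: both routes within 1 px of truth, mutually within 2 px."""
    seq, truth = quiet_phantom
    filtered = median_filter_3d(seq)
    canny = extract_edge_canny(filtered)
    otsu = extract_edge_otsu(filtered)
    for contour in (canny, otsu):
        assert contour.n_missing == 0
        assert np.max(np.abs(contour.values - truth.contour.values)) <= 1.0
    assert np.max(np.abs(canny.values - otsu.values)) <= 2.0


def test_all_dark_frame_gives_missing_columns():
    seq = ImageSequence(np.zeros((20, 10, 3), dtype=np.float32))
    contour = extract_edge_canny(seq)
    assert contour.n_missing == contour.values.size
    assert not validate_contour(contour).ok


def test_pure_noise_fails_validity():
    """Structureless speckle noise yields gappy contours, caught by the rule."""
    rng = np.random.default_rng(5)
    data = np.clip(rng.normal(0.0, 0.3, (40, 30, 6)), 0, 1).astype(np.float32)
    contour = extract_edge_canny(median_filter_3d(ImageSequence(data)))
    assert not validate_contour(contour).ok


def test_erosion_xor_is_inner_boundary(rng):
    """XOR with the 3×3 erosion marks exactly the 8-connected inner boundary."""
    binary = ndimage.binary_dilation(rng.random((30, 30)) > 0.93, iterations=3)
    eroded = ndimage.binary_erosion(binary, structure=np.ones((3, 3)), border_value=1)
    boundary = binary ^ eroded
    # oracle: a pixel is inner-boundary iff set and some in-image 8-neighbour is 0
    oracle = np.zeros_like(binary)
    for m in range(30):
        for n in range(30):
            if not binary[m, n]:
                continue
            nb = binary[max(m - 1, 0) : m + 2, max(n - 1, 0) : n + 2]
            oracle[m, n] = not nb.all()
    assert np.array_equal(boundary, oracle)


# ---------------------------------------------------------------------------
# validation, interpolation, smoothing
# ---------------------------------------------------------------------------


def test_validity_rule():
    flat = Map2D(np.full((20, 10), 33.0), "contour")
    report = validate_contour(flat)
    assert report.ok and report.max_interframe_jump == 0.0

    jump = flat.values.copy()
    jump[7, 5:] += 12.0  # single 12-px interframe step in one column
    report = validate_contour(Map2D(jump, "contour"))
    assert not report.ok
    assert report.max_interframe_jump == pytest.approx(12.0)


def test_validity_accepts_slow_large_deflection(quiet_phantom):
    """A 20-px deflection spread over ~40 frames keeps per-frame steps small."""
    _, truth = quiet_phantom
    assert validate_contour(truth.contour).ok


def test_interpolate_missing_fills_gaps():
    vals = np.tile(np.linspace(10, 20, 11)[:, None], (1, 4))
    vals[5, 2] = np.nan
    filled = interpolate_missing(Map2D(vals, "contour"))
    assert filled.n_missing == 0
    assert filled.values[5, 2] == pytest.approx(15.0)

    vals[:, 1] = np.nan
    with pytest.raises(ContourError):
        interpolate_missing(Map2D(vals, "contour"))


def test_smooth_contour_median_properties(rng):
    const = Map2D(np.full((9, 9), 5.0), "contour")
    assert np.array_equal(smooth_contour(const).values, const.values)

    spike = np.full((9, 9), 40.0)
    spike[4, 4] += 5.0
    assert np.array_equal(smooth_contour(Map2D(spike, "contour")).values, np.full((9, 9), 40.0))

    rnd = rng.random((12, 15))
    ours = smooth_contour(Map2D(rnd, "contour")).values
    assert np.allclose(ours, naive_median(rnd), atol=1e-12)


def test_edge_params_validation():
    with pytest.raises(ValueError):
        EdgeParams(v_r=0.0)
    with pytest.raises(ValueError):
        EdgeParams(median_mask=(2, 3, 3))
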