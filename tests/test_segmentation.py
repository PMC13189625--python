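import numpy as np
import pytest

from synprox import (ImageSimConfig, ImageStack, ROIBox, SegmentationConfig,
                     measure_puncta, segment_puncta, simulate_puncta_image,
                     stack_histogram, triangle_threshold)
from synprox.segmentation import ContrastError
from synprox.simulate_images import render_scene

from _oracles import triangle_scan


# ------------------------------------------------------------ thresholding

def test_two_spike_histogram_threshold_between_spikes():
    hist = np.zeros(256)
    hist[10] = 1000
    hist[200] = 1000
    t = triangle_threshold(hist)
    assert 10 < t < 200


def test_threshold_matches_exhaustive_scan_on_random_histograms():
    """Implemented Triangle threshold equals a brute-force perpendicular
    distance scan on 500 random 8- and 16-bit histograms."""
    rng = np.random.default_rng(123)
    mismatches = 0
    for i in range(500):
        nbins = 256 if i % 2 == 0 else int(rng.integers(1024, 65536))
        hist = np.zeros(nbins)
        # background peak + sparse bright tail, random shape
        peak_loc = int(rng.integers(0, nbins // 4)) if i % 3 else \
            int(rng.integers(3 * nbins // 4, nbins))
        width = max(2, int(rng.integers(1, nbins // 16)))
        lo = max(0, peak_loc - 3 * width)
        hi = min(nbins, peak_loc + 3 * width)
        xs = np.arange(lo, hi)
        hist[lo:hi] = 1e4 * np.exp(-0.5 * ((xs - peak_loc) / width) ** 2)
        n_tail = int(rng.integers(2, 40))
        tail_bins = rng.integers(0, nbins, n_tail)
        hist[tail_bins] += rng.integers(1, 50, n_tail)
        hist = np.floor(hist)
        if np.count_nonzero(hist) < 2:
            continue
        if triangle_threshold(hist) != triangle_scan(hist):
            mismatches += 1
    assert mismatches == 0


def test_mirror_symmetry_of_threshold():
    rng = np.random.default_rng(7)
    for _ in range(50):
        hist = np.floor(rng.random(128) ** 4 * 100)
        hist[int(rng.integers(0, 16))] += 500
        if np.count_nonzero(hist) < 2:
            continue
        t = triangle_threshold(hist)
        tm = triangle_threshold(hist[::-1])
        assert tm == len(hist) - 1 - t


def test_threshold_errors_on_degenerate_histograms():
    with pytest.raises(ContrastError):
        triangle_threshold(np.zeros(10))
    h = np.zeros(10)
    h[4] = 100
    with pytest.raises(ContrastError):
        triangle_threshold(h)


def test_loose_agreement_with_skimage_triangle():
    """Cross-check against an independent Triangle implementation on a
    smooth bimodal image (dialects may differ by a few bins)."""
    from skimage.filters import threshold_triangle
    rng = np.random.default_rng(0)
    img = np.concatenate([
        rng.normal(20, 4, 40000), rng.normal(180, 10, 1500)
    ]).clip(0, 255).astype(np.uint16)
    hist = np.bincount(img, minlength=256)
    t_ours = triangle_threshold(hist)
    t_sk = threshold_triangle(img)
    assert abs(t_ours - t_sk) <= 3


# ------------------------------------------------------------ histograms

def test_stack_histogram_pools_slices():
    rng = np.random.default_rng(1)
    data = rng.integers(0, 50, size=(1, 3, 16, 16)).astype(np.uint16)
    stack = ImageStack(data=data)
    pooled = stack_histogram(stack, 0)
    per_slice = sum(
        np.bincount(data[0, z].ravel(), minlength=len(pooled))
        for z in range(3)
    )
    assert np.array_equal(pooled, per_slice)


def test_two_identical_slices_double_counts():
    sl = (np.arange(64).reshape(8, 8) % 7).astype(np.uint16)
    one = ImageStack(data=sl[None, None])
    two = ImageStack(data=np.stack([sl, sl])[None])
    h1 = stack_histogram(one, 0)
    h2 = stack_histogram(two, 0)
    assert np.array_equal(h2, 2 * h1)


# ------------------------------------------------------------ segmentation

def test_blank_channel_yields_flagged_empty_set():
    stack = ImageStack(data=np.zeros((1, 2, 16, 16), dtype=np.uint16))
    ps = segment_puncta(stack, 0)
    assert ps.error is not None
    assert ps.n_objects == 0


def test_noise_free_scene_recovers_planted_count_and_centroids():
    """Well-separated noise-free puncta are all detected, with centroid
    RMS error below one pixel."""
    px = 0.05
    centers = np.array([[1.0 + 2.0 * i, 1.0 + 2.0 * j]
                        for i in range(5) for j in range(6)])  # 30 puncta
    radii = np.full(30, 0.15)
    z = np.full(30, 3.0)
    scene = render_scene(centers, radii, z, (7, 256, 256), px)
    data = np.round(scene * 1000).astype(np.uint16)[None]
    stack = ImageStack(data=data, pixel_size_um=px)
    ps = segment_puncta(stack, 0)
    assert ps.n_objects == 30
    got = ps.objects[["centroid_row", "centroid_col"]].to_numpy() * px
    got = got[np.lexsort((got[:, 1], got[:, 0]))]
    want = centers[np.lexsort((centers[:, 1], centers[:, 0]))]
    rms = np.sqrt(((got - want) ** 2).sum(axis=1).mean()) / px
    assert rms < 1.0


def test_square_object_pixel_and_physical_area():
    data = np.zeros((1, 1, 32, 32), dtype=np.uint16)
    data[0, 0, 10:15, 10:15] = 100
    stack = ImageStack(data=data, pixel_size_um=0.05)
    ps = segment_puncta(stack, 0)
    assert ps.n_objects == 1
    assert ps.objects["area_px"].iloc[0] == 25
    assert ps.objects["area_um2"].iloc[0] == pytest.approx(0.0625)


def test_area_bookkeeping_and_translation_invariance():
    rng = np.random.default_rng(2)
    base = np.zeros((40, 40), dtype=np.uint16)
    for r, c in rng.integers(5, 30, size=(5, 2)):
        base[r:r + 3, c:c + 3] = 50
    stack = ImageStack(data=base[None, None])
    ps = segment_puncta(stack, 0)
    assert ps.objects["area_px"].sum() == ps.mask.sum()
    shifted = np.roll(base, (4, 4), axis=(0, 1))
    ps2 = segment_puncta(ImageStack(data=shifted[None, None]), 0)
    assert ps2.n_objects == ps.n_objects


def test_scale_consistency_physical_area_invariant():
    """Halving pixel size quadruples pixel areas but leaves physical areas
    unchanged for the same rendered scene."""
    centers = np.array([[2.03, 2.03], [5.07, 5.07]])
    radii = np.array([0.5, 0.5])
    z = np.array([3.0, 3.0])
    areas = {}
    for px in (0.1, 0.05):
        n = int(8.0 / px)
        scene = render_scene(centers, radii, z, (7, n, n), px)
        stack = ImageStack(data=np.round(scene * 1000).astype(np.uint16)[None],
                           pixel_size_um=px)
        ps = segment_puncta(stack, 0)
        assert ps.n_objects == 2
        areas[px] = (ps.objects["area_px"].to_numpy(),
                     ps.objects["area_um2"].to_numpy())
    ratio_px = areas[0.05][0].sum() / areas[0.1][0].sum()
    assert ratio_px == pytest.approx(4.0, rel=0.1)
    assert areas[0.05][1].sum() == pytest.approx(areas[0.1][1].sum(), rel=0.1)


def test_size_filters_remove_objects():
    data = np.zeros((1, 1, 40, 40), dtype=np.uint16)
    data[0, 0, 2:4, 2:4] = 90        # 4 px
    data[0, 0, 10:20, 10:20] = 90    # 100 px
    stack = ImageStack(data=data)
    ps = segment_puncta(stack, 0, SegmentationConfig(min_area_px=10))
    assert ps.n_objects == 1 and ps.objects["area_px"].iloc[0] == 100
    ps2 = segment_puncta(stack, 0, SegmentationConfig(max_area_px=50))
    assert ps2.n_objects == 1 and ps2.objects["area_px"].iloc[0] == 4


# ------------------------------------------------------------ ROI measures

def _single_object_set(row, col):
    data = np.zeros((1, 1, 64, 64), dtype=np.uint16)
    data[0, 0, row, col] = 100
    data[0, 0, 0, 0] = 1  # second nonzero bin so thresholding works
    return segment_puncta(ImageStack(data=data), 0)


def test_roi_density_arithmetic():
    roi = ROIBox(origin=(0, 0), height_um=20.07, width_um=32.91)
    data = np.zeros((1, 1, 512, 720), dtype=np.uint16)
    rng = np.random.default_rng(4)
    rows = rng.integers(5, 350, 10)
    cols = rng.integers(5, 600, 10)
    for r, c in zip(rows, cols):
        data[0, 0, r, c] = 100
    stack = ImageStack(data=data, pixel_size_um=0.05)
    ps = segment_puncta(stack, 0)
    m = measure_puncta(ps, roi)
    inside = sum(1 for r, c in zip(rows, cols)
                 if r < round(20.07 / 0.05) and c < round(32.91 / 0.05))
    assert m["count"] == inside
    assert m["density_per_um2"] == pytest.approx(inside / 660.5037)


def test_roi_edge_centroid_excluded_half_open():
    px = 0.05
    roi = ROIBox(origin=(0, 0), height_um=20 * px, width_um=20 * px)
    inside = _single_object_set(19, 19)
    outside = _single_object_set(20, 10)  # centroid exactly on max-row edge
    assert measure_puncta(inside, roi)["count"] == 1
    assert measure_puncta(outside, roi)["count"] == 0


def test_empty_puncta_set_measures_nan_sizes():
    data = np.zeros((1, 1, 64, 64), dtype=np.uint16)
    data[0, 0, 0, 0] = 1
    data[0, 0, 1, 1] = 3
    ps = segment_puncta(ImageStack(data=data), 0,
                        SegmentationConfig(min_area_px=50))
    roi = ROIBox(origin=(0, 0), height_um=1.0, width_um=1.0)
    m = measure_puncta(ps, roi)
    assert m["count"] == 0 and m["density_per_um2"] == 0.0
    assert np.isnan(m["mean_area_um2"])


def test_roi_outside_image_rejected():
    ps = _single_object_set(5, 5)
    roi = ROIBox(origin=(60, 60), height_um=1.0, width_um=1.0)
    with pytest.raises(ValueError):
        measure_puncta(ps, roi)
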