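import numpy as np
import pytest

from synprox import (ColocConfig, ImageSimConfig, ImageStack, ROIBox,
                     SegmentationConfig, coloc_with_flip,
                     expected_chance_overlap, flipped_control, full_image_roi,
                     overlap_fraction, paired_comparison, segment_puncta,
                     simulate_puncta_image)
from synprox.colocalization import flip_reference
from synprox.segmentation import label_mask

from _oracles import wilcoxon_exact_two_sided
from conftest import SMALL_IMG


def make_set(mask, px=0.05):
    return label_mask(np.asarray(mask, bool), px)


def square_mask(shape, boxes):
    m = np.zeros(shape, bool)
    for r0, c0, size in boxes:
        m[r0:r0 + size, c0:c0 + size] = True
    return m


@pytest.fixture
def four_ref_three_overlap():
    shape = (64, 64)
    ref = square_mask(shape, [(5, 5, 4), (5, 40, 4), (40, 5, 4), (40, 40, 4)])
    # candidate disks overlap exactly three of the four reference squares
    cand = square_mask(shape, [(6, 6, 4), (6, 41, 4), (41, 6, 4), (20, 20, 4)])
    return make_set(ref), make_set(cand)


def test_identity_candidate_gives_100_percent():
    m = square_mask((32, 32), [(4, 4, 3), (20, 20, 3)])
    ref = make_set(m)
    roi = full_image_roi(m.shape, 0.05)
    res = overlap_fraction(ref, make_set(m), roi)
    assert res.percent == 100.0


def test_empty_candidate_gives_0_percent():
    ref = make_set(square_mask((32, 32), [(4, 4, 3)]))
    cand = make_set(np.zeros((32, 32), bool))
    res = overlap_fraction(ref, cand, full_image_roi((32, 32), 0.05))
    assert res.percent == 0.0 and res.n_ref_puncta == 1


def test_three_of_four_reference_overlap(four_ref_three_overlap):
    ref, cand = four_ref_three_overlap
    res = overlap_fraction(ref, cand, full_image_roi((64, 64), 0.05))
    assert res.n_ref_puncta == 4
    assert res.n_ref_overlapping == 3
    assert res.percent == pytest.approx(75.0)


def test_zero_reference_puncta_flagged_undefined():
    ref = make_set(np.zeros((32, 32), bool))
    cand = make_set(square_mask((32, 32), [(4, 4, 3)]))
    res = overlap_fraction(ref, cand, full_image_roi((32, 32), 0.05))
    assert res.undefined and np.isnan(res.percent)


def test_overlap_rules_differ_on_partial_overlap():
    shape = (32, 32)
    ref = make_set(square_mask(shape, [(10, 10, 6)]))
    cand = make_set(square_mask(shape, [(10, 15, 6)]))  # 6 shared columns? 1 col x 6 rows
    roi = full_image_roi(shape, 0.05)
    any_px = overlap_fraction(ref, cand, roi, ColocConfig(overlap_rule="any_pixel"))
    assert any_px.percent == 100.0
    k_big = overlap_fraction(ref, cand, roi, ColocConfig(
        overlap_rule="min_overlap_px", min_overlap_k=20))
    assert k_big.percent == 0.0
    centroid = overlap_fraction(ref, cand, roi, ColocConfig(
        overlap_rule="centroid_in_candidate"))
    assert centroid.percent == 0.0  # ref centroid at col 12.5, cand starts at 15


def test_size_criterion_excludes_large_candidates():
    shape = (64, 64)
    ref = make_set(square_mask(shape, [(10, 10, 4)]))
    cand = make_set(square_mask(shape, [(8, 8, 20)]))  # 400 px blob
    roi = full_image_roi(shape, 0.05)
    res = overlap_fraction(ref, cand, roi, ColocConfig(size_criterion_px2=100))
    assert res.percent == 0.0
    res2 = overlap_fraction(ref, cand, roi, ColocConfig(size_criterion_px2=None))
    assert res2.percent == 100.0


def test_flip_is_involution(four_ref_three_overlap):
    ref, cand = four_ref_three_overlap
    roi = full_image_roi((64, 64), 0.05)
    double = flip_reference(flip_reference(ref))
    orig = overlap_fraction(ref, cand, roi)
    back = overlap_fraction(double, cand, roi)
    assert back.percent == orig.percent
    assert back.n_ref_puncta == orig.n_ref_puncta


def test_mirror_symmetric_candidate_equalizes_flip():
    shape = (64, 64)
    ref = make_set(square_mask(shape, [(10, 4, 4), (30, 50, 4)]))
    sym = square_mask(shape, [(10, 4, 4)])
    sym |= sym[:, ::-1]  # mirror-symmetric candidate mask
    cand = make_set(sym)
    roi = full_image_roi(shape, 0.05)
    orig = overlap_fraction(ref, cand, roi)
    flip = flipped_control(ref, cand, roi)
    assert flip.percent == orig.percent


def test_flip_breaks_true_colocalization(small_image, seg_config):
    _, stack, _ = small_image
    ref = segment_puncta(stack, 0, seg_config)
    cand = segment_puncta(stack, 1, seg_config)
    roi = full_image_roi(stack.shape_yx, stack.pixel_size_um)
    res = coloc_with_flip(ref, cand, roi)
    assert res["pct_original"] > res["pct_flipped"] + 10


def test_chance_overlap_trivial_bounds():
    shape = (64, 64)
    ref = make_set(square_mask(shape, [(10, 10, 4), (40, 40, 4)]))
    empty = make_set(np.zeros(shape, bool))
    out = expected_chance_overlap(ref, empty, n_translations=50)
    assert out["analytic_percent"] == 0.0 and out["mc_percent"] == 0.0
    full = make_set(np.ones(shape, bool))
    out2 = expected_chance_overlap(ref, full,
                                   ColocConfig(size_criterion_px2=None),
                                   n_translations=50)
    assert out2["mc_percent"] == 100.0
    assert out2["analytic_percent"] > 95.0


def test_chance_estimators_cross_validate(seg_config):
    """Boolean-model analytic chance agrees with the Monte-Carlo toroidal
    translation estimate on a random (unplanted) scene."""
    cfg = ImageSimConfig(seed=21, coloc_fraction=0.0, **SMALL_IMG)
    stack, _ = simulate_puncta_image(cfg)
    ref = segment_puncta(stack, 0, seg_config)
    cand = segment_puncta(stack, 1, seg_config)
    out = expected_chance_overlap(ref, cand, n_translations=400, seed=3)
    # analytic Boolean approximation within 3 MC SE + model slack
    assert abs(out["analytic_percent"] - out["mc_percent"]) < \
        3 * out["mc_se"] + 0.15 * out["mc_percent"]


def test_flipped_matches_chance_level(seg_config):
    """The flip null sits at the random-overlap chance level."""
    cfg = ImageSimConfig(seed=33, coloc_fraction=0.6, **SMALL_IMG)
    stack, _ = simulate_puncta_image(cfg)
    ref = segment_puncta(stack, 0, seg_config)
    cand = segment_puncta(stack, 1, seg_config)
    roi = full_image_roi(stack.shape_yx, stack.pixel_size_um)
    res = coloc_with_flip(ref, cand, roi)
    chance = expected_chance_overlap(ref, cand, n_translations=500, seed=1)
    n_ref = res["n_ref"]
    # binomial SE of the flipped percentage around the chance level
    p = chance["mc_percent"] / 100
    se = 100 * np.sqrt(p * (1 - p) / n_ref)
    assert abs(res["pct_flipped"] - chance["mc_percent"]) < 3 * se + 1.0
    assert res["pct_original"] > chance["mc_percent"] + 3 * se


# ------------------------------------------------------------ paired test

def test_all_equal_pairs_degenerate_p1():
    pairs = [(10.0, 10.0)] * 6
    res = paired_comparison(pairs)
    assert res.degenerate and res.p_value == 1.0


def test_all_positive_differences_wilcoxon_exact_p():
    """Non-normal, strictly positive differences at n=10: the two-tailed
    signed-rank p equals the exact enumeration value 2/1024."""
    rng = np.random.default_rng(0)
    # heavy-tailed positive differences fail normality
    diffs = np.abs(rng.standard_cauchy(10)) + 0.1
    flip = rng.uniform(5, 15, 10)
    pairs = np.column_stack([flip + diffs, flip])
    res = paired_comparison(pairs)
    assert res.test_name == "wilcoxon_signed_rank"
    assert res.p_value == pytest.approx(2 / 1024)
    assert res.p_value == pytest.approx(wilcoxon_exact_two_sided(diffs))


def test_normal_differences_take_paired_t():
    rng = np.random.default_rng(1)
    flip = rng.uniform(5, 15, 12)
    orig = flip + rng.normal(3.0, 1.0, 12)
    res = paired_comparison(np.column_stack([orig, flip]))
    assert res.test_name == "paired_t"
    assert res.normality_pass
    assert res.p_value < 0.001


def test_small_n_routes_to_wilcoxon():
    pairs = [(10.0, 8.0), (11.0, 9.5), (12.0, 9.0), (9.0, 8.5)]
    res = paired_comparison(pairs)
    assert res.test_name == "wilcoxon_signed_rank"
    with pytest.raises(ValueError):
        paired_comparison(pairs[:2])


def test_null_rejection_rate_calibrated():
    """Original and flipped drawn iid: rejection rate at alpha=0.05 lies
    in [0.035, 0.065] over 2000 replicates."""
    rng = np.random.default_rng(99)
    rejections = 0
    n_rep = 2000
    for _ in range(n_rep):
        orig = rng.normal(10, 3, 10)
        flip = rng.normal(10, 3, 10)
        res = paired_comparison(np.column_stack([orig, flip]))
        rejections += res.p_value < 0.05
    rate = rejections / n_rep
    assert 0.035 <= rate <= 0.065
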