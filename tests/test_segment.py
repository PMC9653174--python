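"""Segmentation against brute-force thresholding oracles and generator
ground truth."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk
from skimage.filters import threshold_otsu as skimage_otsu

from conftest import make_generator, noise_off
from oatpquant import quantify, segment, simgen
from oatpquant.segment import SegmentationParams


# ---------------------------------------------------------------------------
# Otsu threshold
# ---------------------------------------------------------------------------


def test_otsu_two_equal_masses():
    values, counts = np.array([0.0, 10.0]), np.array([50, 50])
    thr = segment.otsu_threshold((values, counts))
    assert 0.0 <= thr < 10.0
    img = np.repeat(values, counts)
    assert int((img > thr).sum()) == 50


def test_otsu_three_value_histogram_separates_bright_class():
    # brute force over both split points puts the cut between 5 and 100
    thr = segment.otsu_threshold((np.array([0.0, 5.0, 100.0]), np.array([10, 10, 10])))
    img = np.repeat([0.0, 5.0, 100.0], 10)
    assert set(np.unique(img[img > thr])) == {100.0}


def test_otsu_degenerate_histogram_errors():
    with pytest.raises(ValueError, match="degenerate"):
        segment.otsu_threshold((np.array([7.0]), np.array([100])))


@pytest.mark.parametrize("seed", range(8))
def test_otsu_matches_brute_force_oracle_on_8bit(seed, rng=None):
    """Foreground partition equals an exhaustive between-class-variance
    maximizer (via scikit-image) on random 8-bit images."""
    rng = np.random.default_rng(seed)
    img = np.concatenate(
        [rng.integers(0, 90, 500), rng.integers(60, 256, rng.integers(50, 500))]
    ).astype(float)
    ours = segment.otsu_threshold(img)
    ref = skimage_otsu(img.astype(np.uint8), nbins=256)
    assert np.array_equal(img > ours, img > ref)


def test_threshold_monotonicity(rng):
    img = rng.uniform(0, 100, size=(64, 64))
    lo = int((img > 30.0).sum())
    hi = int((img > 60.0).sum())
    assert hi <= lo


# ---------------------------------------------------------------------------
# tissue mask
# ---------------------------------------------------------------------------


def test_tissue_mask_blank_image_is_empty():
    channels = {"a": np.full((64, 64), 100.0), "b": np.full((64, 64), 100.0)}
    assert not segment.tissue_mask(channels, SegmentationParams()).any()


def test_tissue_mask_half_frame_recovers_covered_area():
    rng = np.random.default_rng(0)
    img = np.full((128, 128), 100.0) + rng.normal(0, 5, (128, 128))
    img[:, :64] = 800.0 + rng.normal(0, 5, (128, 64))
    mask = segment.tissue_mask({"oatp": img}, SegmentationParams())
    assert mask.sum() == pytest.approx(128 * 64, rel=0.02)


def test_tissue_mask_union_over_channels_covers_full_frame():
    rng = np.random.default_rng(1)
    shape = (96, 96)
    a = np.full(shape, 100.0) + rng.normal(0, 5, shape)
    b = np.full(shape, 100.0) + rng.normal(0, 5, shape)
    a[:, :60] = 900.0 + rng.normal(0, 5, (96, 60))  # left 62% bright in one channel
    b[:, 40:] = 900.0 + rng.normal(0, 5, (96, 56))  # right 58% in the other; union = full frame
    mask = segment.tissue_mask({"a": a, "b": b}, SegmentationParams())
    assert mask.mean() >= 0.99


def test_tissue_mask_empty_image_errors():
    with pytest.raises(ValueError):
        segment.tissue_mask({"a": np.zeros((0, 0))}, SegmentationParams())


# ---------------------------------------------------------------------------
# nuclei
# ---------------------------------------------------------------------------


def test_nuclei_blank_raster_yields_zero_objects():
    assert segment.segment_nuclei(np.full((64, 64), 7.0), SegmentationParams()).max() == 0


def test_nuclei_count_matches_ground_truth_at_low_noise():
    cfg = make_generator(
        image_shape=(256, 256),
        cell_densities={"myeloid": 3000.0, "astrocyte_tumor": 0.0, "stromal": 0.0},
        vessel_params={"count": 0, "width_px": 8, "tortuosity": 0.25, "rim_px": 2},
        noise={"background_level": 100.0, "gaussian_sd": 5.0, "poisson": False},
    )
    case, truth = simgen.generate_case_image(cfg, "control", 11)
    n = segment.segment_nuclei(case.channels["hoechst"], SegmentationParams()).max()
    assert n == len(truth.objects)


def test_watershed_splits_two_overlapping_disks():
    img = np.zeros((64, 64))
    for center in ((30, 24), (30, 40)):  # overlap well under 30% of radius
        rr, cc = draw_disk(center, 10)
        img[rr, cc] = 1000.0
    params = SegmentationParams(watershed_split=True)
    assert segment.segment_nuclei(img, params).max() == 2
    merged = segment.segment_nuclei(img, SegmentationParams(watershed_split=False))
    assert merged.max() == 1


# ---------------------------------------------------------------------------
# marker objects
# ---------------------------------------------------------------------------


def test_marker_objects_background_channel_yields_none(rng):
    channel = 100.0 + rng.normal(0, 20, (256, 256))
    tissue = np.ones((256, 256), bool)
    assert segment.marker_objects(channel, tissue, SegmentationParams()).max() == 0


def test_marker_object_footprint_matches_ground_truth():
    from scipy import ndimage

    cfg = noise_off(
        make_generator(
            cell_densities={"myeloid": 400.0, "astrocyte_tumor": 0.0, "stromal": 0.0},
            vessel_params={"count": 0, "width_px": 8, "tortuosity": 0.25, "rim_px": 2},
        )
    )
    case, truth = simgen.generate_case_image(cfg, "control", 5)
    assert len(truth.objects) >= 1
    tissue = np.ones(case.shape, bool)
    labs = segment.marker_objects(case.channels["iba1"], tissue, SegmentationParams(), "iba1")
    assert labs.max() == len(truth.objects)
    fp = ndimage.binary_opening(
        truth.labels > 0, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    )
    assert np.array_equal(labs > 0, fp)


def test_area_filter_removes_small_objects():
    channel = np.zeros((64, 64))
    channel[5:9, 5:10] = 100.0  # 20 px
    channel[30:34, 30:35] = 100.0  # 20 px
    params = SegmentationParams(
        threshold_method="fixed",
        fixed_thresholds={"x": 50.0},
        min_object_area=50,
        morphological_cleanup=0,
    )
    labs = segment.marker_objects(channel, np.ones((64, 64), bool), params, "x")
    assert labs.max() == 0
    params.min_object_area = 10
    labs = segment.marker_objects(channel, np.ones((64, 64), bool), params, "x")
    assert labs.max() == 2


def test_otsu_degenerate_falls_back_to_fixed_threshold():
    channel = np.full((32, 32), 5.0)
    params = SegmentationParams(fixed_thresholds={"x": 10.0}, min_object_area=1)
    labs = segment.marker_objects(channel, np.ones((32, 32), bool), params, "x")
    assert labs.max() == 0  # constant channel below the fallback threshold
    with pytest.raises(ValueError):
        segment.marker_objects(channel, np.ones((32, 32), bool), SegmentationParams(), "y")


# ---------------------------------------------------------------------------
# whole-case segmentation
# ---------------------------------------------------------------------------


def match_objects(truth, detected_objects, cell_type):
    """Match ground-truth cells to detected centroids within one radius."""
    gt = truth.objects[truth.objects.type == cell_type]
    cents = np.array([o.centroid for o in detected_objects])
    matched_detected = set()
    n_matched = 0
    for _, row in gt.iterrows():
        radius = np.sqrt(row.area_px / np.pi)
        if len(cents) == 0:
            continue
        d = np.hypot(cents[:, 0] - row.row, cents[:, 1] - row.col)
        hits = np.nonzero(d < radius)[0]
        if len(hits) == 1:
            n_matched += 1
            matched_detected.add(int(hits[0]))
    false_pos = len(detected_objects) - len(matched_detected)
    return len(gt), n_matched, false_pos


def test_myeloid_recall_and_precision_on_default_simulation():
    cfg = simgen.GeneratorConfig(seed=9)
    params = SegmentationParams()
    total = matched = false_pos = 0
    for i in range(3):
        seed = simgen.derive_case_seed(9, "gbm", i)
        case, truth = simgen.generate_case_image(cfg, "gbm", seed, case_id=f"g{i}")
        seg = segment.segment_case(case, params)
        objs = quantify.object_mean_intensities(case.channels, seg.myeloid, case.case_id, "myeloid")
        n_gt, n_match, n_fp = match_objects(truth, objs, "myeloid")
        total += n_gt
        matched += n_match
        false_pos += n_fp
    assert matched / total >= 0.95
    assert false_pos / total <= 0.05


def test_segmentation_result_invariants(default_case):
    case, _truth = default_case
    seg = segment.segment_case(case, SegmentationParams())
    for name, labels in (("myeloid", seg.myeloid), ("vessels", seg.vessels), ("nuclei", seg.nuclei)):
        ids = np.unique(labels)
        ids = ids[ids > 0]
        assert list(ids) == list(range(1, len(ids) + 1)), name
        assert seg.tissue_mask[labels > 0].all(), name
    # vessel priority: myeloid and vessel objects are pixel-disjoint
    assert not np.any((seg.myeloid > 0) & (seg.vessels > 0))
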