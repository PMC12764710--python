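import numpy as np
import pytest

from slicesurv import _dicom
from slicesurv.imaging_io import (
    AugmentConfig,
    CTVolume,
    EmptyMaskWarning,
    LungMask,
    PassthroughSegmenter,
    SliceStack,
    augment_slice,
    crop_roi,
    filter_slices,
    load_ct_volume,
    lung_fraction_per_slice,
    preprocess_volume,
    resample_volume,
    resize_and_normalize,
    save_nifti,
    segment_lungs,
)
from slicesurv.synthetic_cohort import PhantomConfig, generate_phantom


@pytest.fixture(scope="module")
def phantom():
    return generate_phantom(PhantomConfig(seed=3))


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def test_dicom_rescale_identity(tmp_path):
    series = tmp_path / "series"
    series.mkdir()
    pixels = np.full((32, 32), 1024, dtype=np.int16)
    _dicom.write_dicom_slice(series / "s1.dcm", pixels, rescale_slope=1.0,
                             rescale_intercept=-1024.0)
    vol = load_ct_volume(series, format="dicom-series")
    assert vol.voxels.shape == (1, 32, 32)
    assert np.all(vol.voxels == 0.0)  # 1024 * 1 - 1024


def test_dicom_series_sorted_superior_first(tmp_path):
    series = tmp_path / "series"
    series.mkdir()
    # write out of order; z = 0 is most superior and must end up at index 0
    for name, z, value in [("b.dcm", -3.0, 20), ("c.dcm", -6.0, 30), ("a.dcm", 0.0, 10)]:
        _dicom.write_dicom_slice(series / name, np.full((16, 16), value, np.int16),
                                 image_position=(0, 0, z), rescale_intercept=0.0)
    vol = load_ct_volume(series)
    assert vol.voxels[:, 0, 0].tolist() == [10.0, 20.0, 30.0]
    assert vol.spacing[2] == pytest.approx(3.0)


def test_dicom_missing_slice_detected(tmp_path):
    series = tmp_path / "series"
    series.mkdir()
    for z in (0.0, -3.0, -9.0):  # -6 missing
        _dicom.write_dicom_slice(series / f"z{abs(z)}.dcm", np.zeros((8, 8), np.int16),
                                 image_position=(0, 0, z))
    with pytest.raises(ValueError, match="missing slice"):
        load_ct_volume(series)


def test_dicom_inconsistent_geometry(tmp_path):
    series = tmp_path / "series"
    series.mkdir()
    _dicom.write_dicom_slice(series / "a.dcm", np.zeros((8, 8), np.int16),
                             image_position=(0, 0, 0.0))
    _dicom.write_dicom_slice(series / "b.dcm", np.zeros((16, 16), np.int16),
                             image_position=(0, 0, -3.0))
    with pytest.raises(ValueError, match="geometry"):
        load_ct_volume(series)


def test_nifti_round_trip(tmp_path, phantom):
    vol, _, _ = phantom
    path = save_nifti(vol, tmp_path / "phantom.nii.gz")
    back = load_ct_volume(path, format="nifti")
    assert back.spacing == pytest.approx(vol.spacing)
    assert np.abs(back.voxels - vol.voxels).max() < 1e-3  # float32 storage


def test_missing_path_raises():
    with pytest.raises(FileNotFoundError):
        load_ct_volume("/nonexistent/file.nii")


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def test_resample_identity_spacing():
    vol = CTVolume(np.random.default_rng(0).normal(size=(10, 20, 20)), (1, 1, 3))
    out = resample_volume(vol, (1, 1, 3))
    assert out.voxels.shape == vol.voxels.shape
    assert np.abs(out.voxels - vol.voxels).max() < 1e-9


def test_resample_shape_arithmetic():
    # 400 x 400 x 80 at (0.8, 0.8, 3.0) -> 320 x 320 x 80 at (1, 1, 3)
    vol = CTVolume(np.zeros((80, 400, 400)), (0.8, 0.8, 3.0))
    out = resample_volume(vol, (1, 1, 3))
    assert out.voxels.shape == (80, 320, 320)
    assert out.spacing == (1.0, 1.0, 3.0)


def test_resample_preserves_constants():
    vol = CTVolume(np.full((12, 40, 40), 37.5), (0.7, 0.7, 2.0))
    out = resample_volume(vol, (1, 1, 3))
    assert np.abs(out.voxels - 37.5).max() < 1e-9


def test_resample_rejects_bad_spacing():
    vol = CTVolume(np.zeros((8, 8, 8)), (1, 1, 1))
    with pytest.raises(ValueError):
        resample_volume(vol, (0, 1, 3))


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def test_segment_phantom_against_ground_truth(phantom):
    vol, gt, _ = phantom
    mask = segment_lungs(vol)
    covered = (mask.mask & gt.mask).sum() / gt.mask.sum()
    leaked = ((mask.mask == 1) & (gt.mask == 0)).sum() / (gt.mask == 0).sum()
    assert covered >= 0.95
    assert leaked <= 0.01


def test_segment_all_air_is_empty():
    vol = CTVolume(np.full((33, 33, 33), -1000.0), (1, 1, 1))
    with pytest.warns(EmptyMaskWarning):
        mask = segment_lungs(vol)
    assert mask.is_empty


def test_passthrough_segmenter_identity(phantom):
    vol, gt, _ = phantom
    out = segment_lungs(vol, PassthroughSegmenter(gt))
    assert np.array_equal(out.mask, gt.mask)


# ---------------------------------------------------------------------------
# slice filtering and cropping
# ---------------------------------------------------------------------------

def test_lung_fraction_extremes():
    m = np.zeros((3, 10, 10), dtype=np.uint8)
    m[1] = 1
    frac = lung_fraction_per_slice(LungMask(m))
    assert frac.tolist() == [0.0, 1.0, 0.0]


def test_lung_fraction_count_arithmetic():
    m = np.zeros((1, 224, 224), dtype=np.uint8)
    m.reshape(1, -1)[0, :5018] = 1
    frac = lung_fraction_per_slice(LungMask(m))
    assert frac[0] == pytest.approx(5018 / 50176)


def _vol_mask_from_fractions(fractions):
    n = len(fractions)
    mask = np.zeros((n, 40, 50), dtype=np.uint8)  # 2000 px so 0.015 etc. are exact
    for i, f in enumerate(fractions):
        mask[i].reshape(-1)[: int(round(f * 2000))] = 1
    vol = CTVolume(np.zeros((n, 40, 50)), (1, 1, 3))
    return vol, LungMask(mask)


def test_filter_slices_threshold_rule():
    vol, mask = _vol_mask_from_fractions([0.0, 0.01, 0.05, 0.30, 0.015])
    assert filter_slices(vol, mask) == [2, 3]


def test_filter_slices_boundary_kept():
    vol, mask = _vol_mask_from_fractions([0.02, 0.5])
    assert filter_slices(vol, mask) == [0, 1]


def test_filter_slices_all_above():
    vol, mask = _vol_mask_from_fractions([0.5, 0.9, 0.3])
    assert filter_slices(vol, mask) == [0, 1, 2]


def test_filter_slices_trim_ends_keeps_interior_gap():
    vol, mask = _vol_mask_from_fractions([0.0, 0.5, 0.01, 0.5, 0.0])
    assert filter_slices(vol, mask, mode="all") == [1, 3]
    assert filter_slices(vol, mask, mode="trim_ends") == [1, 2, 3]


def test_filter_slices_none_retained_names_patient():
    vol, mask = _vol_mask_from_fractions([0.0, 0.01])
    vol.patient_id = "P42"
    with pytest.raises(ValueError, match="P42"):
        filter_slices(vol, mask)


def test_filter_monotone_in_threshold():
    rng = np.random.default_rng(5)
    vol, mask = _vol_mask_from_fractions(rng.uniform(0, 0.5, size=20))
    counts = [len(filter_slices(vol, mask, min_fraction=t))
              for t in (0.01, 0.05, 0.1, 0.2)]
    assert counts == sorted(counts, reverse=True)


def test_crop_roi_bounding_box_arithmetic():
    mask = np.zeros((4, 100, 100), dtype=np.uint8)
    mask[:, 10:51, 20:81] = 1  # rows 10-50, cols 20-80 inclusive
    vol = CTVolume(np.zeros((4, 100, 100)), (1, 1, 3))
    out = crop_roi(vol, LungMask(mask), [0, 1, 2, 3])
    assert out.voxels.shape == (4, 41, 61)


def test_crop_roi_full_plane_identity():
    vol = CTVolume(np.zeros((3, 20, 20)), (1, 1, 3))
    mask = LungMask(np.ones((3, 20, 20), dtype=np.uint8))
    out = crop_roi(vol, mask, [0, 1, 2])
    assert out.voxels.shape == (3, 20, 20)


def test_crop_roi_union_of_boxes():
    mask = np.zeros((2, 50, 50), dtype=np.uint8)
    mask[0, 10:21, 5:11] = 1
    mask[1, 30:41, 5:11] = 1
    vol = CTVolume(np.zeros((2, 50, 50)), (1, 1, 3))
    out = crop_roi(vol, LungMask(mask), [0, 1])
    assert out.voxels.shape == (2, 31, 6)  # rows 10-40 union


def test_crop_roi_never_discards_masked_voxels(phantom):
    vol, gt, _ = phantom
    retained = filter_slices(vol, gt)
    sub = gt.mask[retained]
    rows = np.nonzero(sub.any(axis=(0, 2)))[0]
    cols = np.nonzero(sub.any(axis=(0, 1)))[0]
    cropped = crop_roi(vol, gt, retained)
    assert cropped.voxels.shape[1] == rows[-1] - rows[0] + 1
    assert cropped.voxels.shape[2] == cols[-1] - cols[0] + 1
    # every masked voxel of retained slices is inside the crop window
    assert sub[:, : rows[0], :].sum() == 0 and sub[:, rows[-1] + 1 :, :].sum() == 0


def test_crop_roi_empty_mask_raises():
    vol = CTVolume(np.zeros((2, 10, 10)), (1, 1, 3))
    mask = LungMask(np.zeros((2, 10, 10), dtype=np.uint8))
    with pytest.raises(ValueError):
        crop_roi(vol, mask, [0, 1])


# ---------------------------------------------------------------------------
# resize / normalize
# ---------------------------------------------------------------------------

def test_resize_constant_slice():
    vol = CTVolume(np.full((1, 33, 47), -300.0), (1, 1, 3))
    stack = resize_and_normalize(vol, out_size=32)
    expected = (-300 + 1000) / 1400
    assert stack.slices[0].shape == (32, 32)
    assert np.abs(stack.slices[0] - expected).max() < 1e-9


def test_window_endpoints():
    vol = CTVolume(np.stack([np.full((16, 16), -1000.0), np.full((16, 16), 400.0),
                             np.full((16, 16), 9999.0)]), (1, 1, 3))
    stack = resize_and_normalize(vol, out_size=16)
    assert np.all(stack.slices[0] == 0.0)
    assert np.all(stack.slices[1] == 1.0)
    assert np.all(stack.slices[2] == 1.0)  # clipped


def test_relative_positions_five_slices():
    vol = CTVolume(np.zeros((5, 16, 16)), (1, 1, 3))
    stack = resize_and_normalize(vol, out_size=16)
    assert stack.relative_positions.tolist() == [0, 0.25, 0.5, 0.75, 1]


def test_relative_position_single_slice():
    vol = CTVolume(np.zeros((1, 16, 16)), (1, 1, 3))
    stack = resize_and_normalize(vol, out_size=16)
    assert stack.relative_positions.tolist() == [0.0]


def test_resize_output_in_unit_interval(phantom):
    vol, _, _ = phantom
    stack = resize_and_normalize(vol, out_size=32)
    for s in stack.slices:
        assert s.min() >= 0.0 and s.max() <= 1.0


def test_resize_rejects_tiny_output():
    vol = CTVolume(np.zeros((1, 16, 16)), (1, 1, 3))
    with pytest.raises(ValueError):
        resize_and_normalize(vol, out_size=4)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def test_augment_probability_zero_is_identity(rng):
    s = rng.random((32, 32))
    cfg = AugmentConfig(apply_probability=0.0)
    assert np.array_equal(augment_slice(s, cfg, rng), s)


def test_augment_deterministic_under_seed(rng):
    s = rng.random((32, 32))
    cfg = AugmentConfig(apply_probability=1.0)
    a = augment_slice(s, cfg, np.random.default_rng(7))
    b = augment_slice(s, cfg, np.random.default_rng(7))
    assert np.array_equal(a, b)


def test_augment_zero_rotation_identity(rng):
    s = rng.random((32, 32))
    cfg = AugmentConfig(apply_probability=1.0, flip_probability=0.0,
                        rotation_range_degrees=0.0)
    assert np.abs(augment_slice(s, cfg, np.random.default_rng(0)) - s).max() < 1e-12


def test_augment_config_validation():
    with pytest.raises(ValueError):
        AugmentConfig(apply_probability=1.5)
    with pytest.raises(ValueError):
        AugmentConfig(rotation_range_degrees=-1)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def test_pipeline_deterministic(phantom):
    vol, _, _ = phantom
    s1, m1 = preprocess_volume(vol, out_size=32)
    s2, m2 = preprocess_volume(vol, out_size=32)
    assert m1 == m2
    assert all(np.array_equal(a, b) for a, b in zip(s1.slices, s2.slices))


def test_pipeline_retains_lesion_slices(phantom):
    vol, _, lesion = phantom
    stack, meta = preprocess_volume(vol, out_size=32)
    retained = set(meta["retained_indices"])
    kept = len(lesion & retained) / len(lesion)
    assert kept >= 0.95


def test_lesion_relative_depth_maps_through_pipeline():
    cfg = PhantomConfig(lesion_relative_depth=0.75, seed=1)
    vol, _, lesion = generate_phantom(cfg)
    stack, meta = preprocess_volume(vol, out_size=32)
    src = stack.source_indices
    pos = stack.relative_positions
    lesion_pos = pos[np.isin(src, list(lesion))]
    assert abs(np.median(lesion_pos) - 0.75) <= 1.5 / (stack.R - 1) + 0.05


def test_slice_stack_invariants():
    with pytest.raises(ValueError, match="shape"):
        SliceStack(slices=[np.zeros((4, 4)), np.zeros((5, 5))],
                   relative_positions=[0, 1], source_indices=[0, 1])
    with pytest.raises(ValueError, match="span"):
        SliceStack(slices=[np.zeros((4, 4)), np.zeros((4, 4))],
                   relative_positions=[0.2, 0.8], source_indices=[0, 1])
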