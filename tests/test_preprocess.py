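"""Preprocessing: z-score, resize, joint augmentation, subject-wise split."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glioseg import (AugmentationParams, SplitSpec, augment_pair, resize_image,
                     stratified_subject_split, zscore_normalize)
from glioseg.errors import (DegenerateInputError, ManifestValidationError,
                            StratificationError)


# -- z-score ----------------------------------------------------------------


def test_zscore_known_values():
    out, params = zscore_normalize(np.array([1.0, 2.0, 3.0, 4.0]))
    np.testing.assert_allclose(out, [-1.3416, -0.4472, 0.4472, 1.3416], atol=1e-4)
    assert params.mu == 2.5
    np.testing.assert_allclose(params.sigma, np.sqrt(1.25))


def test_zscore_output_standardized_and_idempotent():
    rng = np.random.default_rng(0)
    img = rng.normal(2.0, 3.0, size=(32, 32))
    out, _ = zscore_normalize(img)
    assert abs(out.mean()) < 1e-6 and abs(out.std() - 1.0) < 1e-6
    again, _ = zscore_normalize(out)
    np.testing.assert_allclose(again, out, atol=1e-6)


def test_zscore_constant_image_raises():
    with pytest.raises(DegenerateInputError):
        zscore_normalize(np.full((8, 8), 3.0))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(a=st.floats(0.1, 50.0), b=st.floats(-100.0, 100.0), seed=st.integers(0, 2 ** 16))
def test_zscore_affine_equivariance(a, b, seed):
    """zscore(a*X + b) == zscore(X) for a > 0."""
    img = np.random.default_rng(seed).normal(size=(8, 8))
    base, _ = zscore_normalize(img)
    scaled, _ = zscore_normalize(a * img + b)
    np.testing.assert_allclose(scaled, base, atol=1e-6)


# -- resize -------------------------------------------------------------------


def test_resize_identity_and_constant():
    img = np.random.default_rng(1).normal(size=(16, 16))
    np.testing.assert_array_equal(resize_image(img, 16), img)
    const = np.full((16, 16), 4.2)
    out = resize_image(const, 32)
    np.testing.assert_allclose(out, 4.2, atol=1e-12)


def test_resize_bilinear_block_mean_oracle():
    """2x downsampling of 2x2 blocks lands on each block's mean."""
    img = np.array([[1.0, 3.0, 5.0, 7.0],
                    [3.0, 5.0, 7.0, 9.0],
                    [2.0, 2.0, 8.0, 8.0],
                    [4.0, 4.0, 6.0, 6.0]])
    expected = np.array([[3.0, 7.0], [3.0, 7.0]])
    np.testing.assert_allclose(resize_image(img, 2), expected, atol=1e-12)


def test_resize_mask_stays_binary():
    mask = np.zeros((16, 16), dtype=np.uint8)
    mask[4:10, 5:12] = 1
    out = resize_image(mask, 24, is_mask=True)
    assert out.shape == (24, 24)
    assert set(np.unique(out)).issubset({0, 1})


def test_resize_rejects_nonpositive_target():
    with pytest.raises(ValueError):
        resize_image(np.zeros((16, 16)), 0)
    with pytest.raises(ValueError):
        resize_image(np.zeros((16, 16)), -3)


# -- augmentation -------------------------------------------------------------


def _identity_params(seed=0):
    return AugmentationParams(rotation_deg_max=0.0, translate_px_max=0.0,
                              hflip=False, vflip=False, seed=seed)


def test_augment_identity_params_is_noop():
    rng = np.random.default_rng(2)
    img = rng.normal(size=(16, 16))
    mask = (rng.random((16, 16)) > 0.8).astype(np.uint8)
    out_img, out_mask = augment_pair(img, mask, _identity_params(), 0)
    np.testing.assert_allclose(out_img, img, atol=1e-12)
    np.testing.assert_array_equal(out_mask, mask)


def test_hflip_is_involution():
    from glioseg.preprocess import _apply_geometric

    img = np.random.default_rng(3).normal(size=(9, 9))
    once = _apply_geometric(img, 0.0, (0.0, 0.0), True, False, order=1)
    twice = _apply_geometric(once, 0.0, (0.0, 0.0), True, False, order=1)
    np.testing.assert_allclose(twice, img, atol=1e-12)


def test_translation_moves_pixel_exactly():
    from glioseg.preprocess import _apply_geometric

    mask = np.zeros((11, 11))
    mask[5, 4] = 1.0
    out = _apply_geometric(mask, 0.0, (3.0, 0.0), False, False, order=0)
    assert out[5, 7] == 1.0 and out.sum() == 1.0


def test_augment_deterministic_and_mask_binary():
    params = AugmentationParams(seed=42)
    rng = np.random.default_rng(4)
    img = rng.normal(size=(32, 32))
    mask = np.zeros((32, 32), dtype=np.uint8)
    mask[10:20, 12:22] = 1
    a_img, a_mask = augment_pair(img, mask, params, draw_index=7)
    b_img, b_mask = augment_pair(img, mask, params, draw_index=7)
    np.testing.assert_array_equal(a_img, b_img)
    np.testing.assert_array_equal(a_mask, b_mask)
    assert set(np.unique(a_mask)).issubset({0, 1})
    c_img, _ = augment_pair(img, mask, params, draw_index=8)
    assert not np.array_equal(a_img, c_img)


def test_flip_translation_preserve_interior_mask_area():
    """Flips and pure translations keep the positive-pixel count of a mask
    that stays inside the frame."""
    params = AugmentationParams(rotation_deg_max=0.0, translate_px_max=4.0,
                                hflip=True, vflip=True, seed=9)
    mask = np.zeros((32, 32), dtype=np.uint8)
    mask[12:18, 14:20] = 1
    img = np.zeros((32, 32))
    for draw in range(20):
        _, out = augment_pair(img, mask, params, draw)
        assert out.sum() == mask.sum()


def test_augment_shape_mismatch_raises():
    with pytest.raises(ValueError):
        augment_pair(np.zeros((8, 8)), np.zeros((9, 9)), _identity_params(), 0)


# -- split ---------------------------------------------------------------------


def _manifest(n_tumor, n_non, slices=2):
    rows = []
    for i in range(n_tumor + n_non):
        label = "tumor" if i < n_tumor else "non_tumor"
        for j in range(slices):
            rows.append({"path": f"s{i}_{j}.png", "mask_path": "",
                         "subject_id": f"subj{i:03d}", "label": label})
    return pd.DataFrame(rows)


def test_split_allocation_10_subjects():
    split = stratified_subject_split(_manifest(5, 5), SplitSpec(fractions=(0.6, 0.2, 0.2)))
    sizes = {k: getattr(split, k)["subject_id"].nunique() for k in ("train", "val", "test")}
    assert sizes == {"train": 6, "val": 2, "test": 2}
    for part in ("train", "val", "test"):
        assert set(getattr(split, part)["label"]) == {"tumor", "non_tumor"}


def test_split_deterministic_files(tmp_path):
    man = _manifest(6, 6)
    spec = SplitSpec(seed=42)
    stratified_subject_split(man, spec).to_csv(tmp_path / "a")
    stratified_subject_split(man, spec).to_csv(tmp_path / "b")
    for name in ("train", "val", "test"):
        assert ((tmp_path / "a" / f"{name}.csv").read_bytes()
                == (tmp_path / "b" / f"{name}.csv").read_bytes())


def test_split_subject_disjoint_over_random_manifests():
    rng = np.random.default_rng(123)
    for trial in range(1000):
        n_t = int(rng.integers(3, 12))
        n_n = int(rng.integers(3, 12))
        man = _manifest(n_t, n_n, slices=1)
        split = stratified_subject_split(man, SplitSpec(seed=int(rng.integers(2 ** 31))))
        parts = [set(getattr(split, k)["subject_id"]) for k in ("train", "val", "test")]
        assert parts[0] | parts[1] | parts[2] == set(man["subject_id"])
        assert not (parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2])


def test_split_fraction_ratios_track_reference_proportions():
    """At subject granularity the default fractions reproduce a
    0.622/0.155/0.223 partition (checked as ratios)."""
    man = _manifest(490, 490, slices=6)  # 980 subjects x 6 slices = 5880 items
    split = stratified_subject_split(man, SplitSpec())
    total = len(man)
    assert abs(len(split.train) / total - 3655 / 5880) < 0.01
    assert abs(len(split.val) / total - 914 / 5880) < 0.01
    assert abs(len(split.test) / total - 1311 / 5880) < 0.01


def test_split_mixed_label_subject_rejected():
    man = _manifest(2, 2)
    man.loc[1, "label"] = "non_tumor"  # second slice of a tumor subject
    with pytest.raises(ManifestValidationError):
        stratified_subject_split(man, SplitSpec())


def test_split_too_few_subjects_per_class():
    with pytest.raises(StratificationError):
        stratified_subject_split(_manifest(2, 5), SplitSpec())
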