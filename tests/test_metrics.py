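"""Metric suite against independent brute-force oracles."""

import numpy as np
import pytest

from glioseg import (ConfusionCounts, auc_roc, dice_coefficient, evaluate_dataset,
                     hd95, jaccard_index, sensitivity_specificity)
from glioseg.errors import UndefinedMetricError


# -- oracles -------------------------------------------------------------------


def pairwise_auc(scores, labels):
    """O(n^2) Mann-Whitney: P(s+ > s-) + 0.5 P(tie)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def boundary_oracle(mask):
    """Positive pixel with >= 1 non-positive 4-neighbour (edges count)."""
    m = np.asarray(mask) > 0
    pts = []
    h, w = m.shape
    for i in range(h):
        for j in range(w):
            if not m[i, j]:
                continue
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if not (0 <= ni < h and 0 <= nj < w) or not m[ni, nj]:
                    pts.append((i, j))
                    break
    return np.array(pts, dtype=float)


def hd95_oracle(x, y):
    bx, by = boundary_oracle(x), boundary_oracle(y)
    d = np.sqrt(((bx[:, None, :] - by[None, :, :]) ** 2).sum(axis=2))
    return max(np.percentile(d.min(axis=1), 95), np.percentile(d.min(axis=0), 95))


def _random_mask(rng, size=16, p=0.25):
    return (rng.random((size, size)) < p).astype(np.uint8)


# -- dice / jaccard --------------------------------------------------------------


def test_dice_jaccard_closed_cases():
    a = np.zeros((4, 4), dtype=int)
    a[:2, :2] = 1
    assert dice_coefficient(a, a) == 1.0
    assert jaccard_index(a, a) == 1.0
    b = np.zeros((4, 4), dtype=int)
    b[2:, 2:] = 1
    assert dice_coefficient(a, b) == 0.0
    # |X| = |Y| = 4, overlap 2
    c = np.zeros((4, 4), dtype=int)
    c[0, :2] = 1
    c[1, :2] = 1
    d = np.zeros((4, 4), dtype=int)
    d[1, :2] = 1
    d[2, :2] = 1
    assert dice_coefficient(c, d) == 0.5
    assert abs(jaccard_index(c, d) - 2 / 6) < 1e-12


def test_both_empty_convention_warns():
    z = np.zeros((3, 3), dtype=int)
    with pytest.warns(UserWarning):
        assert dice_coefficient(z, z) == 1.0
    with pytest.warns(UserWarning):
        assert jaccard_index(z, z) == 1.0


def test_dice_jaccard_match_pixel_counting_oracle():
    rng = np.random.default_rng(0)
    for _ in range(100):
        x, y = _random_mask(rng), _random_mask(rng)
        if x.sum() + y.sum() == 0:
            continue
        inter = int((x & y).sum())
        assert abs(dice_coefficient(x, y) - 2 * inter / (x.sum() + y.sum())) <= 1e-9
        union = int((x | y).sum())
        if union:
            assert abs(jaccard_index(x, y) - inter / union) <= 1e-9
        d, j = dice_coefficient(x, y), jaccard_index(x, y)
        assert j <= d + 1e-12
        if d not in (0.0, 1.0):
            assert j < d
        assert abs(j - d / (2 - d)) < 1e-12


# -- sensitivity / specificity -----------------------------------------------------


def test_sensitivity_specificity_arithmetic():
    assert sensitivity_specificity(ConfusionCounts(tp=9, fp=0, tn=1, fn=1))[0] == 0.9
    sens, spec = sensitivity_specificity(ConfusionCounts(tp=88, fn=12, tn=86, fp=14))
    assert (sens, spec) == (0.88, 0.86)
    with pytest.raises(UndefinedMetricError, match="specificity"):
        sensitivity_specificity(ConfusionCounts(tp=5, fn=1, tn=0, fp=0))
    with pytest.raises(UndefinedMetricError, match="sensitivity"):
        sensitivity_specificity(ConfusionCounts(tp=0, fn=0, tn=5, fp=1))


# -- AUC-ROC -------------------------------------------------------------------------


def test_auc_closed_cases():
    labels = np.array([0, 0, 1, 1])
    assert auc_roc(np.array([0.1, 0.2, 0.8, 0.9]), labels) == 1.0
    assert auc_roc(np.full(4, 0.5), labels) == 0.5


def test_auc_matches_pairwise_oracle():
    rng = np.random.default_rng(1)
    for _ in range(100):
        labels = rng.integers(0, 2, size=20)
        if labels.min() == labels.max():
            continue
        scores = np.round(rng.random(20), 2)  # rounding forces ties
        assert abs(auc_roc(scores, labels) - pairwise_auc(scores, labels)) <= 1e-12


def test_auc_flip_symmetry_and_single_class_error():
    rng = np.random.default_rng(2)
    labels = rng.integers(0, 2, size=30)
    labels[0], labels[1] = 0, 1
    scores = rng.random(30)
    assert abs(auc_roc(1 - scores, labels) - (1 - auc_roc(scores, labels))) < 1e-12
    with pytest.raises(UndefinedMetricError):
        auc_roc(scores, np.ones(30, dtype=int))


# -- HD95 -------------------------------------------------------------------------------


def test_hd95_identity_and_singletons():
    m = np.zeros((10, 10), dtype=int)
    m[3:6, 4:7] = 1
    assert hd95(m, m) == 0.0
    a = np.zeros((10, 10), dtype=int)
    b = np.zeros((10, 10), dtype=int)
    a[2, 2], b[2, 7] = 1, 1
    assert hd95(a, b) == 5.0


def test_hd95_empty_mask_undefined():
    m = np.zeros((5, 5), dtype=int)
    n = m.copy()
    n[2, 2] = 1
    with pytest.raises(UndefinedMetricError):
        hd95(m, n)


def test_hd95_matches_brute_force_oracle():
    rng = np.random.default_rng(3)
    checked = 0
    while checked < 50:
        x, y = _random_mask(rng, p=0.3), _random_mask(rng, p=0.3)
        if x.sum() == 0 or y.sum() == 0:
            continue
        assert abs(hd95(x, y) - hd95_oracle(x, y)) <= 1e-9
        checked += 1


def test_hd95_symmetric_translation_invariant_with_spacing():
    rng = np.random.default_rng(4)
    x = np.zeros((20, 20), dtype=int)
    y = np.zeros((20, 20), dtype=int)
    x[5:9, 5:9] = 1
    y[6:11, 7:10] = 1
    assert hd95(x, y) == hd95(y, x)
    assert hd95(x, y) >= 0.0
    # joint translation of interior masks leaves the distance unchanged
    assert abs(hd95(np.roll(x, (3, 2), (0, 1)), np.roll(y, (3, 2), (0, 1)))
               - hd95(x, y)) < 1e-12
    # anisotropic spacing scales coordinates
    assert abs(hd95(x, y, spacing=(2.0, 2.0)) - 2.0 * hd95(x, y)) < 1e-12


# -- dataset-level ------------------------------------------------------------------------


def test_evaluate_dataset_perfect_prediction():
    m = np.zeros((8, 8), dtype=int)
    m[2:5, 2:5] = 1
    report = evaluate_dataset([m], [m])
    assert report.dice == 1.0 and report.jaccard == 1.0 and report.hd95 == 0.0
    assert report.n_samples == 1 and report.hd95_undefined == 0


def test_evaluate_dataset_macro_equals_mean_of_per_sample():
    rng = np.random.default_rng(5)
    preds, truths = [], []
    for _ in range(10):
        preds.append(_random_mask(rng))
        truths.append(_random_mask(rng))
    report = evaluate_dataset(preds, truths)
    per_sample = [dice_coefficient(p, t) for p, t in zip(preds, truths)]
    assert abs(report.dice - np.mean(per_sample)) < 1e-12
    np.testing.assert_allclose(report.extras["per_sample_dice"], per_sample)


def test_evaluate_dataset_empty_prediction_convention():
    truth = np.zeros((8, 8), dtype=int)
    truth[2:4, 2:4] = 1
    empty = np.zeros((8, 8), dtype=int)
    report = evaluate_dataset([empty], [truth])
    assert report.dice == 0.0
    assert report.hd95 is None and report.hd95_undefined == 1


def test_evaluate_dataset_misaligned_raises():
    with pytest.raises(ValueError):
        evaluate_dataset([np.zeros((4, 4))], [])


def test_report_serialization(tmp_path):
    m = np.zeros((8, 8), dtype=int)
    m[1:3, 1:3] = 1
    report = evaluate_dataset([m], [m], class_scores=[0.9, 0.2], class_labels=[1, 0])
    report.to_json(tmp_path / "r.json")
    report.to_csv_row(tmp_path / "r.csv")
    import json

    loaded = json.loads((tmp_path / "r.json").read_text())
    assert loaded["dice"] == 1.0
    header = (tmp_path / "r.csv").read_text().splitlines()[0]
    assert header == "dice,jaccard,sensitivity,specificity,hd95"
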