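"""Preprocessing: z-score normalization, resizing, joint image/mask
augmentation, and subject-wise stratified splitting.

Conventions (fixed so geometric tests are exact): arrays are row-major with
pixel centers at integer (row, col) coordinates; rotations are about the image
center with constant-zero padding; translations are given as ``(dx, dy)`` where
``dx`` shifts columns (+x = right) and ``dy`` shifts rows (+y = down); images
are interpolated bilinearly and masks with nearest-neighbour so they stay
binary.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .errors import ConfigError, DegenerateInputError, ManifestValidationError, StratificationError

__all__ = [
    "NormalizationParams", "AugmentationParams", "SplitSpec", "Split",
    "zscore_normalize", "resize_image", "augment_pair", "stratified_subject_split",
]


@dataclass(frozen=True)
class NormalizationParams:
    mu: float
    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise DegenerateInputError("sigma must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class AugmentationParams:
    rotation_deg_max: float = 10.0
    translate_px_max: float = 5.0
    hflip: bool = True
    vflip: bool = True
    seed: int = 42

    def __post_init__(self):
        if self.rotation_deg_max < 0 or self.translate_px_max < 0:
            raise ConfigError("augmentation magnitudes must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# default fractions mirror a 3655/914/1311 three-way split of 5880 items
_DEFAULT_FRACTIONS = (3655 / 5880, 914 / 5880, 1311 / 5880)


@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple[float, float, float] = _DEFAULT_FRACTIONS
    seed: int = 42
    stratify_on: str = "label"

    def __post_init__(self):
        if len(self.fractions) != 3 or any(f <= 0 for f in self.fractions):
            raise ConfigError("need three positive split fractions")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ConfigError("split fractions must sum to 1")


@dataclass
class Split:
    train: pd.DataFrame
    val: pd.DataFrame
    test: pd.DataFrame

    def to_csv(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("train", "val", "test"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# intensity
# ---------------------------------------------------------------------------


def zscore_normalize(image: np.ndarray) -> tuple[np.ndarray, NormalizationParams]:
    """Standardize to zero mean, unit (population) standard deviation."""
    image = np.asarray(image, dtype=np.float64)
    mu = float(image.mean())
    sigma = float(image.std())  # population sigma: no Bessel correction
    if sigma == 0.0:
        raise DegenerateInputError("constant image: standard deviation is zero")
    return (image - mu) / sigma, NormalizationParams(mu=mu, sigma=sigma)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def resize_image(image: np.ndarray, target_size: int | tuple[int, int],
                 is_mask: bool = False) -> np.ndarray:
    """Resize to a square (or explicit (rows, cols)) target.

    Bilinear for images, nearest-neighbour for masks.
    """
    if np.isscalar(target_size):
        if target_size < 1:
            raise ValueError("target_size must be positive")
        shape = (int(target_size), int(target_size))
    else:
        shape = (int(target_size[0]), int(target_size[1]))
        if min(shape) < 1:
            raise ValueError("target dimensions must be positive")
    if image.ndim == 3:  # channels-last
        shape = shape + (image.shape[2],)
    if image.shape == shape:
        return image.astype(np.float64, copy=True) if not is_mask else image.copy()
    order = 0 if is_mask else 1
    out = _sk_resize(image.astype(np.float64), shape, order=order,
                     mode="constant", cval=0.0, anti_aliasing=False,
                     preserve_range=True)
    if is_mask:
        out = (out > 0.5).astype(np.uint8)
    return out


def _draw_transform(params: AugmentationParams, draw_index: int):
    rng = np.random.default_rng(
        np.random.SeedSequence(params.seed, spawn_key=(int(draw_index),))
    )
    angle = rng.uniform(-params.rotation_deg_max, params.rotation_deg_max)
    dx = rng.uniform(-params.translate_px_max, params.translate_px_max)
    dy = rng.uniform(-params.translate_px_max, params.translate_px_max)
    do_h = bool(params.hflip and rng.random() < 0.5)
    do_v = bool(params.vflip and rng.random() < 0.5)
    return angle, (dx, dy), do_h, do_v


def _apply_geometric(arr: np.ndarray, angle_deg: float, translate: tuple[float, float],
                     hflip: bool, vflip: bool, order: int) -> np.ndarray:
    out = np.asarray(arr, dtype=np.float64)
    if hflip:
        out = out[:, ::-1]
    if vflip:
        out = out[::-1, :]
    dx, dy = translate
    if angle_deg != 0.0 or dx != 0.0 or dy != 0.0:
        theta = np.deg2rad(angle_deg)
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        center = (np.array(out.shape[:2], dtype=float) - 1.0) / 2.0
        t = np.array([dy, dx])
        # forward map: p_out = R (p_in - c) + c + t; affine_transform needs the
        # inverse, p_in = R^T (p_out - c - t) + c = R^T p_out + offset
        rinv = rot.T
        offset = center - rinv @ (center + t)
        out = ndimage.affine_transform(out, rinv, offset=offset, order=order,
                                       mode="constant", cval=0.0, prefilter=False)
    return out


def augment_pair(image: np.ndarray, mask: np.ndarray, params: AugmentationParams,
                 draw_index: int) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random-but-deterministic geometric transform to both arrays.

    The draw is a pure function of ``(params.seed, draw_index)``.  The same
    rotation/translation/flips are applied to the image (bilinear) and the
    mask (nearest), so the mask stays binary.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape[:2]:
        raise ValueError("image and mask shapes must match")
    angle, translate, do_h, do_v = _draw_transform(params, draw_index)
    aug_image = _apply_geometric(image, angle, translate, do_h, do_v, order=1)
    aug_mask = _apply_geometric(mask.astype(np.float64), angle, translate, do_h, do_v, order=0)
    return aug_image, (aug_mask > 0.5).astype(np.uint8)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def _largest_remainder(n: int, fractions: tuple[float, float, float]) -> list[int]:
    raw = [n * f for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = np.argsort([-(r - c) for r, c in zip(raw, counts)], kind="stable")
    for i in range(remainder):
        counts[order[i]] += 1
    return counts


def stratified_subject_split(manifest: pd.DataFrame, spec: SplitSpec) -> Split:
    """Split a manifest into train/val/test at subject granularity.

    Subjects (not slices) are allocated, stratified by the subject's label, so
    the three subject sets are disjoint and per-split label proportions match
    the stratified ideal to within one subject per class.  The allocation is a
    pure function of (manifest, spec.seed).
    """
    if "subject_id" not in manifest.columns or spec.stratify_on not in manifest.columns:
        raise ManifestValidationError("manifest needs subject_id and label columns")
    per_subject = manifest.groupby("subject_id")[spec.stratify_on].nunique()
    mixed = per_subject[per_subject > 1]
    if len(mixed):
        raise ManifestValidationError(
            f"subjects with mixed labels: {list(mixed.index[:5])}")
    subj_label = manifest.groupby("subject_id")[spec.stratify_on].first()

    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    parts: dict[str, list[str]] = {"train": [], "val": [], "test": []}
    for label in sorted(subj_label.unique()):
        subjects = sorted(subj_label.index[subj_label == label].tolist())
        if len(subjects) < 3:
            raise StratificationError(
                f"class {label!r} has {len(subjects)} subjects; need >= 3 to stratify")
        subjects = [subjects[i] for i in rng.permutation(len(subjects))]
        n_tr, n_va, n_te = _largest_remainder(len(subjects), spec.fractions)
        # every split must see every class
        while n_va == 0:
            n_tr -= 1
            n_va += 1
        while n_te == 0:
            n_tr -= 1
            n_te += 1
        parts["train"] += subjects[:n_tr]
        parts["val"] += subjects[n_tr:n_tr + n_va]
        parts["test"] += subjects[n_tr + n_va:]

    def take(subjects: list[str]) -> pd.DataFrame:
        sel = manifest[manifest["subject_id"].isin(set(subjects))]
        return sel.sort_values(["subject_id"] + (["path"] if "path" in sel else []),
                               kind="stable").reset_index(drop=True)

    return Split(train=take(parts["train"]), val=take(parts["val"]), test=take(parts["test"]))
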