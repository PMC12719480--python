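"""Synthetic brain-slice phantoms with ground-truth tumor masks.

The generator emulates the structure a 2-D tumor-segmentation pipeline sees in
a curated MRI slice collection: subjects carrying several slices each, a
binary tumor/non-tumor label per subject, roughly elliptical bright lesions
over a smooth soft-tissue-like background, additive Gaussian noise and
controllable class imbalance.  It makes every downstream stage testable with
no external dataset.

Determinism: each sample's RNG stream is derived from
``SeedSequence(spec.seed, spawn_key=(subject_index, slice_index))`` so a
sample is a pure function of (spec, indices) regardless of generation order.

The lesion is an axis-rotated ellipse whose semi-axes are area-preserving
perturbations of a per-subject base radius ``r`` (semi-axes ``r*s`` and
``r/s``), so the expected positive-pixel count stays ``pi * r**2`` and is
analytically checkable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from scipy.ndimage import gaussian_filter

from .errors import ConfigError

__all__ = ["PhantomSpec", "Sample", "generate_phantom", "generate_dataset",
           "MANIFEST_COLUMNS"]

MANIFEST_COLUMNS = ["path", "mask_path", "subject_id", "label"]

LABEL_TUMOR = "tumor"
LABEL_NON_TUMOR = "non_tumor"


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the phantom population.

    Intensities are arbitrary units in roughly [0, 1]: the background field
    has mean ``0.4`` with texture amplitude ``background_texture_amp``, and
    the lesion adds ``tumor_contrast`` on top.
    """

    image_size: int = 64
    n_subjects: int = 50
    slices_per_subject: int = 6
    tumor_prevalence: float = 0.5
    tumor_radius_range: tuple[float, float] = (6.0, 14.0)
    tumor_contrast: float = 0.5
    noise_sigma: float = 0.05
    background_texture_scale: float = 8.0
    background_texture_amp: float = 0.08
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.tumor_prevalence <= 1.0:
            raise ConfigError("tumor_prevalence must be in [0, 1]")
        rmin, rmax = self.tumor_radius_range
        if rmin > rmax:
            raise ConfigError("tumor_radius_range min must be <= max")
        if rmax >= self.image_size / 2:
            raise ConfigError("tumor_radius_range max must be < image_size/2")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if self.image_size < 8:
            raise ConfigError("image_size must be >= 8")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tumor_radius_range"] = list(self.tumor_radius_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["tumor_radius_range"] = tuple(d["tumor_radius_range"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True, indent=2))


@dataclass
class Sample:
    """One image slice with its ground truth.

    ``label == "tumor"`` iff the mask has at least one positive pixel.
    """

    image: np.ndarray
    mask: np.ndarray
    subject_id: str
    label: str

    def __post_init__(self):
        if self.image.shape[-2:] != self.mask.shape:
            raise ValueError("image and mask spatial shapes must match")


def _n_positive_subjects(spec: PhantomSpec) -> int:
    return int(round(spec.tumor_prevalence * spec.n_subjects))


def _positive_subjects(spec: PhantomSpec) -> np.ndarray:
    """Deterministic set of tumor-positive subject indices."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(0xFACE,)))
    order = rng.permutation(spec.n_subjects)
    return np.sort(order[: _n_positive_subjects(spec)])


def _subject_rng(spec: PhantomSpec, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(1, subject_index))
    )


def _slice_rng(spec: PhantomSpec, subject_index: int, slice_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(2, subject_index, slice_index))
    )


def _ellipse_mask(size: int, cy: float, cx: float, a: float, b: float, theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(np.uint8)


def generate_phantom(spec: PhantomSpec, subject_index: int, slice_index: int) -> Sample:
    """Generate one slice of one subject; deterministic in (spec, indices)."""
    if not 0 <= subject_index < spec.n_subjects:
        raise ValueError(f"subject_index {subject_index} out of range")
    if not 0 <= slice_index < spec.slices_per_subject:
        raise ValueError(f"slice_index {slice_index} out of range")

    size = spec.image_size
    positive = subject_index in set(_positive_subjects(spec).tolist())

    srng = _subject_rng(spec, subject_index)
    base_radius = srng.uniform(*spec.tumor_radius_range)
    base_cy = srng.uniform(0.35 * size, 0.65 * size)
    base_cx = srng.uniform(0.35 * size, 0.65 * size)

    rng = _slice_rng(spec, subject_index, slice_index)
    # background: smooth zero-mean random field plus white noise
    field = rng.standard_normal((size, size))
    if spec.background_texture_amp > 0:
        smooth = gaussian_filter(field, sigma=spec.background_texture_scale)
        sd = smooth.std()
        texture = spec.background_texture_amp * (smooth / sd if sd > 0 else smooth)
    else:
        texture = np.zeros((size, size))
    image = 0.4 + texture
    if spec.noise_sigma > 0:
        image = image + spec.noise_sigma * rng.standard_normal((size, size))

    if positive:
        # per-slice jitter: center wander, rotation, area-preserving squeeze
        cy = np.clip(base_cy + rng.uniform(-2.0, 2.0), base_radius + 1, size - base_radius - 1)
        cx = np.clip(base_cx + rng.uniform(-2.0, 2.0), base_radius + 1, size - base_radius - 1)
        squeeze = rng.uniform(1.0, 1.25)
        theta = rng.uniform(0.0, np.pi)
        mask = _ellipse_mask(size, cy, cx, base_radius * squeeze, base_radius / squeeze, theta)
        image = image + spec.tumor_contrast * mask
        label = LABEL_TUMOR if mask.any() else LABEL_NON_TUMOR
    else:
        mask = np.zeros((size, size), dtype=np.uint8)
        label = LABEL_NON_TUMOR

    return Sample(image=image.astype(np.float64), mask=mask,
                  subject_id=f"subj{subject_index:04d}", label=label)


def _write_png(path: Path, array: np.ndarray, is_mask: bool) -> None:
    if is_mask:
        data = (array.astype(np.uint8) * 255)
    else:
        data = np.clip(array, 0.0, 1.0)
        data = np.round(data * 255.0).astype(np.uint8)
    Image.fromarray(data).save(path)


def generate_dataset(spec: PhantomSpec, output_dir: str | Path | None = None
                     ) -> tuple[list[Sample], pd.DataFrame]:
    """Generate the full subject-structured dataset, optionally writing it out.

    Returns the samples and a manifest with columns
    ``path,mask_path,subject_id,label``.  When ``output_dir`` is given, images
    and masks are written as 8-bit PNG (masks in {0, 255}) and the manifest as
    ``manifest.csv``; paths in the manifest are relative to ``output_dir``.
    """
    out = Path(output_dir) if output_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "images").mkdir(exist_ok=True)
        (out / "masks").mkdir(exist_ok=True)

    samples: list[Sample] = []
    rows = []
    for si in range(spec.n_subjects):
        for ki in range(spec.slices_per_subject):
            sample = generate_phantom(spec, si, ki)
            samples.append(sample)
            img_rel = f"images/{sample.subject_id}_s{ki:03d}.png"
            mask_rel = f"masks/{sample.subject_id}_s{ki:03d}.png"
            if out is not None:
                _write_png(out / img_rel, sample.image, is_mask=False)
                _write_png(out / mask_rel, sample.mask, is_mask=True)
            rows.append({"path": img_rel, "mask_path": mask_rel,
                         "subject_id": sample.subject_id, "label": sample.label})
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False, lineterminator="\n")
        spec.to_yaml(out / "phantom_spec.yaml")
    return samples, manifest


def load_sample(base_dir: str | Path, row: pd.Series) -> Sample:
    """Load one manifest row written by :func:`generate_dataset`."""
    base = Path(base_dir)
    image = np.asarray(Image.open(base / row["path"]), dtype=np.float64) / 255.0
    mask_path = row.get("mask_path")
    if isinstance(mask_path, str) and mask_path:
        mask = (np.asarray(Image.open(base / mask_path)) > 127).astype(np.uint8)
    else:
        mask = np.zeros(image.shape[:2], dtype=np.uint8)
    return Sample(image=image, mask=mask, subject_id=str(row["subject_id"]),
                  label=str(row["label"]))
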