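"""Subject-level splitting, photometric augmentation and preprocessing.

Splitting is performed at the subject level: both views of an individual
always land in the same set, which prevents identity leakage between
training and evaluation.  Augmentation is photometric only (brightness
jittering in a configurable range, default [0.7, 1.3]) and is applied to
the training set alone.  Preprocessing resizes images to 128 x 128 x 3,
scales intensities to [0, 1] and normalizes landmark coordinates to
[0, 1] by the original image dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

from .schemas import AnnotatedImage, LandmarkSchema, get_schema

INPUT_SIZE = 128


@dataclass(frozen=True)
class CohortSplit:
    """Disjoint subject-id partition into train/validation/test."""

    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int = 0

    def set_of(self, subject_id: str) -> str | None:
        for name, ids in (("train", self.train_ids), ("val", self.val_ids),
                          ("test", self.test_ids)):
            if subject_id in ids:
                return name
        return None


@dataclass(frozen=True)
class AugmentationConfig:
    brightness_low: float = 0.7
    brightness_high: float = 1.3
    copies_per_image: int = 1
    seed: int = 42

    def __post_init__(self) -> None:
        if not (0 < self.brightness_low <= self.brightness_high):
            raise ValueError("require 0 < brightness_low <= brightness_high")
        if self.copies_per_image < 0:
            raise ValueError("copies_per_image must be >= 0")


@dataclass
class PreprocessedSample:
    """One network-ready sample plus the metadata needed to undo it."""

    input_array: np.ndarray   # (128, 128, 3) float32 in [0, 1]
    target_vector: np.ndarray  # (2L,) float32 in [0, 1], (x/w, y/h) pairs
    subject_id: str
    view: str
    width: int
    height: int


def proportional_sizes(n_subjects: int,
                       ratios: tuple[int, int, int] = (68, 15, 15)
                       ) -> tuple[int, int, int]:
    """Scale the reference 68/15/15 split to a cohort of another size.

    Uses largest-remainder rounding so the parts always sum to
    ``n_subjects``; each non-zero ratio keeps at least one subject.
    """
    total = sum(ratios)
    raw = [n_subjects * r / total for r in ratios]
    sizes = [max(1, int(x)) if r > 0 else 0 for x, r in zip(raw, ratios)]
    while sum(sizes) > n_subjects:
        sizes[int(np.argmax(sizes))] -= 1
    remainders = [x - s for x, s in zip(raw, sizes)]
    while sum(sizes) < n_subjects:
        i = int(np.argmax(remainders))
        sizes[i] += 1
        remainders[i] = -1
    return tuple(sizes)


def subject_split(subject_ids: Sequence[str], sizes: tuple[int, int, int],
                  seed: int) -> CohortSplit:
    """Uniformly random subject-level partition, deterministic in seed."""
    subject_ids = list(subject_ids)
    if sum(sizes) != len(subject_ids):
        raise ValueError(
            f"split sizes {sizes} sum to {sum(sizes)} but there are "
            f"{len(subject_ids)} subjects")
    rng = np.random.default_rng(seed)
    order = [subject_ids[i] for i in rng.permutation(len(subject_ids))]
    n_tr, n_va, n_te = sizes
    return CohortSplit(
        train_ids=tuple(order[:n_tr]),
        val_ids=tuple(order[n_tr:n_tr + n_va]),
        test_ids=tuple(order[n_tr + n_va:]),
        seed=seed,
    )


def assert_no_leakage(split: CohortSplit, cohort: Iterable[AnnotatedImage]
                      ) -> tuple[bool, list[str]]:
    """Check that the split is a leak-free subject partition of the cohort.

    Fails if any subject id appears in more than one set or any image's
    subject is unassigned.  Returns (passed, problems).
    """
    problems: list[str] = []
    sets = {"train": set(split.train_ids), "val": set(split.val_ids),
            "test": set(split.test_ids)}
    names = list(sets)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            for sid in sorted(sets[a] & sets[b]):
                problems.append(f"subject {sid!r} appears in both {a} and {b}")
    assigned = sets["train"] | sets["val"] | sets["test"]
    for sid in sorted({img.subject_id for img in cohort}):
        if sid not in assigned:
            problems.append(f"subject {sid!r} is not assigned to any set")
    return (not problems), problems


def brightness_jitter(img: AnnotatedImage, factor: float) -> AnnotatedImage:
    """Multiply intensities by `factor` and clip to 8-bit; landmarks unchanged."""
    if not factor > 0:
        raise ValueError("factor must be positive")
    pixels = np.clip(img.pixels.astype(np.float32) * factor, 0, 255
                     ).astype(np.uint8)
    return AnnotatedImage(
        subject_id=img.subject_id, view=img.view, pixels=pixels,
        width=img.width, height=img.height,
        landmarks=list(img.landmarks), source_path=img.source_path,
    )


def augment_training_set(train: Sequence[AnnotatedImage],
                         cfg: AugmentationConfig) -> list[AnnotatedImage]:
    """Originals plus brightness-jittered copies, training set only.

    Each copy's factor is drawn uniformly from
    [brightness_low, brightness_high]; deterministic in cfg.seed.  With
    the default one copy per image the training set doubles in size.
    """
    rng = np.random.default_rng(cfg.seed)
    out: list[AnnotatedImage] = []
    for img in train:
        out.append(img)
        for _ in range(cfg.copies_per_image):
            factor = float(rng.uniform(cfg.brightness_low, cfg.brightness_high))
            out.append(brightness_jitter(img, factor))
    return out


def resize_normalize(img: AnnotatedImage,
                     schema: LandmarkSchema | None = None) -> PreprocessedSample:
    """Bilinear-resize to 128 x 128, scale to [0, 1], normalize targets.

    Targets are (x / width, y / height) pairs interleaved in schema
    order; the aspect ratio is stretched to square (no padding).
    """
    if schema is None:
        schema = get_schema(img.view)
    im = Image.fromarray(img.pixels).resize((INPUT_SIZE, INPUT_SIZE),
                                            Image.BILINEAR)
    arr = np.asarray(im, dtype=np.float32) / 255.0
    if img.landmarks:
        coords = img.landmark_array()
        target = np.empty(2 * len(schema), dtype=np.float32)
        target[0::2] = coords[:, 0] / img.width
        target[1::2] = coords[:, 1] / img.height
    else:  # unannotated image: prediction-only sample
        target = np.zeros(0, dtype=np.float32)
    return PreprocessedSample(
        input_array=arr, target_vector=target,
        subject_id=img.subject_id, view=img.view,
        width=img.width, height=img.height,
    )


def denormalize_landmarks(vector: np.ndarray, width: int, height: int
                          ) -> np.ndarray:
    """Invert target normalization: (u, v) pairs -> (L, 2) pixel coordinates."""
    vector = np.asarray(vector, dtype=float).ravel()
    if vector.size % 2 != 0:
        raise ValueError("coordinate vector must have even length")
    if not (width > 0 and height > 0):
        raise ValueError("width and height must be positive")
    out = np.empty((vector.size // 2, 2), dtype=float)
    out[:, 0] = vector[0::2] * width
    out[:, 1] = vector[1::2] * height
    return out


def samples_to_arrays(samples: Sequence[PreprocessedSample]
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Stack samples into network-ready (X, y) arrays."""
    X = np.stack([s.input_array for s in samples]).astype(np.float32)
    y = np.stack([s.target_vector for s in samples]).astype(np.float32)
    return X, y


def filter_view(images: Iterable[AnnotatedImage], view: str
                ) -> list[AnnotatedImage]:
    return [img for img in images if img.view == view]


def filter_subjects(images: Iterable[AnnotatedImage], ids: Sequence[str]
                    ) -> list[AnnotatedImage]:
    ids = set(ids)
    return [img for img in images if img.subject_id in ids]
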