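"""Synthetic speckle-phantom generator with known boxes and class imbalance.

Produces fan-sector grayscale rasters textured with multiplicative unit-mean
speckle and elliptical "nodules" whose class, bounding box, and imbalance
profile are fully known — the ground-truth stand-in used to exercise the
augmentation, balancing, and evaluation pipelines end to end.

Class echo profiles are stylized (higher categories render darker with
softer borders) purely so classes are distinguishable in tests; no clinical
realism is claimed.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage

from .yolo_dataset import DatasetManifest, ImageRecord, LabeledBox

__all__ = [
    "PhantomConfig",
    "DEFAULT_CLASS_PROBS",
    "DEFAULT_ERROR_MATRIX",
    "generate_phantom",
    "corrupt_labels",
]

#: default imbalance: three common classes ~95.7% of nodules, three rare ~4.3%
DEFAULT_CLASS_PROBS = (0.25, 0.45, 0.257, 0.02, 0.015, 0.008)

#: per-class (intensity offset, border blur sigma) echo profiles
DEFAULT_ECHO_PROFILES = (
    (45.0, 1.0),
    (30.0, 1.0),
    (-25.0, 1.5),
    (-40.0, 2.0),
    (-55.0, 2.5),
    (-70.0, 3.0),
)

#: row-stochastic annotator error model: strong diagonal for the common
#: classes, rare classes most often confused into class index 2
DEFAULT_ERROR_MATRIX = np.array(
    [
        [0.82, 0.10, 0.06, 0.01, 0.005, 0.005],
        [0.08, 0.80, 0.09, 0.01, 0.01, 0.01],
        [0.05, 0.10, 0.79, 0.03, 0.02, 0.01],
        [0.02, 0.05, 0.45, 0.40, 0.05, 0.03],
        [0.01, 0.04, 0.42, 0.06, 0.42, 0.05],
        [0.01, 0.03, 0.40, 0.05, 0.06, 0.45],
    ]
)


@dataclasses.dataclass
class PhantomConfig:
    image_size: int = 128
    n_images: int = 50
    class_probs: tuple[float, ...] = DEFAULT_CLASS_PROBS
    nodules_per_image: tuple[int, int] = (1, 2)
    nodule_echo_profiles: tuple[tuple[float, float], ...] = DEFAULT_ECHO_PROFILES
    speckle_scale: float = 0.3
    background_level: float = 120.0
    nodule_radius_range: tuple[float, float] = (0.05, 0.12)  # fraction of size
    seed: int = 0

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.class_probs), 1.0, abs_tol=1e-9):
            raise ValueError(f"class_probs must sum to 1, got {sum(self.class_probs)}")
        if self.nodules_per_image[0] < 1:
            raise ValueError("every image must contain at least one nodule")
        if self.speckle_scale < 0:
            raise ValueError("speckle_scale must be non-negative")
        if len(self.nodule_echo_profiles) != len(self.class_probs):
            raise ValueError("need one echo profile per class")

    @property
    def class_count(self) -> int:
        return len(self.class_probs)


def _fan_mask(size: int) -> np.ndarray:
    """Fan-sector support: apex above top-center, bounded radius and angle."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    apex_r, apex_c = -0.15 * size, size / 2.0
    dy, dx = yy - apex_r, xx - apex_c
    radius = np.hypot(dy, dx)
    angle = np.arctan2(dx, dy)  # 0 = straight down
    return (radius < 1.25 * size) & (radius > 0.2 * size) & (np.abs(angle) < math.radians(40))


def _nodule_geometry(
    rng: np.random.Generator, size: int, radius_range: tuple[float, float]
) -> tuple[float, float, float, float]:
    a = rng.uniform(*radius_range) * size  # semi-axis, columns
    b = rng.uniform(*radius_range) * size  # semi-axis, rows
    max_a = 0.2 * size
    if a > max_a or b > max_a:
        raise ValueError("nodule larger than the usable sector region")
    # central region guaranteed inside the fan sector
    cx = rng.uniform(0.30 * size + a, 0.70 * size - a)
    cy = rng.uniform(0.35 * size + b, 0.80 * size - b)
    return cx, cy, a, b


def generate_phantom(config: PhantomConfig) -> list[ImageRecord]:
    """Generate fully seeded phantom records with exact ellipse boxes."""
    rng = np.random.default_rng(config.seed)
    size = config.image_size
    fan = _fan_mask(size)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    records = []
    for i in range(config.n_images):
        structure = config.background_level * fan.astype(np.float64)
        n_nod = int(rng.integers(config.nodules_per_image[0],
                                 config.nodules_per_image[1] + 1))
        boxes = []
        for _ in range(n_nod):
            cls = int(rng.choice(config.class_count, p=config.class_probs))
            cx, cy, a, b = _nodule_geometry(rng, size, config.nodule_radius_range)
            offset, border_sigma = config.nodule_echo_profiles[cls]
            ellipse = (((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2) <= 1.0
            soft = ndimage.gaussian_filter(ellipse.astype(np.float64), border_sigma)
            # renormalize so the nodule interior keeps the full offset
            peak = soft.max()
            if peak > 0:
                soft /= peak
            structure += offset * soft * fan
            boxes.append(
                LabeledBox(
                    class_id=cls,
                    cx=cx / size,
                    cy=cy / size,
                    w=2 * a / size,
                    h=2 * b / size,
                )
            )
        if config.speckle_scale > 0:
            var = config.speckle_scale**2
            speckle = rng.gamma(shape=1.0 / var, scale=var, size=(size, size))
        else:
            speckle = 1.0
        pixels = np.round(np.clip(structure * speckle, 0, 255)).astype(np.uint8)
        records.append(
            ImageRecord(
                image_id=f"phantom{i:05d}", image=pixels, boxes=boxes,
                source="synthetic",
            )
        )
    return records


def corrupt_labels(
    records: list[ImageRecord],
    error_matrix: np.ndarray = DEFAULT_ERROR_MATRIX,
    fp_rate: float = 0.0,
    fn_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[ImageRecord], list[ImageRecord]]:
    """Simulate an imperfect annotator over gold records.

    Each box's class is resampled from its error-matrix row; boxes are
    dropped with probability ``fn_rate``; spurious boxes are added at a
    per-image Poisson rate ``fp_rate``.  Returns ``(corrupted, gold)`` where
    gold is the untouched input relabeled as the reference annotation.
    """
    error_matrix = np.asarray(error_matrix, dtype=np.float64)
    C = error_matrix.shape[0]
    if error_matrix.shape != (C, C) or not np.allclose(error_matrix.sum(axis=1), 1.0):
        raise ValueError("error_matrix must be square with rows summing to 1")
    if not (0.0 <= fp_rate and 0.0 <= fn_rate <= 1.0):
        raise ValueError("rates must be non-negative; fn_rate <= 1")
    rng = np.random.default_rng(seed)
    corrupted = []
    gold = []
    for rec in records:
        new_boxes: list[LabeledBox] = []
        for box in rec.boxes:
            if box.class_id >= C:
                raise ValueError(f"box class {box.class_id} outside error matrix")
            if rng.random() < fn_rate:
                continue
            new_cls = int(rng.choice(C, p=error_matrix[box.class_id]))
            new_boxes.append(dataclasses.replace(box, class_id=new_cls))
        for _ in range(rng.poisson(fp_rate)):
            w = float(rng.uniform(0.05, 0.15))
            h = float(rng.uniform(0.05, 0.15))
            new_boxes.append(
                LabeledBox(
                    class_id=int(rng.integers(C)),
                    cx=float(rng.uniform(w / 2, 1 - w / 2)),
                    cy=float(rng.uniform(h / 2, 1 - h / 2)),
                    w=w,
                    h=h,
                )
            )
        corrupted.append(
            ImageRecord(rec.image_id, rec.image.copy(), new_boxes, source="junior")
        )
        gold.append(
            ImageRecord(rec.image_id, rec.image.copy(), list(rec.boxes), source="senior")
        )
    return corrupted, gold


def write_phantom_dataset(
    records: list[ImageRecord], out_dir, class_names: list[str] | None = None
) -> DatasetManifest:
    """Write records as a YOLO-layout dataset and return its manifest."""
    from pathlib import Path

    from .yolo_dataset import save_image, write_labels

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = class_names or DatasetManifest.DEFAULT_CLASS_NAMES
    image_paths, label_paths = [], []
    for rec in records:
        img_path = out_dir / f"{rec.image_id}.png"
        lbl_path = out_dir / f"{rec.image_id}.txt"
        save_image(rec.image, img_path)
        write_labels(rec.boxes, lbl_path)
        image_paths.append(img_path)
        label_paths.append(lbl_path)
    return DatasetManifest(list(names), image_paths, label_paths)
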