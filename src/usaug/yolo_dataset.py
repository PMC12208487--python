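"""YOLO-format dataset I/O: images, label files, manifests, class statistics.

Conventions
-----------
* Boxes use YOLO normalized center format: ``class cx cy w h`` with ``cx, cy,
  w, h`` expressed as fractions of the image width/height.  Pixel space is
  0-based, origin at the top-left corner, row-major.
* One label text file per image, same stem; a file may hold any number of
  lines (multi-nodule images carry one file with multiple lines).
* An optional sixth column holds a detection confidence; its absence marks a
  human annotation.
* Images are single-channel 8-bit; color inputs are collapsed to grayscale by
  channel averaging.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from PIL import Image

__all__ = [
    "LabeledBox",
    "ImageRecord",
    "DatasetManifest",
    "as_gray_image",
    "load_image",
    "save_image",
    "read_labels",
    "write_labels",
    "read_manifest",
    "write_manifest",
    "load_records",
    "class_counts",
]


class LabelParseError(ValueError):
    """A label line could not be parsed or violates box invariants."""


@dataclasses.dataclass(frozen=True)
class LabeledBox:
    """One annotated box in normalized center coordinates.

    ``confidence`` is ``None`` for human annotations and a score in [0, 1]
    for model detections.
    """

    class_id: int
    cx: float
    cy: float
    w: float
    h: float
    confidence: float | None = None

    def __post_init__(self) -> None:
        if self.class_id < 0:
            raise ValueError(f"class_id must be non-negative, got {self.class_id}")
        if not (0.0 <= self.cx <= 1.0 and 0.0 <= self.cy <= 1.0):
            raise ValueError(f"box center ({self.cx}, {self.cy}) outside [0, 1]")
        if not (0.0 < self.w <= 1.0 and 0.0 < self.h <= 1.0):
            raise ValueError(f"box extent ({self.w}, {self.h}) outside (0, 1]")
        # the box must intersect the image
        if self.cx - self.w / 2 >= 1.0 or self.cx + self.w / 2 <= 0.0:
            raise ValueError("box lies entirely outside the image in x")
        if self.cy - self.h / 2 >= 1.0 or self.cy + self.h / 2 <= 0.0:
            raise ValueError("box lies entirely outside the image in y")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def x0(self) -> float:
        return self.cx - self.w / 2

    @property
    def y0(self) -> float:
        return self.cy - self.h / 2

    @property
    def x1(self) -> float:
        return self.cx + self.w / 2

    @property
    def y1(self) -> float:
        return self.cy + self.h / 2

    def area(self) -> float:
        return self.w * self.h

    def clipped(self) -> "LabeledBox":
        """Return the box clipped to the unit square (evaluation-time view)."""
        x0, y0 = max(self.x0, 0.0), max(self.y0, 0.0)
        x1, y1 = min(self.x1, 1.0), min(self.y1, 1.0)
        return LabeledBox(
            class_id=self.class_id,
            cx=(x0 + x1) / 2,
            cy=(y0 + y1) / 2,
            w=x1 - x0,
            h=y1 - y0,
            confidence=self.confidence,
        )


@dataclasses.dataclass
class ImageRecord:
    """An image together with its annotations and provenance tag."""

    image_id: str
    image: np.ndarray
    boxes: list[LabeledBox]
    source: str = "synthetic"  # one of: junior, senior, model, synthetic

    VALID_SOURCES = ("junior", "senior", "model", "synthetic")

    def __post_init__(self) -> None:
        if self.source not in self.VALID_SOURCES:
            raise ValueError(f"source must be one of {self.VALID_SOURCES}")
        self.image = as_gray_image(self.image)


@dataclasses.dataclass
class DatasetManifest:
    """Ordered class names plus parallel image/label path lists."""

    class_names: list[str]
    image_paths: list[Path]
    label_paths: list[Path]

    DEFAULT_CLASS_NAMES = ["2", "3", "4A", "4B", "4C", "5"]

    def __post_init__(self) -> None:
        if len(set(self.class_names)) != len(self.class_names):
            raise ValueError("class_names must be unique")
        if len(self.image_paths) != len(self.label_paths):
            raise ValueError(
                f"{len(self.image_paths)} image paths vs "
                f"{len(self.label_paths)} label paths"
            )
        self.image_paths = [Path(p) for p in self.image_paths]
        self.label_paths = [Path(p) for p in self.label_paths]

    def __len__(self) -> int:
        return len(self.image_paths)

    @property
    def class_count(self) -> int:
        return len(self.class_names)

    def image_ids(self) -> list[str]:
        return [p.stem for p in self.image_paths]


def as_gray_image(pixels: np.ndarray) -> np.ndarray:
    """Validate/coerce an array into a 2-D uint8 intensity raster."""
    arr = np.asarray(pixels)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"expected a non-empty 2-D raster, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        if np.nanmin(arr) < 0 or np.nanmax(arr) > 255:
            raise ValueError("intensities outside [0, 255]")
        arr = np.round(arr).astype(np.uint8)
    return arr


def load_image(path: Path | str) -> np.ndarray:
    with Image.open(path) as im:
        if im.mode != "L":
            im = im.convert("RGB")
            arr = np.asarray(im, dtype=np.float64).mean(axis=2)
            return np.round(arr).astype(np.uint8)
        return np.asarray(im, dtype=np.uint8).copy()


def save_image(image: np.ndarray, path: Path | str) -> None:
    Image.fromarray(as_gray_image(image), mode="L").save(path)


def read_labels(path: Path | str, class_count: int) -> list[LabeledBox]:
    """Parse one YOLO label file; malformed lines raise, never skip."""
    path = Path(path)
    boxes: list[LabeledBox] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) not in (5, 6):
            raise LabelParseError(
                f"{path}:{lineno}: expected 5 or 6 fields, got {len(fields)}"
            )
        try:
            class_id = int(fields[0])
            cx, cy, w, h = (float(v) for v in fields[1:5])
            conf = float(fields[5]) if len(fields) == 6 else None
        except ValueError as exc:
            raise LabelParseError(f"{path}:{lineno}: {exc}") from None
        if not 0 <= class_id < class_count:
            raise LabelParseError(
                f"{path}:{lineno}: class_id {class_id} out of range "
                f"[0, {class_count})"
            )
        try:
            boxes.append(LabeledBox(class_id, cx, cy, w, h, conf))
        except ValueError as exc:
            raise LabelParseError(f"{path}:{lineno}: {exc}") from None
    return boxes


def write_labels(boxes: Iterable[LabeledBox], path: Path | str) -> None:
    """Write boxes in YOLO text format with 6-decimal coordinates."""
    lines = []
    for b in boxes:
        line = f"{b.class_id} {b.cx:.6f} {b.cy:.6f} {b.w:.6f} {b.h:.6f}"
        if b.confidence is not None:
            line += f" {b.confidence:.6f}"
        lines.append(line)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_manifest(path: Path | str) -> DatasetManifest:
    """Load a YAML manifest with ``names:`` and ``images:``/``labels:`` keys.

    ``images``/``labels`` may be directories (paired by sorted stem) or
    explicit path lists; relative paths resolve against the manifest's parent.
    """
    path = Path(path)
    data = yaml.safe_load(path.read_text()) or {}
    root = path.parent
    names = [str(n) for n in data.get("names", DatasetManifest.DEFAULT_CLASS_NAMES)]

    def _resolve(entry, exts: tuple[str, ...]) -> list[Path]:
        if entry is None:
            return []
        if isinstance(entry, str):
            d = root / entry if not Path(entry).is_absolute() else Path(entry)
            return sorted(p for p in d.iterdir() if p.suffix.lower() in exts)
        return [root / p if not Path(p).is_absolute() else Path(p) for p in entry]

    images = _resolve(data.get("images"), (".png", ".jpg", ".jpeg"))
    labels = _resolve(data.get("labels"), (".txt",))
    if isinstance(data.get("images"), str) and isinstance(data.get("labels"), str):
        by_stem = {p.stem: p for p in labels}
        labels = [by_stem[p.stem] for p in images]
    return DatasetManifest(names, images, labels)


def write_manifest(manifest: DatasetManifest, path: Path | str) -> None:
    path = Path(path)
    root = path.parent

    def _rel(p: Path) -> str:
        try:
            return str(p.relative_to(root))
        except ValueError:
            return str(p)

    data = {
        "names": list(manifest.class_names),
        "images": [_rel(p) for p in manifest.image_paths],
        "labels": [_rel(p) for p in manifest.label_paths],
    }
    path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_records(manifest: DatasetManifest, source: str = "senior") -> list[ImageRecord]:
    records = []
    for img_path, lbl_path in zip(manifest.image_paths, manifest.label_paths):
        records.append(
            ImageRecord(
                image_id=img_path.stem,
                image=load_image(img_path),
                boxes=read_labels(lbl_path, manifest.class_count),
                source=source,
            )
        )
    return records


def class_counts(
    manifest: DatasetManifest, boxes_per_image: Sequence[Sequence[LabeledBox]] | None = None
) -> dict[str, int]:
    """Count nodule instances (not images) per class across the dataset."""
    counter: Counter[int] = Counter()
    if boxes_per_image is None:
        boxes_per_image = [
            read_labels(p, manifest.class_count) for p in manifest.label_paths
        ]
    for boxes in boxes_per_image:
        counter.update(b.class_id for b in boxes)
    return {name: counter.get(i, 0) for i, name in enumerate(manifest.class_names)}
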