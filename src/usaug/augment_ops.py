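"""Ultrasound-specific and conventional augmentation operators.

Every operator is a pure, deterministic function of ``(image, params)``:
randomness lives exclusively in the parameter-sampling layer
(:mod:`usaug.balance_plan`), never inside an operator.  All operators
preserve image dimensions and the [0, 255] intensity range; only
:func:`apply_rotation` changes boxes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from typing import Any

import numpy as np
from scipy import ndimage

from .yolo_dataset import ImageRecord, LabeledBox, as_gray_image

__all__ = [
    "OP_NAMES",
    "GaussianKernel",
    "AugSpec",
    "gaussian_kernel",
    "apply_defocus",
    "apply_shadow_box",
    "apply_sidelobe",
    "apply_brightness_contrast",
    "rotate_boxes",
    "apply_rotation",
    "rotate_image",
    "apply_spec",
]

OP_NAMES = ("defocus", "shadow_box", "sidelobe", "brightness", "contrast", "rotation")

#: fraction of a rotated box's original area that must survive clipping for
#: the box to be kept
DEFAULT_MIN_BOX_AREA_FRACTION = 0.25


@dataclasses.dataclass(frozen=True)
class GaussianKernel:
    """A discrete, renormalized 2-D Gaussian convolution kernel."""

    size: int
    sigma: float
    weights: np.ndarray


@dataclasses.dataclass(frozen=True)
class AugSpec:
    """Reproducible record of one augmentation op and its sampled parameters."""

    op: str
    params: dict[str, Any]
    seed: int = 0

    _REQUIRED = {
        "defocus": {"sigma"},
        "shadow_box": {"x0", "y0", "width", "height", "alpha"},
        "sidelobe": {"angle_deg", "alpha"},
        "brightness": {"bias"},
        "contrast": {"gain"},
        "rotation": {"angle_deg"},
    }

    def __post_init__(self) -> None:
        if self.op not in OP_NAMES:
            raise ValueError(f"unknown op {self.op!r}; expected one of {OP_NAMES}")
        missing = self._REQUIRED[self.op] - set(self.params)
        if missing:
            raise ValueError(f"op {self.op!r} missing params {sorted(missing)}")

    def to_dict(self) -> dict[str, Any]:
        return {"op": self.op, "params": dict(self.params), "seed": self.seed}

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "AugSpec":
        return cls(op=data["op"], params=dict(data["params"]), seed=int(data.get("seed", 0)))

    def suffix(self) -> str:
        """Deterministic short tag encoding this spec, for output image ids."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return f"{self.op}-{hashlib.sha1(blob).hexdigest()[:8]}"


def gaussian_kernel(size: int = 5, sigma: float = 1.0) -> GaussianKernel:
    """Build a ``size``×``size`` Gaussian kernel, renormalized to sum to 1.

    Weights are proportional to ``exp(-(x² + y²) / (2σ²))`` with ``x``/``y``
    the column/row offsets from the center.  The continuous normalization
    coefficient does not sum to 1 on a finite grid, so the discrete kernel is
    renormalized, which preserves mean brightness under convolution.
    """
    if size % 2 == 0 or size < 3:
        raise ValueError(f"kernel size must be odd and >= 3, got {size}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    half = (size - 1) // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1]
    w = np.exp(-(x**2 + y**2) / (2.0 * sigma**2))
    w /= w.sum()
    return GaussianKernel(size=size, sigma=float(sigma), weights=w)


def apply_defocus(image: np.ndarray, sigma: float, size: int = 5) -> np.ndarray:
    """Blur with a 5×5 Gaussian kernel, stride 1, replicate edge padding."""
    img = as_gray_image(image)
    kern = gaussian_kernel(size, sigma)
    out = ndimage.convolve(img.astype(np.float64), kern.weights, mode="nearest")
    return np.round(np.clip(out, 0, 255)).astype(np.uint8)


def apply_shadow_box(
    image: np.ndarray,
    region: tuple[int, int, int, int],
    alpha: float,
) -> np.ndarray:
    """Darken a rectangle ``(x0, y0, width, height)`` by opacity ``alpha``.

    Inside the region (clipped to the image) the output is
    ``round((1 - alpha) * input)``; alpha=1 gives a fully black box.
    """
    img = as_gray_image(image)
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    x0, y0, width, height = region
    H, W = img.shape
    cx0, cy0 = max(int(x0), 0), max(int(y0), 0)
    cx1, cy1 = min(int(x0 + width), W), min(int(y0 + height), H)
    if cx1 <= cx0 or cy1 <= cy0:
        raise ValueError(f"region {region} has zero area after clipping to {W}x{H}")
    out = img.copy()
    patch = out[cy0:cy1, cx0:cx1].astype(np.float64)
    out[cy0:cy1, cx0:cx1] = np.round((1.0 - alpha) * patch).astype(np.uint8)
    return out


def rotate_image(image: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate about the image center; bilinear interpolation, zero fill.

    Positive angles rotate content clockwise on screen (x right, y down);
    canvas size is preserved.
    """
    img = as_gray_image(image)
    if angle_deg % 360 == 0:
        return img.copy()
    theta = math.radians(angle_deg)
    H, W = img.shape
    center = np.array([(H - 1) / 2.0, (W - 1) / 2.0])
    # forward map in (row, col): p' = C + R (p - C); affine_transform needs
    # the inverse map, output -> input.  R is chosen so that in (x=col,
    # y=row) coordinates the content rotates by +theta with y pointing down,
    # matching the box-corner math in _rotate_box.
    rot = np.array(
        [[math.cos(theta), math.sin(theta)], [-math.sin(theta), math.cos(theta)]]
    )
    inv = rot.T
    offset = center - inv @ center
    out = ndimage.affine_transform(
        img.astype(np.float64), inv, offset=offset, order=1, mode="constant", cval=0.0
    )
    return np.round(np.clip(out, 0, 255)).astype(np.uint8)


def apply_sidelobe(image: np.ndarray, angle_deg: float, alpha: float) -> np.ndarray:
    """Overlay a faint rotated copy: ``(1 - α)·original + α·rotated``."""
    img = as_gray_image(image)
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if angle_deg % 360 == 0:
        return img.copy()
    ghost = rotate_image(img, angle_deg).astype(np.float64)
    out = (1.0 - alpha) * img.astype(np.float64) + alpha * ghost
    return np.round(np.clip(out, 0, 255)).astype(np.uint8)


def apply_brightness_contrast(
    image: np.ndarray, gain: float = 1.0, bias: float = 0.0
) -> np.ndarray:
    """Linear intensity map ``clip(round(gain·in + bias))``."""
    img = as_gray_image(image)
    if gain <= 0:
        raise ValueError(f"gain must be positive, got {gain}")
    out = gain * img.astype(np.float64) + bias
    return np.round(np.clip(out, 0, 255)).astype(np.uint8)


def _rotate_box(
    box: LabeledBox, angle_deg: float, aspect: float
) -> tuple[float, float, float, float]:
    """Axis-aligned hull of the box's four corners rotated about (0.5, 0.5).

    ``aspect`` = width/height in pixels; corners are rotated in a square
    pixel-metric space so the geometry matches :func:`rotate_image`.
    """
    theta = math.radians(angle_deg)
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    corners = [
        (box.x0, box.y0),
        (box.x1, box.y0),
        (box.x0, box.y1),
        (box.x1, box.y1),
    ]
    xs, ys = [], []
    for x, y in corners:
        # to centered pixel-metric coordinates (square aspect)
        px = (x - 0.5) * aspect
        py = y - 0.5
        rx = cos_t * px - sin_t * py
        ry = sin_t * px + cos_t * py
        xs.append(rx / aspect + 0.5)
        ys.append(ry + 0.5)
    return min(xs), min(ys), max(xs), max(ys)


def rotate_boxes(
    boxes: list[LabeledBox],
    angle_deg: float,
    aspect: float = 1.0,
    min_area_fraction: float = DEFAULT_MIN_BOX_AREA_FRACTION,
) -> list[LabeledBox]:
    """Box geometry of a rotation, without touching pixels.

    Each box becomes the axis-aligned hull of its four rotated corners,
    clipped to the unit square; boxes whose clipped area drops below
    ``min_area_fraction`` of the hull area are dropped.
    """
    if angle_deg % 360 == 0:
        return list(boxes)
    new_boxes: list[LabeledBox] = []
    for box in boxes:
        x0, y0, x1, y1 = _rotate_box(box, angle_deg, aspect)
        hull_area = (x1 - x0) * (y1 - y0)
        cx0, cy0 = max(x0, 0.0), max(y0, 0.0)
        cx1, cy1 = min(x1, 1.0), min(y1, 1.0)
        if cx1 <= cx0 or cy1 <= cy0:
            continue
        if (cx1 - cx0) * (cy1 - cy0) < min_area_fraction * hull_area:
            continue
        new_boxes.append(
            LabeledBox(
                class_id=box.class_id,
                cx=(cx0 + cx1) / 2,
                cy=(cy0 + cy1) / 2,
                w=cx1 - cx0,
                h=cy1 - cy0,
                confidence=box.confidence,
            )
        )
    return new_boxes


def apply_rotation(
    image: np.ndarray,
    boxes: list[LabeledBox],
    angle_deg: float,
    min_area_fraction: float = DEFAULT_MIN_BOX_AREA_FRACTION,
) -> tuple[np.ndarray, list[LabeledBox]]:
    """Rotate image and boxes together (see :func:`rotate_boxes`)."""
    img = as_gray_image(image)
    out = rotate_image(img, angle_deg)
    H, W = img.shape
    return out, rotate_boxes(boxes, angle_deg, aspect=W / H,
                             min_area_fraction=min_area_fraction)


def apply_spec(record: ImageRecord, spec: AugSpec) -> ImageRecord:
    """Dispatch one :class:`AugSpec` to its operator.

    The output ``image_id`` is the input id plus a deterministic suffix
    encoding the spec, so identical (record, spec) always yields identical
    output.
    """
    p = spec.params
    boxes = list(record.boxes)
    if spec.op == "defocus":
        img = apply_defocus(record.image, sigma=p["sigma"])
    elif spec.op == "shadow_box":
        # shadow_box spec params are fractions of image size, so one spec
        # applies to any raster; converted to pixels here
        H, W = record.image.shape
        img = apply_shadow_box(
            record.image,
            region=(
                round(p["x0"] * W),
                round(p["y0"] * H),
                max(1, round(p["width"] * W)),
                max(1, round(p["height"] * H)),
            ),
            alpha=p["alpha"],
        )
    elif spec.op == "sidelobe":
        img = apply_sidelobe(record.image, angle_deg=p["angle_deg"], alpha=p["alpha"])
    elif spec.op == "brightness":
        img = apply_brightness_contrast(record.image, gain=1.0, bias=p["bias"])
    elif spec.op == "contrast":
        img = apply_brightness_contrast(
            record.image, gain=p["gain"], bias=p.get("bias", 0.0)
        )
    elif spec.op == "rotation":
        img, boxes = apply_rotation(
            record.image,
            boxes,
            angle_deg=p["angle_deg"],
            min_area_fraction=p.get(
                "min_area_fraction", DEFAULT_MIN_BOX_AREA_FRACTION
            ),
        )
    else:  # pragma: no cover - AugSpec already validates
        raise ValueError(f"unknown op {spec.op!r}")
    return ImageRecord(
        image_id=f"{record.image_id}__{spec.suffix()}",
        image=img,
        boxes=boxes,
        source=record.source,
    )
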