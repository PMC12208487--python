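"""Physics-inspired acoustic-shadow simulator.

A directional front-marching scheme: a shadow front seeded on an occluder is
propagated line by line along the beam direction, spreading laterally through
a 1-D Gaussian blur (diffraction) and fading by a multiplicative decay per
propagated line.  The result is a graded attenuation field in [0, 1] (1 =
full shadow) that can darken an image or be rendered as contours.

No wave equation is solved; the scheme is the simplest one reproducing the
two qualitative phenomena of interest — lateral diffraction spreading and
shadow intensity decreasing with distance behind the occluder.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage
from skimage import measure

from .yolo_dataset import as_gray_image

__all__ = ["ShadowField", "propagate_shadow", "apply_shadow_field", "render_contours"]

#: axis-aligned and 45-degree beam-direction presets as (drow, dcol)
DIRECTION_PRESETS = {
    "down": (1.0, 0.0),
    "up": (-1.0, 0.0),
    "right": (0.0, 1.0),
    "left": (0.0, -1.0),
    "down-right": (math.sqrt(0.5), math.sqrt(0.5)),
    "down-left": (math.sqrt(0.5), -math.sqrt(0.5)),
    "up-right": (-math.sqrt(0.5), math.sqrt(0.5)),
    "up-left": (-math.sqrt(0.5), -math.sqrt(0.5)),
}


@dataclasses.dataclass
class ShadowField:
    attenuation: np.ndarray  # 2-D, values in [0, 1]; 1 = full shadow
    direction: tuple[float, float]  # unit (drow, dcol) of beam propagation
    occluder: np.ndarray  # binary mask, same shape
    diffusion_rate: float  # 1-D blur sigma per propagated line
    decay_rate: float  # multiplicative fade per propagated line, in [0, 1)


def _march(occ: np.ndarray, diffusion_rate: float, decay_rate: float) -> np.ndarray:
    """Propagate a shadow front down the rows of ``occ`` (direction (1, 0))."""
    H, W = occ.shape
    field = np.zeros((H, W), dtype=np.float64)
    front = np.zeros(W, dtype=np.float64)
    for r in range(H):
        front = (1.0 - decay_rate) * front
        if diffusion_rate > 0:
            front = ndimage.gaussian_filter1d(
                front, sigma=diffusion_rate, mode="constant", cval=0.0
            )
        front = np.maximum(front, occ[r].astype(np.float64))
        field[r] = front
    return np.clip(field, 0.0, 1.0)


def propagate_shadow(
    occluder: np.ndarray,
    direction: tuple[float, float] | str = "down",
    diffusion_rate: float = 0.5,
    decay_rate: float = 0.02,
) -> ShadowField:
    """March a shadow front behind ``occluder`` along ``direction``.

    ``direction`` is a (drow, dcol) vector or a named preset ("down",
    "up-left", ...).  Non-axis-aligned directions are handled by rotating the
    grid so the beam points down, marching, and rotating back.
    """
    occ = np.asarray(occluder).astype(bool)
    if occ.ndim != 2:
        raise ValueError(f"occluder must be 2-D, got shape {occ.shape}")
    if not occ.any():
        raise ValueError("occluder mask is empty")
    if isinstance(direction, str):
        try:
            dvec = DIRECTION_PRESETS[direction]
        except KeyError:
            raise ValueError(
                f"unknown direction preset {direction!r}; "
                f"options: {sorted(DIRECTION_PRESETS)}"
            ) from None
    else:
        norm = math.hypot(*direction)
        if norm == 0:
            raise ValueError("direction vector must be non-zero")
        dvec = (direction[0] / norm, direction[1] / norm)
    if diffusion_rate < 0:
        raise ValueError("diffusion_rate must be non-negative")
    if not 0.0 <= decay_rate < 1.0:
        raise ValueError("decay_rate must be in [0, 1)")

    dr, dc = dvec
    # angle by which the grid must be rotated so the beam points down (+row)
    angle = math.degrees(math.atan2(dc, dr))
    if abs(angle) < 1e-9:
        att = _march(occ, diffusion_rate, decay_rate)
    elif abs(abs(angle) - 180.0) < 1e-9:
        att = _march(occ[::-1], diffusion_rate, decay_rate)[::-1]
    elif abs(angle - 90.0) < 1e-9:  # beam points right: transpose
        att = _march(occ.T, diffusion_rate, decay_rate).T
    elif abs(angle + 90.0) < 1e-9:
        att = _march(occ.T[::-1], diffusion_rate, decay_rate)[::-1].T
    else:
        rot = ndimage.rotate(
            occ.astype(np.float64), -angle, reshape=True, order=0, mode="constant"
        )
        marched = _march(rot >= 0.5, diffusion_rate, decay_rate)
        back = ndimage.rotate(marched, angle, reshape=False, order=1, mode="constant")
        # crop the center back to the original shape
        H, W = occ.shape
        h0 = (back.shape[0] - H) // 2
        w0 = (back.shape[1] - W) // 2
        att = np.clip(back[h0 : h0 + H, w0 : w0 + W], 0.0, 1.0)
    return ShadowField(
        attenuation=att,
        direction=dvec,
        occluder=occ,
        diffusion_rate=float(diffusion_rate),
        decay_rate=float(decay_rate),
    )


def apply_shadow_field(image: np.ndarray, field: ShadowField) -> np.ndarray:
    """Darken ``image`` by the field: ``round(in · (1 − attenuation))``."""
    img = as_gray_image(image)
    if field.attenuation.shape != img.shape:
        raise ValueError(
            f"field shape {field.attenuation.shape} != image shape {img.shape}"
        )
    out = img.astype(np.float64) * (1.0 - field.attenuation)
    return np.round(np.clip(out, 0, 255)).astype(np.uint8)


def render_contours(field: ShadowField, levels: list[float]) -> dict[float, list[np.ndarray]]:
    """Iso-lines of the attenuation field, keyed by level.

    Each contour is an (N, 2) array of (row, col) vertices; purely for
    plotting.
    """
    if not levels:
        raise ValueError("levels must be non-empty")
    if any(not 0.0 < lv < 1.0 for lv in levels):
        raise ValueError("levels must lie strictly inside (0, 1)")
    if any(b <= a for a, b in zip(levels, levels[1:])):
        raise ValueError("levels must be strictly increasing")
    return {
        float(lv): measure.find_contours(field.attenuation, lv) for lv in levels
    }
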