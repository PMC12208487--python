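"""Class-imbalance-driven augmentation planning and execution.

The planner counts nodules per class, derives per-class targets from the
largest class, and repeatedly selects images containing under-target classes
(with replacement), assigning each selected copy exactly two distinct,
randomly chosen augmentation ops.  Co-occurring nodules of other classes in a
selected image count toward those classes too, so balancing one class can
raise others as a side effect.

Planning and execution are split so a plan is a reviewable, reproducible
artifact: executing the same plan twice yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from .augment_ops import OP_NAMES, AugSpec, apply_spec, rotate_boxes
from .yolo_dataset import (
    DatasetManifest,
    ImageRecord,
    LabeledBox,
    load_image,
    read_labels,
    save_image,
    write_labels,
)

__all__ = [
    "DEFAULT_OP_RANGES",
    "BalancePlan",
    "sample_op_pair",
    "plan_balancing",
    "execute_plan",
]

#: per-op parameter sampling ranges (uniform); all values configurable
DEFAULT_OP_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "defocus": {"sigma": (0.5, 2.5)},
    "shadow_box": {"size": (0.05, 0.30), "alpha": (0.4, 1.0)},
    "sidelobe": {"angle_deg": (-10.0, 10.0), "alpha": (0.1, 0.35)},
    "brightness": {"bias": (-40.0, 40.0)},
    "contrast": {"gain": (0.7, 1.4)},
    "rotation": {"angle_deg": (-10.0, 10.0)},
}

#: hard cap on augmented copies generated per original image
DEFAULT_COPY_CAP = 10


@dataclasses.dataclass
class BalancePlan:
    """Per-class targets plus the (image, op-pair) selections meeting them."""

    targets: dict[str, float]
    selections: list[tuple[str, tuple[AugSpec, AugSpec]]]
    seed: int
    projected_counts: dict[str, int]

    def to_dict(self) -> dict[str, Any]:
        return {
            "targets": self.targets,
            "seed": self.seed,
            "projected_counts": self.projected_counts,
            "selections": [
                {"image_id": iid, "specs": [a.to_dict(), b.to_dict()]}
                for iid, (a, b) in self.selections
            ],
        }


def _sample_params(
    op: str, rng: np.random.Generator, ranges: dict[str, dict[str, tuple[float, float]]]
) -> dict[str, float]:
    r = ranges[op]
    if op == "defocus":
        return {"sigma": float(rng.uniform(*r["sigma"]))}
    if op == "shadow_box":
        w = float(rng.uniform(*r["size"]))
        h = float(rng.uniform(*r["size"]))
        return {
            "x0": float(rng.uniform(0.0, 1.0 - w)),
            "y0": float(rng.uniform(0.0, 1.0 - h)),
            "width": w,
            "height": h,
            "alpha": float(rng.uniform(*r["alpha"])),
        }
    if op == "sidelobe":
        return {
            "angle_deg": float(rng.uniform(*r["angle_deg"])),
            "alpha": float(rng.uniform(*r["alpha"])),
        }
    if op == "brightness":
        return {"bias": float(rng.uniform(*r["bias"]))}
    if op == "contrast":
        return {"gain": float(rng.uniform(*r["gain"]))}
    if op == "rotation":
        return {"angle_deg": float(rng.uniform(*r["angle_deg"]))}
    raise ValueError(f"unknown op {op!r}")


def sample_op_pair(
    catalog: Sequence[str],
    rng: np.random.Generator,
    ranges: dict[str, dict[str, tuple[float, float]]] | None = None,
) -> tuple[AugSpec, AugSpec]:
    """Draw two distinct ops uniformly without replacement, with parameters."""
    if len(catalog) < 2:
        raise ValueError(f"op catalog needs >= 2 entries, got {list(catalog)}")
    unknown = set(catalog) - set(OP_NAMES)
    if unknown:
        raise ValueError(f"unknown ops in catalog: {sorted(unknown)}")
    ranges = ranges or DEFAULT_OP_RANGES
    idx = rng.choice(len(catalog), size=2, replace=False)
    specs = []
    for i in idx:
        op = catalog[int(i)]
        specs.append(
            AugSpec(
                op=op,
                params=_sample_params(op, rng, ranges),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs[0], specs[1]


def _boxes_after(boxes: list[LabeledBox], specs: Sequence[AugSpec]) -> list[LabeledBox]:
    """Project label geometry through a spec sequence (only rotation acts)."""
    out = list(boxes)
    for spec in specs:
        if spec.op == "rotation":
            out = rotate_boxes(out, spec.params["angle_deg"])
    return out


def plan_balancing(
    dataset: DatasetManifest,
    target_ratio: float = 3.0,
    catalog: Sequence[str] = OP_NAMES,
    seed: int = 0,
    ranges: dict[str, dict[str, tuple[float, float]]] | None = None,
    copy_cap: int = DEFAULT_COPY_CAP,
) -> BalancePlan:
    """Plan augmentations until every class reaches ``max_count/target_ratio``.

    Selections are drawn with replacement from images containing the most
    deficient class; each selection gets a fresh op pair.  Projected counts
    account for rotation's box drops, so they match execution exactly.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    if target_ratio < 1.0:
        raise ValueError(f"target_ratio must be >= 1, got {target_ratio}")
    rng = np.random.default_rng(seed)

    boxes_per_image = [
        read_labels(p, dataset.class_count) for p in dataset.label_paths
    ]
    ids = dataset.image_ids()
    counts = Counter()
    for boxes in boxes_per_image:
        counts.update(b.class_id for b in boxes)
    max_count = max(counts.values(), default=0)
    if max_count == 0:
        raise ValueError("dataset has no annotations")
    targets = {c: max_count / target_ratio for c in range(dataset.class_count)}

    # index: class -> image positions containing it
    images_with: dict[int, list[int]] = {c: [] for c in range(dataset.class_count)}
    for pos, boxes in enumerate(boxes_per_image):
        for c in {b.class_id for b in boxes}:
            images_with[c].append(pos)

    deficient_unfixable = [
        dataset.class_names[c]
        for c in range(dataset.class_count)
        if counts.get(c, 0) < targets[c] and not images_with[c]
    ]
    if deficient_unfixable:
        raise ValueError(
            "no image contains deficient class(es): "
            + ", ".join(deficient_unfixable)
        )

    projected = Counter(counts)
    copies = Counter()  # per original image
    selections: list[tuple[str, tuple[AugSpec, AugSpec]]] = []
    while True:
        deficits = {
            c: targets[c] - projected.get(c, 0)
            for c in range(dataset.class_count)
            if projected.get(c, 0) < targets[c]
        }
        if not deficits:
            break
        worst = max(deficits, key=lambda c: (deficits[c], -c))
        pool = [p for p in images_with[worst] if copies[p] < copy_cap]
        if not pool:
            break  # copy cap exhausted for this class; stop rather than spin
        pos = pool[int(rng.integers(len(pool)))]
        pair = sample_op_pair(catalog, rng, ranges)
        new_boxes = _boxes_after(boxes_per_image[pos], pair)
        projected.update(b.class_id for b in new_boxes)
        copies[pos] += 1
        selections.append((ids[pos], pair))

    return BalancePlan(
        targets={dataset.class_names[c]: targets[c] for c in targets},
        selections=selections,
        seed=seed,
        projected_counts={
            name: projected.get(i, 0) for i, name in enumerate(dataset.class_names)
        },
    )


def execute_plan(
    plan: BalancePlan, dataset: DatasetManifest, out_dir: Path | str
) -> DatasetManifest:
    """Apply every selection (second op composed onto the first op's output),
    write augmented images/labels plus a JSON sidecar of specs, and return
    the merged manifest (originals + augmented)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_id = {
        p.stem: (p, lp) for p, lp in zip(dataset.image_paths, dataset.label_paths)
    }
    missing = {iid for iid, _ in plan.selections} - set(by_id)
    if missing:
        raise ValueError(f"plan refers to unknown image ids: {sorted(missing)}")

    image_paths = list(dataset.image_paths)
    label_paths = list(dataset.label_paths)
    sidecar = []
    for k, (iid, (spec_a, spec_b)) in enumerate(plan.selections):
        img_path, lbl_path = by_id[iid]
        record = ImageRecord(
            image_id=iid,
            image=load_image(img_path),
            boxes=read_labels(lbl_path, dataset.class_count),
        )
        out_rec = apply_spec(apply_spec(record, spec_a), spec_b)
        stem = f"{iid}__aug{k:05d}"
        out_img = out_dir / f"{stem}.png"
        out_lbl = out_dir / f"{stem}.txt"
        save_image(out_rec.image, out_img)
        write_labels(out_rec.boxes, out_lbl)
        image_paths.append(out_img)
        label_paths.append(out_lbl)
        sidecar.append(
            {
                "image_id": out_rec.image_id,
                "file_stem": stem,
                "source_image_id": iid,
                "specs": [spec_a.to_dict(), spec_b.to_dict()],
            }
        )
    (out_dir / "augmentations.json").write_text(json.dumps(sidecar, indent=2))
    return DatasetManifest(list(dataset.class_names), image_paths, label_paths)
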