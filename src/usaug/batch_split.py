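"""Batched dataset splitting: 25 equal portions, 5 cumulative batches, 4:1
train/validation portion ratio.

The id list is shuffled once with the seed and chunked in order into
portions.  Batch N uses exactly the first ``block·N`` portions (``block`` =
portions per batch); within each block the last portion validates and the
rest train, so earlier batches' assignments never change as N grows and
train/val never leak into each other.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .yolo_dataset import DatasetManifest

__all__ = ["BatchAssignment", "BatchSchedule", "make_schedule", "materialize_batch"]


@dataclasses.dataclass(frozen=True)
class BatchAssignment:
    train_portions: tuple[int, ...]
    val_portions: tuple[int, ...]


@dataclasses.dataclass
class BatchSchedule:
    portions: list[list[str]]
    batches: list[BatchAssignment]  # index 0 = batch 1
    seed: int

    @property
    def n_portions(self) -> int:
        return len(self.portions)

    @property
    def n_batches(self) -> int:
        return len(self.batches)

    def train_ids(self, batch_n: int) -> list[str]:
        a = self._assignment(batch_n)
        return [iid for p in a.train_portions for iid in self.portions[p]]

    def val_ids(self, batch_n: int) -> list[str]:
        a = self._assignment(batch_n)
        return [iid for p in a.val_portions for iid in self.portions[p]]

    def _assignment(self, batch_n: int) -> BatchAssignment:
        if not 1 <= batch_n <= self.n_batches:
            raise ValueError(
                f"batch_n must be in [1, {self.n_batches}], got {batch_n}"
            )
        return self.batches[batch_n - 1]

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "portions": self.portions,
            "batches": [
                {
                    "batch": i + 1,
                    "train_portions": list(a.train_portions),
                    "val_portions": list(a.val_portions),
                }
                for i, a in enumerate(self.batches)
            ],
        }

    def save(self, path: Path | str) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def make_schedule(
    image_ids: Sequence[str],
    n_portions: int = 25,
    n_batches: int = 5,
    seed: int = 0,
) -> BatchSchedule:
    """Shuffle ids once, chunk into portions, derive the cumulative batches.

    Portion sizes differ by at most one (earlier portions take the extras);
    within each block of ``n_portions // n_batches`` portions the last one is
    the validation portion, giving the 4:1 split at the default 25/5.
    """
    ids = [str(i) for i in image_ids]
    if len(set(ids)) != len(ids):
        raise ValueError("image ids must be unique")
    if len(ids) < n_portions:
        raise ValueError(f"{len(ids)} ids cannot fill {n_portions} portions")
    if n_portions % n_batches != 0:
        raise ValueError(
            f"n_portions ({n_portions}) must be divisible by n_batches ({n_batches})"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]

    base, extra = divmod(len(ids), n_portions)
    portions: list[list[str]] = []
    start = 0
    for p in range(n_portions):
        size = base + (1 if p < extra else 0)
        portions.append(shuffled[start : start + size])
        start += size

    block = n_portions // n_batches
    batches = []
    for n in range(1, n_batches + 1):
        in_play = range(block * n)
        val = tuple(b * block + block - 1 for b in range(n))
        train = tuple(p for p in in_play if p not in val)
        batches.append(BatchAssignment(train_portions=train, val_portions=val))
    return BatchSchedule(portions=portions, batches=batches, seed=seed)


def materialize_batch(
    schedule: BatchSchedule, batch_n: int, dataset: DatasetManifest
) -> tuple[DatasetManifest, DatasetManifest]:
    """Select the original images of one batch into train/val manifests."""
    by_id = {
        p.stem: (p, lp) for p, lp in zip(dataset.image_paths, dataset.label_paths)
    }

    def _subset(ids: list[str]) -> DatasetManifest:
        missing = [i for i in ids if i not in by_id]
        if missing:
            raise ValueError(f"schedule ids missing from dataset: {missing[:5]}...")
        imgs = [by_id[i][0] for i in ids]
        lbls = [by_id[i][1] for i in ids]
        return DatasetManifest(list(dataset.class_names), imgs, lbls)

    return _subset(schedule.train_ids(batch_n)), _subset(schedule.val_ids(batch_n))
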