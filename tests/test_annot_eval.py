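import dataclasses
import math

import numpy as np
import pytest

from conftest import random_box
from usaug.annot_eval import (
    MatchResult,
    accuracy,
    class_agnostic_nms,
    confusion,
    filter_confidence,
    iou,
    match_to_gold,
    mean_average_precision,
)
from usaug.yolo_dataset import LabeledBox

CLASS_NAMES = ["2", "3", "4A", "4B", "4C", "5"]


def box(cx, cy, w, h, cls=0, conf=None):
    return LabeledBox(cls, cx, cy, w, h, confidence=conf)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def nms_oracle(boxes, thr):
    """Straight re-derivation of greedy class-agnostic NMS via a pair matrix."""
    n = len(boxes)
    alive = [True] * n
    order = sorted(range(n), key=lambda i: (-boxes[i].confidence, i))
    kept = []
    for i in order:
        if alive[i]:
            kept.append(i)
            for j in range(n):
                if j != i and alive[j] and iou(boxes[i], boxes[j]) > thr:
                    alive[j] = False
    return [boxes[i] for i in kept]


def match_oracle(cands, gold, thr):
    """Greedy matching by repeatedly taking the global-max IoU pair."""
    m = np.full((len(cands), len(gold)), -1.0)
    for i, c in enumerate(cands):
        for j, g in enumerate(gold):
            v = iou(c, g)
            if v >= thr:
                m[i, j] = v
    pairs = []
    while m.size and m.max() >= 0:
        i, j = np.unravel_index(np.argmax(m), m.shape)
        pairs.append((i, j))
        m[i, :] = -1.0
        m[:, j] = -1.0
    return sorted(pairs)


class TestIoU:
    def test_identical(self):
        b = box(0.5, 0.5, 0.4, 0.4)
        assert iou(b, b) == 1.0

    def test_disjoint(self):
        assert iou(box(0.2, 0.2, 0.1, 0.1), box(0.8, 0.8, 0.1, 0.1)) == 0.0

    def test_half_overlap_one_third(self):
        a = box(0.25, 0.5, 0.5, 1.0)
        b = box(0.5, 0.5, 0.5, 1.0)
        assert iou(a, b) == pytest.approx(1 / 3)

    def test_symmetry(self, rng):
        for _ in range(50):
            a, b = random_box(rng), random_box(rng)
            assert iou(a, b) == pytest.approx(iou(b, a))


class TestNMS:
    def test_single_box(self):
        b = box(0.5, 0.5, 0.2, 0.2, conf=0.5)
        assert class_agnostic_nms([b]) == [b]

    def test_duplicate_suppressed(self):
        hi = box(0.5, 0.5, 0.2, 0.2, conf=0.9)
        lo = box(0.5, 0.5, 0.2, 0.2, cls=3, conf=0.8)  # other class: still suppressed
        assert class_agnostic_nms([hi, lo], 0.7) == [hi]

    def test_missing_confidence(self):
        with pytest.raises(ValueError):
            class_agnostic_nms([box(0.5, 0.5, 0.2, 0.2)])

    def test_antichain_property(self, rng):
        boxes = [random_box(rng, confidence=True) for _ in range(20)]
        kept = class_agnostic_nms(boxes, 0.5)
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert iou(a, b) <= 0.5

    def test_matches_bruteforce_oracle(self):
        for trial in range(200):
            rng = np.random.default_rng(trial)
            n = int(rng.integers(1, 9))
            boxes = [random_box(rng, confidence=True) for _ in range(n)]
            thr = float(rng.uniform(0.2, 0.8))
            assert class_agnostic_nms(boxes, thr) == nms_oracle(boxes, thr)


class TestFilterConfidence:
    def test_threshold_zero_keeps_all(self):
        boxes = [box(0.5, 0.5, 0.2, 0.2, conf=c) for c in (0.05, 0.5)]
        assert filter_confidence(boxes, 0.0) == boxes

    def test_all_below(self):
        assert filter_confidence([box(0.5, 0.5, 0.2, 0.2, conf=0.01)], 0.1) == []

    def test_boundary_inclusive(self):
        boxes = [box(0.5, 0.5, 0.2, 0.2, conf=c) for c in (0.05, 0.1, 0.5)]
        assert len(filter_confidence(boxes, 0.1)) == 2

    def test_monotone_in_threshold(self, rng):
        boxes = [random_box(rng, confidence=True) for _ in range(30)]
        sizes = [len(filter_confidence(boxes, t)) for t in np.linspace(0, 1, 11)]
        assert sizes == sorted(sizes, reverse=True)


class TestMatchToGold:
    def test_identical_lists_all_paired(self, rng):
        gold = [random_box(rng) for _ in range(5)]
        res = match_to_gold(list(gold), gold)
        assert len(res.pairs) == 5
        assert not res.unmatched_candidates and not res.unmatched_gold

    def test_empty_candidates(self, rng):
        gold = [random_box(rng) for _ in range(3)]
        res = match_to_gold([], gold)
        assert res.unmatched_gold == gold

    def test_class_blind(self):
        cand = [box(0.5, 0.5, 0.2, 0.2, cls=4)]
        gold = [box(0.5, 0.5, 0.2, 0.2, cls=1)]
        assert len(match_to_gold(cand, gold).pairs) == 1

    def test_pairs_meet_threshold(self, rng):
        cands = [random_box(rng) for _ in range(6)]
        gold = [random_box(rng) for _ in range(6)]
        res = match_to_gold(cands, gold, 0.3)
        assert all(v >= 0.3 for _, _, v in res.pairs)

    def test_matches_bruteforce_oracle(self):
        for trial in range(200):
            rng = np.random.default_rng(10_000 + trial)
            cands = [random_box(rng) for _ in range(int(rng.integers(0, 9)))]
            gold = [random_box(rng) for _ in range(int(rng.integers(0, 9)))]
            thr = float(rng.uniform(0.2, 0.6))
            res = match_to_gold(cands, gold, thr)
            got = sorted(
                (cands.index(c), gold.index(g)) for c, g, _ in res.pairs
            )
            assert got == match_oracle(cands, gold, thr)


class TestConfusion:
    def test_perfect_annotator_diagonal(self, rng):
        matches = []
        for _ in range(10):
            gold = [random_box(rng) for _ in range(3)]
            matches.append(match_to_gold(list(gold), gold))
        cm = confusion(matches, CLASS_NAMES)
        assert np.array_equal(cm.counts, np.diag(np.diag(cm.counts)))
        assert cm.counts[:6, :6].sum() == 30

    def test_single_offdiagonal_cell(self):
        cand = [box(0.5, 0.5, 0.2, 0.2, cls=2)]  # called 4A
        gold = [box(0.5, 0.5, 0.2, 0.2, cls=3)]  # truly 4B
        cm = confusion([match_to_gold(cand, gold)], CLASS_NAMES)
        assert cm.counts[2, 3] == 1
        assert cm.counts.sum() == 1

    def test_background_row_and_column(self):
        res = MatchResult(
            pairs=[],
            unmatched_candidates=[box(0.5, 0.5, 0.2, 0.2, cls=1)],
            unmatched_gold=[box(0.2, 0.2, 0.1, 0.1, cls=4)],
        )
        cm = confusion([res], CLASS_NAMES)
        assert cm.counts[1, 6] == 1  # false detection
        assert cm.counts[6, 4] == 1  # miss

    def test_conservation(self, rng):
        matches = []
        total = 0
        for _ in range(20):
            cands = [random_box(rng) for _ in range(int(rng.integers(0, 5)))]
            gold = [random_box(rng) for _ in range(int(rng.integers(0, 5)))]
            m = match_to_gold(cands, gold)
            total += len(m.pairs) + len(m.unmatched_candidates) + len(m.unmatched_gold)
            matches.append(m)
        cm = confusion(matches, CLASS_NAMES)
        assert cm.counts.sum() == total
        # column sums over gold classes equal per-class gold totals
        gold_totals = np.zeros(6, dtype=int)
        for m in matches:
            for _, g, _ in m.pairs:
                gold_totals[g.class_id] += 1
            for g in m.unmatched_gold:
                gold_totals[g.class_id] += 1
        assert np.array_equal(cm.counts[:, :6].sum(axis=0), gold_totals)

    def test_proportions_columns_sum_to_one(self, rng):
        gold = [random_box(rng) for _ in range(20)]
        cm = confusion([match_to_gold(list(gold), gold)], CLASS_NAMES)
        sums = cm.proportions.sum(axis=0)
        totals = cm.counts.sum(axis=0)
        for s, t in zip(sums, totals):
            assert s == pytest.approx(1.0 if t > 0 else 0.0)


class TestAccuracy:
    def test_diagonal_all_ones(self):
        counts = np.zeros((7, 7), dtype=int)
        np.fill_diagonal(counts[:6, :6], 5)
        from usaug.annot_eval import ConfusionMatrix

        per_class, overall = accuracy(ConfusionMatrix(counts, CLASS_NAMES))
        assert overall == 1.0
        assert all(v == 1.0 for v in per_class.values())

    def test_printed_toy(self):
        # gold {A:8, B:2}, correct {A:7, B:0} -> per-class {0.875, 0}, overall 0.7
        from usaug.annot_eval import ConfusionMatrix

        counts = np.zeros((3, 3), dtype=int)
        counts[0, 0] = 7
        counts[1, 0] = 1
        counts[0, 1] = 2
        per_class, overall = accuracy(ConfusionMatrix(counts, ["A", "B"]))
        assert per_class["A"] == pytest.approx(0.875)
        assert per_class["B"] == 0.0
        assert overall == pytest.approx(0.7)

    def test_overall_is_weighted_mean(self, rng):
        from usaug.annot_eval import ConfusionMatrix

        counts = rng.integers(0, 20, size=(7, 7))
        counts[:, 6] = 0  # keep it simple: no false detections
        cm = ConfusionMatrix(counts, CLASS_NAMES)
        per_class, overall = accuracy(cm)
        gold_totals = cm.counts[:, :6].sum(axis=0)
        weighted = sum(
            per_class[n] * gold_totals[i]
            for i, n in enumerate(CLASS_NAMES)
            if gold_totals[i] > 0
        ) / gold_totals.sum()
        assert overall == pytest.approx(weighted)

    def test_empty_gold_raises(self):
        from usaug.annot_eval import ConfusionMatrix

        with pytest.raises(ValueError):
            accuracy(ConfusionMatrix(np.zeros((7, 7), dtype=int), CLASS_NAMES))


class TestMeanAveragePrecision:
    def test_perfect_detector(self, rng):
        gold = [[random_box(rng) for _ in range(3)] for _ in range(4)]
        cands = [
            [dataclasses.replace(b, confidence=0.9) for b in boxes] for boxes in gold
        ]
        _, map50, map50_95 = mean_average_precision(cands, gold)
        assert map50 == pytest.approx(1.0)
        assert map50_95 == pytest.approx(1.0)

    def test_no_detections(self, rng):
        gold = [[random_box(rng)] for _ in range(3)]
        _, map50, map50_95 = mean_average_precision([[], [], []], gold)
        assert map50 == 0.0 and map50_95 == 0.0

    def test_toy_ap_hand_enumerated(self):
        # one class, one image, 3 gold; detections ranked TP, FP, TP:
        # PR points (1/3, 1), (1/3, 1/2), (2/3, 2/3); all-points AP =
        # 1/3 * 1 + 1/3 * 2/3 = 5/9
        gold = [[box(0.2, 0.2, 0.1, 0.1), box(0.5, 0.5, 0.1, 0.1),
                 box(0.8, 0.8, 0.1, 0.1)]]
        cands = [[
            box(0.2, 0.2, 0.1, 0.1, conf=0.9),
            box(0.2, 0.8, 0.1, 0.1, conf=0.8),  # false positive
            box(0.5, 0.5, 0.1, 0.1, conf=0.7),
        ]]
        per_thr, map50, _ = mean_average_precision(cands, gold, iou_thresholds=(0.5,))
        assert map50 == pytest.approx(5 / 9)

    def test_monotone_in_iou_threshold(self, rng):
        gold = [[random_box(rng) for _ in range(4)] for _ in range(5)]
        cands = [
            [
                dataclasses.replace(
                    b,
                    cx=min(max(b.cx + rng.normal(0, 0.01), b.w / 2), 1 - b.w / 2),
                    confidence=float(rng.uniform(0.2, 1.0)),
                )
                for b in boxes
            ]
            for boxes in gold
        ]
        per_thr, _, _ = mean_average_precision(cands, gold)
        vals = [per_thr[t] for t in sorted(per_thr)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_invariant_under_reordering(self, rng):
        gold = [[random_box(rng) for _ in range(3)] for _ in range(4)]
        cands = [
            [dataclasses.replace(b, confidence=float(rng.uniform(0.1, 1)))
             for b in boxes]
            for boxes in gold
        ]
        _, m1, c1 = mean_average_precision(cands, gold)
        shuffled = [list(reversed(boxes)) for boxes in cands]
        _, m2, c2 = mean_average_precision(shuffled, gold)
        assert m1 == pytest.approx(m2)
        assert c1 == pytest.approx(c2)
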