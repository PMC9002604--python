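"""Detection metrics against hand geometry and brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trusscast.boxes import Box, InvalidBoxError, read_darknet, write_darknet
from trusscast.detect_eval import (
    MatchCounts,
    average_precision,
    evaluate_detections,
    iou,
    match_boxes,
    mean_ap,
    precision_recall_f1,
)

# ---------------------------------------------------------------- oracles


def oracle_max_tp(preds, gts, thresh=0.5):
    """Maximum number of one-to-one pairs with IoU >= thresh, by
    exhaustive enumeration of assignments."""
    best = 0
    for k in range(min(len(preds), len(gts)), -1, -1):
        for psub in itertools.combinations(range(len(preds)), k):
            for gperm in itertools.permutations(range(len(gts)), k):
                if all(iou(preds[p], gts[g]) >= thresh for p, g in zip(psub, gperm)):
                    return k
    return best


def oracle_ap(preds, gts, thresh=0.5):
    """AP by exhaustive enumeration of every distinct score cutoff,
    with the assignment oracle at each cutoff and right-monotonized
    precision (all-point interpolation)."""
    if not gts or not preds:
        return 0.0
    cutoffs = sorted({p.score for p in preds}, reverse=True)
    recalls, precisions = [0.0], [0.0]
    for th in cutoffs:
        kept = [p for p in preds if p.score >= th]
        tp = oracle_max_tp(kept, gts, thresh)
        precisions.append(tp / len(kept))
        recalls.append(tp / len(gts))
    precisions = np.maximum.accumulate(np.asarray(precisions)[::-1])[::-1]
    return float(np.sum(np.diff(recalls) * precisions[1:]))


def random_instance(rng, max_boxes=8):
    def boxes(k):
        return [
            Box(
                rng.uniform(0, 4),
                rng.uniform(0, 4),
                rng.uniform(0.5, 3),
                rng.uniform(0.5, 3),
                score=float(rng.random()),
            )
            for _ in range(k)
        ]

    return boxes(int(rng.integers(0, max_boxes + 1))), boxes(int(rng.integers(0, max_boxes + 1)))


# ---------------------------------------------------------------- iou


def test_iou_identity_and_disjoint():
    a = Box(1, 1, 2, 2)
    assert iou(a, a) == 1.0
    assert iou(Box(0.5, 0.5, 1, 1), Box(5.5, 5.5, 1, 1)) == 0.0


def test_iou_hand_geometry():
    # unit-offset squares: intersection 2, union 6
    assert iou(Box(1, 1, 2, 2), Box(2, 1, 2, 2)) == pytest.approx(1 / 3)


def test_invalid_box_rejected():
    with pytest.raises(InvalidBoxError):
        Box(0, 0, 0, 1)
    with pytest.raises(InvalidBoxError):
        Box(0, 0, 1, 1, score=1.5)


@given(
    st.tuples(
        *[st.floats(-5, 5) for _ in range(2)],
        *[st.floats(0.01, 5) for _ in range(2)],
        *[st.floats(-5, 5) for _ in range(2)],
        *[st.floats(0.01, 5) for _ in range(2)],
    )
)
def test_iou_symmetric_and_bounded(vals):
    a = Box(vals[0], vals[1], vals[2], vals[3])
    b = Box(vals[4], vals[5], vals[6], vals[7])
    v = iou(a, b)
    assert 0.0 <= v <= 1.0
    assert v == pytest.approx(iou(b, a))


# ---------------------------------------------------------------- matching


def test_match_exact_and_threshold_rule():
    g = Box(1, 1, 2, 2)
    counts, pairs = match_boxes([g], [g])
    assert (counts.tp, counts.fp, counts.fn) == (1, 0, 0)
    # IoU 1/3 < 0.5 -> not a true positive
    counts, _ = match_boxes([Box(2, 1, 2, 2)], [g])
    assert (counts.tp, counts.fp, counts.fn) == (0, 1, 1)
    # boundary: a box half-covered by a double-height box has IoU exactly 0.5
    counts, _ = match_boxes([Box(0.5, 1.0, 1, 2)], [Box(0.5, 0.5, 1, 1)], iou_thresh=0.5)
    assert counts.tp == 1


def test_match_counts_conserved(rng):
    for _ in range(100):
        preds, gts = random_instance(rng, max_boxes=6)
        c, _ = match_boxes(preds, gts)
        assert c.tp + c.fp == len(preds)
        assert c.tp + c.fn == len(gts)


def test_match_agrees_with_assignment_oracle(rng):
    for _ in range(200):
        preds, gts = random_instance(rng, max_boxes=5)
        c, _ = match_boxes(preds, gts)
        assert c.tp == oracle_max_tp(preds, gts)


def test_raising_threshold_never_increases_tp(rng):
    for _ in range(50):
        preds, gts = random_instance(rng, max_boxes=6)
        tps = [match_boxes(preds, gts, th)[0].tp for th in (0.3, 0.5, 0.7, 0.9)]
        assert tps == sorted(tps, reverse=True)


# ---------------------------------------------------------------- P/R/F1


@pytest.mark.parametrize(
    "tp,fp,fn,expected",
    [
        (10, 0, 0, (1.0, 1.0, 1.0)),
        (3, 1, 2, (0.75, 0.60, 2 * 0.75 * 0.6 / 1.35)),
        (0, 0, 0, (0.0, 0.0, 0.0)),
        (0, 5, 3, (0.0, 0.0, 0.0)),
    ],
)
def test_precision_recall_f1(tp, fp, fn, expected):
    p, r, f1 = precision_recall_f1(MatchCounts(tp, fp, fn))
    assert (p, r, f1) == pytest.approx(expected)


@given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
def test_f1_below_arithmetic_mean(tp, fp, fn):
    p, r, f1 = precision_recall_f1(MatchCounts(tp, fp, fn))
    assert f1 <= (p + r) / 2 + 1e-12


# ---------------------------------------------------------------- AP / mAP


def test_ap_perfect_detector():
    gts = [Box(i * 3, 0, 2, 2) for i in range(4)]
    preds = [Box(i * 3, 0, 2, 2, score=0.9 - 0.1 * i) for i in range(4)]
    assert average_precision(preds, gts) == pytest.approx(1.0)


def test_ap_empty_inputs_warns_zero():
    with pytest.warns(UserWarning):
        assert average_precision([], []) == 0.0


def test_ap_matches_cutoff_oracle(rng):
    for _ in range(200):
        preds, gts = random_instance(rng, max_boxes=8)
        got = average_precision(preds, gts) if (preds and gts) else None
        if got is None:
            continue
        assert got == pytest.approx(oracle_ap(preds, gts), abs=1e-9)


def test_mean_ap():
    assert mean_ap({"flower": 0.9, "fruit": 0.9}) == pytest.approx(0.9)
    assert mean_ap({"flower": 1.0, "fruit": 0.5}) == pytest.approx(0.75)
    assert mean_ap({"flower": 0.42}) == pytest.approx(0.42)
    with pytest.raises(ValueError):
        mean_ap({})


def test_evaluate_detections_report():
    gts = [Box(0, 0, 2, 2, cls="bloomed_flower"), Box(5, 5, 2, 2, cls="immature_fruit")]
    preds = [
        Box(0, 0, 2, 2, cls="bloomed_flower", score=0.9),
        Box(5.1, 5, 2, 2, cls="immature_fruit", score=0.8),
    ]
    rep = evaluate_detections(preds, gts)
    assert rep.map_value == pytest.approx(np.mean(list(rep.per_class_ap.values())))
    assert rep.f1 == pytest.approx(1.0)
    assert 0.9 < rep.avg_iou <= 1.0


# ---------------------------------------------------------------- darknet IO


def test_darknet_round_trip(tmp_path, rng):
    boxes = [
        Box(
            float(rng.uniform(0.2, 0.8)),
            float(rng.uniform(0.2, 0.8)),
            float(rng.uniform(0.05, 0.3)),
            float(rng.uniform(0.05, 0.3)),
            cls="bloomed_flower" if rng.random() < 0.5 else "immature_fruit",
            score=float(rng.random()),
        )
        for _ in range(10)
    ]
    path = tmp_path / "ann.txt"
    write_darknet(boxes, path)
    back = read_darknet(path)
    assert len(back) == len(boxes)
    for a, b in zip(boxes, back):
        assert a.cls == b.cls
        assert a.cx == pytest.approx(b.cx, abs=1e-6)
        assert a.score == pytest.approx(b.score, abs=1e-6)
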