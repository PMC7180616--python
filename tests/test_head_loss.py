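"""Decode/encode, target assignment and the five-term loss."""

import math

import numpy as np
import pytest

from circdet.anchors import AnchorSet, concentric_iou
from circdet.geometry import CircleBox
from circdet.head_loss import (
    DEFAULT_STRIDES,
    HeadOutput,
    TargetTensor,
    assign_targets,
    decode,
    encode,
    total_loss,
    total_loss_grad,
)
from circdet.synthetic import GroundTruth

NINE_ANCHORS = AnchorSet(
    "circle",
    np.array([4.0, 6.0, 9.0, 12.0, 16.0, 20.0, 26.0, 34.0, 44.0]),
    ((0, 1, 2), (3, 4, 5), (6, 7, 8)),
)


def test_decode_cell_offsets_and_prior_scaling():
    S, stride = 13, 32
    head = HeadOutput.zeros(S, 1)
    dets = decode(head, np.array([10.0]), image_size=S * stride)
    assert len(dets) == S * S
    # tx = ty = 0 puts the center at cell + 0.5; cell (row 4, col 3)
    d = dets[4 * S + 3]
    assert (d.box.cx, d.box.cy) == pytest.approx((3.5 * 32, 4.5 * 32))
    assert d.box.r == pytest.approx(10.0)  # e^0 = 1
    assert d.confidence == pytest.approx(0.5)


def test_decode_radius_exponential():
    head = HeadOutput.zeros(1, 1)
    head.t_r[0, 0, 0] = math.log(2.0)
    (d,) = decode(head, np.array([10.0]), image_size=32)
    assert d.box.r == pytest.approx(20.0)


def test_decode_anchor_count_mismatch():
    head = HeadOutput.zeros(2, 2)
    with pytest.raises(ValueError):
        decode(head, np.array([10.0]), image_size=64)


def test_encode_fixed_point_and_radius():
    # gt at the cell center with r = anchor encodes to (0, 0, 0)
    gt = CircleBox(3.5 * 32, 4.5 * 32, 10.0)
    tx, ty, tr = encode(gt, 10.0, cell=(4, 3), stride=32)
    assert (tx, ty, tr) == pytest.approx((0.0, 0.0, 0.0), abs=1e-9)
    # r = 2 * anchor forces tr = ln 2
    assert encode(CircleBox(112, 144, 20.0), 10.0, (4, 3), 32)[2] == pytest.approx(math.log(2))


def test_encode_decode_round_trip(rng):
    S, stride = 13, 32
    for _ in range(1000):
        col, row = int(rng.integers(S)), int(rng.integers(S))
        gt = CircleBox(
            (col + float(rng.uniform(0.001, 0.999))) * stride,
            (row + float(rng.uniform(0.001, 0.999))) * stride,
            float(rng.uniform(2, 80)),
        )
        pr = float(rng.uniform(2, 50))
        tx, ty, tr = encode(gt, pr, (row, col), stride)
        head = HeadOutput.zeros(S, 1)
        head.t_x[row, col, 0] = tx
        head.t_y[row, col, 0] = ty
        head.t_r[row, col, 0] = tr
        d = decode(head, np.array([pr]), image_size=S * stride)[row * S + col]
        assert d.box.cx == pytest.approx(gt.cx, rel=1e-9, abs=1e-9)
        assert d.box.cy == pytest.approx(gt.cy, rel=1e-9, abs=1e-9)
        assert d.box.r == pytest.approx(gt.r, rel=1e-9)


def test_encode_nudges_cell_edge():
    gt = CircleBox(4 * 32.0, 2 * 32.0, 10.0)  # exactly on the cell corner
    tx, ty, _ = encode(gt, 10.0, (2, 4), 32)
    assert math.isfinite(tx) and math.isfinite(ty)


def test_assign_targets_conservation_and_anchor_choice():
    gts = [GroundTruth(CircleBox(100.0, 150.0, 16.0))]
    targets = assign_targets(gts, NINE_ANCHORS, image_size=416)
    total_obj = sum(t.obj_mask.sum() for t in targets)
    assert total_obj == 1
    # radius 16 has IoU 1 with anchor index 4, which lives on scale 1 (stride 16)
    t = targets[1]
    row, col = int(150 // 16), int(100 // 16)
    assert t.obj_mask[row, col, 1] == 1
    assert t.noobj_mask[row, col, 1] == 0
    assert t.r[row, col, 1] == pytest.approx(16.0)
    assert t.conf[row, col, 1] == 1.0
    # every other slot across all scales is noobj
    assert sum(t.noobj_mask.sum() for t in targets) == sum(t.obj_mask.size for t in targets) - 1


def test_assign_targets_matches_argmax_oracle(rng):
    gts = [
        GroundTruth(CircleBox(float(rng.uniform(5, 410)), float(rng.uniform(5, 410)),
                              float(rng.uniform(3, 50))))
        for _ in range(20)
    ]
    targets = assign_targets(gts, NINE_ANCHORS, image_size=416)
    for gt in gts:
        ious = [concentric_iou(gt.box.r, a, "circle") for a in NINE_ANCHORS.dims]
        best = int(np.argmax(ious))
        scale = best // 3
        stride = DEFAULT_STRIDES[scale]
        row, col = int(gt.box.cy // stride), int(gt.box.cx // stride)
        assert targets[scale].obj_mask[row, col, best % 3] == 1


def test_assign_targets_collision_last_wins(caplog):
    a = GroundTruth(CircleBox(100.0, 100.0, 16.0))
    b = GroundTruth(CircleBox(101.0, 101.0, 16.5))  # same cell, same best anchor
    with caplog.at_level("WARNING"):
        targets = assign_targets([a, b], NINE_ANCHORS, image_size=416)
    assert "collision" in caplog.text
    t = targets[1]
    row, col = int(101 // 16), int(101 // 16)
    assert t.obj_mask.sum() == 1
    assert t.r[row, col, 1] == pytest.approx(16.5)  # the later ground truth won


def test_perfect_prediction_loss_vanishes():
    S, stride = 4, 32
    gt = GroundTruth(CircleBox(70.0, 40.0, 12.0))
    anchors = AnchorSet("circle", np.array([12.0]), ((0,), (), ()))
    targets = assign_targets([gt], anchors, image_size=S * stride, strides=(stride,))
    t = targets[0]
    head = HeadOutput.zeros(S, 1)
    big = 30.0  # sigmoid(30) is 1 within 1e-13
    row, col = int(40 // 32), int(70 // 32)
    tx, ty, tr = encode(gt.box, 12.0, (row, col), stride)
    head.t_x[row, col, 0] = tx
    head.t_y[row, col, 0] = ty
    head.t_r[row, col, 0] = tr
    head.t_conf[...] = -big
    head.t_conf[row, col, 0] = big
    head.t_class[row, col, 0, 0] = big
    lb = total_loss(head, t, [np.array([12.0])])
    assert lb.total <= 1e-5 * S * S


def test_loss_worked_examples():
    """Hand-evaluated single-slot losses.

    One object slot, center off by one grid unit, radius exact, predicted
    confidence 0.5.  With a single class score at 0.5 (target 1) the loss is
    5 + 2 ln 2; with two class scores at 0.5 (targets 1 and 0) both halves
    of the class cross-entropy fire and the loss is 5 + 3 ln 2.
    """
    for n_classes, want in ((1, 5 + 2 * math.log(2)), (2, 5 + 3 * math.log(2))):
        head = HeadOutput.zeros(1, 1, n_classes=n_classes)
        t = TargetTensor.empty(1, 1, n_classes=n_classes)
        t.obj_mask[0, 0, 0] = 1
        t.noobj_mask[0, 0, 0] = 0
        t.x[0, 0, 0] = 1.5   # decoded x is 0.5 -> error 1 grid unit
        t.y[0, 0, 0] = 0.5
        t.r[0, 0, 0] = 10.0
        t.conf[0, 0, 0] = 1.0
        t.class_probs[0, 0, 0, 0] = 1.0
        lb = total_loss(head, t, [np.array([10.0])])
        assert lb.total == pytest.approx(want, abs=1e-6)
        assert lb.coord_xy == pytest.approx(1.0)
        assert lb.conf_obj == pytest.approx(math.log(2))


def test_lambda_coord_scales_coordinate_terms_only():
    head = HeadOutput.zeros(2, 1)
    head.t_x[...] = 0.3
    t = TargetTensor.empty(2, 1)
    t.obj_mask[0, 1, 0] = 1
    t.noobj_mask[0, 1, 0] = 0
    t.x[0, 1, 0] = 0.2
    t.r[0, 1, 0] = 7.0
    t.conf[0, 1, 0] = 1.0
    t.class_probs[0, 1, 0, 0] = 1.0
    lb1 = total_loss(head, t, [np.array([10.0])], lambda_coord=5.0)
    lb2 = total_loss(head, t, [np.array([10.0])], lambda_coord=10.0)
    assert lb2.total - lb1.total == pytest.approx(5.0 * (lb1.coord_xy + lb1.coord_r))
    assert lb1.conf_obj == lb2.conf_obj
    assert lb1.class_term == lb2.class_term


def test_loss_components_non_negative(rng):
    head = HeadOutput.zeros(4, 3)
    for name in ("t_x", "t_y", "t_r", "t_conf"):
        getattr(head, name)[...] = rng.normal(0, 1, (4, 4, 3))
    head.t_class[...] = rng.normal(0, 1, (4, 4, 3, 1))
    t = TargetTensor.empty(4, 3)
    t.obj_mask[1, 2, 0] = 1
    t.noobj_mask[1, 2, 0] = 0
    t.x[1, 2, 0], t.y[1, 2, 0], t.r[1, 2, 0] = 2.3, 1.6, 12.0
    t.conf[1, 2, 0] = 1.0
    t.class_probs[1, 2, 0, 0] = 1.0
    lb = total_loss(head, t, [np.array([8.0, 12.0, 20.0])])
    for comp in (lb.coord_xy, lb.coord_r, lb.conf_obj, lb.conf_noobj, lb.class_term):
        assert comp >= 0.0
    assert lb.total > 0


def test_nan_head_rejected():
    head = HeadOutput.zeros(2, 1)
    with pytest.raises(ValueError):
        HeadOutput(2, 1, head.t_x * np.nan, head.t_y, head.t_r, head.t_conf, head.t_class)


def test_gradient_matches_finite_differences(rng):
    S, B = 3, 2
    head = HeadOutput.zeros(S, B)
    head.t_x[...] = rng.normal(0, 0.8, (S, S, B))
    head.t_y[...] = rng.normal(0, 0.8, (S, S, B))
    head.t_r[...] = rng.normal(0, 0.4, (S, S, B))
    head.t_conf[...] = rng.normal(0, 1.0, (S, S, B))
    head.t_class[...] = rng.normal(0, 1.0, (S, S, B, 1))
    t = TargetTensor.empty(S, B)
    for row, col, b in [(0, 1, 0), (2, 2, 1)]:
        t.obj_mask[row, col, b] = 1
        t.noobj_mask[row, col, b] = 0
        t.x[row, col, b] = col + 0.4
        t.y[row, col, b] = row + 0.7
        t.r[row, col, b] = 15.0
        t.conf[row, col, b] = 1.0
        t.class_probs[row, col, b, 0] = 1.0
    prior = [np.array([10.0, 20.0])]
    grads = total_loss_grad(head, t, prior)[0]
    h = 1e-6
    for name in ("t_x", "t_y", "t_r", "t_conf", "t_class"):
        arr = getattr(head, name)
        for idx in [(0, 1, 0), (2, 2, 1), (1, 1, 0)]:
            full_idx = idx + (0,) if name == "t_class" else idx
            orig = arr[full_idx]
            arr[full_idx] = orig + h
            up = total_loss(head, t, prior).total
            arr[full_idx] = orig - h
            down = total_loss(head, t, prior).total
            arr[full_idx] = orig
            fd = (up - down) / (2 * h)
            an = grads[name][full_idx]
            assert an == pytest.approx(fd, rel=1e-4, abs=1e-7), (name, idx)
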