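"""Matching, PR/F1, interpolated AP and the Wilcoxon protocol."""

import numpy as np
import pytest
import scipy.stats

from circdet.geometry import CircleBox, RectBox
from circdet.metrics import (
    average_precision,
    detector_ap,
    match_detections,
    pooled_pr_curve,
    pr_curve,
    prf_at_threshold,
    subsample_ap,
    wilcoxon_signed_rank,
)
from circdet.nms import Detection
from conftest import brute_force_match, enumerate_ap


def det(cx, cy, r, conf):
    return Detection(CircleBox(cx, cy, r), conf)


def far_apart_gts(n, r=10.0, spacing=100.0):
    return [CircleBox(i * spacing, 0.0, r) for i in range(n)]


def test_perfect_match():
    gts = far_apart_gts(4)
    dets = [det(g.cx, g.cy, g.r, 1.0) for g in gts]
    m = match_detections(dets, gts, 0.5)
    assert (m.tp, m.fp, m.fn) == (4, 0, 0)
    assert all(m.labels)


def test_partial_match_counts():
    gts = far_apart_gts(3)
    dets = [det(0, 0, 10, 0.9), det(100, 0, 10, 0.8), det(500, 500, 10, 0.7)]
    m = match_detections(dets, gts, 0.5)
    assert (m.tp, m.fp, m.fn) == (2, 1, 1)


def test_each_gt_claimed_once():
    gts = [CircleBox(0, 0, 10)]
    dets = [det(0, 0, 10, 0.9), det(0.5, 0, 10, 0.8)]
    m = match_detections(dets, gts, 0.5)
    assert (m.tp, m.fp, m.fn) == (1, 1, 0)


def test_match_counts_identities_and_oracle(rng):
    for _ in range(100):
        n_gt, n_det = int(rng.integers(0, 12)), int(rng.integers(0, 15))
        gts = [
            CircleBox(float(rng.uniform(0, 120)), float(rng.uniform(0, 120)),
                      float(rng.uniform(4, 15)))
            for _ in range(n_gt)
        ]
        dets = [
            det(float(rng.uniform(0, 120)), float(rng.uniform(0, 120)),
                float(rng.uniform(4, 15)), round(float(rng.uniform(0, 1)), 3))
            for _ in range(n_det)
        ]
        m = match_detections(dets, gts, 0.5)
        assert m.tp + m.fn == n_gt
        assert m.tp + m.fp == n_det
        tp, fp, fn, labels = brute_force_match(dets, gts, 0.5)
        assert (m.tp, m.fp, m.fn) == (tp, fp, fn)
        assert list(m.labels) == labels


def test_mixed_geometry_rejected():
    with pytest.raises(TypeError):
        match_detections([det(0, 0, 1, 0.5)], [RectBox(0, 0, 2, 2)], 0.5)


def test_prf_arithmetic():
    gts = far_apart_gts(3)
    dets = [det(0, 0, 10, 0.9), det(100, 0, 10, 0.8), det(500, 500, 10, 0.7)]
    recall, precision, f1 = prf_at_threshold(dets, gts, conf_thresh=0.0)
    assert recall == pytest.approx(2 / 3)
    assert precision == pytest.approx(2 / 3)
    assert f1 == pytest.approx(2 / 3)


def test_prf_no_detections_above_threshold():
    gts = far_apart_gts(2)
    dets = [det(0, 0, 10, 0.3)]
    recall, precision, f1 = prf_at_threshold(dets, gts, conf_thresh=0.8)
    assert (recall, precision, f1) == (0.0, 0.0, 0.0)


def test_prf_no_gts_raises():
    with pytest.raises(ValueError):
        prf_at_threshold([det(0, 0, 1, 0.9)], [], 0.5)


def test_ap_perfect_detector():
    gts = far_apart_gts(5)
    dets = [det(g.cx, g.cy, g.r, 1.0 - 0.01 * i) for i, g in enumerate(gts)]
    assert detector_ap(dets, gts) == pytest.approx(1.0)


def test_ap_single_tp():
    gts = [CircleBox(0, 0, 10)]
    assert detector_ap([det(0, 0, 10, 0.9)], gts) == pytest.approx(1.0)


def test_ap_worked_example():
    # 2 GT; dets: conf .9 TP, conf .8 FP, conf .7 TP
    gts = far_apart_gts(2)
    dets = [det(0, 0, 10, 0.9), det(500, 500, 10, 0.8), det(100, 0, 10, 0.7)]
    curve = pr_curve(dets, gts)
    assert list(zip(curve.recalls, curve.precisions)) == [
        (0.5, 1.0), (0.5, 0.5), (1.0, pytest.approx(2 / 3)),
    ]
    assert average_precision(curve) == pytest.approx(5 / 6)
    assert enumerate_ap(dets, gts) == pytest.approx(5 / 6)


def test_ap_equals_exhaustive_enumeration_on_all_small_lists(rng):
    # all detection lists of size <= 6 against 2-3 ground truths
    gts3 = far_apart_gts(3)
    positions = [(0, 0), (100, 0), (200, 0), (500, 500), (600, 600), (700, 700)]
    for n_det in range(1, 7):
        for _ in range(30):
            idx = rng.choice(len(positions), n_det, replace=False)
            confs = rng.uniform(0.1, 1.0, n_det).round(2)
            dets = [det(*positions[i], 10, c) for i, c in zip(idx, confs)]
            n_gt = int(rng.integers(2, 4))
            gts = gts3[:n_gt]
            assert detector_ap(dets, gts) == pytest.approx(enumerate_ap(dets, gts), abs=1e-12)


def test_ap_invariant_to_monotone_confidence_rescaling(rng):
    gts = far_apart_gts(4)
    dets = [det(0, 0, 10, 0.9), det(100, 0, 10, 0.6), det(900, 0, 10, 0.5), det(200, 0, 10, 0.4)]
    base = detector_ap(dets, gts)
    squashed = [Detection(d.box, d.confidence**2) for d in dets]
    assert detector_ap(squashed, gts) == pytest.approx(base)


def test_ap_envelope_monotone_and_bounds(rng):
    for _ in range(20):
        gts = far_apart_gts(int(rng.integers(2, 6)))
        dets = [
            det(float(rng.uniform(0, 600)), 0, 10, round(float(rng.uniform(0, 1)), 2))
            for _ in range(int(rng.integers(1, 10)))
        ]
        curve = pr_curve(dets, gts)
        ap = average_precision(curve)
        assert 0.0 <= ap <= 1.0
        rs = sorted(set(curve.recalls))
        envs = [curve.interpolated(r) for r in rs]
        assert all(e1 >= e2 - 1e-12 for e1, e2 in zip(envs, envs[1:]))


def test_lowest_confidence_additions():
    gts = far_apart_gts(3)
    dets = [det(0, 0, 10, 0.9), det(100, 0, 10, 0.8)]
    base = detector_ap(dets, gts)
    with_fp = dets + [det(900, 900, 10, 0.1)]
    assert detector_ap(with_fp, gts) <= base + 1e-12
    with_tp = dets + [det(200, 0, 10, 0.1)]
    assert detector_ap(with_tp, gts) >= base - 1e-12


def test_pooled_curve_matches_single_image_curve():
    gts = far_apart_gts(3)
    dets = [det(0, 0, 10, 0.9), det(500, 500, 10, 0.6), det(100, 0, 10, 0.5)]
    single = pr_curve(dets, gts)
    pooled = pooled_pr_curve({"img": dets}, {"img": gts})
    assert pooled == single


def test_subsample_ap_determinism_and_whole_set(rng):
    gts_by_image = {}
    dets_by_image = {}
    for i in range(90):
        gts = far_apart_gts(3)
        gts_by_image[f"im{i:03d}"] = gts
        dets_by_image[f"im{i:03d}"] = [det(g.cx, g.cy, g.r, 0.9) for g in gts[:2]]
    aps1 = subsample_ap(dets_by_image, gts_by_image, n_subsets=5, subset_size=80, seed=3)
    aps2 = subsample_ap(dets_by_image, gts_by_image, n_subsets=5, subset_size=80, seed=3)
    assert aps1 == aps2
    whole = subsample_ap(dets_by_image, gts_by_image, n_subsets=1, subset_size=90, seed=0)
    assert whole[0] == pytest.approx(
        average_precision(pooled_pr_curve(dets_by_image, gts_by_image))
    )
    with pytest.raises(ValueError):
        subsample_ap(dets_by_image, gts_by_image, subset_size=91)


def test_subsample_ap_spread_small_on_homogeneous_data(rng):
    gts_by_image, dets_by_image = {}, {}
    for i in range(120):
        gts = far_apart_gts(4)
        gts_by_image[i] = gts
        dets = [det(g.cx, g.cy, g.r, float(rng.uniform(0.6, 1.0))) for g in gts[:3]]
        dets.append(det(900, 900, 10, float(rng.uniform(0.05, 0.4))))
        dets_by_image[i] = dets
    aps = subsample_ap(dets_by_image, gts_by_image, n_subsets=30, subset_size=80, seed=0)
    q1, q3 = np.percentile(aps, [25, 75])
    assert q3 - q1 < 0.1


def test_wilcoxon_degenerate_equal_lists():
    res = wilcoxon_signed_rank([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
    assert res.p_value == 1.0
    assert res.degenerate


def test_wilcoxon_exact_all_positive_n6():
    a = [0.9, 0.91, 0.92, 0.93, 0.94, 0.95]
    b = [0.8, 0.82, 0.84, 0.86, 0.88, 0.89]
    res = wilcoxon_signed_rank(a, b)
    assert res.method == "exact"
    assert res.statistic == 21.0
    assert res.p_value == pytest.approx(2 / 64)


def test_wilcoxon_exact_matches_scipy(rng):
    for _ in range(20):
        n = int(rng.integers(5, 13))
        d = rng.normal(0.02, 0.05, n)
        d = np.where(d == 0, 0.01, d)
        a = 0.8 + np.zeros(n)
        b = a - d
        ours = wilcoxon_signed_rank(a, b)
        if len(np.unique(np.abs(d))) == n:  # scipy exact mode requires no ties
            ref = scipy.stats.wilcoxon(a, b, alternative="two-sided", method="exact")
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-10)


def test_wilcoxon_normal_approximation_near_exact_at_n12(rng):
    for _ in range(10):
        d = rng.normal(0.01, 0.03, 12)
        d = np.where(d == 0, 0.005, d)
        a = 0.85 + np.zeros(12)
        b = a - d
        exact = wilcoxon_signed_rank(a, b, exact_max_n=12)
        approx = wilcoxon_signed_rank(a, b, exact_max_n=0)
        assert exact.method == "exact" and approx.method == "normal"
        assert approx.p_value == pytest.approx(exact.p_value, abs=0.02)


def test_wilcoxon_input_validation():
    with pytest.raises(ValueError):
        wilcoxon_signed_rank([0.1, 0.2], [0.1])
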