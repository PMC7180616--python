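"""Recall/precision/F1 and interpolated average precision.

Two ground-truth fruits, three detections: a confident hit, a confident
false alarm, and a weaker hit.  The precision-recall sweep gives points
(0.5, 1), (0.5, 0.5), (1, 2/3); the interpolated envelope integrates to
AP = 5/6.
"""

from circdet import CircleBox, Detection, average_precision, pr_curve, prf_at_threshold

gts = [CircleBox(0, 0, 10), CircleBox(100, 0, 10)]
dets = [
    Detection(CircleBox(0, 0, 10), 0.9),        # true positive
    Detection(CircleBox(500, 500, 10), 0.8),    # false positive
    Detection(CircleBox(100, 0, 10), 0.7),      # true positive
]

recall, precision, f1 = prf_at_threshold(dets, gts, conf_thresh=0.0)
print(f"at conf 0.0: recall={recall:.3f} precision={precision:.3f} F1={f1:.3f}")
recall, precision, f1 = prf_at_threshold(dets, gts, conf_thresh=0.8)
print(f"at conf 0.8: recall={recall:.3f} precision={precision:.3f} F1={f1:.3f}")

curve = pr_curve(dets, gts, iou_thresh=0.5)
print("PR points:", list(zip(curve.recalls, [round(p, 3) for p in curve.precisions])))
print(f"AP = {average_precision(curve):.4f}  (5/6 = 0.8333)")
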