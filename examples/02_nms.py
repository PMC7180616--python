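"""Circular non-maximum suppression on a cluster of redundant detections.

Three detections sit on the same fruit, one sits elsewhere.  Greedy NMS
keeps the most confident detection of each group and removes everything
overlapping it at IoU >= 0.5.
"""

from circdet import CircleBox, Detection, nms

dets = [
    Detection(CircleBox(100, 100, 20), confidence=0.95),
    Detection(CircleBox(103, 101, 21), confidence=0.80),   # same fruit
    Detection(CircleBox(98, 99, 19), confidence=0.75),     # same fruit
    Detection(CircleBox(200, 200, 15), confidence=0.60),   # different fruit
]

kept = nms(dets, lambda_nms=0.5)
print(f"{len(dets)} detections in, {len(kept)} kept:")
for d in kept:
    print(f"  center=({d.box.cx:.0f}, {d.box.cy:.0f}) r={d.box.r:.0f} conf={d.confidence:.2f}")

# Prints 2 kept detections: the 0.95 one (its two overlapping rivals are
# suppressed) and the isolated 0.60 one.
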