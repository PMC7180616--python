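"""Circular-box decoding, target assignment, and the detection loss.

A ground-truth circle is encoded into raw head coordinates (tx, ty, tr),
decoded back, and the five-term loss is evaluated at the perfect
prediction and at a deliberately wrong one.
"""

import numpy as np

from circdet import (
    AnchorSet,
    CircleBox,
    GroundTruth,
    HeadOutput,
    assign_targets,
    decode,
    encode,
    total_loss,
)

anchors = AnchorSet(
    "circle",
    np.array([4.0, 6.0, 9.0, 12.0, 16.0, 20.0, 26.0, 34.0, 44.0]),
    ((0, 1, 2), (3, 4, 5), (6, 7, 8)),
)

gt = GroundTruth(CircleBox(100.0, 150.0, 17.0))
targets = assign_targets([gt], anchors, image_size=416)
for s, t in enumerate(targets):
    if t.obj_mask.sum():
        print(f"ground truth r=17 assigned to scale {s} "
              f"(stride {(8, 16, 32)[s]}), {int(t.obj_mask.sum())} object slot")

# encode/decode round trip on one slot
tx, ty, tr = encode(gt.box, anchor_radius=16.0, cell=(9, 6), stride=16)
head = HeadOutput.zeros(26, 1)
head.t_x[9, 6, 0], head.t_y[9, 6, 0], head.t_r[9, 6, 0] = tx, ty, tr
d = decode(head, np.array([16.0]), image_size=416)[9 * 26 + 6]
print(f"round trip: ({d.box.cx:.6f}, {d.box.cy:.6f}, r={d.box.r:.6f})  vs GT (100, 150, 17)")

# loss at a half-confident, one-grid-unit-off prediction
from circdet import TargetTensor

h = HeadOutput.zeros(1, 1)
t = TargetTensor.empty(1, 1)
t.obj_mask[0, 0, 0] = 1
t.noobj_mask[0, 0, 0] = 0
t.x[0, 0, 0], t.y[0, 0, 0], t.r[0, 0, 0] = 1.5, 0.5, 10.0
t.conf[0, 0, 0] = 1.0
t.class_probs[0, 0, 0, 0] = 1.0
lb = total_loss(h, t, [np.array([10.0])])
print(f"loss: coord_xy={lb.coord_xy:.3f} conf_obj={lb.conf_obj:.4f} "
      f"class={lb.class_term:.4f} total={lb.total:.4f}")

# Prints total 6.3863 = 5*(1 grid unit)^2 + ln 2 (confidence 0.5) + ln 2
# (class score 0.5); the round trip reproduces the ground truth exactly.
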