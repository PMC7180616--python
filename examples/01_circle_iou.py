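"""Exact circle-circle IoU across its three geometric regimes.

Two circles either miss each other, overlap in a lens, or one contains the
other.  The lens area has a closed form in the two chord half-angles; the
containment IoU collapses to the squared radius ratio.
"""

from circdet import CircleBox, circle_iou, circle_overlap_area

pairs = {
    "identical": (CircleBox(0, 0, 10), CircleBox(0, 0, 10)),
    "lens (unit circles, centers 1 apart)": (CircleBox(0, 0, 1), CircleBox(1, 0, 1)),
    "containment (r = R/2, concentric)": (CircleBox(0, 0, 2), CircleBox(0, 0, 1)),
    "tangent": (CircleBox(0, 0, 1), CircleBox(2, 0, 1)),
    "disjoint": (CircleBox(0, 0, 1), CircleBox(5, 0, 1)),
}

for name, (a, b) in pairs.items():
    print(f"{name:42s} overlap={circle_overlap_area(a, b):8.5f}  iou={circle_iou(a, b):.5f}")

# The lens pair prints overlap 1.22837 (= 2*pi/3 - sqrt(3)/2) and IoU 0.24301;
# the concentric pair prints IoU 0.25 = (1/2)^2, the squared radius ratio.
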