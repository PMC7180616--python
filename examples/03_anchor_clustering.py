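"""Prior-anchor clustering of ground-truth radii under IoU distance.

300 synthetic fruit radii drawn from three planted size groups are
clustered with k-means using 1 - IoU of concentric circles as the metric.
The average best IoU (mean over ground truths of the best anchor IoU)
rises monotonically with k and saturates — the curve used to pick k = 9.
"""

import numpy as np

from circdet import average_best_iou, kmeans_anchors

rng = np.random.default_rng(0)
radii = np.concatenate([rng.uniform(c - 1, c + 1, 100) for c in (6.0, 16.0, 38.0)])

anchors3, miou3 = kmeans_anchors(radii, k=3, seed=0, n_restarts=10)
print("k=3 anchors (px):", np.round(anchors3.dims, 2), f" mean best IoU {miou3:.3f}")

for k in (1, 3, 6, 9):
    _, miou = kmeans_anchors(radii, k=k, seed=0, n_restarts=10)
    print(f"k={k}: mean best IoU {miou:.3f}")

anchors9, _ = kmeans_anchors(radii, k=9, seed=0, n_restarts=10)
print("k=9 scale groups (fine to coarse):",
      [np.round(anchors9.dims_for_scale(s), 1).tolist() for s in range(3)])
print("recheck:", round(average_best_iou(radii, anchors9), 3))

# The k=3 anchors recover the planted 6/16/38 px groups to within a fraction
# of a pixel, and the mean best IoU climbs from ~0.5 at k=1 toward 1.
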