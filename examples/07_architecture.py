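"""Building and validating the dense detection backbone.

Five dense blocks of 6/12/24/16/16 layers, transitions between blocks,
and three detection branches pruned to two convolutions each.  The
validator checks the dense-connection counts (L(L+1)/2 per block), channel
sums at every concatenation, and the circular-head channel arithmetic
(3 anchors x (4 + 1 class) = 15 channels per scale).
"""

from circdet import build_graph, count_params, validate_graph
from circdet.architecture import dense_connection_count

g = build_graph(block_sizes=(6, 12, 24, 16, 16), growth_rate=32)
report = validate_graph(g)
print("validation passed:", report["passed"])
for bi, L in enumerate((6, 12, 24, 16, 16)):
    print(f"  block {bi}: {L} layers, {dense_connection_count(g, bi)} dense connections "
          f"(= {L}*{L + 1}/2)")
print("detect head channels per scale:", [d.out_channels for d in g.detect_nodes])
print(f"total parameters: {count_params(g):,}")

rect = build_graph(circular=False)
print("rect-head channels (5 numbers per anchor):",
      [d.out_channels for d in rect.detect_nodes])
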