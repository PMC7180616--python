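"""Declarative dense-backbone graph for the circular-box detector.

This module builds and validates the layer graph of a densely connected
YOLO-style backbone as pure bookkeeping — channel arithmetic, connectivity
and parameter counts — with no tensor execution.

The backbone stacks five dense blocks (6, 12, 24, 16 and 16 dense layers by
default), each dense layer being a 1x1 bottleneck convolution followed by a
3x3 convolution, with every layer consuming the concatenation of the block
input and all preceding layers' outputs (L(L+1)/2 direct feature
connections for L layers).  Transition layers between consecutive blocks
halve the channels and downsample by 2.  Three detection branches hang off
the last three blocks; each branch has exactly two convolutions before a
1x1 detect convolution whose output has n_anchors * (4 + n_classes)
channels — for a circular box there are four box-plus-confidence numbers
per anchor (tx, ty, tr, conf), one fewer than the rectangular five.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ArchNode",
    "ArchGraph",
    "DenseBlockSpec",
    "build_graph",
    "validate_graph",
    "count_params",
]

DEFAULT_BLOCK_SIZES = (6, 12, 24, 16, 16)


@dataclass
class ArchNode:
    name: str
    kind: str                   # conv | bottleneck | transition | concat | detect | upsample
    in_channels: int
    out_channels: int
    kernel: int = 1
    stride: int = 1
    batch_norm: bool = False
    inputs: list[str] = field(default_factory=list)


@dataclass
class DenseBlockSpec:
    n_layers: int
    growth_rate: int = 32
    bottleneck_width: int = 128  # channels of the 1x1 bottleneck (4 x growth by convention)

    def __post_init__(self) -> None:
        if self.n_layers < 1 or self.growth_rate <= 0 or self.bottleneck_width <= 0:
            raise ValueError("dense block sizes must be positive")


@dataclass
class ArchGraph:
    nodes: dict[str, ArchNode] = field(default_factory=dict)
    block_layer_counts: tuple[int, ...] = ()

    def add(self, node: ArchNode) -> ArchNode:
        if node.name in self.nodes:
            raise ValueError(f"duplicate node name {node.name!r}")
        for src in node.inputs:
            if src not in self.nodes:
                raise ValueError(f"node {node.name!r} references unknown input {src!r}")
        self.nodes[node.name] = node
        return node

    @property
    def detect_nodes(self) -> list[ArchNode]:
        return [n for n in self.nodes.values() if n.kind == "detect"]

    def predecessors(self, name: str) -> list[ArchNode]:
        return [self.nodes[s] for s in self.nodes[name].inputs]

    def to_dict(self) -> dict:
        return {
            "block_layer_counts": list(self.block_layer_counts),
            "nodes": [
                {
                    "name": n.name, "kind": n.kind, "in_channels": n.in_channels,
                    "out_channels": n.out_channels, "kernel": n.kernel,
                    "stride": n.stride, "batch_norm": n.batch_norm, "inputs": n.inputs,
                }
                for n in self.nodes.values()
            ],
        }


def build_graph(
    block_sizes=DEFAULT_BLOCK_SIZES,
    growth_rate: int = 32,
    n_classes: int = 1,
    n_anchors_per_scale: int = 3,
    stem_channels: int = 32,
    circular: bool = True,
) -> ArchGraph:
    """Build the dense detection backbone graph.

    Detection branches attach to the outputs of the last three dense
    blocks (the three strides); deeper branch features are routed to
    shallower ones via 1x1 conv + upsample + concat, following the usual
    multi-scale fusion pattern.
    """
    if any(s <= 0 for s in block_sizes):
        raise ValueError("block sizes must be positive")
    if len(block_sizes) < 3:
        raise ValueError("need at least three blocks for three detection scales")
    g = ArchGraph(block_layer_counts=tuple(block_sizes))
    bottleneck = 4 * growth_rate

    stem = g.add(ArchNode("stem", "conv", 3, stem_channels, kernel=3, stride=2, batch_norm=True))
    prev = stem
    block_outputs: list[ArchNode] = []
    for bi, L in enumerate(block_sizes):
        spec = DenseBlockSpec(L, growth_rate, bottleneck)
        feats = [prev]  # feature sources available inside the block
        for li in range(L):
            in_ch = sum(f.out_channels for f in feats)
            cat = g.add(
                ArchNode(f"b{bi}_l{li}_concat", "concat", in_ch, in_ch,
                         inputs=[f.name for f in feats])
            )
            bneck = g.add(
                ArchNode(f"b{bi}_l{li}_bottleneck", "bottleneck", in_ch, spec.bottleneck_width,
                         kernel=1, batch_norm=True, inputs=[cat.name])
            )
            conv = g.add(
                ArchNode(f"b{bi}_l{li}_conv", "conv", spec.bottleneck_width, spec.growth_rate,
                         kernel=3, batch_norm=True, inputs=[bneck.name])
            )
            feats.append(conv)
        out_ch = sum(f.out_channels for f in feats)
        block_out = g.add(
            ArchNode(f"b{bi}_out", "concat", out_ch, out_ch, inputs=[f.name for f in feats])
        )
        block_outputs.append(block_out)
        if bi < len(block_sizes) - 1:
            prev = g.add(
                ArchNode(f"transition{bi}", "transition", out_ch, out_ch // 2,
                         kernel=1, stride=2, batch_norm=True, inputs=[block_out.name])
            )

    # three detection scales from the last three blocks, deepest first
    scale_feats = block_outputs[-1:-4:-1]
    head_ch = n_anchors_per_scale * ((4 if circular else 5) + n_classes)
    route_prev: ArchNode | None = None
    for si, feat in enumerate(scale_feats):
        branch_in = feat
        if route_prev is not None:
            route = g.add(
                ArchNode(f"scale{si}_route", "conv", route_prev.out_channels,
                         route_prev.out_channels // 2, kernel=1, batch_norm=True,
                         inputs=[route_prev.name])
            )
            up = g.add(
                ArchNode(f"scale{si}_upsample", "upsample", route.out_channels,
                         route.out_channels, inputs=[route.name])
            )
            in_ch = feat.out_channels + up.out_channels
            branch_in = g.add(
                ArchNode(f"scale{si}_fuse", "concat", in_ch, in_ch,
                         inputs=[feat.name, up.name])
            )
        c1 = g.add(
            ArchNode(f"scale{si}_conv0", "conv", branch_in.out_channels, 256,
                     kernel=3, batch_norm=True, inputs=[branch_in.name])
        )
        c2 = g.add(
            ArchNode(f"scale{si}_conv1", "conv", c1.out_channels, 512,
                     kernel=3, batch_norm=True, inputs=[c1.name])
        )
        g.add(ArchNode(f"scale{si}_detect", "detect", c2.out_channels, head_ch,
                       kernel=1, inputs=[c2.name]))
        route_prev = c2
    return g


def dense_connection_count(g: ArchGraph, block_index: int) -> int:
    """Number of direct feature-source connections into the block's layers.

    Every dense layer consumes the block input plus all earlier layers'
    outputs, so for L layers the count is 1 + 2 + ... + L = L(L+1)/2.
    Counted by walking the concat nodes' incoming edges.
    """
    total = 0
    li = 0
    while f"b{block_index}_l{li}_concat" in g.nodes:
        total += len(g.nodes[f"b{block_index}_l{li}_concat"].inputs)
        li += 1
    return total


def validate_graph(g: ArchGraph) -> dict:
    """Check structural invariants; returns {'passed': bool, 'violations': [...]}."""
    violations: list[str] = []

    # DAG-ness: nodes only reference already-added nodes, so the insertion
    # order is a topological order; verify explicitly anyway.
    seen: set[str] = set()
    for name, node in g.nodes.items():
        for src in node.inputs:
            if src not in seen:
                violations.append(f"edge {src} -> {name} violates topological order")
        seen.add(name)

    for node in g.nodes.values():
        if node.kind == "concat":
            want = sum(g.nodes[s].out_channels for s in node.inputs)
            if node.in_channels != want or node.out_channels != want:
                violations.append(
                    f"concat {node.name}: channels {node.in_channels} != sum of inputs {want}"
                )
        elif node.inputs:
            want = sum(g.nodes[s].out_channels for s in node.inputs)
            if node.in_channels != want:
                violations.append(
                    f"{node.name}: in_channels {node.in_channels} != predecessor out {want}"
                )

    detects = g.detect_nodes
    if len(detects) != 3:
        violations.append(f"expected 3 detect nodes, found {len(detects)}")
    for d in detects:
        n_convs = 0
        cur = d
        while cur.inputs:
            pred = g.nodes[cur.inputs[-1] if cur.kind != "concat" else cur.inputs[0]]
            if pred.kind == "conv" and pred.name.startswith("scale"):
                n_convs += 1
                cur = pred
            else:
                break
        if n_convs != 2:
            violations.append(f"detect branch {d.name} has {n_convs} convs, expected 2")

    for bi, L in enumerate(g.block_layer_counts):
        want = L * (L + 1) // 2
        got = dense_connection_count(g, bi)
        if got != want:
            violations.append(f"block {bi}: {got} dense connections, expected {want}")

    return {"passed": not violations, "violations": violations}


def count_params(g: ArchGraph) -> int:
    """Total learnable parameters: k^2 * in * out per conv-like node, + 2 * out per BN."""
    total = 0
    for n in g.nodes.values():
        if n.kind in ("conv", "bottleneck", "transition", "detect"):
            total += n.kernel * n.kernel * n.in_channels * n.out_channels
            if n.batch_norm:
                total += 2 * n.out_channels
    return total
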