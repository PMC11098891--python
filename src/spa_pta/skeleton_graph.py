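"""Upper-body skeleton graph: nodes, spatial edges, hop distances.

The pose network operates on a 9-joint upper-body graph (neck, shoulders,
elbows, wrists, hips).  Spatial edges follow the skeletal structure; the
same-joint-across-consecutive-frames temporal rule is kept implicit because
the network applies spatial attention per frame and mixes time only through
pooling.  Hop distance (shortest path length on the spatial graph) drives
the channel-squeezing schedule: hop 0 is the self node, hops 1-2 are
short-range, hops >= 3 are long-range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

#: canonical joint order used everywhere downstream (feature columns,
#: adjacency rows, attention reports)
UPPER_BODY_JOINTS: tuple[str, ...] = (
    "neck",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
)

#: skeletal edges: wrist-elbow, elbow-shoulder, shoulder-neck per side,
#: plus neck-hip on both sides (one connected trunk, no hip-hip edge so
#: that cross-arm hop distances stay large)
UPPER_BODY_EDGES: tuple[tuple[str, str], ...] = (
    ("left_wrist", "left_elbow"),
    ("left_elbow", "left_shoulder"),
    ("left_shoulder", "neck"),
    ("right_wrist", "right_elbow"),
    ("right_elbow", "right_shoulder"),
    ("right_shoulder", "neck"),
    ("neck", "left_hip"),
    ("neck", "right_hip"),
)

HOP_SELF = "self"
HOP_SHORT = "short"
HOP_LONG = "long"


class GraphConstructionError(ValueError):
    """Raised when the requested joint set does not yield a connected graph."""


@dataclass(frozen=True)
class SkeletonGraph:
    """Spatial skeleton graph G=(V, E) with normalized adjacency and hops.

    Attributes
    ----------
    nodes : ordered joint names (graph vertex order = feature column order).
    edges : undirected spatial edges as index pairs.
    adjacency : row-normalized adjacency with self-loops, shape (V, V);
        every row sums to 1 and entries are nonzero only on edges/self-loops.
    hops : all-pairs shortest-path matrix on the spatial graph, shape (V, V).
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[int, int], ...]
    adjacency: np.ndarray = field(repr=False)
    hops: np.ndarray = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def index(self, joint: str) -> int:
        return self.nodes.index(joint)

    def directed_edges(self) -> list[tuple[int, int]]:
        """Directed (target, source) pairs with nonzero adjacency, incl. self-loops."""
        tgt, src = np.nonzero(self.adjacency)
        return list(zip(tgt.tolist(), src.tolist()))

    def to_edge_list(self) -> str:
        """Plain-text edge list (one ``a<TAB>b`` per line) for export."""
        return "\n".join(f"{self.nodes[i]}\t{self.nodes[j]}" for i, j in self.edges)

    def hops_to_csv(self) -> str:
        """Hop-distance matrix as CSV (header row/column of joint names)."""
        lines = ["," + ",".join(self.nodes)]
        for i, name in enumerate(self.nodes):
            lines.append(name + "," + ",".join(str(int(d)) for d in self.hops[i]))
        return "\n".join(lines)


def build_graph(joints: tuple[str, ...] = UPPER_BODY_JOINTS) -> SkeletonGraph:
    """Build the spatial skeleton graph over ``joints``.

    Edges are the subset of :data:`UPPER_BODY_EDGES` whose endpoints are both
    present.  The adjacency is row-normalized with self-loops so each node
    averages over itself and its skeletal neighbors.

    Raises
    ------
    GraphConstructionError
        If the resulting spatial graph is disconnected (e.g. the neck is
        missing, which splits the arms from the trunk).
    """
    joints = tuple(joints)
    idx = {name: k for k, name in enumerate(joints)}
    edges = tuple(
        (idx[a], idx[b]) for a, b in UPPER_BODY_EDGES if a in idx and b in idx
    )
    g = nx.Graph()
    g.add_nodes_from(range(len(joints)))
    g.add_edges_from(edges)
    if len(joints) == 0 or not nx.is_connected(g):
        raise GraphConstructionError(
            f"spatial graph over {joints!r} is not connected; "
            "the upper-body joint set requires neck, shoulders, elbows, "
            "wrists and hips"
        )

    n = len(joints)
    a = np.zeros((n, n))
    for i, j in edges:
        a[i, j] = a[j, i] = 1.0
    a += np.eye(n)  # self-loops
    adjacency = a / a.sum(axis=1, keepdims=True)

    spl = dict(nx.all_pairs_shortest_path_length(g))
    hops = np.array([[spl[i][j] for j in range(n)] for i in range(n)], dtype=int)
    return SkeletonGraph(nodes=joints, edges=edges, adjacency=adjacency, hops=hops)


def hop_distances(graph: SkeletonGraph) -> np.ndarray:
    """All-pairs shortest-path lengths on the spatial graph."""
    return graph.hops


def classify_hops(hops: np.ndarray) -> np.ndarray:
    """Label every ordered node pair self / short / long by hop distance.

    self: d = 0; short: d in {1, 2}; long: d >= 3.  Returns an object array
    of the same shape as ``hops``.
    """
    hops = np.asarray(hops)
    labels = np.full(hops.shape, HOP_LONG, dtype=object)
    labels[hops <= 2] = HOP_SHORT
    labels[hops == 0] = HOP_SELF
    return labels
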