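"""Cross-frame assignment graph construction.

Every candidate correspondence between a cell ``x`` of frame t and a cell
``y`` of frame t+1 becomes a *node* carrying the concatenated single-cell
features of both cells. Two nodes (x, y) and (x', y') are connected by an
*edge* — carrying the concatenated within-frame pair features of x–x' and
y–y' — iff both same-frame pairs are closer than a distance threshold
(default 8 px, closest points along contours, strict inequality) and the
four cells are distinct (x ≠ x', y ≠ y').

For dense colonies the full bipartite node product grows quadratically, so
cross-frame pairs whose CoM distance exceeds a generous gate (default
60 px after area normalization) are pruned; at realistic growth rates the
gate never drops a true correspondence.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .features import FrameGeometry, PAIR_VECTOR_FLIP
from .mask_io import LabeledFrame

__all__ = ["TrackingGraph", "build_graph", "label_nodes",
           "DEFAULT_EDGE_THRESHOLD", "DEFAULT_COM_GATE"]

DEFAULT_EDGE_THRESHOLD = 8.0
DEFAULT_COM_GATE = 60.0


@dataclasses.dataclass
class TrackingGraph:
    """Assignment graph for one frame transition.

    ``nodes`` holds (label_t, label_t1) pairs in deterministic order
    (frame-t label major, then frame-t+1 label). ``edges`` holds
    undirected node-index pairs (u < v); ``edge_features`` is oriented
    u -> v (use :data:`PAIR_VECTOR_FLIP` on both halves for v -> u).
    """

    nodes: list[tuple[int, int]]
    node_features: np.ndarray          # (n_nodes, 2 * n_cell_feats)
    edges: np.ndarray                  # (n_edges, 2) int
    edge_features: np.ndarray          # (n_edges, 2 * n_pair_feats)
    labels_t: list[int]
    labels_t1: list[int]
    node_labels: np.ndarray | None = None   # binary, 1 = correct assignment
    uncovered_truth: list[tuple[int, int]] = dataclasses.field(
        default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def directed_edges(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(src, dst, features) with every undirected edge expanded both
        ways; sign-sensitive pair components are flipped for the reverse
        direction."""
        if self.n_edges == 0:
            e = np.zeros((0,), dtype=np.intp)
            f = np.zeros((0, self.edge_features.shape[1]
                          if self.edge_features.ndim == 2 else 12))
            return e, e, f
        u, v = self.edges[:, 0], self.edges[:, 1]
        flip = np.concatenate([PAIR_VECTOR_FLIP, PAIR_VECTOR_FLIP])
        src = np.concatenate([u, v])
        dst = np.concatenate([v, u])
        feats = np.concatenate([self.edge_features,
                                self.edge_features * flip])
        return src, dst, feats


def build_graph(frame_t: LabeledFrame | FrameGeometry,
                frame_t1: LabeledFrame | FrameGeometry,
                threshold: float = DEFAULT_EDGE_THRESHOLD,
                com_gate: float | None = DEFAULT_COM_GATE) -> TrackingGraph:
    """Build the assignment graph between two consecutive frames.

    ``com_gate=None`` disables node pruning (full bipartite product).
    An empty frame yields an empty graph (the caller decides whether all
    cells are new or lost).
    """
    geo_t = frame_t if isinstance(frame_t, FrameGeometry) \
        else FrameGeometry(frame_t)
    geo_t1 = frame_t1 if isinstance(frame_t1, FrameGeometry) \
        else FrameGeometry(frame_t1)

    labels_t = geo_t.labels_sorted
    labels_t1 = geo_t1.labels_sorted

    nodes: list[tuple[int, int]] = []
    node_feats: list[np.ndarray] = []
    node_index: dict[tuple[int, int], int] = {}
    for a in labels_t:
        ra = geo_t.record(a)
        va = ra.features.vector()
        for b in labels_t1:
            rb = geo_t1.record(b)
            if com_gate is not None:
                d = np.hypot(rb.com[0] - ra.com[0], rb.com[1] - ra.com[1])
                if d > com_gate:
                    continue
            node_index[(a, b)] = len(nodes)
            nodes.append((a, b))
            node_feats.append(np.concatenate([va, rb.features.vector()]))

    # same-frame proximity pairs (strict inequality at the threshold)
    near_t = _near_pairs(geo_t, threshold)
    near_t1 = _near_pairs(geo_t1, threshold)
    near_t1_map: dict[int, list[int]] = {}
    for (y, y2) in near_t1:
        near_t1_map.setdefault(y, []).append(y2)
        near_t1_map.setdefault(y2, []).append(y)

    edges: list[tuple[int, int]] = []
    edge_feats: list[np.ndarray] = []
    for (x, x2) in near_t:
        # both role assignments of the unordered near pair; each undirected
        # edge is kept once (u < v) with features oriented u -> v
        for a, b in ((x, x2), (x2, x)):
            pf_t = None
            for y in labels_t1:
                u = node_index.get((a, y))
                if u is None:
                    continue
                for y2 in near_t1_map.get(y, ()):
                    v = node_index.get((b, y2))
                    if v is None or v <= u:
                        continue
                    if pf_t is None:
                        pf_t = geo_t.pair(a, b).vector()
                    edges.append((u, v))
                    edge_feats.append(np.concatenate(
                        [pf_t, geo_t1.pair(y, y2).vector()]))

    n_cell_feats = len(geo_t.record(labels_t[0]).features.vector()) \
        if labels_t else 7
    graph = TrackingGraph(
        nodes=nodes,
        node_features=(np.array(node_feats) if node_feats
                       else np.zeros((0, 2 * n_cell_feats))),
        edges=(np.array(edges, dtype=np.intp) if edges
               else np.zeros((0, 2), dtype=np.intp)),
        edge_features=(np.array(edge_feats) if edge_feats
                       else np.zeros((0, 12))),
        labels_t=labels_t, labels_t1=labels_t1,
    )
    if edges:
        order = np.lexsort((graph.edges[:, 1], graph.edges[:, 0]))
        graph.edges = graph.edges[order]
        graph.edge_features = graph.edge_features[order]
    return graph


def _near_pairs(geo: FrameGeometry, threshold: float) -> list[tuple[int, int]]:
    """Unordered same-frame label pairs with closest contour distance
    strictly below the threshold."""
    out = []
    labels = geo.labels_sorted
    for i, a in enumerate(labels):
        ra = geo.record(a)
        for b in labels[i + 1:]:
            rb = geo.record(b)
            com_d = np.hypot(rb.com[0] - ra.com[0], rb.com[1] - ra.com[1])
            # conservative circumradius bound on the contour distance
            if com_d - geo._rmax[a] - geo._rmax[b] >= threshold:
                continue
            if geo.closest_distance(a, b) < threshold:
                out.append((a, b))
    return out


class CoverageError(ValueError):
    pass


def label_nodes(graph: TrackingGraph,
                ground_truth: dict[int, int],
                strict: bool = False) -> TrackingGraph:
    """Set binary node labels from a frame-t-label -> frame-t1-label map.

    Ground-truth pairs missing from the node set (e.g. pruned by the CoM
    gate) are recorded in ``graph.uncovered_truth``; with ``strict=True``
    they raise instead.
    """
    lab = np.zeros(graph.n_nodes, dtype=np.int64)
    index = {pair: i for i, pair in enumerate(graph.nodes)}
    uncovered = []
    for a, b in ground_truth.items():
        i = index.get((a, b))
        if i is None:
            uncovered.append((a, b))
        else:
            lab[i] = 1
    if uncovered and strict:
        raise CoverageError(f"{len(uncovered)} ground-truth pairs not in "
                            f"node set: {uncovered[:5]}...")
    graph.node_labels = lab
    graph.uncovered_truth = uncovered
    return graph
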