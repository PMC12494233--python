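"""Label adjacency analysis: touching-object clusters and graph coloring.

Two labels are adjacent when any pair of their pixels are 8-neighbors.
Clusters of mutually touching objects are the connected components of
this region adjacency graph; a greedy proper coloring of the graph lets
touching objects be dispatched to parallel workers without contention.
"""

from __future__ import annotations

import numpy as np

__all__ = ["label_adjacency_edges", "partition_label_graph"]

_SHIFTS = [(0, 1), (1, 0), (1, 1), (1, -1)]  # half of the 8-neighborhood


def label_adjacency_edges(labels) -> set:
    """Set of (a, b) pairs (a < b) of labels sharing an 8-neighbor pixel."""
    labels = np.asarray(labels)
    edges = set()
    for dr, dc in _SHIFTS:
        a = labels[max(dr, 0) or None : labels.shape[0] + min(dr, 0),
                   max(dc, 0) or None : labels.shape[1] + min(dc, 0)]
        b = labels[max(-dr, 0) or None : labels.shape[0] + min(-dr, 0),
                   max(-dc, 0) or None : labels.shape[1] + min(-dc, 0)]
        touch = (a > 0) & (b > 0) & (a != b)
        pairs = np.stack([a[touch], b[touch]], axis=1)
        if pairs.size:
            lo = pairs.min(axis=1)
            hi = pairs.max(axis=1)
            edges.update(map(tuple, np.unique(np.stack([lo, hi], 1), axis=0)))
    return edges


def partition_label_graph(labels):
    """Cluster touching objects and color the adjacency graph.

    Returns
    -------
    (edges, clusters, colors)
        ``edges``: sorted list of (a, b) touching-label pairs;
        ``clusters``: dict label -> cluster id (connected component,
        numbered by smallest member label);
        ``colors``: dict label -> color index such that no edge joins two
        labels of the same color (greedy, labels visited in id order).
    """
    labels = np.asarray(labels)
    ids = [int(i) for i in np.unique(labels) if i > 0]
    edges = sorted(label_adjacency_edges(labels))

    adj = {i: set() for i in ids}
    for a, b in edges:
        adj[int(a)].add(int(b))
        adj[int(b)].add(int(a))

    # connected components by BFS over sorted ids
    clusters = {}
    for i in ids:
        if i in clusters:
            continue
        stack, comp = [i], i
        while stack:
            v = stack.pop()
            if v in clusters:
                continue
            clusters[v] = comp
            stack.extend(adj[v] - clusters.keys())

    colors = {}
    for i in ids:
        used = {colors[j] for j in adj[i] if j in colors}
        c = 0
        while c in used:
            c += 1
        colors[i] = c
    return edges, clusters, colors
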