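"""Global spatial-arrangement features of cell centroids.

Summary statistics of the Voronoi tessellation (bounded cells only),
Delaunay triangulation, and Euclidean minimum spanning tree of a point
set, plus the point density over the convex hull.  Each measured
quantity x is summarized by mean, population std, min/max ratio, and the
disorder ``std / (mean + std)``.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import ConvexHull, Delaunay, QhullError, Voronoi

__all__ = ["compute_global_cell_graph_features", "mst_total_length"]


def _summary(prefix: str, x) -> dict:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        # no bounded Voronoi cells etc. -> all-zero block by convention
        return {f"{prefix}.{s}": 0.0 for s in ("Mean", "Std", "MinMaxRatio", "Disorder")}
    mean, std = x.mean(), x.std()
    return {
        f"{prefix}.Mean": float(mean),
        f"{prefix}.Std": float(std),
        f"{prefix}.MinMaxRatio": float(x.min() / x.max()) if x.max() > 0 else 0.0,
        f"{prefix}.Disorder": float(std / (mean + std)) if mean + std > 0 else 0.0,
    }


def _polygon_area_perimeter(pts: np.ndarray):
    x, y = pts[:, 0], pts[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    perim = np.hypot(*(pts - np.roll(pts, -1, axis=0)).T).sum()
    return float(area), float(perim)


def _delaunay_edges(tri: Delaunay):
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            e = (simplex[a], simplex[(a + 1) % 3])
            edges.add((min(e), max(e)))
    return sorted(edges)


def mst_total_length(points: np.ndarray) -> float:
    """Total length of the Euclidean MST (built on the Delaunay graph)."""
    points = np.asarray(points, dtype=float)
    tri = Delaunay(points)
    edges = _delaunay_edges(tri)
    w = [np.hypot(*(points[a] - points[b])) for a, b in edges]
    n = points.shape[0]
    g = coo_matrix((w, tuple(np.array(edges).T)), shape=(n, n))
    return float(minimum_spanning_tree(g).sum())


def compute_global_cell_graph_features(points) -> dict:
    """Spatial-distribution features of a set of (row, col) centroids.

    Requires at least 4 points in general position; collinear input
    raises ``ValueError``.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if points.shape[0] < 4:
        raise ValueError("need at least 4 points")
    try:
        tri = Delaunay(points)
        vor = Voronoi(points)
        hull = ConvexHull(points)
    except QhullError as exc:
        raise ValueError("points are degenerate (collinear?)") from exc
    if tri.simplices.shape[0] == 0:
        raise ValueError("points are degenerate (collinear?)")

    edges = _delaunay_edges(tri)
    edge_lengths = np.array([np.hypot(*(points[a] - points[b])) for a, b in edges])
    tri_areas = np.array([
        _polygon_area_perimeter(points[s])[0] for s in tri.simplices
    ])

    # MST over the Delaunay graph (equals the Euclidean MST)
    n = points.shape[0]
    g = coo_matrix((edge_lengths, tuple(np.array(edges).T)), shape=(n, n))
    mst = minimum_spanning_tree(g)
    mst_lengths = np.asarray(mst[mst.nonzero()]).ravel()

    v_areas, v_perims = [], []
    for region_idx in vor.point_region:
        region = vor.regions[region_idx]
        if -1 in region or len(region) < 3:
            continue
        a, p = _polygon_area_perimeter(vor.vertices[region])
        v_areas.append(a)
        v_perims.append(p)

    out = {}
    out.update(_summary("Graph.VoronoiArea", v_areas))
    out.update(_summary("Graph.VoronoiPerimeter", v_perims))
    out.update(_summary("Graph.DelaunayEdgeLength", edge_lengths))
    out.update(_summary("Graph.DelaunayTriangleArea", tri_areas))
    out.update(_summary("Graph.MSTEdgeLength", mst_lengths))
    out["Graph.MSTTotalLength"] = float(mst_lengths.sum())
    out["Graph.Density"] = float(points.shape[0] / hull.volume) if hull.volume > 0 else 0.0
    return out
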