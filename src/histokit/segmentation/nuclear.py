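"""Nuclei segmentation algorithms.

All algorithms operate on a nuclei-bright single-channel raster —
typically the hematoxylin concentration from color deconvolution — plus a
binary foreground mask, and return label images and/or seed lists.

Four complementary approaches are provided:

* :func:`detect_nuclei_kofahi` — seeds from a constrained multi-scale LoG
  response, objects grown by marker-based watershed.
* :func:`max_clustering` — every pixel links to the largest response in
  its neighborhood; chains of links are compressed to local maxima and
  each attracting maximum becomes one object.
* :func:`gaussian_voting` — edge pixels cast Gaussian-weighted votes
  along the inward gradient direction; accumulator maxima are centroids.
* :func:`gvf_tracking` — pixels are tracked along a diffused gradient
  vector field to its sinks; basins of merged sinks become objects.

Tie-breaking is deterministic everywhere: on equal responses the pixel
with the smallest row-major linear index wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from ..filters.edge import gaussian_grad
from ..filters.shape import clog

__all__ = [
    "SeedList",
    "detect_nuclei_kofahi",
    "max_clustering",
    "gaussian_voting",
    "gvf_tracking",
]


@dataclass
class SeedList:
    """Detected nuclear centroids with their scores and scales."""

    points: np.ndarray  # (n, 2) float (row, col)
    scores: np.ndarray  # (n,)
    scales: np.ndarray  # (n,)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.points.shape[0]

    @classmethod
    def empty(cls) -> "SeedList":
        return cls(np.empty((0, 2)), np.empty(0), np.empty(0))


def _as_mask(mask, shape):
    if mask is None:
        return np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError("mask shape does not match raster")
    return mask


def detect_nuclei_kofahi(density, mask=None, r_min: float = 3.0, r_max: float = 10.0,
                         min_distance: float = 5.0, response_threshold: float = 1e-6):
    """Multi-scale LoG nuclei segmentation (Kofahi-style).

    The constrained LoG response is computed over sigmas matched to the
    radius range (``sigma = r / sqrt(2)``, where a disk of radius r peaks);
    its local maxima separated by at least ``min_distance`` become
    markers, and objects are grown over the mask by watershed flooding of
    the negated response.

    Returns an ``(H, W)`` int label image (empty mask -> all zero).
    """
    density = np.asarray(density, dtype=float)
    if not r_min < r_max:
        raise ValueError("need r_min < r_max")
    mask = _as_mask(mask, density.shape)
    if not mask.any():
        return np.zeros(density.shape, dtype=np.int32)

    resp = clog(density, mask, sigma_min=r_min / np.sqrt(2), sigma_max=r_max / np.sqrt(2))
    peaks = peak_local_max(
        resp.response, min_distance=max(int(round(min_distance)), 1),
        threshold_abs=response_threshold, exclude_border=False, labels=mask,
    )
    if peaks.shape[0] == 0:
        return np.zeros(density.shape, dtype=np.int32)
    markers = np.zeros(density.shape, dtype=np.int32)
    order = np.lexsort((peaks[:, 1], peaks[:, 0]))
    markers[tuple(peaks[order].T)] = np.arange(1, peaks.shape[0] + 1)
    return watershed(-resp.response, markers=markers, mask=mask, connectivity=2).astype(np.int32)


def _disk_offsets(radius: float):
    r = int(np.floor(radius))
    offs = [(dr, dc) for dr in range(-r, r + 1) for dc in range(-r, r + 1)
            if dr * dr + dc * dc <= radius * radius and (dr, dc) != (0, 0)]
    return offs


def max_clustering(response, mask=None, radius: float = 10.0):
    """Local-maximum clustering of a response map.

    Each foreground pixel points at the highest-response pixel inside its
    Euclidean ``radius`` neighborhood (ties: smallest linear index, which
    also makes the pixel prefer itself on plateaus it tops).  Pointer
    chains are compressed to their fixed points — the attracting local
    maxima — and each maximum gets one label, numbered in row-major order
    of the maxima.

    Returns ``(label_image, SeedList)``.
    """
    response = np.asarray(response, dtype=float)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    mask = _as_mask(mask, response.shape)
    h, w = response.shape
    lin = np.arange(h * w).reshape(h, w)

    big = np.inf
    r_int = int(np.floor(radius))
    pv = np.full((h + 2 * r_int, w + 2 * r_int), -big)
    pi = np.full((h + 2 * r_int, w + 2 * r_int), h * w, dtype=np.int64)
    pv[r_int : r_int + h, r_int : r_int + w] = np.where(mask, response, -big)
    pi[r_int : r_int + h, r_int : r_int + w] = lin

    cur_val = np.where(mask, response, -big)
    cur_idx = lin.astype(np.int64).copy()
    for dr, dc in _disk_offsets(radius):
        nv = pv[r_int + dr : r_int + dr + h, r_int + dc : r_int + dc + w]
        ni = pi[r_int + dr : r_int + dr + h, r_int + dc : r_int + dc + w]
        upd = (nv > cur_val) | ((nv == cur_val) & (ni < cur_idx))
        upd &= mask
        cur_val = np.where(upd, nv, cur_val)
        cur_idx = np.where(upd, ni, cur_idx)

    parent = np.where(mask.ravel(), cur_idx.ravel(), lin.ravel())
    # path compression: parent is monotone in (response, -index), so
    # log2(N) doublings reach the fixed points
    for _ in range(int(np.ceil(np.log2(h * w + 1))) + 1):
        new = parent[parent]
        if np.array_equal(new, parent):
            break
        parent = new

    roots = np.unique(parent[mask.ravel()])
    label_of_root = np.zeros(h * w, dtype=np.int32)
    label_of_root[roots] = np.arange(1, roots.size + 1)
    labels = np.zeros(h * w, dtype=np.int32)
    labels[mask.ravel()] = label_of_root[parent[mask.ravel()]]
    labels = labels.reshape(h, w)

    pts = np.stack(np.unravel_index(roots, (h, w)), axis=1).astype(float)
    seeds = SeedList(pts, response.reshape(-1)[roots], np.full(roots.size, radius))
    return labels, seeds


def gaussian_voting(density, mask=None, grad_threshold: float = 0.05,
                    r_min: float = 5.0, r_max: float = 15.0,
                    sigma_vote: float = 2.0, min_distance: float = 5.0,
                    grad_sigma: float = 1.0, accumulator_threshold: float = 0.25):
    """Gaussian kernel voting for nuclear centroid localization.

    Edge pixels (gradient magnitude above ``grad_threshold``) cast votes
    along the inward (uphill) gradient direction at unit radial offsets
    in ``[r_min, r_max]``; the vote field is smoothed with a Gaussian of
    scale ``sigma_vote`` and its local maxima, separated by at least
    ``min_distance`` and above ``accumulator_threshold`` of the global
    maximum, become seeds.

    Returns a :class:`SeedList` (empty if no edge pixel passes threshold).
    """
    density = np.asarray(density, dtype=float)
    if not r_min < r_max:
        raise ValueError("need r_min < r_max")
    mask = _as_mask(mask, density.shape)
    dx, dy, mag, _ = gaussian_grad(density, grad_sigma)
    edges = mask & (mag > grad_threshold)
    if not edges.any():
        return SeedList.empty()

    rr, cc = np.nonzero(edges)
    ur = dy[rr, cc] / mag[rr, cc]
    uc = dx[rr, cc] / mag[rr, cc]
    weights = mag[rr, cc]

    acc = np.zeros(density.shape)
    h, w = density.shape
    for r in np.arange(r_min, r_max + 1e-9, 1.0):
        tr = np.rint(rr + r * ur).astype(int)
        tc = np.rint(cc + r * uc).astype(int)
        ok = (tr >= 0) & (tr < h) & (tc >= 0) & (tc < w)
        np.add.at(acc, (tr[ok], tc[ok]), weights[ok])
    acc = ndi.gaussian_filter(acc, sigma_vote)

    peaks = peak_local_max(
        acc, min_distance=max(int(round(min_distance)), 1),
        threshold_abs=accumulator_threshold * acc.max(), exclude_border=False,
    )
    if peaks.shape[0] == 0:
        return SeedList.empty()
    order = np.lexsort((peaks[:, 1], peaks[:, 0]))
    peaks = peaks[order]
    return SeedList(
        peaks.astype(float), acc[tuple(peaks.T)],
        np.full(peaks.shape[0], 0.5 * (r_min + r_max)),
    )


_NEIGHBORS = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
)
_NEIGHBOR_UNITS = _NEIGHBORS / np.linalg.norm(_NEIGHBORS, axis=1, keepdims=True)


def gvf_tracking(density, mask=None, mu: float = 0.1, iterations: int = 50,
                 sink_merge_radius: float = 3.0, smooth_sigma: float = 2.0):
    """Gradient-vector-flow tracking segmentation.

    A gradient vector field of the (smoothed) density is diffused by
    ``iterations`` Xu-Prince updates with regularization ``mu``; every
    foreground pixel then steps to the 8-neighbor most aligned with its
    local field vector until it reaches a fixed point.  Fixed points
    within ``sink_merge_radius`` of one another are merged, and labels
    are the basins of the merged sinks.  Tracks that fail to converge
    within the step budget are cut and assigned to their last position
    (counted in ``meta['nonconvergent']`` of the result).

    Returns ``(label_image, SeedList of merged sinks)``.
    """
    density = np.asarray(density, dtype=float)
    if mu <= 0 or iterations < 1:
        raise ValueError("mu must be > 0 and iterations >= 1")
    mask = _as_mask(mask, density.shape)
    h, w = density.shape
    if not mask.any():
        return np.zeros((h, w), dtype=np.int32), SeedList.empty()

    f = ndi.gaussian_filter(density, smooth_sigma)
    rng_span = f.max() - f.min()
    if rng_span > 0:
        f = (f - f.min()) / rng_span
    fy, fx = np.gradient(f)
    b = fx**2 + fy**2
    u, v = fx.copy(), fy.copy()
    dt = min(0.25 / mu, 0.5 / (b.max() + 1e-12), 1.0)
    for _ in range(iterations):
        u += dt * (mu * ndi.laplace(u, mode="nearest") - (u - fx) * b)
        v += dt * (mu * ndi.laplace(v, mode="nearest") - (v - fy) * b)

    # step rule: move to the 8-neighbor best aligned with (v, u)
    lin = np.arange(h * w).reshape(h, w)
    best_align = np.full((h, w), -np.inf)
    best_idx = lin.copy()
    field_mag = np.hypot(u, v)
    for (dr, dc), (unit_r, unit_c) in zip(_NEIGHBORS, _NEIGHBOR_UNITS):
        align = v * unit_r + u * unit_c
        nr = np.clip(np.arange(h)[:, None] + dr, 0, h - 1)
        nc = np.clip(np.arange(w)[None, :] + dc, 0, w - 1)
        nidx = lin[nr, nc]
        in_bounds = (
            (np.arange(h)[:, None] + dr >= 0) & (np.arange(h)[:, None] + dr < h)
            & (np.arange(w)[None, :] + dc >= 0) & (np.arange(w)[None, :] + dc < w)
        )
        valid = in_bounds & mask[nr, nc] & mask
        upd = valid & ((align > best_align)
                       | ((align == best_align) & (nidx < best_idx)))
        best_align[upd] = align[upd]
        best_idx[upd] = nidx[upd]

    sink = (best_align <= 0) | (field_mag < 1e-9)
    parent = np.where(mask & ~sink, best_idx, lin).ravel()
    parent[~mask.ravel()] = lin.ravel()[~mask.ravel()]

    budget = int(np.ceil(np.log2(2 * max(h, w) + 1))) + 1
    pos = parent.copy()
    for _ in range(budget):
        new = pos[pos]
        if np.array_equal(new, pos):
            break
        pos = new
    converged = parent[pos] == pos
    nonconvergent = int((~converged & mask.ravel()).sum())

    finals = np.unique(pos[mask.ravel()])
    pts = np.stack(np.unravel_index(finals, (h, w)), axis=1).astype(float)

    # merge sinks within sink_merge_radius by union-find over KD-tree pairs
    group = np.arange(finals.size)

    def find(a):
        while group[a] != a:
            group[a] = group[group[a]]
            a = group[a]
        return a

    if finals.size > 1:
        tree = cKDTree(pts)
        for i, j in sorted(tree.query_pairs(sink_merge_radius)):
            ri, rj = find(i), find(j)
            if ri != rj:
                group[max(ri, rj)] = min(ri, rj)
    roots = np.array([find(i) for i in range(finals.size)])
    root_ids = np.unique(roots)
    label_of_group = {g: k for k, g in enumerate(root_ids, start=1)}

    sink_label = np.zeros(h * w, dtype=np.int32)
    for i, fidx in enumerate(finals):
        sink_label[fidx] = label_of_group[roots[i]]
    labels = np.zeros(h * w, dtype=np.int32)
    m = mask.ravel()
    labels[m] = sink_label[pos[m]]
    labels = labels.reshape(h, w)

    centers = np.array([pts[roots == g].mean(axis=0) for g in root_ids])
    seeds = SeedList(
        centers, np.array([density.reshape(-1)[finals[roots == g]].max() for g in root_ids]),
        np.full(root_ids.size, sink_merge_radius),
        meta={"nonconvergent": nonconvergent},
    )
    return labels, seeds
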