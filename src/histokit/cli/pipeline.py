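"""End-to-end pipelines behind the CLI commands.

Each pipeline is a plain function so it can be called from Python as
well as from the shell.  Nuclei segmentation runs per tile: every tile
is processed with an overlap of at least twice the maximum nuclear
radius, each detected object is owned by the tile whose core region
contains its centroid, and duplicates in overlap zones are dropped.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from ..color.deconvolution import DEFAULT_HE_MATRIX, StainMatrix, color_deconvolution
from ..filters.shape import clog
from ..segmentation.label import clean_label_image, trace_object_boundaries
from ..segmentation.nuclear import (
    detect_nuclei_kofahi,
    gaussian_voting,
    gvf_tracking,
    max_clustering,
)
from .annotations import AnnotationDoc
from .tiles import TileGrid, iterate_tiles

__all__ = ["NUCLEI_ALGORITHMS", "segment_nuclei_field", "segment_nuclei_tiled",
           "nuclei_annotation"]

NUCLEI_ALGORITHMS = ("kofahi", "max_clustering", "gaussian_voting", "gvf_tracking")


def _nuclear_density(im_rgb, stain_matrix: StainMatrix):
    """Hematoxylin (first stain) concentration channel of an RGB field."""
    return color_deconvolution(im_rgb, stain_matrix)[..., 0]


def segment_nuclei_field(
    im_rgb,
    algorithm: str = "kofahi",
    stain_matrix: StainMatrix = DEFAULT_HE_MATRIX,
    r_min: float = 3.0,
    r_max: float = 10.0,
    min_distance: float = 5.0,
    density_threshold: float = 0.1,
    min_area: int = 10,
):
    """Deconvolve one RGB field and segment nuclei with a chosen algorithm.

    Returns an int label image.
    """
    if algorithm not in NUCLEI_ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; options: {NUCLEI_ALGORITHMS}")
    density = _nuclear_density(im_rgb, stain_matrix)
    mask = density >= density_threshold

    if algorithm == "kofahi":
        labels = detect_nuclei_kofahi(density, mask, r_min, r_max, min_distance)
    elif algorithm == "max_clustering":
        resp = clog(density, mask, sigma_min=r_min / np.sqrt(2), sigma_max=r_max / np.sqrt(2))
        labels, _ = max_clustering(resp.response, mask, radius=r_max)
    elif algorithm == "gaussian_voting":
        seeds = gaussian_voting(density, mask, r_min=r_min, r_max=r_max,
                                min_distance=min_distance)
        labels = _labels_from_seeds(density, mask, seeds)
    else:  # gvf_tracking
        labels, _ = gvf_tracking(density, mask)
    return clean_label_image(labels, min_area=min_area)


def _labels_from_seeds(density, mask, seeds):
    from skimage.segmentation import watershed

    if len(seeds) == 0:
        return np.zeros(density.shape, dtype=np.int32)
    markers = np.zeros(density.shape, dtype=np.int32)
    pts = np.rint(seeds.points).astype(int)
    markers[pts[:, 0], pts[:, 1]] = np.arange(1, len(seeds) + 1)
    return watershed(-density, markers=markers, mask=mask).astype(np.int32)


def segment_nuclei_tiled(im_rgb, tile_size=None, overlap=None, **kwargs):
    """Tiled nuclei segmentation with centroid-ownership seam merging.

    ``overlap`` defaults to ``2 * ceil(2 * r_max)`` (twice the largest
    nuclear diameter) so any nucleus near a seam is fully contained in
    the tile that owns its centroid.  With ``tile_size=None`` the image
    is processed in one piece.
    """
    im = np.asarray(im_rgb, dtype=float)
    if tile_size is None:
        # canonical numbering so tiled and untiled outputs are comparable
        return _relabel_rowmajor(segment_nuclei_field(im, **kwargs))
    r_max = kwargs.get("r_max", 10.0)
    if overlap is None:
        overlap = 2 * int(np.ceil(2 * r_max))
    grid = TileGrid((tile_size, tile_size), overlap)

    canvas = np.zeros(im.shape[:2], dtype=np.int32)
    next_label = 1
    for tile, (r0, c0) in iterate_tiles(im, grid):
        labels = segment_nuclei_field(tile, **kwargs)
        if labels.max() == 0:
            continue
        core_r, core_c = grid.core_slices((r0, c0), im.shape)
        coms = ndi.center_of_mass(labels > 0, labels, range(1, labels.max() + 1))
        for obj_id, (cr, cc) in enumerate(coms, start=1):
            if np.isnan(cr):
                continue
            gr, gc = cr + r0, cc + c0
            if not (core_r.start <= gr < core_r.stop and core_c.start <= gc < core_c.stop):
                continue
            obj = labels == obj_id
            rows, cols = np.nonzero(obj)
            target = canvas[rows + r0, cols + c0]
            paint = target == 0
            canvas[rows[paint] + r0, cols[paint] + c0] = next_label
            next_label += 1
    return _relabel_rowmajor(canvas)


def _relabel_rowmajor(labels):
    """Renumber labels by the row-major order of each object's first pixel."""
    labels = np.asarray(labels)
    flat = labels.ravel()
    ids, first = np.unique(flat, return_index=True)
    pos = {i: f for i, f in zip(ids, first) if i > 0}
    order = sorted(pos, key=pos.get)
    remap = np.zeros(labels.max() + 1 if labels.size else 1, dtype=np.int32)
    for new, old in enumerate(order, start=1):
        remap[old] = new
    return remap[labels]


def nuclei_annotation(labels) -> AnnotationDoc:
    """Centroid points and traced boundary polygons of a label image."""
    doc = AnnotationDoc()
    labels = np.asarray(labels)
    if labels.max() == 0:
        return doc
    coms = ndi.center_of_mass(labels > 0, labels, range(1, labels.max() + 1))
    boundaries = trace_object_boundaries(labels)
    for obj_id, com in enumerate(coms, start=1):
        if np.isnan(com[0]) or obj_id not in boundaries:
            continue
        doc.add_point(com[0], com[1], obj_id)
        doc.add_polygon(boundaries[obj_id], obj_id)
    return doc
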