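"""Per-object morphometry.

Size and shape descriptors of each labeled object: area, convex hull
area, axis lengths from second central moments, perimeter measured along
the Moore-traced contour (straight steps 1, diagonal steps sqrt(2)),
circularity ``4*pi*A / P**2``, eccentricity, equivalent diameter, extent,
solidity, orientation in (-pi/2, pi/2], a box-counting fractal dimension
of the boundary, the 7 Hu invariant moments, and (when an intensity
raster is supplied) intensity-weighted Hu moments.

Degenerate conventions: a single-pixel object has perimeter 0 and
circularity 1; objects too small for a box-counting fit report fractal
dimension 1.
"""

from __future__ import annotations

import numpy as np
from skimage.measure import regionprops

from ..segmentation.label import _trace_single
from ._util import assemble, iter_objects

__all__ = ["compute_morphometry_features", "MORPHOMETRY_COLUMNS", "boundary_perimeter"]

MORPHOMETRY_COLUMNS = (
    [
        "Shape.Orientation",
        "Shape.Area",
        "Shape.ConvexArea",
        "Shape.MajorAxisLength",
        "Shape.MinorAxisLength",
        "Shape.MinorMajorAxisRatio",
        "Shape.Perimeter",
        "Shape.Circularity",
        "Shape.Eccentricity",
        "Shape.EquivalentDiameter",
        "Shape.Extent",
        "Shape.Solidity",
        "Shape.FractalDimension",
    ]
    + [f"Shape.HuMoments{i}" for i in range(1, 8)]
)
WEIGHTED_HU_COLUMNS = [f"Shape.WeightedHuMoments{i}" for i in range(1, 8)]


def boundary_perimeter(boundary) -> float:
    """Weighted step length of a closed boundary (1 straight, sqrt(2) diagonal)."""
    if len(boundary) < 2:
        return 0.0
    pts = np.asarray(list(boundary) + [boundary[0]], dtype=float)
    steps = np.diff(pts, axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def _fractal_dimension(boundary_mask: np.ndarray) -> float:
    h, w = boundary_mask.shape
    max_size = min(h, w) // 4
    sizes = []
    s = 2
    while s <= max_size:
        sizes.append(s)
        s *= 2
    if len(sizes) < 2:
        return 1.0
    pts = np.argwhere(boundary_mask)
    counts = []
    for s in sizes:
        boxes = set(map(tuple, pts // s))
        counts.append(len(boxes))
    slope = np.polyfit(np.log(1.0 / np.asarray(sizes, float)), np.log(counts), 1)[0]
    return float(slope)


def compute_morphometry_features(labels, intensity=None):
    """One row of shape descriptors per labeled object."""
    labels = np.asarray(labels)
    intensity = None if intensity is None else np.asarray(intensity, dtype=float)
    if intensity is not None and intensity.shape != labels.shape:
        raise ValueError("labels and intensity must have the same shape")

    columns = MORPHOMETRY_COLUMNS + (WEIGHTED_HU_COLUMNS if intensity is not None else [])
    rows = {}
    for idx, sl, sub in iter_objects(labels):
        sub_int = intensity[sl] * sub if intensity is not None else None
        props = regionprops(sub.astype(np.uint8), intensity_image=sub_int)[0]

        boundary = _trace_single(sub)
        perimeter = boundary_perimeter(boundary)
        area = float(props.area)
        circularity = 1.0 if perimeter == 0 else 4.0 * np.pi * area / perimeter**2

        bmask = np.zeros(sub.shape, dtype=bool)
        bmask[tuple(np.asarray(boundary).T)] = True

        row = {
            "Shape.Orientation": float(props.orientation),
            "Shape.Area": area,
            "Shape.ConvexArea": float(props.area_convex),
            "Shape.MajorAxisLength": float(props.axis_major_length),
            "Shape.MinorAxisLength": float(props.axis_minor_length),
            "Shape.MinorMajorAxisRatio": (
                float(props.axis_minor_length / props.axis_major_length)
                if props.axis_major_length > 0 else 1.0
            ),
            "Shape.Perimeter": perimeter,
            "Shape.Circularity": circularity,
            "Shape.Eccentricity": float(props.eccentricity),
            "Shape.EquivalentDiameter": float(props.equivalent_diameter_area),
            "Shape.Extent": float(props.extent),
            "Shape.Solidity": float(props.solidity),
            "Shape.FractalDimension": _fractal_dimension(bmask),
        }
        for i, v in enumerate(props.moments_hu, start=1):
            row[f"Shape.HuMoments{i}"] = float(v)
        if intensity is not None:
            for i, v in enumerate(props.moments_weighted_hu, start=1):
                row[f"Shape.WeightedHuMoments{i}"] = float(v)
        rows[idx] = row
    return assemble(rows, columns)
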