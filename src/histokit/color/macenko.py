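"""Macenko stain-vector estimation.

The method projects above-background optical-density pixels onto their
principal 2-D plane, measures each pixel's angle within that plane, and
takes the stain vectors to be the directions at robust angular extremes
(by default the 1st and 99th percentiles).  It needs two chromatically
distinct stain populations; a near-collinear OD cloud is rejected.
"""

from __future__ import annotations

import warnings

import numpy as np

from .deconvolution import StainMatrix, complement_stain_matrix
from .density import DEFAULT_BACKGROUND, rgb_to_od

__all__ = ["estimate_stains_macenko", "CollinearStainsWarning", "order_stain_columns"]

#: Minimum number of above-threshold pixels for a meaningful estimate.
MIN_PIXELS = 50
#: Angular spread (degrees) below which the OD cloud is treated as one stain.
MIN_ANGULAR_SPREAD_DEG = 1.0


class CollinearStainsWarning(UserWarning):
    """Emitted when the OD cloud is nearly one-dimensional."""


def order_stain_columns(w: np.ndarray, names=("hematoxylin", "eosin")) -> StainMatrix:
    """Apply the deterministic column convention.

    The column with the larger second-channel (green-absorbing) component
    comes first and is labeled hematoxylin; signs are fixed so each
    column's entry sum is nonnegative.
    """
    w = np.asarray(w, dtype=float).copy()
    for j in range(w.shape[1]):
        if w[:, j].sum() < 0:
            w[:, j] = -w[:, j]
    if w[1, 1] > w[1, 0]:
        w = w[:, [1, 0] + list(range(2, w.shape[1]))]
    return complement_stain_matrix(StainMatrix(w[:, :2], tuple(names[:2])))


def estimate_stains_macenko(
    im_rgb,
    od_threshold: float = 0.15,
    angle_percentile: float = 1.0,
    bg_intensity: float = DEFAULT_BACKGROUND,
    min_pixels: int = MIN_PIXELS,
) -> StainMatrix:
    """Estimate a two-stain matrix from an RGB field by the Macenko method.

    Parameters
    ----------
    im_rgb : (H, W, 3) array
        RGB intensities on ``[0, bg_intensity]``.
    od_threshold : float
        Pixels whose OD vector norm falls below this are background and
        excluded from the fit.
    angle_percentile : float
        Robust extreme: stain angles are the ``p``-th and ``(100-p)``-th
        percentiles of the in-plane angle distribution.

    Returns
    -------
    StainMatrix
        Complemented 3x3 matrix, columns ordered by the green-absorption
        convention (hematoxylin first).

    Raises
    ------
    ValueError
        If too few pixels exceed the threshold or the OD cloud is
        angularly degenerate (single stain).
    """
    od = rgb_to_od(im_rgb, bg_intensity).reshape(-1, 3)
    keep = np.linalg.norm(od, axis=1) >= od_threshold
    od = od[keep]
    if od.shape[0] < min_pixels:
        raise ValueError(
            f"only {od.shape[0]} pixels above OD threshold {od_threshold}; "
            f"need at least {min_pixels}"
        )

    # Principal plane of the (uncentered) OD cloud.
    _, _, vt = np.linalg.svd(od, full_matrices=False)
    plane = vt[:2]
    # Orient the first axis toward the data so angles stay in one branch.
    if plane[0] @ od.mean(axis=0) < 0:
        plane[0] = -plane[0]
    if plane[1].sum() < 0:
        plane[1] = -plane[1]

    proj = od @ plane.T
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, [angle_percentile, 100.0 - angle_percentile])
    spread_deg = np.degrees(hi - lo)
    if spread_deg < MIN_ANGULAR_SPREAD_DEG:
        raise ValueError(
            f"OD cloud angular spread {spread_deg:.3f} deg is degenerate; "
            "image appears to contain a single stain"
        )
    if spread_deg < 5.0:
        warnings.warn(
            f"OD cloud angular spread is only {spread_deg:.2f} deg; "
            "stain estimates may be unstable",
            CollinearStainsWarning,
        )

    v1 = np.cos(lo) * plane[0] + np.sin(lo) * plane[1]
    v2 = np.cos(hi) * plane[0] + np.sin(hi) * plane[1]
    return order_stain_columns(np.column_stack([v1, v2]))
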