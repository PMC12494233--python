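"""Gaussian derivative (edge) filtering."""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

__all__ = ["gaussian_grad"]


def gaussian_grad(im, sigma: float):
    """Smoothed image gradient via separable derivative-of-Gaussian kernels.

    Parameters
    ----------
    im : (H, W) array
        Single-channel raster; must be finite.
    sigma : float
        Gaussian scale in pixels (> 0).

    Returns
    -------
    (dx, dy, magnitude, direction)
        ``dx`` is the column-direction derivative, ``dy`` the row
        direction; ``direction = arctan2(dy, dx)`` lies in (-pi, pi].
        Boundaries use reflective padding.
    """
    im = np.asarray(im, dtype=float)
    if im.ndim != 2:
        raise ValueError("expected a 2-D raster")
    if not np.isfinite(im).all():
        raise ValueError("input contains non-finite values")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    dx = ndi.gaussian_filter(im, sigma, order=(0, 1), mode="reflect")
    dy = ndi.gaussian_filter(im, sigma, order=(1, 0), mode="reflect")
    mag = np.hypot(dx, dy)
    direction = np.arctan2(dy, dx)
    return dx, dy, mag, direction
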