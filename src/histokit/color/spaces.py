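"""Color-space conversions used throughout histology preprocessing.

Conversions provided:

* RGB <-> HSI (hue-saturation-intensity).  Hue is stored as a fraction of
  a turn in ``[0, 1)`` with pure red at 0, which makes circular hue
  arithmetic a matter of ``mod 1``.
* RGB <-> CIELAB (thin wrappers over scikit-image).
* RGB <-> Ruderman log-opponent (l-alpha-beta), the decorrelated space in
  which Reinhard-style statistics matching operates.

All functions accept float arrays shaped ``(H, W, 3)`` with RGB values on
the ``[0, 255]`` scale and are pure (no in-place modification).
"""

from __future__ import annotations

import numpy as np
from skimage.color import lab2rgb, rgb2lab

__all__ = [
    "rgb_to_hsi",
    "hsi_to_rgb",
    "rgb_to_lab",
    "lab_to_rgb",
    "rgb_to_lab_opponent",
    "lab_opponent_to_rgb",
    "convert_color_space",
]

# Ruderman et al. log-opponent decomposition: RGB -> LMS cone response,
# elementwise log10, then an orthogonal rotation into (l, alpha, beta).
_RGB2LMS = np.array(
    [
        [0.3811, 0.5783, 0.0402],
        [0.1967, 0.7244, 0.0782],
        [0.0241, 0.1288, 0.8444],
    ]
)
_LMS2LAB = np.diag([1 / np.sqrt(3), 1 / np.sqrt(6), 1 / np.sqrt(2)]) @ np.array(
    [[1, 1, 1], [1, 1, -2], [1, -1, 0]], dtype=float
)
_LMS2RGB = np.linalg.inv(_RGB2LMS)
_LAB2LMS = np.linalg.inv(_LMS2LAB)

# Floor used before logarithms so that black pixels stay finite.
_LMS_FLOOR = 1e-6


def _check_rgb(im: np.ndarray) -> np.ndarray:
    im = np.asarray(im, dtype=float)
    if im.ndim != 3 or im.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB array, got shape {im.shape}")
    if not np.isfinite(im).all():
        raise ValueError("RGB image contains non-finite pixel values")
    return im


def rgb_to_hsi(im_rgb: np.ndarray) -> np.ndarray:
    """Convert RGB (0-255) to hue-saturation-intensity.

    Hue is a fraction of a turn in ``[0, 1)`` with red at 0; saturation is
    ``1 - min/I`` in ``[0, 1]``; intensity is the channel mean on the input
    scale.  Achromatic pixels (r = g = b) get hue 0 and saturation 0.
    """
    im = _check_rgb(im_rgb)
    r, g, b = im[..., 0], im[..., 1], im[..., 2]
    intensity = im.mean(axis=-1)

    minimum = im.min(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        saturation = np.where(intensity > 0, 1.0 - minimum / np.maximum(intensity, 1e-12), 0.0)

    # Hue from the standard trigonometric formula, folded to [0, 1).
    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(num / np.maximum(den, 1e-12), -1.0, 1.0))
    hue = np.where(b > g, 2 * np.pi - theta, theta) / (2 * np.pi)
    hue = np.where(den < 1e-12, 0.0, hue) % 1.0

    return np.stack([hue, saturation, intensity], axis=-1)


def hsi_to_rgb(im_hsi: np.ndarray) -> np.ndarray:
    """Invert :func:`rgb_to_hsi`; output on the 0-255 scale (unclipped)."""
    im = np.asarray(im_hsi, dtype=float)
    h = (im[..., 0] % 1.0) * 2 * np.pi
    s = im[..., 1]
    i = im[..., 2]

    # Sector-wise reconstruction (three 120-degree sectors).
    h_sector = h % (2 * np.pi / 3)
    x = i * (1 - s)
    y = i * (1 + s * np.cos(h_sector) / np.cos(np.pi / 3 - h_sector))
    z = 3 * i - x - y

    out = np.empty(im.shape, dtype=float)
    sector = np.floor(h / (2 * np.pi / 3)).astype(int) % 3
    for k, order in enumerate([(2, 0, 1), (0, 1, 2), (1, 2, 0)]):
        # order = channel indices receiving (x, y, z) in sector k
        m = sector == k
        out[..., order[0]][m] = x[m]
        out[..., order[1]][m] = y[m]
        out[..., order[2]][m] = z[m]
    return out


def rgb_to_lab(im_rgb: np.ndarray) -> np.ndarray:
    """RGB (0-255) to CIELAB via scikit-image (sRGB, D65)."""
    return rgb2lab(_check_rgb(im_rgb) / 255.0)


def lab_to_rgb(im_lab: np.ndarray) -> np.ndarray:
    """CIELAB back to RGB on the 0-255 scale."""
    return lab2rgb(np.asarray(im_lab, dtype=float)) * 255.0


def rgb_to_lab_opponent(im_rgb: np.ndarray) -> np.ndarray:
    """RGB (0-255) to Ruderman log-opponent (l, alpha, beta) coordinates."""
    im = _check_rgb(im_rgb) / 255.0
    lms = im @ _RGB2LMS.T
    log_lms = np.log10(np.maximum(lms, _LMS_FLOOR))
    return log_lms @ _LMS2LAB.T


def lab_opponent_to_rgb(im_lab: np.ndarray) -> np.ndarray:
    """Invert :func:`rgb_to_lab_opponent`; output on 0-255 (unclipped)."""
    log_lms = np.asarray(im_lab, dtype=float) @ _LAB2LMS.T
    lms = np.power(10.0, log_lms)
    return (lms @ _LMS2RGB.T) * 255.0


_FORWARD = {"hsi": rgb_to_hsi, "cielab": rgb_to_lab, "log_opponent": rgb_to_lab_opponent}
_INVERSE = {"hsi": hsi_to_rgb, "cielab": lab_to_rgb, "log_opponent": lab_opponent_to_rgb}


def convert_color_space(
    im: np.ndarray, target: str, inverse: bool = False
) -> np.ndarray:
    """Dispatch conversion between RGB and a named color space.

    Parameters
    ----------
    im : ndarray
        ``(H, W, 3)`` raster.  RGB on 0-255 for the forward direction,
        target-space coordinates for ``inverse=True``.
    target : {"hsi", "cielab", "log_opponent"}
        Name of the non-RGB space (case-insensitive).
    inverse : bool
        Convert from ``target`` back to RGB.
    """
    key = target.lower()
    table = _INVERSE if inverse else _FORWARD
    if key not in table:
        raise ValueError(f"unknown color space {target!r}; options: {sorted(table)}")
    if not inverse:
        return table[key](im)
    im = np.asarray(im, dtype=float)
    if not np.isfinite(im).all():
        raise ValueError("input contains non-finite values")
    return table[key](im)
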