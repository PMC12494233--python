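"""Intensity <-> stain-density transforms (Beer-Lambert spaces).

Optical density (OD) of a transmitted intensity ``I`` against background
``I0`` is ``log10(I0 / I)``: the space in which stain absorptions add
linearly.  Stain darkness (SDA) rescales OD so the representable range is
``[0, 255]``: ``SDA = OD * 255 / log10(I0)``.

Intensities are clamped to ``[intensity_floor, I0]`` before the logarithm
so black pixels remain finite; the default floor of 1 bounds OD at
``log10(I0)``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rgb_to_od", "od_to_rgb", "rgb_to_sda", "sda_to_rgb", "intensity_density_transform"]

DEFAULT_BACKGROUND = 255.0
DEFAULT_FLOOR = 1.0


def _as_float(im):
    im = np.asarray(im, dtype=float)
    if not np.isfinite(im).all():
        raise ValueError("image contains non-finite values")
    return im


def rgb_to_od(im_rgb, bg_intensity: float = DEFAULT_BACKGROUND, floor: float = DEFAULT_FLOOR):
    """Intensity (0..I0) to optical density ``log10(I0 / I)`` per channel."""
    if bg_intensity <= 0:
        raise ValueError("background intensity must be positive")
    im = np.clip(_as_float(im_rgb), floor, bg_intensity)
    return np.log10(bg_intensity / im)


def od_to_rgb(im_od, bg_intensity: float = DEFAULT_BACKGROUND):
    """Optical density back to intensity: ``I = I0 * 10**(-OD)``."""
    return bg_intensity * np.power(10.0, -np.asarray(im_od, dtype=float))


def _sda_scale(bg_intensity: float) -> float:
    return 255.0 / np.log10(bg_intensity)


def rgb_to_sda(im_rgb, bg_intensity: float = DEFAULT_BACKGROUND, floor: float = DEFAULT_FLOOR):
    """Intensity to stain darkness: OD rescaled to span [0, 255]."""
    return rgb_to_od(im_rgb, bg_intensity, floor) * _sda_scale(bg_intensity)


def sda_to_rgb(im_sda, bg_intensity: float = DEFAULT_BACKGROUND):
    """Stain darkness back to intensity."""
    return od_to_rgb(np.asarray(im_sda, dtype=float) / _sda_scale(bg_intensity), bg_intensity)


def intensity_density_transform(
    im, space: str = "optical_density", inverse: bool = False,
    bg_intensity: float = DEFAULT_BACKGROUND,
):
    """Convert between intensity and a density space by name.

    ``space`` is ``"optical_density"`` or ``"stain_darkness"``; the map is
    monotone decreasing per channel and exactly invertible for intensities
    in ``[floor, I0]``.
    """
    table = {
        "optical_density": (rgb_to_od, od_to_rgb),
        "stain_darkness": (rgb_to_sda, sda_to_rgb),
    }
    if space not in table:
        raise ValueError(f"unknown density space {space!r}")
    fwd, inv = table[space]
    if inverse:
        return inv(im, bg_intensity)
    return fwd(im, bg_intensity)
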