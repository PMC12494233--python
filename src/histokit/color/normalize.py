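"""Color normalization: Reinhard statistics matching and stain-basis swap.

Reinhard normalization matches per-channel mean and standard deviation in
the Ruderman log-opponent space against a reference.  Because tiles of a
slide normalized independently acquire visible seams, slide-level pooled
statistics (:class:`ReinhardStats`, :func:`aggregate_reinhard_stats`) can
be computed once and reused for every tile.

Deconvolution-based normalization instead unmixes the image with its own
(estimated) stain matrix and re-convolves the concentrations with a target
stain matrix, changing stain color while preserving stain quantity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .deconvolution import (
    StainMatrix,
    color_convolution,
    color_deconvolution,
    complement_stain_matrix,
)
from .density import DEFAULT_BACKGROUND, rgb_to_od
from .macenko import estimate_stains_macenko
from .spaces import lab_opponent_to_rgb, rgb_to_lab_opponent

__all__ = [
    "ReinhardStats",
    "reinhard_stats",
    "aggregate_reinhard_stats",
    "reinhard_normalize",
    "deconvolution_normalize",
]


@dataclass(frozen=True)
class ReinhardStats:
    """Channel means/stds in log-opponent space plus contributing count."""

    mu: np.ndarray
    sigma: np.ndarray
    pixel_count: int

    def __post_init__(self):
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float).reshape(3))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float).reshape(3))
        if (self.sigma < 0).any():
            raise ValueError("sigma components must be nonnegative")
        if self.pixel_count < 1:
            raise ValueError("pixel_count must be >= 1")

    def to_json(self) -> str:
        return json.dumps(
            {"mu": self.mu.tolist(), "sigma": self.sigma.tolist(), "pixel_count": int(self.pixel_count)}
        )

    @classmethod
    def from_json(cls, text: str) -> "ReinhardStats":
        doc = json.loads(text)
        return cls(np.array(doc["mu"]), np.array(doc["sigma"]), int(doc["pixel_count"]))


def reinhard_stats(im_rgb, mask=None) -> ReinhardStats:
    """Compute log-opponent channel statistics of an image (or masked part)."""
    lab = rgb_to_lab_opponent(im_rgb)
    px = lab.reshape(-1, 3)
    if mask is not None:
        px = px[np.asarray(mask, dtype=bool).reshape(-1)]
    if px.shape[0] < 1:
        raise ValueError("no pixels selected for statistics")
    return ReinhardStats(px.mean(axis=0), px.std(axis=0), px.shape[0])


def aggregate_reinhard_stats(parts) -> ReinhardStats:
    """Pool per-tile statistics into exact slide-level statistics.

    Uses the exact pooled mean and pooled (population) variance, not a
    mean of means, so the result equals single-pass statistics over the
    concatenated pixels.
    """
    parts = list(parts)
    if not parts:
        raise ValueError("cannot aggregate an empty list of statistics")
    if len(parts) == 1:
        return parts[0]
    counts = np.array([p.pixel_count for p in parts], dtype=float)
    mus = np.stack([p.mu for p in parts])
    sigmas = np.stack([p.sigma for p in parts])
    n = counts.sum()
    mu = (counts[:, None] * mus).sum(axis=0) / n
    # E[x^2] pooled from per-part second moments.
    second = (counts[:, None] * (sigmas**2 + mus**2)).sum(axis=0) / n
    var = np.maximum(second - mu**2, 0.0)
    return ReinhardStats(mu, np.sqrt(var), int(n))


def reinhard_normalize(im_rgb, target: ReinhardStats, source: ReinhardStats | None = None,
                       mask=None):
    """Match an image's log-opponent statistics to a target.

    Per channel, ``out = (x - mu_src) / sigma_src * sigma_tgt + mu_tgt``.
    A zero source sigma maps the whole channel to the target mean.  When
    ``source`` is None the statistics are measured from ``im_rgb`` itself
    (restricted to ``mask`` if given); the transform is still applied to
    every pixel.
    """
    if source is None:
        source = reinhard_stats(im_rgb, mask=mask)
    lab = rgb_to_lab_opponent(im_rgb)
    scale = np.where(source.sigma > 0, target.sigma / np.maximum(source.sigma, 1e-300), 0.0)
    out = (lab - source.mu) * scale + target.mu
    return np.clip(lab_opponent_to_rgb(out), 0.0, 255.0)


def deconvolution_normalize(
    im_rgb,
    target_w: StainMatrix,
    source_w: StainMatrix | None = None,
    mask=None,
    od_threshold: float = 0.15,
    bg_intensity: float = DEFAULT_BACKGROUND,
):
    """Re-express an image's stain concentrations in a target stain basis.

    Concentrations are unmixed with ``source_w`` (estimated via Macenko
    when None) and re-convolved with ``target_w``.  Pixels outside the
    mask are returned unchanged; the default mask marks as background any
    pixel whose OD vector norm is below ``od_threshold``.  Stain channels
    correspond by column index, so both matrices should follow the same
    ordering convention (hematoxylin first).
    """
    im = np.asarray(im_rgb, dtype=float)
    if source_w is None:
        source_w = estimate_stains_macenko(
            im, od_threshold=od_threshold, bg_intensity=bg_intensity
        )
    if mask is None:
        od = rgb_to_od(im, bg_intensity)
        mask = np.linalg.norm(od, axis=-1) >= od_threshold
    mask = np.asarray(mask, dtype=bool)

    conc = color_deconvolution(im, source_w, bg_intensity)
    # deconvolution yields a third (null) channel; re-convolve in the
    # complemented target basis so residuals are preserved
    out = color_convolution(conc, complement_stain_matrix(target_w), bg_intensity)
    result = im.copy()
    result[mask] = out[mask]
    return result
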