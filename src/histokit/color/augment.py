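"""Stain-concentration augmentation.

Generates color-plausible training variants of a stained image by
unmixing it into stain-darkness concentrations, applying a random affine
perturbation ``c -> alpha * c + beta`` independently per stain channel,
and re-convolving to RGB.  One (alpha, beta) pair is drawn per stain per
image from an explicit seed, so augmentation is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .deconvolution import (
    StainMatrix,
    color_convolution,
    color_deconvolution,
    complement_stain_matrix,
)
from .density import DEFAULT_BACKGROUND

__all__ = ["AugmentParams", "perturb_stain_concentration", "apply_stain_affine"]


@dataclass(frozen=True)
class AugmentParams:
    """Half-ranges of the per-stain perturbation and the RNG seed.

    ``alpha ~ Uniform(1 - sigma1, 1 + sigma1)`` scales each stain's
    concentration; ``beta ~ Uniform(-sigma2, +sigma2)`` shifts it (in
    stain-darkness units).  ``sigma1 = sigma2 = 0`` is the identity.
    """

    sigma1: float = 0.2
    sigma2: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.sigma1 < 0 or self.sigma2 < 0:
            raise ValueError("sigma1 and sigma2 must be nonnegative")


def apply_stain_affine(
    im_rgb, w: StainMatrix, alpha, beta, mask=None,
    bg_intensity: float = DEFAULT_BACKGROUND,
):
    """Deterministic core: perturb concentrations with given (alpha, beta).

    The affine map operates on stain-darkness concentrations (OD scaled
    to [0, 255]), so ``beta`` is in stain-darkness units.  Exposed
    separately so the map can be verified independently of the random
    draw.
    """
    im = np.asarray(im_rgb, dtype=float)
    sda_scale = 255.0 / np.log10(bg_intensity)
    full_w = complement_stain_matrix(w)
    conc = color_deconvolution(im, full_w, bg_intensity) * sda_scale
    # deconvolution always yields one channel per column of the
    # complemented matrix; leave any channel without a supplied
    # coefficient untouched (alpha=1, beta=0)
    alpha = np.asarray(alpha, dtype=float).ravel()
    beta = np.asarray(beta, dtype=float).ravel()
    k = conc.shape[-1]
    if alpha.size > k or beta.size > k:
        raise ValueError(
            f"got {alpha.size} alpha / {beta.size} beta coefficients for "
            f"{k} stain channels"
        )
    alpha = np.concatenate([alpha, np.ones(k - alpha.size)])
    beta = np.concatenate([beta, np.zeros(k - beta.size)])
    perturbed = np.maximum(conc * alpha + beta, 0.0) / sda_scale
    out = color_convolution(perturbed, full_w, bg_intensity)
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        result = im.copy()
        result[m] = out[m]
        return result
    return out


def perturb_stain_concentration(
    im_rgb, w: StainMatrix, params: AugmentParams, mask=None,
    bg_intensity: float = DEFAULT_BACKGROUND,
):
    """Randomly perturb per-stain concentrations and reconstruct RGB."""
    rng = np.random.default_rng(params.seed)
    k = w.matrix.shape[1] if isinstance(w, StainMatrix) else np.asarray(w).shape[1]
    alpha = rng.uniform(1.0 - params.sigma1, 1.0 + params.sigma1, size=k)
    beta = rng.uniform(-params.sigma2, params.sigma2, size=k)
    return apply_stain_affine(im_rgb, w, alpha, beta, mask=mask, bg_intensity=bg_intensity)
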