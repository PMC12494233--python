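"""Blob and ridge enhancement filters.

All filters here expect a nuclei-bright (or ridge-bright, per polarity)
single-channel raster — typically a hematoxylin concentration image — and
return a :class:`FilterResponse` carrying the aggregated response, the
per-pixel argmax scale, and the scale grid.

Scale semantics: Laplacian responses are multiplied by sigma^2 so that a
blob of Gaussian scale sigma0 produces its maximum response at
sigma = sigma0, making the argmax scale a size estimate.  The
difference-of-Gaussian ladder is geometric with ratio 2**(1/4); each DoG
layer's effective scale is the geometric mean of its two smoothing
sigmas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

__all__ = ["FilterResponse", "scale_ladder", "cdog", "clog", "glog", "vesselness"]

LADDER_RATIO = 2.0 ** 0.25


@dataclass
class FilterResponse:
    """Aggregated multi-scale filter output."""

    response: np.ndarray
    scale_map: np.ndarray | None
    sigma_grid: np.ndarray
    extras: dict = field(default_factory=dict)


def _check_raster(im) -> np.ndarray:
    im = np.asarray(im, dtype=float)
    if im.ndim != 2:
        raise ValueError("expected a 2-D raster")
    if not np.isfinite(im).all():
        raise ValueError("input contains non-finite values")
    return im


def _as_mask(mask, shape) -> np.ndarray:
    if mask is None:
        return np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError("mask shape does not match image")
    return mask


def scale_ladder(sigma_min: float, sigma_max: float, ratio: float = LADDER_RATIO):
    """Geometric sigma ladder covering [sigma_min, sigma_max]."""
    if not 0 < sigma_min < sigma_max:
        raise ValueError("need 0 < sigma_min < sigma_max")
    n = int(np.ceil(np.log(sigma_max / sigma_min) / np.log(ratio)))
    return sigma_min * ratio ** np.arange(n + 1)


def cdog(im, mask=None, sigma_min: float = 2.0, sigma_max: float = 10.0):
    """Scale-adaptive multi-scale difference-of-Gaussian blob filter.

    Blurs the image along a geometric sigma ladder and takes per-pixel
    differences of consecutive levels (fine minus coarse, so bright blobs
    respond positively).  The per-pixel maximum over layers and the
    effective scale of the maximizing layer are returned; the response is
    zeroed outside the mask.
    """
    im = _check_raster(im)
    mask = _as_mask(mask, im.shape)
    sigmas = scale_ladder(sigma_min, sigma_max)
    blurred = [ndi.gaussian_filter(im, s, mode="reflect") for s in sigmas]
    eff = np.sqrt(sigmas[:-1] * sigmas[1:])

    response = np.full(im.shape, -np.inf)
    arg = np.zeros(im.shape, dtype=int)
    for i in range(len(sigmas) - 1):
        layer = blurred[i] - blurred[i + 1]
        take = layer > response
        response[take] = layer[take]
        arg[take] = i
    response[~mask] = 0.0
    return FilterResponse(response, eff[arg], eff)


def clog(im, mask=None, sigma_min: float = 2.0, sigma_max: float = 10.0):
    """Constrained multi-scale Laplacian-of-Gaussian for nuclear seeding.

    The scale-normalized LoG (``-sigma^2 * laplace(G_sigma * im)``, bright
    blobs positive) is maximized over a geometric sigma ladder, but at
    each pixel only scales no larger than the pixel's distance to the
    mask boundary are admissible (floored at ``sigma_min``, capped at
    ``sigma_max``), which suppresses spuriously coarse responses near
    object edges.  The response is exactly zero outside the mask; an
    empty mask yields an all-zero response.
    """
    im = _check_raster(im)
    mask = _as_mask(mask, im.shape)
    sigmas = scale_ladder(sigma_min, sigma_max)
    if not mask.any():
        return FilterResponse(np.zeros(im.shape), np.full(im.shape, sigmas[0]), sigmas)

    bound = np.clip(ndi.distance_transform_edt(mask), sigma_min, sigma_max)
    response = np.full(im.shape, -np.inf)
    arg = np.zeros(im.shape, dtype=int)
    for i, s in enumerate(sigmas):
        layer = -(s**2) * ndi.gaussian_laplace(im, s, mode="reflect")
        admissible = s <= bound
        take = admissible & (layer > response)
        response[take] = layer[take]
        arg[take] = i
    response[~mask] = 0.0
    response[~np.isfinite(response)] = 0.0
    return FilterResponse(response, sigmas[arg], sigmas)


def _glog_kernel(sigma: float, elongation: float, theta: float, truncate: float = 4.0):
    # Anisotropic LoG with area-preserving axes: the major/minor sigmas
    # are sigma*sqrt(e) and sigma/sqrt(e), normalized by their product.
    su = sigma * np.sqrt(elongation)
    sv = sigma / np.sqrt(elongation)
    radius = int(np.ceil(truncate * max(su, sv)))
    y, x = np.mgrid[-radius : radius + 1, -radius : radius + 1].astype(float)
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * x + st * y
    v = -st * x + ct * y
    g = np.exp(-0.5 * ((u / su) ** 2 + (v / sv) ** 2))
    g /= g.sum()
    lap = g * ((u**2 / su**4 - 1.0 / su**2) + (v**2 / sv**4 - 1.0 / sv**2))
    k = -(su * sv) * lap
    return k - k.mean()  # zero DC so flat inputs give exactly zero


def glog(im, sigma_grid, orientations: int = 4, elongation_grid=(1.0, 1.5, 2.0)):
    """Generalized (oriented, elliptical) LoG blob filter.

    Responses of rotated elliptical LoG kernels are aggregated by maximum
    over scale, orientation, and elongation.  ``extras`` records the
    argmax elongation and orientation maps.
    """
    im = _check_raster(im)
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    elong = np.asarray(elongation_grid, dtype=float)
    if orientations < 1:
        raise ValueError("orientations must be >= 1")
    if sigma_grid.size == 0 or elong.size == 0 or (sigma_grid <= 0).any() or (elong < 1).any():
        raise ValueError("sigma_grid must be positive and elongations >= 1")

    thetas = np.pi * np.arange(orientations) / orientations
    response = np.full(im.shape, -np.inf)
    scale_map = np.full(im.shape, sigma_grid[0])
    elong_map = np.full(im.shape, elong[0])
    theta_map = np.zeros(im.shape)
    for s in sigma_grid:
        for e in elong:
            # elongation 1 is orientation-free; one kernel suffices
            for theta in (thetas if e > 1 else thetas[:1]):
                layer = ndi.convolve(im, _glog_kernel(s, e, theta), mode="reflect")
                take = layer > response
                response[take] = layer[take]
                scale_map[take] = s
                elong_map[take] = e
                theta_map[take] = theta
    return FilterResponse(
        response, scale_map, sigma_grid,
        extras={"elongation_map": elong_map, "orientation_map": theta_map},
    )


def vesselness(im, sigma_grid, polarity: str = "bright", beta: float = 0.5):
    """Hessian-eigenvalue ridge (vesselness) filter.

    At each scale the sigma^2-normalized Hessian is diagonalized; the
    ridge score is high where the large eigenvalue dominates the small
    one (``|l2| >> |l1|``) with the sign matching ``polarity`` (bright
    ridges: l2 < 0).  The structureness cutoff gamma is half the maximum
    Hessian norm at each scale.  Scores are maximized over scales.
    """
    im = _check_raster(im)
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    if sigma_grid.size == 0:
        raise ValueError("sigma_grid must be non-empty")
    if polarity not in ("bright", "dark"):
        raise ValueError("polarity must be 'bright' or 'dark'")

    response = np.zeros(im.shape)
    scale_map = np.full(im.shape, sigma_grid[0])
    # truncate=8: the default truncation leaves the derivative kernels
    # with a nonzero weight sum (~1e-4), which turns flat regions into
    # spurious structure proportional to their intensity
    for s in sigma_grid:
        hrr = s**2 * ndi.gaussian_filter(im, s, order=(2, 0), mode="reflect", truncate=8.0)
        hcc = s**2 * ndi.gaussian_filter(im, s, order=(0, 2), mode="reflect", truncate=8.0)
        hrc = s**2 * ndi.gaussian_filter(im, s, order=(1, 1), mode="reflect", truncate=8.0)
        # closed-form symmetric 2x2 eigenvalues
        tr_half = 0.5 * (hrr + hcc)
        disc = np.sqrt(np.maximum(0.25 * (hrr - hcc) ** 2 + hrc**2, 0.0))
        e1, e2 = tr_half - disc, tr_half + disc  # e1 <= e2 numerically
        small = np.where(np.abs(e1) <= np.abs(e2), e1, e2)
        large = np.where(np.abs(e1) <= np.abs(e2), e2, e1)

        wanted = large < 0 if polarity == "bright" else large > 0
        structure = np.sqrt(small**2 + large**2)
        gamma = 0.5 * structure.max()
        # floor keeps gamma from adapting to numerical noise on a
        # featureless image
        if gamma <= 1e-9 * max(1.0, float(np.abs(im).max())):
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            rb2 = np.where(large != 0, (small / np.where(large != 0, large, 1.0)) ** 2, 0.0)
        score = np.exp(-rb2 / (2 * beta**2)) * (1 - np.exp(-(structure**2) / (2 * gamma**2)))
        score = np.where(wanted, score, 0.0)
        take = score > response
        response[take] = score[take]
        scale_map[take] = s
    return FilterResponse(response, scale_map, sigma_grid)
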