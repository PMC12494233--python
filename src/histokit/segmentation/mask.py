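"""Tissue/background separation for brightfield fields.

Brightfield slides have a bright, low-variance glass background and a
darker tissue foreground.  :func:`simple_mask` models the darkness
distribution (255 minus the mean-RGB intensity) of a random pixel sample
as a two-component Gaussian mixture, seeded from the two dominant modes
of a kernel-density-smoothed histogram, and thresholds at the darkness
where the two components' posteriors cross.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import argrelmax
from sklearn.mixture import GaussianMixture

__all__ = ["simple_mask"]

#: Components with means closer than this (darkness units) are treated
#: as one mode and rejected as unimodal.
MIN_SEPARATION = 10.0


def simple_mask(im_rgb, sample_fraction: float = 0.1, bandwidth: float = 2.0,
                seed: int = 0, min_separation: float = MIN_SEPARATION):
    """Binary tissue mask from a two-component Gaussian mixture.

    Parameters
    ----------
    im_rgb : (H, W, 3) array
        Brightfield RGB field containing both tissue and background.
    sample_fraction : float
        Fraction of pixels used to fit the mixture.
    bandwidth : float
        Gaussian bandwidth (darkness units) of the histogram smoothing
        used to locate the two initial modes.
    seed : int
        Seed for pixel sampling and the EM fit.

    Returns
    -------
    (H, W) bool array, True on (darker) tissue.

    Raises
    ------
    ValueError
        If the darkness sample is effectively unimodal (component means
        closer than ``min_separation``); choose a manual threshold then.
    """
    im = np.asarray(im_rgb, dtype=float)
    darkness = 255.0 - im.mean(axis=-1)
    flat = darkness.reshape(-1)

    rng = np.random.default_rng(seed)
    n = max(int(sample_fraction * flat.size), 1000)
    sample = rng.choice(flat, size=min(n, flat.size), replace=False)

    # KDE-smoothed histogram at 1-unit resolution; take the two tallest modes.
    hist, edges = np.histogram(sample, bins=256, range=(0.0, 255.0))
    smooth = gaussian_filter1d(hist.astype(float), bandwidth)
    peaks = argrelmax(smooth, order=2)[0]
    if smooth.argmax() not in peaks:  # plateau/edge maxima
        peaks = np.append(peaks, smooth.argmax())
    if peaks.size < 2:
        raise ValueError(
            "darkness distribution appears unimodal; "
            "tissue/background separation needs a manual threshold"
        )
    top2 = peaks[np.argsort(smooth[peaks])[-2:]]
    centers = (edges[:-1] + 0.5 * np.diff(edges))[np.sort(top2)]
    if abs(centers[1] - centers[0]) < min_separation:
        raise ValueError(
            f"dominant darkness modes at {centers[0]:.1f} and {centers[1]:.1f} "
            f"are closer than {min_separation}; use a manual threshold"
        )

    gmm = GaussianMixture(
        n_components=2, means_init=centers.reshape(-1, 1), random_state=seed
    ).fit(sample.reshape(-1, 1))
    means = gmm.means_.ravel()
    if abs(means[0] - means[1]) < min_separation:
        raise ValueError(
            "fitted mixture components overlap; use a manual threshold"
        )
    tissue_comp = int(np.argmax(means))  # darker = larger darkness

    # Threshold where the posterior flips, found on a fine grid.
    grid = np.linspace(means.min(), means.max(), 2048).reshape(-1, 1)
    post = gmm.predict_proba(grid)[:, tissue_comp]
    crossings = np.nonzero(np.diff(post >= 0.5))[0]
    thresh = float(grid[crossings[0], 0]) if crossings.size else float(means.mean())
    return darkness >= thresh
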