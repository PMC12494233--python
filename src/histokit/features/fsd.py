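"""Fourier shape descriptors.

Each object's Moore-traced boundary is resampled to ``K`` points equally
spaced in arc length, written as complex numbers ``col + i*row``, and
Fourier transformed.  The spectral energy at frequencies ``1..K/2``
(positive and negative branches combined) is normalized by the total
non-DC energy and summed over dyadic frequency bins, so the lowest bin
captures the smooth elliptic component and high bins capture boundary
complexity.  The bin energies are invariant to translation, rotation,
and the choice of start point.

Objects with fewer than 4 boundary pixels get an all-zero row with the
``FSD.Degenerate`` flag set.
"""

from __future__ import annotations

import numpy as np

from ..segmentation.label import _trace_single
from ._util import assemble, iter_objects

__all__ = ["compute_fsd_features", "fsd_bin_edges", "resample_boundary"]


def fsd_bin_edges(K: int, n_bins: int = 6):
    """Dyadic frequency-bin edges partitioning 1..K/2.

    Bins are ``[1,2), [2,4), ... , [2**(n-1), K/2]`` (last bin closed).
    """
    edges = [2**i for i in range(n_bins)] + [K // 2 + 1]
    return edges


def resample_boundary(boundary, K: int) -> np.ndarray:
    """Resample a closed boundary to K points equally spaced in arc length."""
    pts = np.asarray(list(boundary) + [boundary[0]], dtype=float)
    seg = np.hypot(*np.diff(pts, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    targets = np.linspace(0.0, total, K, endpoint=False)
    rr = np.interp(targets, arc, pts[:, 0])
    cc = np.interp(targets, arc, pts[:, 1])
    return np.stack([rr, cc], axis=1)


def compute_fsd_features(labels, K: int = 128, n_bins: int = 6):
    """Per-object spectral boundary-energy fractions over dyadic bins."""
    if K < 8:
        raise ValueError("K must be >= 8")
    edges = fsd_bin_edges(K, n_bins)
    columns = [f"FSD.Bin{i}" for i in range(1, n_bins + 1)] + ["FSD.Degenerate"]

    rows = {}
    for idx, sl, sub in iter_objects(labels):
        boundary = _trace_single(sub)
        if len(boundary) < 4:
            rows[idx] = {c: 0.0 for c in columns}
            rows[idx]["FSD.Degenerate"] = 1.0
            continue
        pts = resample_boundary(boundary, K)
        z = pts[:, 1] + 1j * pts[:, 0]
        spectrum = np.fft.fft(z)
        power = np.abs(spectrum) ** 2
        # fold positive and negative branches onto frequencies 1..K/2
        freq_energy = np.zeros(K // 2 + 1)
        for k in range(1, K // 2):
            freq_energy[k] = power[k] + power[K - k]
        freq_energy[K // 2] = power[K // 2]
        total = freq_energy[1:].sum()
        row = {"FSD.Degenerate": 0.0}
        for b in range(n_bins):
            lo, hi = edges[b], edges[b + 1]
            row[f"FSD.Bin{b + 1}"] = (
                float(freq_energy[lo:hi].sum() / total) if total > 0 else 0.0
            )
        rows[idx] = row
    return assemble(rows, columns)
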