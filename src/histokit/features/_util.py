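"""Shared helpers for per-object feature extraction."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

__all__ = ["iter_objects", "assemble", "histogram_stats", "moment_stats"]


def iter_objects(labels):
    """Yield (label_id, bbox_slice, boolean submask) for each object."""
    labels = np.asarray(labels)
    for idx, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is None:
            continue
        yield idx, sl, labels[sl] == idx


def assemble(rows: dict, columns) -> pd.DataFrame:
    """Build a feature table from {label: {column: value}}."""
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(columns))
    df.index.name = "Label"
    return df.astype(float)


def moment_stats(values: np.ndarray):
    """Mean, population std, and zero-variance-safe skewness/kurtosis.

    Skewness is ``m3 / m2**1.5`` and kurtosis the excess ``m4 / m2**2 - 3``
    (population central moments); both are 0 by convention when the
    variance is zero.
    """
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    d = values - mean
    m2 = np.mean(d**2)
    if m2 <= 0:
        return mean, 0.0, 0.0, 0.0
    m3, m4 = np.mean(d**3), np.mean(d**4)
    return mean, np.sqrt(m2), m3 / m2**1.5, m4 / m2**2 - 3.0


def histogram_stats(values: np.ndarray, bins: int = 10):
    """Entropy (bits) and energy of an equal-width histogram.

    Bins span the values' own range; a zero-range sample concentrates in
    one bin (entropy 0, energy 1).
    """
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi <= lo:
        return 0.0, 1.0
    counts, _ = np.histogram(values, bins=bins, range=(lo, hi))
    p = counts / counts.sum()
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    energy = float((p**2).sum())
    return entropy, energy
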