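"""Per-object intensity statistics.

Twelve statistics of the pixel values inside each labeled object:
location (min/max/mean/median and the mean-median difference), spread
(population standard deviation, inter-quartile range, median absolute
deviation), shape (skewness, excess kurtosis), and histogram entropy and
energy (10 equal-width bins over the object's own range, log base 2).
"""

from __future__ import annotations

import numpy as np

from ._util import assemble, histogram_stats, iter_objects, moment_stats

__all__ = ["compute_intensity_features", "INTENSITY_COLUMNS"]

INTENSITY_COLUMNS = [
    "Intensity.Min",
    "Intensity.Max",
    "Intensity.Mean",
    "Intensity.Median",
    "Intensity.MeanMedianDiff",
    "Intensity.Std",
    "Intensity.IQR",
    "Intensity.MAD",
    "Intensity.Skewness",
    "Intensity.Kurtosis",
    "Intensity.HistEntropy",
    "Intensity.HistEnergy",
]


def compute_intensity_features(labels, intensity, num_bins: int = 10):
    """One row of intensity statistics per labeled object."""
    intensity = np.asarray(intensity, dtype=float)
    labels = np.asarray(labels)
    if labels.shape != intensity.shape:
        raise ValueError("labels and intensity must have the same shape")

    rows = {}
    for idx, sl, sub in iter_objects(labels):
        v = intensity[sl][sub]
        mean, std, skew, kurt = moment_stats(v)
        median = float(np.median(v))
        q75, q25 = np.percentile(v, [75, 25])
        entropy, energy = histogram_stats(v, num_bins)
        rows[idx] = {
            "Intensity.Min": float(v.min()),
            "Intensity.Max": float(v.max()),
            "Intensity.Mean": mean,
            "Intensity.Median": median,
            "Intensity.MeanMedianDiff": mean - median,
            "Intensity.Std": std,
            "Intensity.IQR": float(q75 - q25),
            "Intensity.MAD": float(np.median(np.abs(v - median))),
            "Intensity.Skewness": skew,
            "Intensity.Kurtosis": kurt,
            "Intensity.HistEntropy": entropy,
            "Intensity.HistEnergy": energy,
        }
    return assemble(rows, INTENSITY_COLUMNS)
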