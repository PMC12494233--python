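"""Small helpers for comparing stain matrices."""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .deconvolution import StainMatrix

__all__ = ["angular_distance_deg", "match_stain_columns"]


def _cols(w) -> np.ndarray:
    m = w.matrix if isinstance(w, StainMatrix) else np.asarray(w, dtype=float)
    norms = np.linalg.norm(m, axis=0)
    return m[:, norms > 1e-12] / norms[norms > 1e-12]


def angular_distance_deg(u, v) -> float:
    """Unsigned angle between two stain vectors, in degrees (sign-blind)."""
    c = abs(float(np.dot(u, v)) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def match_stain_columns(estimated, reference):
    """Pair estimated stain columns with reference columns.

    Hungarian assignment on pairwise angular distance; returns
    ``(pairs, per_pair_angles_deg)`` where pairs are (est_idx, ref_idx).
    Null/zero columns are ignored.
    """
    a, b = _cols(estimated), _cols(reference)
    k = min(a.shape[1], b.shape[1])
    cost = np.array([[angular_distance_deg(a[:, i], b[:, j]) for j in range(b.shape[1])]
                     for i in range(a.shape[1])])
    rows, cols = linear_sum_assignment(cost)
    pairs = list(zip(rows[:k], cols[:k]))
    return pairs, np.array([cost[i, j] for i, j in pairs])
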