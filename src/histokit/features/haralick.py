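"""Haralick texture features from gray-level co-occurrence matrices.

Per object, pixel values are quantized to ``levels`` gray levels by
min-max scaling over the object's own range, a symmetric normalized GLCM
is accumulated for each spatial offset (pairs with both pixels inside
the object), and 13 classical features are computed per offset and
averaged: angular second moment (ASM/energy), contrast, correlation,
variance (sum of squares), inverse difference moment, sum average, sum
variance, sum entropy, entropy, difference variance, difference entropy,
and the two information measures of correlation.

Entropies use log base 2 with ``0*log0 = 0``.  Degenerate conventions:
correlation is 0 when either marginal variance vanishes; IMC1 is 0 when
``max(HX, HY) = 0``; an object with no valid pixel pair for any offset
reports all features 0 with the ``Haralick.Degenerate`` flag set.
"""

from __future__ import annotations

import numpy as np

from ._util import assemble, iter_objects

__all__ = ["compute_haralick_features", "HARALICK_COLUMNS", "glcm_features", "object_glcm"]

DEFAULT_OFFSETS = [(0, 1), (-1, 1), (-1, 0), (-1, -1)]  # 0, 45, 90, 135 degrees

HARALICK_COLUMNS = [
    "Haralick.ASM",
    "Haralick.Contrast",
    "Haralick.Correlation",
    "Haralick.SumOfSquares",
    "Haralick.IDM",
    "Haralick.SumAverage",
    "Haralick.SumVariance",
    "Haralick.SumEntropy",
    "Haralick.Entropy",
    "Haralick.DifferenceVariance",
    "Haralick.DifferenceEntropy",
    "Haralick.IMC1",
    "Haralick.IMC2",
]


def _entropy(p):
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def quantize(values: np.ndarray, levels: int) -> np.ndarray:
    """Min-max quantization of a value sample onto 0..levels-1."""
    lo, hi = values.min(), values.max()
    if hi <= lo:
        return np.zeros(values.shape, dtype=np.intp)
    q = ((values - lo) / (hi - lo) * levels).astype(np.intp)
    return np.minimum(q, levels - 1)


def object_glcm(sub_mask: np.ndarray, quantized: np.ndarray, levels: int, offset):
    """Symmetric co-occurrence counts for one offset within an object mask."""
    dr, dc = offset
    h, w = sub_mask.shape
    glcm = np.zeros((levels, levels), dtype=float)
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a_mask = sub_mask[r0:r1, c0:c1]
    b_mask = sub_mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    both = a_mask & b_mask
    if not both.any():
        return glcm
    a = quantized[r0:r1, c0:c1][both]
    b = quantized[r0 + dr : r1 + dr, c0 + dc : c1 + dc][both]
    np.add.at(glcm, (a, b), 1.0)
    np.add.at(glcm, (b, a), 1.0)
    return glcm


def glcm_features(p: np.ndarray) -> dict:
    """The 13 Haralick features of one normalized symmetric GLCM."""
    levels = p.shape[0]
    i = np.arange(levels)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mx, my = (i * px).sum(), (i * py).sum()
    vx, vy = (((i - mx) ** 2) * px).sum(), (((i - my) ** 2) * py).sum()

    asm = float((p**2).sum())
    contrast = float((((ii - jj) ** 2) * p).sum())
    if vx > 0 and vy > 0:
        correlation = float(((ii * jj * p).sum() - mx * my) / np.sqrt(vx * vy))
    else:
        correlation = 0.0
    variance = float((((ii - mx) ** 2) * p).sum())
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())

    # p_{x+y} over k = 0..2(L-1) and p_{|x-y|} over k = 0..L-1
    psum = np.zeros(2 * levels - 1)
    np.add.at(psum, (ii + jj).ravel(), p.ravel())
    pdiff = np.zeros(levels)
    np.add.at(pdiff, np.abs(ii - jj).ravel(), p.ravel())

    k_sum = np.arange(2 * levels - 1)
    sum_avg = float((k_sum * psum).sum())
    sum_var = float((((k_sum - sum_avg) ** 2) * psum).sum())
    sum_ent = _entropy(psum)

    k_diff = np.arange(levels)
    mu_diff = (k_diff * pdiff).sum()
    diff_var = float((((k_diff - mu_diff) ** 2) * pdiff).sum())
    diff_ent = _entropy(pdiff)

    hxy = _entropy(p.ravel())
    hx, hy = _entropy(px), _entropy(py)
    pxy = np.outer(px, py)
    nz = (p > 0) & (pxy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxy[nz])).sum())
    nz2 = pxy > 0
    hxy2 = float(-(pxy[nz2] * np.log2(pxy[nz2])).sum())
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0)))

    return {
        "Haralick.ASM": asm,
        "Haralick.Contrast": contrast,
        "Haralick.Correlation": correlation,
        "Haralick.SumOfSquares": variance,
        "Haralick.IDM": idm,
        "Haralick.SumAverage": sum_avg,
        "Haralick.SumVariance": sum_var,
        "Haralick.SumEntropy": sum_ent,
        "Haralick.Entropy": hxy,
        "Haralick.DifferenceVariance": diff_var,
        "Haralick.DifferenceEntropy": diff_ent,
        "Haralick.IMC1": float(imc1),
        "Haralick.IMC2": imc2,
    }


def compute_haralick_features(labels, intensity, levels: int = 32, offsets=None):
    """Per-object Haralick features averaged over offsets."""
    if levels < 2:
        raise ValueError("levels must be >= 2")
    offsets = list(offsets) if offsets is not None else list(DEFAULT_OFFSETS)
    intensity = np.asarray(intensity, dtype=float)
    labels = np.asarray(labels)
    if labels.shape != intensity.shape:
        raise ValueError("labels and intensity must have the same shape")

    columns = HARALICK_COLUMNS + ["Haralick.Degenerate"]
    rows = {}
    for idx, sl, sub in iter_objects(labels):
        vals = intensity[sl]
        q = np.zeros(sub.shape, dtype=np.intp)
        q[sub] = quantize(vals[sub], levels)

        per_offset = []
        for off in offsets:
            glcm = object_glcm(sub, q, levels, off)
            total = glcm.sum()
            if total > 0:
                per_offset.append(glcm_features(glcm / total))
        if not per_offset:
            rows[idx] = {c: 0.0 for c in columns}
            rows[idx]["Haralick.Degenerate"] = 1.0
            continue
        row = {c: float(np.mean([f[c] for f in per_offset])) for c in HARALICK_COLUMNS}
        row["Haralick.Degenerate"] = 0.0
        rows[idx] = row
    return assemble(rows, columns)
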