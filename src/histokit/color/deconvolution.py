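"""Color deconvolution: linear unmixing of RGB into stain channels.

Under the Beer-Lambert model the optical density of a pixel is a
nonnegative combination of unit-norm stain absorption vectors: ``od = W c``
where the columns of the 3x3 stain matrix ``W`` are the stains and ``c``
holds per-stain concentrations.  Deconvolution solves this linear system
per pixel; convolution reconstructs RGB from given concentrations.

Stain matrices with only two physical stains are made invertible by
complementing the third column with the normalized cross product of the
first two.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .density import DEFAULT_BACKGROUND, od_to_rgb, rgb_to_od

__all__ = [
    "StainMatrix",
    "complement_stain_matrix",
    "color_deconvolution",
    "color_convolution",
    "DEFAULT_HE_MATRIX",
]

#: Widely used H&E absorption vectors (hematoxylin, eosin), unnormalized.
_H = np.array([0.65, 0.70, 0.29])
_E = np.array([0.07, 0.99, 0.11])

MAX_CONDITION_NUMBER = 1e8


def _normalize_columns(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    norms = np.linalg.norm(w, axis=0)
    out = w.copy()
    nz = norms > 1e-12
    out[:, nz] = w[:, nz] / norms[nz]
    return out


@dataclass(frozen=True)
class StainMatrix:
    """A 3xK matrix of unit-norm stain vectors in optical-density space.

    Columns are normalized on construction; an all-zero column is kept as
    an explicit "null" third stain.
    """

    matrix: np.ndarray
    names: tuple = field(default=())

    def __post_init__(self):
        m = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if m.shape[0] != 3 or m.shape[1] not in (2, 3):
            raise ValueError(f"stain matrix must be 3x2 or 3x3, got {m.shape}")
        object.__setattr__(self, "matrix", _normalize_columns(m))
        names = tuple(self.names) or tuple(f"stain_{i}" for i in range(m.shape[1]))
        if len(names) != m.shape[1]:
            raise ValueError("one name per stain column required")
        object.__setattr__(self, "names", names)

    @property
    def n_stains(self) -> int:
        return self.matrix.shape[1]

    def complemented(self) -> "StainMatrix":
        return complement_stain_matrix(self)

    def to_json(self) -> str:
        return json.dumps({"matrix": self.matrix.tolist(), "names": list(self.names)})

    @classmethod
    def from_json(cls, text: str) -> "StainMatrix":
        doc = json.loads(text)
        return cls(np.array(doc["matrix"]), tuple(doc.get("names", ())))


DEFAULT_HE_MATRIX = StainMatrix(
    np.column_stack([_H / np.linalg.norm(_H), _E / np.linalg.norm(_E)]),
    names=("hematoxylin", "eosin"),
)


def _as_matrix(w) -> np.ndarray:
    if isinstance(w, StainMatrix):
        return w.matrix
    return _normalize_columns(np.asarray(w, dtype=float))


def complement_stain_matrix(w) -> StainMatrix:
    """Fill in a third stain column orthogonal to the first two.

    The complement is the normalized cross product of the two defined
    columns, so the returned 3x3 matrix is invertible whenever the inputs
    are not collinear.  A 3x3 input whose third column is already nonzero
    is returned unchanged.
    """
    names = w.names if isinstance(w, StainMatrix) else ()
    m = _as_matrix(w)
    if m.shape[1] == 3 and np.linalg.norm(m[:, 2]) > 1e-12:
        return StainMatrix(m, names if len(names) == 3 else ())
    a, b = m[:, 0], m[:, 1]
    c = np.cross(a, b)
    norm = np.linalg.norm(c)
    if norm < 1e-9:
        raise ValueError("stain vectors are collinear; cannot complement")
    full = np.column_stack([a, b, c / norm])
    base = list(names[:2]) if len(names) >= 2 else ["stain_0", "stain_1"]
    return StainMatrix(full, tuple(base + ["null"]))


def color_deconvolution(
    im_rgb,
    w,
    bg_intensity: float = DEFAULT_BACKGROUND,
    clip_negative: bool = True,
):
    """Unmix an RGB image into per-stain concentration channels (OD units).

    Parameters
    ----------
    im_rgb : (H, W, 3) array
        Intensities on ``[0, bg_intensity]``.
    w : StainMatrix or (3, 2|3) array
        Stain matrix; a two-column matrix is complemented automatically.
    clip_negative : bool
        Clip small negative concentrations (noise outside the stain cone)
        to zero.

    Returns
    -------
    (H, W, 3) array of concentrations, one channel per stain column.
    """
    wm = complement_stain_matrix(w).matrix
    cond = np.linalg.cond(wm)
    if not np.isfinite(cond) or cond > MAX_CONDITION_NUMBER:
        corr = np.abs(wm.T @ wm)
        np.fill_diagonal(corr, 0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        raise ValueError(
            f"stain matrix is singular (condition number {cond:.3g}); "
            f"columns {i} and {j} are nearly collinear"
        )
    od = rgb_to_od(im_rgb, bg_intensity)
    conc = np.linalg.solve(wm, od.reshape(-1, 3).T).T.reshape(od.shape)
    if clip_negative:
        conc = np.maximum(conc, 0.0)
    return conc


def color_convolution(conc, w, bg_intensity: float = DEFAULT_BACKGROUND):
    """Reconstruct an RGB image from stain concentrations.

    Inverse of :func:`color_deconvolution` up to intensity clamping: zero
    concentration everywhere reproduces the background color.
    """
    wm = _as_matrix(w)
    conc = np.asarray(conc, dtype=float)
    k = conc.shape[-1] if conc.ndim == 3 else 1
    if conc.ndim != 3 or k > wm.shape[1]:
        raise ValueError(
            f"concentration image shape {conc.shape} does not match "
            f"stain matrix with {wm.shape[1]} columns"
        )
    od = conc.reshape(-1, k) @ wm[:, :k].T
    rgb = od_to_rgb(od.reshape(conc.shape[:2] + (3,)), bg_intensity)
    return np.clip(rgb, 0.0, bg_intensity)
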