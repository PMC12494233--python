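"""Composite nucleus + cytoplasm feature extraction.

For each nucleus: morphometry and Fourier shape descriptors on its mask,
and intensity, gradient, and Haralick features on the nuclear stain
raster within the nucleus.  When a cytoplasm raster is given, the same
appearance features are also computed in a cytoplasmic ring of width
``cyto_radius`` around each nucleus; ring pixels are assigned to the
nearest nucleus (so rings of adjacent nuclei never overlap) and exclude
all nucleus pixels.
"""

from __future__ import annotations

import pandas as pd
from skimage.segmentation import expand_labels

from .fsd import compute_fsd_features
from .gradient import compute_gradient_features
from .haralick import compute_haralick_features
from .intensity import compute_intensity_features
from .morphometry import compute_morphometry_features

__all__ = ["compute_nuclei_features", "cytoplasm_rings"]


def cytoplasm_rings(labels, cyto_radius: int):
    """Label image of disjoint cytoplasmic rings around each nucleus."""
    expanded = expand_labels(labels, distance=cyto_radius)
    rings = expanded.copy()
    rings[labels > 0] = 0
    return rings


def _prefixed(df: pd.DataFrame, prefix: str) -> pd.DataFrame:
    return df.rename(columns=lambda c: f"{prefix}.{c}")


def compute_nuclei_features(labels, nucleus_density, cytoplasm_density=None,
                            cyto_radius: int = 8, fsd_K: int = 128,
                            haralick_levels: int = 32):
    """One row of composite features per nucleus."""
    parts = [
        compute_morphometry_features(labels, nucleus_density),
        compute_fsd_features(labels, K=fsd_K),
        _prefixed(compute_intensity_features(labels, nucleus_density), "Nucleus"),
        _prefixed(compute_gradient_features(labels, nucleus_density), "Nucleus"),
        _prefixed(
            compute_haralick_features(labels, nucleus_density, levels=haralick_levels),
            "Nucleus",
        ),
    ]
    if cytoplasm_density is not None:
        rings = cytoplasm_rings(labels, cyto_radius)
        cyto = [
            _prefixed(compute_intensity_features(rings, cytoplasm_density), "Cytoplasm"),
            _prefixed(compute_gradient_features(rings, cytoplasm_density), "Cytoplasm"),
            _prefixed(
                compute_haralick_features(rings, cytoplasm_density, levels=haralick_levels),
                "Cytoplasm",
            ),
        ]
        # a nucleus may lack a ring (fully enclosed); fill its row with 0
        cyto = [df.reindex(parts[0].index).fillna(0.0) for df in cyto]
        parts.extend(cyto)
    return pd.concat(parts, axis=1)
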