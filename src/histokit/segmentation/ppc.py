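"""Positive pixel counting for immunohistochemistry.

Pixels are classified in hue-saturation-intensity space: a pixel is
positive when its circular hue distance to a target hue is within half a
hue window, its saturation is high enough, and its intensity lies inside
the analyzed band.  Positives are graded strong / plain / weak by
half-open intensity intervals (stronger staining = darker); everything
else is negative.  Per-tile results add fieldwise, so whole-slide counts
are an exact merge of tile counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..color.spaces import rgb_to_hsi

__all__ = ["PPCParams", "PPCResult", "count_image", "count_slide"]

CLASS_CODES = {"negative": 0, "weak": 1, "plain": 2, "strong": 3}


@dataclass(frozen=True)
class PPCParams:
    """Thresholds of the positive-pixel rule.

    Defaults target brown DAB staining.  Hue values are fractions of a
    turn; intensity thresholds are on the 0-255 scale and must satisfy
    ``lower < strong < weak < upper``.  Grading (all on positive pixels):
    intensity < strong -> strong; [strong, weak) -> plain;
    [weak, upper) -> weak.
    """

    hue_value: float = 0.05
    hue_width: float = 0.15
    saturation_minimum: float = 0.05
    intensity_upper_limit: float = 245.0
    intensity_weak_threshold: float = 175.0
    intensity_strong_threshold: float = 100.0
    intensity_lower_limit: float = 0.0

    def __post_init__(self):
        if not (self.intensity_lower_limit < self.intensity_strong_threshold
                < self.intensity_weak_threshold < self.intensity_upper_limit):
            raise ValueError("intensity thresholds must satisfy lower < strong < weak < upper")
        if not 0 < self.hue_width <= 1:
            raise ValueError("hue_width must lie in (0, 1]")


@dataclass
class PPCResult:
    """Counts and intensity sums per class, plus an optional class raster."""

    counts: dict = field(default_factory=lambda: {k: 0 for k in CLASS_CODES})
    intensity_sums: dict = field(default_factory=lambda: {k: 0.0 for k in CLASS_CODES})
    label: np.ndarray | None = None

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def positive(self) -> int:
        return self.total - self.counts["negative"]

    def merge(self, other: "PPCResult") -> "PPCResult":
        counts = {k: self.counts[k] + other.counts[k] for k in CLASS_CODES}
        sums = {k: self.intensity_sums[k] + other.intensity_sums[k] for k in CLASS_CODES}
        return PPCResult(counts, sums, None)

    def to_dict(self) -> dict:
        return {
            "counts": {k: int(v) for k, v in self.counts.items()},
            "intensity_sums": {k: float(v) for k, v in self.intensity_sums.items()},
        }


def count_image(im_rgb, params: PPCParams = PPCParams(), return_label: bool = False) -> PPCResult:
    """Classify and count positively stained pixels in one field."""
    hsi = rgb_to_hsi(im_rgb)
    hue, sat, inten = hsi[..., 0], hsi[..., 1], hsi[..., 2]

    hue_dist = np.abs(hue - params.hue_value)
    hue_dist = np.minimum(hue_dist, 1.0 - hue_dist)  # circular
    positive = (
        (hue_dist <= params.hue_width / 2.0)
        & (sat >= params.saturation_minimum)
        & (inten >= params.intensity_lower_limit)
        & (inten < params.intensity_upper_limit)
    )

    strong = positive & (inten < params.intensity_strong_threshold)
    plain = positive & ~strong & (inten < params.intensity_weak_threshold)
    weak = positive & ~strong & ~plain

    label = np.zeros(hue.shape, dtype=np.uint8)
    label[weak] = CLASS_CODES["weak"]
    label[plain] = CLASS_CODES["plain"]
    label[strong] = CLASS_CODES["strong"]

    counts, sums = {}, {}
    masks = {"negative": ~positive, "weak": weak, "plain": plain, "strong": strong}
    for name, m in masks.items():
        counts[name] = int(m.sum())
        sums[name] = float(inten[m].sum())
    return PPCResult(counts, sums, label if return_label else None)


def count_slide(tiles, params: PPCParams = PPCParams()) -> PPCResult:
    """Fieldwise merge of per-tile counts over a non-overlapping tiling.

    ``tiles`` is an iterable of RGB tiles that partition the slide;
    overlapping tiles would be double counted (caller contract).
    """
    result = PPCResult()
    for tile in tiles:
        result = result.merge(count_image(tile, params))
    return result
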