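"""Minimal annotation document: detected points and polygons in global
pixel coordinates, serializable to JSON.

The schema is deliberately small: ``{"elements": [{"type": "point"|
"polygon", "coordinates": [[row, col], ...], "label": int, "meta":
{...}}]}``.  Polygon rings are closed implicitly (last point connects to
the first).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

__all__ = ["AnnotationDoc"]


@dataclass
class AnnotationDoc:
    elements: list = field(default_factory=list)

    def add_point(self, row: float, col: float, label: int, **meta):
        self.elements.append(
            {"type": "point", "coordinates": [[float(row), float(col)]],
             "label": int(label), "meta": meta}
        )

    def add_polygon(self, coords, label: int, **meta):
        self.elements.append(
            {"type": "polygon",
             "coordinates": [[float(r), float(c)] for r, c in coords],
             "label": int(label), "meta": meta}
        )

    def to_json(self) -> str:
        return json.dumps({"elements": self.elements}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AnnotationDoc":
        return cls(json.loads(text)["elements"])
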