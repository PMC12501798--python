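"""Bounding-box primitives shared by the I/O and detection-evaluation layers.

Boxes are corner-form ``(x_min, y_min, x_max, y_max)`` in continuous pixel
coordinates; areas are ``(x_max - x_min) * (y_max - y_min)`` with no +1
correction. Each box carries one of the three seed-object class labels:

* ``IP`` — intact pod (seed still inside the pod carpel)
* ``WS`` — whole seed (seed coat intact, pod removed)
* ``SS`` — split seed (seed coat removed; two halves per seed)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

CLASS_LABELS = ("IP", "WS", "SS")

# COCO category names we accept, mapped onto the canonical short labels.
_CATEGORY_SYNONYMS = {
    "ip": "IP",
    "intact_pod": "IP",
    "ws": "WS",
    "whole_seed": "WS",
    "ss": "SS",
    "split_seed": "SS",
}


def canonical_label(name: str) -> str:
    """Map a category name (case-insensitive) onto {IP, WS, SS}.

    Raises ``ValueError`` for anything unrecognised rather than guessing.
    """
    try:
        return _CATEGORY_SYNONYMS[name.strip().lower()]
    except KeyError:
        raise ValueError(
            f"unrecognised seed-object category {name!r}; "
            f"expected one of {sorted(set(_CATEGORY_SYNONYMS))}"
        ) from None


@dataclass(frozen=True)
class BoundingBox:
    """One labelled (optionally scored) axis-aligned box."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    class_label: str
    confidence: float | None = None

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"box must have strictly positive area, got "
                f"({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})"
            )
        if self.class_label not in CLASS_LABELS:
            raise ValueError(
                f"class_label must be one of {CLASS_LABELS}, got {self.class_label!r}"
            )
        if self.confidence is not None and not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must lie in [0, 1], got {self.confidence}")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    @classmethod
    def from_coco(
        cls, bbox: list[float], class_label: str, confidence: float | None = None
    ) -> "BoundingBox":
        """Build from a COCO ``[x, y, width, height]`` record."""
        x, y, w, h = bbox
        return cls(x, y, x + w, y + h, class_label, confidence)

    def to_coco(self) -> list[float]:
        return [self.x_min, self.y_min, self.x_max - self.x_min, self.y_max - self.y_min]


@dataclass
class ImageAnnotationSet:
    """All boxes belonging to one image, linked to its sample."""

    image_id: str
    width: float
    height: float
    boxes: list[BoundingBox] = field(default_factory=list)
    sample_id: str | None = None

    def clipped(self) -> "ImageAnnotationSet":
        """Clip boxes to the image canvas, warning about any overshoot.

        Annotation tools commonly allow a couple of pixels of overshoot;
        these boxes are clipped, not rejected. A box entirely outside the
        canvas cannot be clipped to positive area and raises instead.
        """
        out: list[BoundingBox] = []
        n_clipped = 0
        for b in self.boxes:
            x0 = min(max(b.x_min, 0.0), self.width)
            y0 = min(max(b.y_min, 0.0), self.height)
            x1 = min(max(b.x_max, 0.0), self.width)
            y1 = min(max(b.y_max, 0.0), self.height)
            if (x0, y0, x1, y1) != (b.x_min, b.y_min, b.x_max, b.y_max):
                n_clipped += 1
            out.append(replace(b, x_min=x0, y_min=y0, x_max=x1, y_max=y1))
        if n_clipped:
            warnings.warn(
                f"image {self.image_id}: clipped {n_clipped} box(es) to the "
                f"{self.width}x{self.height} canvas",
                stacklevel=2,
            )
        return ImageAnnotationSet(self.image_id, self.width, self.height, out, self.sample_id)
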