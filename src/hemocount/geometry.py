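"""Axis-aligned boxes in pixel coordinates.

Convention used throughout the package: images are indexed ``(row, col)``
zero-based; a box is ``(x0, y0, x1, y1)`` with ``x`` the column and ``y`` the
row axis, half-open on both, i.e. it covers columns ``x0..x1-1`` and rows
``y0..y1-1``.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class RegionBox:
    """Axis-aligned rectangle, half-open ``[x0, x1) x [y0, y1)``."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError(f"degenerate box {self}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    def contains_point(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1

    def within_image(self, shape: tuple[int, ...]) -> bool:
        h, w = shape[0], shape[1]
        return 0 <= self.x0 and 0 <= self.y0 and self.x1 <= w and self.y1 <= h

    def intersection_area(self, other: "RegionBox") -> int:
        dx = min(self.x1, other.x1) - max(self.x0, other.x0)
        dy = min(self.y1, other.y1) - max(self.y0, other.y0)
        if dx <= 0 or dy <= 0:
            return 0
        return dx * dy

    def iou(self, other: "RegionBox") -> float:
        inter = self.intersection_area(other)
        union = self.area + other.area - inter
        return inter / union if union else 0.0

    def union_box(self, other: "RegionBox") -> "RegionBox":
        return RegionBox(
            min(self.x0, other.x0),
            min(self.y0, other.y0),
            max(self.x1, other.x1),
            max(self.y1, other.y1),
        )

    def crop(self, image):
        """Return the image slice covered by this box (view, not copy)."""
        return image[self.y0 : self.y1, self.x0 : self.x1]

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.x0, self.y0, self.x1, self.y1)
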