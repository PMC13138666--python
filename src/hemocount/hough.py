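"""Circle detection by Hough voting over edge pixels.

Every edge pixel votes for all circle centres ``(a, b)`` and radii ``r``
consistent with the circle model ``r^2 = (x - a)^2 + (y - b)^2``: the vote
count of a candidate ``(a, b, r)`` is the number of edge pixels whose rounded
distance to ``(a, b)`` equals ``r``.  Candidates reaching the accumulator
threshold (``param2``) are kept and reduced by greedy non-maximum suppression
on centre distance, strongest first.  A perimeter-support check
(:func:`perimeter_support`) then measures what fraction of each candidate's
perimeter actually lies on edge evidence, which is what rejects straight
structures such as hemocytometer grid lines that can accumulate accidental
votes.

Raising ``param2`` (or the support threshold) prunes candidates without
reordering the survivors, so detections are monotone: a stricter threshold
returns a subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class HoughParams:
    """Detection thresholds for the circle transform.

    ``param1`` is the edge-strength (Canny high) threshold used when the
    input is a grayscale image rather than a precomputed edge map; ``param2``
    is the accumulator threshold — the minimum number of supporting edge
    pixels for a candidate circle.  The radius band ``[min_radius,
    max_radius]`` and the minimum distance between accepted centres control
    the scale of detected features and duplicate suppression.
    """

    param1: float = 60.0
    param2: float = 28.0
    min_radius: int = 6
    max_radius: int = 14
    min_center_dist: float | None = None  # defaults to min_radius
    accumulator_resolution: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.min_radius <= self.max_radius):
            raise ValueError("need 0 < min_radius <= max_radius")
        if self.param1 <= 0 or self.param2 <= 0:
            raise ValueError("param1 and param2 must be positive")
        if self.accumulator_resolution != 1:
            raise ValueError("only full-resolution accumulation is supported")

    @property
    def center_dist(self) -> float:
        return float(self.min_radius if self.min_center_dist is None else self.min_center_dist)


@dataclass
class DetectedCircle:
    """Candidate cell: centre ``(x, y)`` = (a, b), radius, and evidence."""

    x: float
    y: float
    radius: float
    votes: int = 0
    perimeter_support: float | None = None

    def as_row(self) -> list[float]:
        s = -1.0 if self.perimeter_support is None else self.perimeter_support
        return [float(self.x), float(self.y), float(self.radius), s]


def circle_offsets(radius: int) -> np.ndarray:
    """Integer offsets ``(dy, dx)`` whose rounded distance to 0 equals radius."""
    r = int(radius)
    dy, dx = np.mgrid[-r - 1 : r + 2, -r - 1 : r + 2]
    mask = np.rint(np.hypot(dy, dx)).astype(int) == r
    return np.stack([dy[mask], dx[mask]], axis=1)


def _is_edge_map(image: np.ndarray) -> bool:
    if image.dtype == bool:
        return True
    vals = np.unique(image)
    return len(vals) <= 2 and set(vals.tolist()) <= {0, 1, 255}


def hough_accumulator(edges: np.ndarray, min_radius: int,
                      max_radius: int) -> np.ndarray:
    """Vote counts of shape ``(n_radii, H, W)`` for radii min..max inclusive."""
    edges = np.asarray(edges, dtype=bool)
    h, w = edges.shape
    radii = range(min_radius, max_radius + 1)
    acc = np.zeros((len(radii), h, w), dtype=np.int32)
    ys, xs = np.nonzero(edges)
    if len(ys) == 0:
        return acc
    for i, r in enumerate(radii):
        off = circle_offsets(r)
        # an edge pixel at p supports centres p - offset
        cy = ys[:, None] - off[None, :, 0]
        cx = xs[:, None] - off[None, :, 1]
        ok = (cy >= 0) & (cy < h) & (cx >= 0) & (cx < w)
        np.add.at(acc[i], (cy[ok], cx[ok]), 1)
    return acc


def hough_circles(image: np.ndarray, params: HoughParams = HoughParams()) -> list[DetectedCircle]:
    """Detect circles in a binary edge map (or a grayscale image).

    Grayscale input is first converted to Canny edges using ``param1`` as the
    high threshold (low = ``param1 / 2``).  Returns circles sorted by vote
    count (ties broken deterministically), mutually separated by at least
    ``min_center_dist``.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("hough_circles expects a single-plane image")
    if _is_edge_map(image):
        edges = image.astype(bool)
    else:
        from .counting import canny_edges

        edges = canny_edges(image, low=params.param1 / 2.0,
                            high=params.param1).astype(bool)

    acc = hough_accumulator(edges, params.min_radius, params.max_radius)
    ir, yy, xx = np.nonzero(acc >= params.param2)
    if len(ir) == 0:
        return []
    votes = acc[ir, yy, xx]
    # strongest first; stable deterministic tie-break on (y, x, r)
    order = np.lexsort((ir, xx, yy, -votes))
    min_d2 = params.center_dist ** 2
    chosen: list[DetectedCircle] = []
    for k in order:
        x, y = float(xx[k]), float(yy[k])
        if any((x - c.x) ** 2 + (y - c.y) ** 2 < min_d2 for c in chosen):
            continue
        chosen.append(DetectedCircle(x=x, y=y,
                                     radius=float(params.min_radius + ir[k]),
                                     votes=int(votes[k])))
    return chosen


def perimeter_support(circle: DetectedCircle, edges: np.ndarray,
                      tolerance: int = 1) -> float:
    """Fraction of perimeter sample points lying within ``tolerance`` px of an edge."""
    edges = np.asarray(edges, dtype=bool)
    h, w = edges.shape
    n = max(16, int(np.ceil(2 * np.pi * circle.radius)))
    theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    px = np.rint(circle.x + circle.radius * np.cos(theta)).astype(int)
    py = np.rint(circle.y + circle.radius * np.sin(theta)).astype(int)
    hits = 0
    for qx, qy in zip(px, py):
        y0, y1 = max(0, qy - tolerance), min(h, qy + tolerance + 1)
        x0, x1 = max(0, qx - tolerance), min(w, qx + tolerance + 1)
        if y0 < y1 and x0 < x1 and edges[y0:y1, x0:x1].any():
            hits += 1
    return hits / n


def verify_perimeter(circle: DetectedCircle, edges: np.ndarray,
                     support_threshold: float = 0.8) -> bool:
    """Accept the circle iff its perimeter edge support reaches the threshold.

    Records the measured support on ``circle.perimeter_support``.
    """
    circle.perimeter_support = perimeter_support(circle, edges)
    return circle.perimeter_support >= support_threshold
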