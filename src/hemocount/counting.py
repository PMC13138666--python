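"""Cell counting inside an ROI crop, and chamber aggregation.

The counting pipeline follows the classical sequence used for hemocytometer
images: grayscale conversion, morphological opening (noise suppression),
Canny edge detection, a Hough circle transform over the radius band expected
for the cell line, and a perimeter-support check that discards candidates —
typically straight grid-line structures — whose perimeter is not actually
traced by edges.

Concentration follows hemocytometer geometry: each chamber grid covers 1 mm^2
at 0.1 mm depth, i.e. 0.1 mm^3 = 1e-4 mL, so

    concentration [cells/mL] = mean count per chamber x dilution factor x 1e4
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage import feature
from skimage.draw import circle_perimeter
from sklearn.base import BaseEstimator

from .hough import DetectedCircle, HoughParams, hough_circles, verify_perimeter
from .morphology import StructuringElement, opening

#: chamber volume of 0.1 mm^3 = 1e-4 mL gives 1e4 chambers per mL
CHAMBER_VOLUMES_PER_ML = 1.0e4

#: ITU-R 601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse an RGB image to single-plane luminance (ITU-R 601 weights)."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB image (H, W, 3), got shape {image.shape}")
    gray = image.astype(np.float64) @ _LUMA
    if np.issubdtype(image.dtype, np.integer):
        return np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    return gray


def canny_edges(gray: np.ndarray, low: float, high: float,
                sigma: float = 1.4) -> np.ndarray:
    """Canny edge map as uint8 {0, 255}; thresholds on the 0-255 gradient scale."""
    if not 0 < low <= high:
        raise ValueError("need 0 < low <= high")
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("canny_edges expects a single-plane image")
    edges = feature.canny(gray.astype(np.float64), sigma=sigma,
                          low_threshold=low, high_threshold=high)
    return edges.astype(np.uint8) * 255


@dataclass
class ChamberCount:
    """Detection result for one chamber image."""

    chamber_index: int
    circles: list[DetectedCircle] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.circles)

    def to_dict(self) -> dict:
        return {
            "index": self.chamber_index,
            "count": self.n_cells,
            "circles": [c.as_row() for c in self.circles],
        }


@dataclass
class CountReport:
    """Aggregate over the (normally four) chambers of one slide."""

    chambers: list[ChamberCount]
    dilution_factor: float
    cell_type: str | None = None

    @property
    def total(self) -> int:
        return sum(c.n_cells for c in self.chambers)

    @property
    def mean_per_chamber(self) -> float:
        return self.total / len(self.chambers)

    @property
    def concentration_cells_per_ml(self) -> float:
        return self.mean_per_chamber * self.dilution_factor * CHAMBER_VOLUMES_PER_ML

    def to_dict(self) -> dict:
        d = {
            "chambers": [c.to_dict() for c in self.chambers],
            "total": self.total,
            "mean": self.mean_per_chamber,
            "dilution": self.dilution_factor,
            "concentration_cells_per_ml": self.concentration_cells_per_ml,
        }
        if self.cell_type is not None:
            d["cell_type"] = self.cell_type
        return d

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def aggregate_report(chambers: list[ChamberCount], dilution_factor: float,
                     cell_type: str | None = None,
                     require_four: bool = True) -> CountReport:
    """Combine chamber counts into a slide-level concentration report.

    The standard protocol reads exactly four chambers; pass
    ``require_four=False`` to aggregate a different number.
    """
    if dilution_factor <= 0:
        raise ValueError("dilution_factor must be > 0")
    if require_four and len(chambers) != 4:
        raise ValueError(f"expected 4 chambers, got {len(chambers)}")
    if not chambers:
        raise ValueError("no chambers to aggregate")
    return CountReport(chambers=list(chambers), dilution_factor=float(dilution_factor),
                       cell_type=cell_type)


class CellCounter(BaseEstimator):
    """Counts circular cells in ROI crops.

    Parameters mirror the pipeline stages: the structuring element of the
    opening, the Canny thresholds (tied to ``param1`` when not overridden:
    high = param1, low = param1 / 2), the Hough radius band and accumulator
    threshold, and the perimeter-support threshold.  Defaults are calibrated
    for the synthetic chamber scenes this package generates (cells of radius
    8-12 px); for other image scales set the radius band accordingly.
    """

    def __init__(
        self,
        selem_shape: str = "square",
        selem_size: int = 3,
        param1: float = 60.0,
        param2: float = 28.0,
        min_radius: int = 6,
        max_radius: int = 14,
        min_center_dist: float | None = None,
        canny_low: float | None = None,
        canny_high: float | None = None,
        canny_sigma: float = 1.4,
        support_threshold: float = 0.8,
    ) -> None:
        self.selem_shape = selem_shape
        self.selem_size = selem_size
        self.param1 = param1
        self.param2 = param2
        self.min_radius = min_radius
        self.max_radius = max_radius
        self.min_center_dist = min_center_dist
        self.canny_low = canny_low
        self.canny_high = canny_high
        self.canny_sigma = canny_sigma
        self.support_threshold = support_threshold

    # -- pipeline stages -------------------------------------------------
    def _hough_params(self) -> HoughParams:
        return HoughParams(param1=self.param1, param2=self.param2,
                           min_radius=self.min_radius, max_radius=self.max_radius,
                           min_center_dist=self.min_center_dist)

    def _thresholds(self) -> tuple[float, float]:
        high = self.param1 if self.canny_high is None else self.canny_high
        low = high / 2.0 if self.canny_low is None else self.canny_low
        return low, high

    def preprocess(self, crop: np.ndarray) -> np.ndarray:
        """Grayscale + morphological opening."""
        crop = np.asarray(crop)
        gray = to_grayscale(crop) if crop.ndim == 3 else crop
        selem = StructuringElement(self.selem_shape, self.selem_size)
        return opening(gray, selem)

    def edges(self, crop: np.ndarray) -> np.ndarray:
        low, high = self._thresholds()
        return canny_edges(self.preprocess(crop), low=low, high=high,
                           sigma=self.canny_sigma)

    def count_chamber(self, crop: np.ndarray, chamber_index: int = 0) -> ChamberCount:
        """Run the full stage sequence on one ROI crop."""
        edge_map = self.edges(crop)
        candidates = hough_circles(edge_map, self._hough_params())
        accepted = [c for c in candidates
                    if verify_perimeter(c, edge_map, self.support_threshold)]
        return ChamberCount(chamber_index=chamber_index, circles=accepted)

    # -- sklearn-flavoured surface --------------------------------------
    def fit(self, X=None, y=None) -> "CellCounter":
        """No-op; the counter has no trainable state."""
        return self

    def predict(self, X) -> np.ndarray:
        """Cell counts for a sequence of ROI crops."""
        return np.array([self.count_chamber(img, i).n_cells
                         for i, img in enumerate(X)], dtype=np.int64)


def draw_overlay(image: np.ndarray, circles: list[DetectedCircle]) -> np.ndarray:
    """RGB copy of the crop with detected circles drawn in red."""
    image = np.asarray(image)
    if image.ndim == 2:
        rgb = np.repeat(image[:, :, np.newaxis], 3, axis=2).astype(np.uint8)
    else:
        rgb = image.astype(np.uint8).copy()
    for c in circles:
        rr, cc = circle_perimeter(int(round(c.y)), int(round(c.x)),
                                  int(round(c.radius)), shape=rgb.shape[:2])
        rgb[rr, cc] = (255, 0, 0)
    return rgb


def write_overlay(path: str | Path, image: np.ndarray,
                  circles: list[DetectedCircle]) -> None:
    iio.imwrite(Path(path), draw_overlay(image, circles))
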