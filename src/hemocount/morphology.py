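"""Morphological erosion, dilation and opening.

Binary semantics: erosion keeps a pixel iff the structuring element S,
centred there, *fits* entirely inside the foreground; dilation sets a pixel
iff S *hits* (intersects) the foreground.  The grayscale operators are the
neighbourhood minimum / maximum over the S footprint, which reduce exactly to
the fits/hits rule on 0/1 images.  Opening is erosion followed by dilation:
it removes objects smaller than S (speckle noise, thin bridges) while
preserving larger shapes, and is idempotent and anti-extensive.

Borders are handled by reflect padding, so an all-foreground image is a fixed
point of every operator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass(frozen=True)
class StructuringElement:
    """Square or disc footprint of odd side length, origin at the centre."""

    shape: str = "square"
    size: int = 3

    def __post_init__(self) -> None:
        if self.shape not in ("square", "disc"):
            raise ValueError(f"unknown structuring element shape {self.shape!r}")
        if self.size < 1 or self.size % 2 == 0:
            raise ValueError("structuring element size must be odd and >= 1")

    def footprint(self) -> np.ndarray:
        if self.shape == "square":
            return np.ones((self.size, self.size), dtype=bool)
        rad = self.size // 2
        yy, xx = np.mgrid[-rad : rad + 1, -rad : rad + 1]
        return (yy**2 + xx**2) <= rad**2


def _window_reduce(image: np.ndarray, selem: StructuringElement,
                   reduce_max: bool) -> np.ndarray:
    if image.ndim != 2:
        raise ValueError("morphology expects a single-plane image")
    fp = selem.footprint()
    rad = selem.size // 2
    if rad == 0:
        return image.copy()
    padded = np.pad(image, rad, mode="reflect")
    windows = sliding_window_view(padded, (selem.size, selem.size))
    stack = windows[:, :, fp]  # (H, W, n_footprint)
    return stack.max(axis=-1) if reduce_max else stack.min(axis=-1)


def erode(image: np.ndarray, selem: StructuringElement = StructuringElement()) -> np.ndarray:
    """Neighbourhood minimum; on 0/1 images: 1 iff S fits the foreground."""
    return _window_reduce(np.asarray(image), selem, reduce_max=False)


def dilate(image: np.ndarray, selem: StructuringElement = StructuringElement()) -> np.ndarray:
    """Neighbourhood maximum; on 0/1 images: 1 iff S hits the foreground."""
    return _window_reduce(np.asarray(image), selem, reduce_max=True)


def opening(image: np.ndarray, selem: StructuringElement = StructuringElement()) -> np.ndarray:
    """Erosion followed by dilation with the same structuring element."""
    return dilate(erode(image, selem), selem)
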