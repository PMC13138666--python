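"""Seeded synthetic hemocytometer scenes with exact ground truth.

No public phone-photo dataset of counting chambers exists, so the package
carries its own scene generator and every downstream stage is tested against
it.  Two kinds of scene are produced:

* a *chamber* scene — the bright grid-ruled counting area itself, containing
  dark quasi-circular cells within a radius band (what the counting pipeline
  sees after ROI cropping);
* a *phone* scene — a chamber scene pasted at a random offset into a larger,
  darker, cluttered canvas, emulating a hand-held phone photograph with
  extraneous background around the chamber (what the ROI detector sees).

Ground truth (cell centres/radii, count, and for phone scenes the chamber
bounding box) is recorded exactly as drawn.  Generation is a pure function of
:class:`SceneParams`: the same parameters, including the seed, reproduce the
same pixels bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize

from .geometry import RegionBox


class PlacementError(RuntimeError):
    """Rejection sampling could not place the requested number of cells."""


@dataclass(frozen=True)
class SceneParams:
    """Parameters of a synthetic chamber scene.

    Intensities are on the 0-255 grayscale; cells default darker than the
    chamber background (the polarity seen through a hemocytometer), which can
    be inverted by swapping the intensities.  ``min_center_separation`` at
    least ``2 * r_max`` guarantees non-overlapping cells.
    """

    image_size: tuple[int, int] = (400, 400)  # (height, width)
    n_cells: int = 50
    radius_range: tuple[float, float] = (8.0, 12.0)
    min_center_separation: float = 24.0
    grid_spacing: int = 50
    grid_line_width: int = 2
    cell_intensity: float = 70.0
    background_intensity: float = 200.0
    grid_intensity: float = 150.0
    noise_sd: float = 4.0
    illumination_gradient: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        r_min, r_max = self.radius_range
        if r_min < 2:
            raise ValueError("r_min must be >= 2 px")
        if r_max < r_min:
            raise ValueError("radius_range must satisfy r_max >= r_min")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.image_size[0] < 4 * r_max or self.image_size[1] < 4 * r_max:
            raise ValueError("image too small for the requested radius band")
        if self.grid_spacing < 2 or self.grid_line_width < 1:
            raise ValueError("invalid grid geometry")
        if not 0.0 <= self.illumination_gradient <= 1.0:
            raise ValueError("illumination_gradient must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SceneTruth:
    """Exact ground truth for one scene.

    ``cells`` holds ``(center_x, center_y, radius)`` in pixels, ``(x, y)``
    being (column, row).  ``roi_box`` is set for phone scenes only.
    """

    cells: list[tuple[float, float, float]] = field(default_factory=list)
    roi_box: RegionBox | None = None

    @property
    def count(self) -> int:
        return len(self.cells)

    def to_dict(self) -> dict:
        return {
            "cells": [[float(x), float(y), float(r)] for x, y, r in self.cells],
            "count": self.count,
            "roi_box": list(self.roi_box.as_tuple()) if self.roi_box else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SceneTruth":
        box = RegionBox(*d["roi_box"]) if d.get("roi_box") else None
        return cls(cells=[tuple(c) for c in d["cells"]], roi_box=box)


def _place_cells(params: SceneParams, rng: np.random.Generator,
                 margin_shape: tuple[int, int]) -> list[tuple[float, float, float]]:
    """Rejection-sample non-overlapping (x, y, r) triples."""
    h, w = margin_shape
    r_min, r_max = params.radius_range
    sep2 = params.min_center_separation ** 2
    cells: list[tuple[float, float, float]] = []
    max_attempts = 2000 * max(params.n_cells, 1)
    attempts = 0
    while len(cells) < params.n_cells:
        if attempts >= max_attempts:
            raise PlacementError(
                f"placed only {len(cells)}/{params.n_cells} cells after "
                f"{max_attempts} attempts; lower n_cells or the separation"
            )
        attempts += 1
        r = rng.uniform(r_min, r_max)
        # keep the full disc inside the frame
        x = rng.uniform(r + 1, w - r - 1)
        y = rng.uniform(r + 1, h - r - 1)
        if all((x - cx) ** 2 + (y - cy) ** 2 >= sep2 for cx, cy, _ in cells):
            cells.append((x, y, r))
    return cells


def _draw_disc(canvas: np.ndarray, x: float, y: float, r: float,
               intensity: float) -> None:
    """Alpha-blend an anti-aliased filled disc onto a float canvas."""
    h, w = canvas.shape
    y0, y1 = max(0, int(y - r - 2)), min(h, int(y + r + 3))
    x0, x1 = max(0, int(x - r - 2)), min(w, int(x + r + 3))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(xx - x, yy - y)
    alpha = np.clip(r + 0.5 - dist, 0.0, 1.0)
    patch = canvas[y0:y1, x0:x1]
    patch[:] = alpha * intensity + (1.0 - alpha) * patch


def _draw_grid(canvas: np.ndarray, params: SceneParams) -> None:
    lw = params.grid_line_width
    for c0 in range(params.grid_spacing, canvas.shape[1] - lw, params.grid_spacing):
        canvas[:, c0 : c0 + lw] = params.grid_intensity
    for r0 in range(params.grid_spacing, canvas.shape[0] - lw, params.grid_spacing):
        canvas[r0 : r0 + lw, :] = params.grid_intensity


def _finish(canvas: np.ndarray, params: SceneParams,
            rng: np.random.Generator) -> np.ndarray:
    """Apply illumination gradient, replicate to RGB, add noise, quantize."""
    h, w = canvas.shape
    if params.illumination_gradient > 0:
        ramp = np.linspace(1.0 - params.illumination_gradient, 1.0, w)
        canvas = canvas * ramp[np.newaxis, :]
    rgb = np.repeat(canvas[:, :, np.newaxis], 3, axis=2)
    if params.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, params.noise_sd, rgb.shape)
    return np.clip(rgb, 0, 255).astype(np.uint8)


def make_chamber_image(params: SceneParams) -> tuple[np.ndarray, SceneTruth]:
    """Render a grid-ruled chamber with dark circular cells.

    Returns an RGB uint8 image of ``params.image_size`` and the exact
    :class:`SceneTruth` of the discs drawn.  Raises :class:`PlacementError`
    if non-overlapping placement fails within a bounded number of attempts.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size
    canvas = np.full((h, w), float(params.background_intensity))
    _draw_grid(canvas, params)
    cells = _place_cells(params, rng, (h, w))
    for x, y, r in cells:
        _draw_disc(canvas, x, y, r, params.cell_intensity)
    image = _finish(canvas, params, rng)
    return image, SceneTruth(cells=cells)


def _clutter_background(shape: tuple[int, int], clutter_level: float,
                        base_intensity: float, noise_sd: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Dark cluttered background: low-frequency field + rectangles + strokes.

    ``clutter_level`` 0 gives an exactly uniform canvas.
    """
    h, w = shape
    canvas = np.full((h, w), float(base_intensity))
    if clutter_level <= 0:
        return canvas
    # low-frequency illumination/texture field
    coarse = rng.normal(0.0, 1.0, (8, 8))
    field_img = resize(coarse, (h, w), order=3, mode="reflect",
                       anti_aliasing=False)
    canvas += 40.0 * clutter_level * field_img
    # extraneous objects: filled rectangles
    for _ in range(int(round(12 * clutter_level))):
        rh = rng.integers(20, max(21, h // 3))
        rw = rng.integers(20, max(21, w // 3))
        r0 = rng.integers(0, max(1, h - rh))
        c0 = rng.integers(0, max(1, w - rw))
        canvas[r0 : r0 + rh, c0 : c0 + rw] = rng.uniform(30, 180)
    # thin text-like strokes
    for _ in range(int(round(15 * clutter_level))):
        horizontal = rng.random() < 0.5
        length = int(rng.integers(30, 120))
        thick = int(rng.integers(1, 4))
        r0 = int(rng.integers(0, max(1, h - thick)))
        c0 = int(rng.integers(0, max(1, w - thick)))
        val = rng.uniform(20, 235)
        if horizontal:
            canvas[r0 : r0 + thick, c0 : min(w, c0 + length)] = val
        else:
            canvas[r0 : min(h, r0 + length), c0 : c0 + thick] = val
    if noise_sd > 0:
        canvas += rng.normal(0.0, noise_sd * clutter_level, canvas.shape)
    return canvas


def make_phone_image(
    params: SceneParams,
    clutter_level: float = 0.6,
    canvas_size: tuple[int, int] | None = None,
    background_intensity: float = 90.0,
) -> tuple[np.ndarray, SceneTruth]:
    """Embed a chamber scene in a larger cluttered canvas.

    The chamber rendered from ``params`` is pasted at a random offset; the
    remainder of the canvas imitates the extraneous content of a hand-held
    phone photograph (desk surfaces, labels, shadows).  ``truth.roi_box`` is
    the pasted rectangle and cell coordinates are given in canvas coordinates.
    """
    if not 0.0 <= clutter_level <= 1.0:
        raise ValueError("clutter_level must be in [0, 1]")
    params.validate()
    ch, cw = params.image_size
    if canvas_size is None:
        canvas_size = (int(ch * 1.6), int(cw * 1.6))
    H, W = canvas_size
    if ch > H or cw > W:
        raise ValueError(f"chamber {params.image_size} larger than canvas {canvas_size}")

    chamber, truth = make_chamber_image(params)
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0x9E3779B9]))
    bg = _clutter_background((H, W), clutter_level, background_intensity,
                             params.noise_sd, rng)
    image = np.clip(np.repeat(bg[:, :, np.newaxis], 3, axis=2), 0, 255).astype(np.uint8)

    y_off = int(rng.integers(0, H - ch + 1))
    x_off = int(rng.integers(0, W - cw + 1))
    image[y_off : y_off + ch, x_off : x_off + cw] = chamber
    box = RegionBox(x_off, y_off, x_off + cw, y_off + ch)
    cells = [(x + x_off, y + y_off, r) for x, y, r in truth.cells]
    return image, SceneTruth(cells=cells, roi_box=box)


#: labels follow the training-directory convention: 0 = Non-ROI, 1 = ROI
NON_ROI_LABEL, ROI_LABEL = 0, 1


def make_training_set(
    n_roi: int,
    n_nonroi: int,
    seed: int = 0,
    image_size: tuple[int, int] = (128, 128),
) -> tuple[list[np.ndarray], np.ndarray]:
    """Generate a labelled ROI / Non-ROI classification set.

    ROI examples are chamber crops (grid lines, bright background, a few
    cells) with jittered geometry and intensities; Non-ROI examples are
    clutter-only crops.  Returns ``(images, labels)`` with labels 0 = Non-ROI,
    1 = ROI; images are RGB uint8 of ``image_size``.
    """
    if n_roi < 1 or n_nonroi < 1:
        raise ValueError("need at least one example per class")
    rng = np.random.default_rng(seed)
    images: list[np.ndarray] = []
    labels: list[int] = []
    for i in range(n_roi):
        # vary size and aspect: proposal crops arrive at many shapes and are
        # squashed square by preprocessing, so the classifier must see that
        h = int(image_size[0] * rng.uniform(0.6, 1.4))
        w = int(image_size[1] * rng.uniform(0.6, 1.4))
        scale = min(h, w) / 400.0
        p = SceneParams(
            image_size=(h, w),
            n_cells=int(rng.integers(3, 16)),
            radius_range=(max(2.0, 8 * scale), max(3.0, 12 * scale)),
            min_center_separation=max(6.0, 24 * scale),
            grid_spacing=int(rng.integers(max(8, int(30 * scale * 1.6)),
                                          max(10, int(60 * scale * 1.6)))),
            grid_line_width=int(rng.integers(1, 3)),
            cell_intensity=float(rng.uniform(50, 90)),
            background_intensity=float(rng.uniform(180, 220)),
            grid_intensity=float(rng.uniform(130, 170)),
            noise_sd=float(rng.uniform(2, 6)),
            illumination_gradient=float(rng.uniform(0.0, 0.25)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        img, _ = make_chamber_image(p)
        images.append(img)
        labels.append(ROI_LABEL)
    for i in range(n_nonroi):
        sub = np.random.default_rng(rng.integers(0, 2**31 - 1))
        kind = rng.random()
        if kind < 0.3:
            # blank surface at any brightness: a bright featureless patch is
            # NOT a counting grid, and region proposals produce many of these
            h = int(image_size[0] * rng.uniform(0.6, 1.4))
            w = int(image_size[1] * rng.uniform(0.6, 1.4))
            level = sub.uniform(40, 235)
            bg = np.full((h, w), level) + sub.normal(0, sub.uniform(1, 5), (h, w))
            img = np.clip(np.repeat(bg[:, :, np.newaxis], 3, axis=2),
                          0, 255).astype(np.uint8)
            images.append(img)
            labels.append(NON_ROI_LABEL)
            continue
        if kind < 0.5:
            # elongated sliver, as cut out by a thin region proposal
            h = int(image_size[0] * rng.uniform(0.15, 0.4))
            w = int(image_size[1] * rng.uniform(0.9, 1.4))
            if rng.random() < 0.5:
                h, w = w, h
        else:
            h = int(image_size[0] * rng.uniform(0.6, 1.4))
            w = int(image_size[1] * rng.uniform(0.6, 1.4))
        bg = _clutter_background(
            (h, w),
            clutter_level=float(sub.uniform(0.3, 1.0)),
            base_intensity=float(sub.uniform(50, 130)),
            noise_sd=float(sub.uniform(2, 6)),
            rng=sub,
        )
        img = np.clip(np.repeat(bg[:, :, np.newaxis], 3, axis=2), 0, 255).astype(np.uint8)
        images.append(img)
        labels.append(NON_ROI_LABEL)
    return images, np.asarray(labels, dtype=np.int64)


def write_scene(out_dir: str | Path, name: str, image: np.ndarray,
                truth: SceneTruth) -> tuple[Path, Path]:
    """Write ``<name>.png`` plus a ``<name>.json`` truth sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    png = out_dir / f"{name}.png"
    sidecar = out_dir / f"{name}.json"
    iio.imwrite(png, image)
    sidecar.write_text(json.dumps(truth.to_dict(), indent=1))
    return png, sidecar


def read_truth(path: str | Path) -> SceneTruth:
    return SceneTruth.from_dict(json.loads(Path(path).read_text()))
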