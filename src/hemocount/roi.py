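"""ROI extraction: selective-search proposals + a small CNN classifier.

Phone photographs of a hemocytometer contain large extraneous areas (bench
surfaces, labels, shadows) around the counting grid.  The extractor first
proposes candidate rectangles by hierarchical grouping of an initial
over-segmentation — a selective-search scheme: Felzenszwalb superpixels are
merged greedily by colour/size/fill similarity, and every node of the merge
hierarchy contributes its bounding box as a proposal — and then scores each
proposal with a binary CNN (Non-ROI = 0, ROI = 1).  The highest-scoring ROI
proposal is cropped at original resolution and handed to the counting
pipeline.

The classifier is the shallow architecture the task needs: two 2x2
convolutions (256 then 128 filters) each followed by batch normalization and
max pooling, then a dense head 128-128-64-2 with two batch normalizations
and one dropout, softmax output, trained with categorical cross-entropy and
Adam.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
from skimage.segmentation import felzenszwalb
from skimage.transform import resize
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.preprocessing import OneHotEncoder

from . import nn
from .geometry import RegionBox


class NoRoiFound(RuntimeError):
    """No region proposal was classified as ROI."""


@dataclass
class ClassifiedRegion:
    box: RegionBox
    label: int  # 0 = Non-ROI, 1 = ROI
    score: float  # probability of ROI


# ---------------------------------------------------------------------------
# selective search
# ---------------------------------------------------------------------------

_N_HIST_BINS = 8


def _color_hist(pixels: np.ndarray) -> np.ndarray:
    """L1-normalized per-channel intensity histogram, concatenated."""
    hs = [np.bincount((pixels[:, c] * (_N_HIST_BINS - 1e-6) / 256.0).astype(int),
                      minlength=_N_HIST_BINS) for c in range(pixels.shape[1])]
    h = np.concatenate(hs).astype(np.float64)
    return h / max(h.sum(), 1)


def _similarity(a: dict, b: dict, img_area: int) -> float:
    s_color = np.minimum(a["hist"], b["hist"]).sum()
    s_size = 1.0 - (a["size"] + b["size"]) / img_area
    bb = a["box"].union_box(b["box"])
    s_fill = 1.0 - (bb.area - a["size"] - b["size"]) / img_area
    return float(s_color + s_size + s_fill)


def propose_regions(
    image: np.ndarray,
    max_proposals: int = 200,
    scale: float = 150.0,
    sigma: float = 0.8,
    min_size: int = 80,
    min_box_area: int = 256,
) -> list[RegionBox]:
    """Ranked candidate object boxes by hierarchical segment grouping.

    Boxes from high in the merge hierarchy (large grouped objects) are ranked
    first, then initial segments by decreasing size.  At most
    ``max_proposals`` boxes are returned, all within image bounds.
    """
    image = np.asarray(image)
    if image.ndim == 2:
        image = np.repeat(image[:, :, np.newaxis], 3, axis=2)
    if image.ndim != 3 or image.size == 0 or min(image.shape[:2]) < 8:
        raise ValueError("degenerate input image")
    h, w = image.shape[:2]
    img_area = h * w

    seg = felzenszwalb(image, scale=scale, sigma=sigma, min_size=min_size)
    n_seg = int(seg.max()) + 1
    flat_img = image.reshape(-1, 3).astype(np.float64)
    flat_seg = seg.ravel()

    regions: dict[int, dict] = {}
    order = np.argsort(flat_seg, kind="stable")
    bounds = np.searchsorted(flat_seg[order], np.arange(n_seg + 1))
    ys, xs = np.divmod(order, w)
    for sid in range(n_seg):
        lo, hi = bounds[sid], bounds[sid + 1]
        if lo == hi:
            continue
        sy, sx = ys[lo:hi], xs[lo:hi]
        regions[sid] = {
            "size": hi - lo,
            "box": RegionBox(int(sx.min()), int(sy.min()),
                             int(sx.max()) + 1, int(sy.max()) + 1),
            "hist": _color_hist(flat_img[order[lo:hi]]),
        }

    # adjacency from horizontal/vertical neighbours
    pairs = set()
    for a, b in ((seg[:, :-1], seg[:, 1:]), (seg[:-1, :], seg[1:, :])):
        diff = a != b
        for u, v in zip(a[diff].ravel(), b[diff].ravel()):
            if u != v:
                pairs.add((min(u, v), max(u, v)))

    sims = {p: _similarity(regions[p[0]], regions[p[1]], img_area)
            for p in pairs if p[0] in regions and p[1] in regions}

    merged_boxes: list[RegionBox] = []
    next_id = n_seg
    neighbours: dict[int, set[int]] = {sid: set() for sid in regions}
    for u, v in sims:
        neighbours[u].add(v)
        neighbours[v].add(u)

    while sims:
        (u, v), _ = max(sims.items(), key=lambda kv: (kv[1], -kv[0][0], -kv[0][1]))
        ra, rb = regions.pop(u), regions.pop(v)
        new = {
            "size": ra["size"] + rb["size"],
            "box": ra["box"].union_box(rb["box"]),
            "hist": (ra["hist"] * ra["size"] + rb["hist"] * rb["size"])
            / (ra["size"] + rb["size"]),
        }
        regions[next_id] = new
        merged_boxes.append(new["box"])
        nbrs = (neighbours.pop(u) | neighbours.pop(v)) - {u, v}
        neighbours[next_id] = set()
        sims = {p: s for p, s in sims.items() if u not in p and v not in p}
        for nb in nbrs:
            if nb not in regions:
                continue
            neighbours[next_id].add(nb)
            neighbours[nb].discard(u)
            neighbours[nb].discard(v)
            neighbours[nb].add(next_id)
            key = (min(nb, next_id), max(nb, next_id))
            sims[key] = _similarity(regions[nb], new, img_area)
        next_id += 1

    initial_boxes = [r["box"] for r in
                     sorted(regions.values(), key=lambda r: -r["size"])]
    # later merges = larger grouped objects first
    ranked = list(reversed(merged_boxes)) + initial_boxes

    seen: set[tuple] = set()
    out: list[RegionBox] = []
    for box in ranked:
        key = box.as_tuple()
        if key in seen or box.area < min_box_area:
            continue
        seen.add(key)
        out.append(box)
        if len(out) >= max_proposals:
            break
    return out


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def preprocess_crop(image: np.ndarray, box: RegionBox,
                    out_size: tuple[int, int] = (256, 256)) -> np.ndarray:
    """Crop ``box``, resize to ``out_size`` and scale intensities to [0, 1]."""
    image = np.asarray(image)
    if not box.within_image(image.shape):
        raise ValueError(f"box {box} outside image of shape {image.shape}")
    crop = box.crop(image).astype(np.float32)
    if np.issubdtype(np.asarray(image).dtype, np.integer):
        crop = crop / 255.0
    if crop.shape[:2] != tuple(out_size):
        crop = resize(crop, out_size, order=1, mode="reflect",
                      anti_aliasing=True, preserve_range=True).astype(np.float32)
    return crop


def _stack_images(images, input_size) -> np.ndarray:
    arrs = []
    for img in images:
        img = np.asarray(img)
        if img.ndim == 2:
            img = np.repeat(img[:, :, np.newaxis], 3, axis=2)
        h, w = img.shape[:2]
        arrs.append(preprocess_crop(img, RegionBox(0, 0, w, h), input_size))
    return np.stack(arrs).astype(np.float32)


# ---------------------------------------------------------------------------
# classifier configuration and training
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassifierConfig:
    """Architecture of the ROI/Non-ROI network (see module docstring)."""

    input_size: tuple[int, int] = (256, 256)
    channels: int = 3
    conv_filters: tuple[int, ...] = (256, 128)
    conv_kernel: int = 2
    conv_dropout_rate: float = 0.25
    dense_units: tuple[int, ...] = (128, 128, 64, 2)
    dense_dropout_rate: float = 0.5

    def validate(self) -> None:
        if self.dense_units[-1] != 2:
            raise ValueError("output layer must have width 2 (Non-ROI, ROI)")
        if self.conv_kernel < 1 or not self.conv_filters:
            raise ValueError("invalid convolutional stack")
        h, w = self.input_size
        for _ in self.conv_filters:
            h, w = (h - self.conv_kernel + 1) // 2, (w - self.conv_kernel + 1) // 2
        if h < 1 or w < 1:
            raise ValueError("input_size too small for the conv/pool stack")


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol: 10 epochs, batches of 32, 90/10 split,
    horizontal-flip augmentation, Adam on categorical cross-entropy."""

    epochs: int = 10
    batch_size: int = 32
    train_fraction: float = 0.9
    horizontal_flip: bool = True
    learning_rate: float = 1e-3
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("invalid epochs/batch_size")


def build_classifier(config: ClassifierConfig = ClassifierConfig(),
                     seed: int = 0) -> nn.Sequential:
    """Instantiate the untrained network with seeded initialization."""
    config.validate()
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    h, w = config.input_size
    cin = config.channels
    for f in config.conv_filters:
        layers += [nn.Conv2D(cin, f, config.conv_kernel, rng),
                   nn.BatchNorm(f), nn.ReLU(), nn.MaxPool2()]
        h = (h - config.conv_kernel + 1) // 2
        w = (w - config.conv_kernel + 1) // 2
        cin = f
    layers += [nn.Dropout(config.conv_dropout_rate), nn.Flatten()]
    n_in = h * w * cin
    *hidden, n_out = config.dense_units
    for i, units in enumerate(hidden):
        layers.append(nn.Dense(n_in, units, rng))
        if i < 2:  # batch normalization on the first two dense layers
            layers.append(nn.BatchNorm(units))
        layers.append(nn.ReLU())
        n_in = units
    layers += [nn.Dropout(config.dense_dropout_rate), nn.Dense(n_in, n_out, rng)]
    return nn.Sequential(layers)


def train_classifier(
    model: nn.Sequential,
    images: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig = TrainConfig(),
) -> dict[str, list[float]]:
    """Train in place; returns per-epoch train/validation accuracy history.

    ``images`` must already be preprocessed ``(N, H, W, C)`` float in [0, 1];
    ``labels`` are 0 (Non-ROI) / 1 (ROI).  The set is split 90/10 (per
    ``train_fraction``) into disjoint train/validation parts before
    augmentation; horizontal flips never change a label.
    """
    cfg.validate()
    labels = np.asarray(labels, dtype=np.int64)
    if len(np.unique(labels)) < 2:
        raise ValueError("training needs both classes present")
    onehot = OneHotEncoder(categories=[[0, 1]], sparse_output=False).fit_transform(
        labels.reshape(-1, 1)
    ).astype(np.float32)

    rng = np.random.default_rng(cfg.seed)
    n = len(images)
    perm = rng.permutation(n)
    n_train = max(1, int(round(cfg.train_fraction * n)))
    train_idx, val_idx = perm[:n_train], perm[n_train:]
    x_val, y_val = images[val_idx], labels[val_idx]

    opt = nn.Adam(model, learning_rate=cfg.learning_rate)
    history: dict[str, list[float]] = {"train_accuracy": [], "val_accuracy": [],
                                       "train_loss": []}
    for _ in range(cfg.epochs):
        order = rng.permutation(train_idx)
        correct = total = 0
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb = images[idx].copy()
            yb = onehot[idx]
            if cfg.horizontal_flip:
                flip = rng.random(len(idx)) < 0.5
                xb[flip] = xb[flip, :, ::-1, :]
            logits = model.forward(xb, training=True, rng=rng)
            loss, dlogits = nn.cross_entropy(logits, yb)
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == labels[idx]).sum())
            total += len(idx)
        history["train_accuracy"].append(correct / total)
        history["train_loss"].append(float(np.mean(losses)))
        if len(x_val):
            pv = model.predict_proba(x_val).argmax(axis=1)
            history["val_accuracy"].append(float((pv == y_val).mean()))
        else:
            history["val_accuracy"].append(float("nan"))
    return history


# ---------------------------------------------------------------------------
# sklearn estimator surface
# ---------------------------------------------------------------------------


class RoiClassifier(BaseEstimator, ClassifierMixin):
    """Binary ROI/Non-ROI image classifier (sklearn-compatible).

    ``fit`` takes a sequence of RGB uint8 images (any sizes) and 0/1 labels;
    images are resized to ``input_size`` and scaled to [0, 1] internally.
    Fitted attributes: ``model_`` (the network), ``history_`` (per-epoch
    accuracies), ``classes_``.
    """

    def __init__(
        self,
        input_size: tuple[int, int] = (256, 256),
        conv_filters: tuple[int, ...] = (256, 128),
        conv_kernel: int = 2,
        conv_dropout_rate: float = 0.25,
        dense_units: tuple[int, ...] = (128, 128, 64, 2),
        dense_dropout_rate: float = 0.5,
        epochs: int = 10,
        batch_size: int = 32,
        train_fraction: float = 0.9,
        horizontal_flip: bool = True,
        learning_rate: float = 1e-3,
        random_state: int = 0,
    ) -> None:
        self.input_size = input_size
        self.conv_filters = conv_filters
        self.conv_kernel = conv_kernel
        self.conv_dropout_rate = conv_dropout_rate
        self.dense_units = dense_units
        self.dense_dropout_rate = dense_dropout_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.train_fraction = train_fraction
        self.horizontal_flip = horizontal_flip
        self.learning_rate = learning_rate
        self.random_state = random_state

    # -- config plumbing -------------------------------------------------
    def _classifier_config(self) -> ClassifierConfig:
        return ClassifierConfig(
            input_size=tuple(self.input_size),
            conv_filters=tuple(self.conv_filters),
            conv_kernel=self.conv_kernel,
            conv_dropout_rate=self.conv_dropout_rate,
            dense_units=tuple(self.dense_units),
            dense_dropout_rate=self.dense_dropout_rate,
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            train_fraction=self.train_fraction,
            horizontal_flip=self.horizontal_flip,
            learning_rate=self.learning_rate,
            seed=self.random_state,
        )

    # -- estimator API ---------------------------------------------------
    def fit(self, X, y) -> "RoiClassifier":
        y = np.asarray(y, dtype=np.int64)
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("labels must be 0 (Non-ROI) or 1 (ROI)")
        images = _stack_images(X, tuple(self.input_size))
        self.model_ = build_classifier(self._classifier_config(),
                                       seed=self.random_state)
        self.history_ = train_classifier(self.model_, images, y,
                                         self._train_config())
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        return self.model_.predict_proba(_stack_images(X, tuple(self.input_size)))

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("RoiClassifier is not fitted")

    # -- persistence -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write weights (.npz) plus a JSON sidecar with the configuration."""
        self._check_fitted()
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.model_.state_dict())
        sidecar = {"params": {k: list(v) if isinstance(v, tuple) else v
                              for k, v in self.get_params().items()},
                   "history": self.history_}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "RoiClassifier":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        params = sidecar["params"]
        for key in ("input_size", "conv_filters", "dense_units"):
            params[key] = tuple(params[key])
        est = cls(**params)
        est.model_ = build_classifier(est._classifier_config(),
                                      seed=est.random_state)
        with np.load(path.with_suffix(".npz")) as state:
            est.model_.load_state_dict(dict(state))
        est.history_ = sidecar.get("history", {})
        est.classes_ = np.array([0, 1])
        return est


# ---------------------------------------------------------------------------
# end-to-end extraction
# ---------------------------------------------------------------------------


def classify_regions(image: np.ndarray, classifier: RoiClassifier,
                     boxes: list[RegionBox]) -> list[ClassifiedRegion]:
    """Score every proposal with the classifier."""
    if not boxes:
        return []
    crops = np.stack([preprocess_crop(image, b, tuple(classifier.input_size))
                      for b in boxes])
    probs = classifier.model_.predict_proba(crops)
    return [ClassifiedRegion(box=b, label=int(p.argmax()), score=float(p[1]))
            for b, p in zip(boxes, probs)]


def extract_roi(
    image: np.ndarray,
    classifier: RoiClassifier,
    max_proposals: int = 200,
    **proposal_kwargs,
) -> tuple[np.ndarray, ClassifiedRegion]:
    """Crop the counting-grid region out of a cluttered phone image.

    Among proposals classified ROI the highest-scoring one wins, ties broken
    by larger area (suppressing marginally-scored oversized regions is the
    classifier's job, not the tie-break's).  Raises :class:`NoRoiFound` when
    no proposal is classified as ROI; callers may fall back to the whole
    image.
    """
    classifier._check_fitted()
    boxes = propose_regions(image, max_proposals=max_proposals, **proposal_kwargs)
    scored = classify_regions(image, classifier, boxes)
    rois = [r for r in scored if r.label == 1]
    if not rois:
        raise NoRoiFound("no proposal classified as ROI")
    # score-first selection; scores are compared at 3 decimals so that the
    # area tie-break actually engages once the softmax saturates
    best = max(rois, key=lambda r: (round(r.score, 3), r.box.area))
    return best.box.crop(np.asarray(image)).copy(), best
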