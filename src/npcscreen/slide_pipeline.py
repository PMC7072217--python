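"""Whole-slide tiling, probability-map reconstruction and slide-level model.

A slide is cropped sequentially into non-overlapping 256x256 tiles (edge
tiles padded with white, the background color), every tile is scored by the
patch-level classifier, and the per-tile probabilities are reassembled into
a small 3-channel image — one pixel per tile, channels (NPC, benign,
background).  The probability map is stacked with a tile-aligned RGB
thumbnail (area mean of each tile) into a 6-channel slide input.

The slide-level classifier is a residual net with global average pooling
before its 2-way head, so it accepts any input size.  Training resizes each
batch to one of six fixed target shapes drawn uniformly at random — the
free-input-size augmentation — and uses balanced batches of 8 (4 NPC + 4
benign) with the same SGD/Nesterov + plateau schedule as the patch stage.
At test time a slide is scored under all six targets and the mean is
reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .annotations import Window
from .patch_pipeline import PATCH_SIZE, PatchClassifier, TrainingConfig

__all__ = [
    "RESIZE_TARGETS",
    "ProbabilityMap",
    "SlideInput",
    "SlideClassifier",
    "tile_windows",
    "build_probability_map",
    "compose_slide_input",
    "resize_input",
    "resize_for_batch",
    "train_slide_model",
    "infer_slide",
    "save_probability_map",
    "load_probability_map",
]

#: fixed training resize targets, (height, width) pixels
RESIZE_TARGETS: tuple[tuple[int, int], ...] = (
    (256, 256), (256, 512), (256, 768), (512, 768), (400, 600), (500, 500),
)

_PAD_VALUE = 255  # white, absorbed by the background class


@dataclass
class ProbabilityMap:
    """One pixel per tile; 3 channels (NPC, benign, background) summing to 1."""

    grid: np.ndarray            # (H', W', 3) float32
    slide_id: str = ""
    checkpoint_id: str = ""
    tile_size: int = PATCH_SIZE

    def __post_init__(self) -> None:
        if self.grid.ndim != 3 or self.grid.shape[2] != 3:
            raise ValueError("probability map grid must be (H', W', 3)")


@dataclass
class SlideInput:
    """Probability map stacked with a tile-aligned thumbnail: (H', W', 6)."""

    grid: np.ndarray
    slide_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        if self.grid.ndim != 3 or self.grid.shape[2] != 6:
            raise ValueError("slide input grid must be (H', W', 6)")


def tile_windows(width: int, height: int, size: int = PATCH_SIZE) -> list[Window]:
    """Row-major non-overlapping tile grid covering the whole image.

    ceil(height/size) x ceil(width/size) windows; edge windows extend past
    the image and are padded (with white) at crop time.
    """
    if width < 1 or height < 1:
        raise ValueError("image must be at least 1x1")
    n_rows = -(-height // size)
    n_cols = -(-width // size)
    return [Window(c * size, r * size, size)
            for r in range(n_rows) for c in range(n_cols)]


def _crop_padded(image: np.ndarray, window: Window) -> np.ndarray:
    """Crop a window, padding past-edge area with white."""
    s = window.size
    h, w = image.shape[:2]
    y1 = min(window.y0 + s, h)
    x1 = min(window.x0 + s, w)
    tile = np.full((s, s, image.shape[2]), _PAD_VALUE, dtype=image.dtype)
    tile[:y1 - window.y0, :x1 - window.x0] = image[window.y0:y1, window.x0:x1]
    return tile


def build_probability_map(patch_model: PatchClassifier, slide_image: np.ndarray,
                          slide_id: str = "", checkpoint_id: str = "",
                          batch_size: int = 48) -> ProbabilityMap:
    """Sequentially score every tile and reassemble the probabilities."""
    if slide_image.ndim != 3 or slide_image.shape[2] != 3:
        raise ValueError("slide image must be RGB (H, W, 3)")
    h, w = slide_image.shape[:2]
    windows = tile_windows(w, h)
    n_rows, n_cols = -(-h // PATCH_SIZE), -(-w // PATCH_SIZE)
    grid = np.empty((n_rows, n_cols, 3), dtype=np.float32)
    for start in range(0, len(windows), batch_size):
        chunk = windows[start:start + batch_size]
        tiles = np.stack([_crop_padded(slide_image, wdw) for wdw in chunk])
        probs = patch_model.predict_proba(tiles)
        for wdw, p in zip(chunk, probs):
            grid[wdw.y0 // PATCH_SIZE, wdw.x0 // PATCH_SIZE] = p
    return ProbabilityMap(grid=grid, slide_id=slide_id,
                          checkpoint_id=checkpoint_id)


def _tile_thumbnail(slide_image: np.ndarray) -> np.ndarray:
    """Tile-aligned thumbnail: area mean over each (padded) tile, in [0, 1]."""
    h, w = slide_image.shape[:2]
    n_rows, n_cols = -(-h // PATCH_SIZE), -(-w // PATCH_SIZE)
    ph, pw = n_rows * PATCH_SIZE - h, n_cols * PATCH_SIZE - w
    img = slide_image.astype(np.float32) / 255.0
    img = np.pad(img, ((0, ph), (0, pw), (0, 0)), constant_values=_PAD_VALUE / 255.0)
    return img.reshape(n_rows, PATCH_SIZE, n_cols, PATCH_SIZE, 3).mean(axis=(1, 3))


def compose_slide_input(prob_map: ProbabilityMap, slide_image: np.ndarray,
                        label: str | None = None) -> SlideInput:
    """Concatenate probability channels with the tile-aligned thumbnail."""
    thumb = _tile_thumbnail(slide_image)
    if thumb.shape[:2] != prob_map.grid.shape[:2]:
        raise ValueError(
            f"thumbnail grid {thumb.shape[:2]} does not match probability map "
            f"{prob_map.grid.shape[:2]}; images differ?")
    grid = np.concatenate([prob_map.grid, thumb.astype(np.float32)], axis=2)
    return SlideInput(grid=grid, slide_id=prob_map.slide_id, label=label)


def _bilinear_matrix(n_src: int, n_dst: int) -> np.ndarray:
    """(n_dst, n_src) interpolation weights, pixel-center convention."""
    src = (np.arange(n_dst, dtype=np.float64) + 0.5) * (n_src / n_dst) - 0.5
    src = np.clip(src, 0.0, n_src - 1.0)
    lo = np.floor(src).astype(np.int64)
    hi = np.minimum(lo + 1, n_src - 1)
    t = src - lo
    m = np.zeros((n_dst, n_src), dtype=np.float32)
    rows = np.arange(n_dst)
    m[rows, lo] += (1.0 - t).astype(np.float32)
    m[rows, hi] += t.astype(np.float32)
    return m


def resize_input(grid: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Bilinear resize to (height, width), aspect ratio not preserved.

    Separable matrix form (out = My @ grid @ Mx^T per channel): exact
    pixel-center bilinear interpolation, fast for the small probability
    grids this stage handles.
    """
    grid = np.asarray(grid, dtype=np.float32)
    h, w = grid.shape[:2]
    th, tw = int(target[0]), int(target[1])
    if (h, w) == (th, tw):
        return grid
    my = _bilinear_matrix(h, th)
    mx = _bilinear_matrix(w, tw)
    # (th, h) @ (h, w*c) -> (th, w, c); then columns
    out = (my @ grid.reshape(h, w * grid.shape[2])).reshape(th, w, grid.shape[2])
    out = np.einsum("wj,hjc->hwc", mx, out, optimize=True)
    return np.ascontiguousarray(out, dtype=np.float32)


def resize_for_batch(inputs: Sequence[SlideInput | np.ndarray],
                     rng: np.random.Generator
                     ) -> tuple[np.ndarray, tuple[int, int]]:
    """Resize a batch to one resize target drawn uniformly at random."""
    if len(inputs) == 0:
        raise ValueError("empty batch")
    target = RESIZE_TARGETS[rng.integers(0, len(RESIZE_TARGETS))]
    grids = [x.grid if isinstance(x, SlideInput) else np.asarray(x) for x in inputs]
    batch = np.stack([resize_input(g, target) for g in grids])
    return batch, target


# ---------------------------------------------------------------------------
# persistence (float TIFF + JSON sidecar)
# ---------------------------------------------------------------------------


def save_probability_map(pmap: ProbabilityMap, path) -> None:
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, pmap.grid.astype(np.float32), photometric="rgb")
    sidecar = {"slide_id": pmap.slide_id, "checkpoint_id": pmap.checkpoint_id,
               "tile_size": pmap.tile_size}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_probability_map(path) -> ProbabilityMap:
    import tifffile

    path = Path(path)
    grid = tifffile.imread(path).astype(np.float32)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return ProbabilityMap(grid=grid, slide_id=meta.get("slide_id", ""),
                          checkpoint_id=meta.get("checkpoint_id", ""),
                          tile_size=meta.get("tile_size", PATCH_SIZE))


# ---------------------------------------------------------------------------
# slide-level classifier
# ---------------------------------------------------------------------------

_SLIDE_BATCH = 8            # 4 NPC + 4 benign
_NPC_CLASS = 1              # index of the positive (NPC) logit


class SlideClassifier(ClassifierMixin, BaseEstimator):
    """Free-input-size 2-way slide classifier over 6-channel slide inputs.

    Global average pooling before the head makes the net size-agnostic; the
    per-batch resize to a random member of :data:`RESIZE_TARGETS` is the
    data augmentation.  ``predict_proba`` scores each slide under all six
    targets and averages.
    """

    def __init__(self, learning_rate: float = 0.0017, momentum: float = 0.95,
                 batch_size: int = _SLIDE_BATCH, eval_interval: int = 100,
                 plateau_factor: float = 0.1, plateau_patience: int = 5,
                 min_lr: float = 1e-6, max_steps: int = 600,
                 arch: dict | None = None, seed: int = 0) -> None:
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.batch_size = batch_size
        self.eval_interval = eval_interval
        self.plateau_factor = plateau_factor
        self.plateau_patience = plateau_patience
        self.min_lr = min_lr
        self.max_steps = max_steps
        self.arch = arch
        self.seed = seed

    def fit(self, X: Sequence[SlideInput | np.ndarray], y=None, validation=None):
        """Train on slide inputs with labels y (1 = NPC, 0 = benign).

        ``y`` may be omitted when every element of X is a SlideInput with a
        label.  ``validation`` is an optional (X_val, y_val) pair.
        """
        grids, y = _as_grids(X, y)
        if self.batch_size % 2:
            raise ValueError("batch size must be even (balanced 2-way batches)")
        pos = np.flatnonzero(y == 1)
        neg = np.flatnonzero(y == 0)
        if len(pos) == 0 or len(neg) == 0:
            raise ValueError("training manifest must contain both labels")
        rng = np.random.default_rng(self.seed)
        if validation is not None:
            v_grids, v_y = _as_grids(*validation) if isinstance(validation, tuple) \
                else _as_grids(validation, None)
        else:
            v_grids, v_y = grids, y
        # validation set resized once to the median target for stable curves
        v_batch = np.stack([resize_input(g, (400, 600)) for g in v_grids])

        arch = self.arch or nn.default_slide_arch()
        net = nn.ConvNet(arch, seed=self.seed)
        opt = nn.SGDNesterov(net, self.learning_rate, self.momentum)
        sched = nn.ReduceLROnPlateau(opt, factor=self.plateau_factor,
                                     patience=self.plateau_patience,
                                     min_lr=self.min_lr)
        from .evaluation import auc

        half = self.batch_size // 2
        rows = []
        best_state, best_loss = None, np.inf
        running, n_running = 0.0, 0
        for step in range(1, self.max_steps + 1):
            idx = np.concatenate([rng.choice(pos, half, replace=True),
                                  rng.choice(neg, half, replace=True)])
            batch, _ = resize_for_batch([grids[i] for i in idx], rng)
            yb = y[idx]
            logits = net.forward(batch, train=True)
            loss, dlogits = nn.cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at step {step}")
            net.backward(dlogits)
            opt.step()
            net.step += 1
            running += loss
            n_running += 1
            if step % self.eval_interval == 0 or step == self.max_steps:
                logits = np.concatenate([net.forward(v_batch[i:i + 16])
                                         for i in range(0, len(v_batch), 16)])
                val_loss, _ = nn.cross_entropy(logits, v_y)
                probs = nn.softmax(logits)[:, _NPC_CLASS]
                val_auc = auc(probs, v_y) if 0 < v_y.sum() < len(v_y) else np.nan
                rows.append({"step": step, "train_loss": running / max(n_running, 1),
                             "val_loss": val_loss, "val_auc": val_auc, "lr": opt.lr})
                running, n_running = 0.0, 0
                if val_loss < best_loss:
                    best_loss = val_loss
                    best_state = net.state_dict()
                sched.step(val_loss)
        if best_state is not None:
            net.load_state_dict(best_state)
        self.net_ = net
        self.curves_ = pd.DataFrame(rows)
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Mean NPC/benign probabilities over the six resize targets."""
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "net_")
        grids, _ = _as_grids(X, None, require_labels=False)
        out = np.zeros((len(grids), 2), dtype=np.float64)
        for target in RESIZE_TARGETS:
            batch = np.stack([resize_input(g, target) for g in grids])
            for i in range(0, len(batch), 16):
                out[i:i + 16] += nn.softmax(self.net_.forward(batch[i:i + 16]))
        out /= len(RESIZE_TARGETS)
        # columns: [benign, NPC] -> reorder to sklearn classes_ = [0, 1]
        return out[:, [0, _NPC_CLASS]] if _NPC_CLASS == 1 else out

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def save(self, path) -> None:
        self.net_.save(path)

    @classmethod
    def load(cls, path) -> "SlideClassifier":
        est = cls()
        est.net_ = nn.ConvNet.load(path)
        est.arch = est.net_.arch
        est.seed = est.net_.seed
        est.classes_ = np.array([0, 1])
        return est


def _as_grids(X, y, require_labels: bool = True):
    grids = []
    labels = []
    for x in X:
        if isinstance(x, SlideInput):
            grids.append(x.grid)
            labels.append(1 if x.label == "NPC" else 0 if x.label == "BENIGN" else None)
        else:
            grids.append(np.asarray(x, dtype=np.float32))
            labels.append(None)
    if y is None:
        if require_labels and any(lab is None for lab in labels):
            raise ValueError("labels missing: pass y or labelled SlideInputs")
        y_arr = np.array([0 if lab is None else lab for lab in labels], dtype=np.int64)
    else:
        y_arr = np.asarray(y, dtype=np.int64)
    return grids, y_arr


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def train_slide_model(slide_inputs: Sequence[SlideInput], labels,
                      config: TrainingConfig | None = None,
                      validation=None, arch: dict | None = None,
                      max_steps: int | None = None
                      ) -> tuple[SlideClassifier, pd.DataFrame]:
    kwargs = {}
    if config is not None:
        kwargs = dict(learning_rate=config.learning_rate, momentum=config.momentum,
                      plateau_factor=config.plateau_factor,
                      plateau_patience=config.plateau_patience,
                      min_lr=config.min_lr, seed=config.seed)
    if max_steps is not None:
        kwargs["max_steps"] = max_steps
    est = SlideClassifier(arch=arch, **kwargs)
    est.fit(slide_inputs, labels, validation=validation)
    return est, est.curves_


def infer_slide(slide_model: SlideClassifier, slide_input: SlideInput | np.ndarray) -> float:
    """Slide NPC score: mean softmax NPC probability over the six targets."""
    return float(slide_model.predict_proba([slide_input])[0, 1])
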