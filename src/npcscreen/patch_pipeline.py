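"""Patch sampling and the patch-level classifier.

Training patches are 256x256 crops sampled dynamically from annotated
slides under the acceptance rules used for annotation-constrained cropping:
benign and background patches must lie 100% inside the union of their
class's annotated regions; tumor patches need at least 50% of their area
inside the union of tumor annotations.  Batches are balanced, 16 patches per
class, 48 total.

The classifier itself is a small residual conv net with a 3-way softmax
head, trained with SGD + Nesterov momentum (initial learning rate 0.0017,
momentum 0.95), evaluated on a held-out patch set every ``eval_interval``
steps, with a reduce-on-plateau learning-rate schedule.  It is exposed as a
scikit-learn style estimator (`PatchClassifier`); the module-level functions
are thin wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .annotations import (
    AnnotationRegion,
    TrainingClass,
    Window,
    load_annotations,
    overlap_fraction,
    rasterize,
)

__all__ = [
    "Patch",
    "TrainingConfig",
    "SlideRecord",
    "SlideDataset",
    "PatchClassifier",
    "NoRegionError",
    "SamplingExhaustedError",
    "CompositionError",
    "accept_window",
    "sample_patch",
    "balanced_patch_batch",
    "train_patch_model",
    "infer_patch_probs",
    "compliance_audit",
]

PATCH_SIZE = 256

#: minimum window fraction inside the class union, per training class
_MIN_OVERLAP = {
    TrainingClass.NPC: 0.5,
    TrainingClass.BENIGN: 1.0,
    TrainingClass.BACKGROUND: 1.0,
}


class NoRegionError(LookupError):
    """Slide has no region of the requested class."""


class SamplingExhaustedError(RuntimeError):
    """Rejection sampling failed too often; geometry likely unsatisfiable."""


class CompositionError(ValueError):
    """A balanced batch cannot be assembled (a class is missing)."""


@dataclass
class Patch:
    """One training/inference patch.

    ``pixels`` is the raw uint8 crop; ``normalized()`` returns the float32
    image scaled to [0, 1], which is the network input convention.
    """

    pixels: np.ndarray
    slide_id: str
    window: Window
    label: TrainingClass

    def normalized(self) -> np.ndarray:
        return self.pixels.astype(np.float32) / 255.0


@dataclass
class TrainingConfig:
    """Hyperparameters of the SGD/Nesterov + plateau training loop."""

    learning_rate: float = 0.0017
    momentum: float = 0.95
    batch_size: int = 48
    eval_interval: int = 1000
    plateau_factor: float = 0.1
    plateau_patience: int = 5
    min_lr: float = 1e-6
    max_steps: int = 3000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


# ---------------------------------------------------------------------------
# slide records and datasets
# ---------------------------------------------------------------------------


class SlideRecord:
    """One slide held in memory: image, annotations, and fast-lookup masks.

    Class masks are rasterized lazily (pixel-center rule) and cached with a
    summed-area table, so each window-overlap query is O(1).
    """

    def __init__(self, slide_id: str, image: np.ndarray,
                 regions: Sequence[AnnotationRegion], label: str) -> None:
        self.slide_id = slide_id
        self.image = np.ascontiguousarray(image)
        self.regions = list(regions)
        self.label = label
        self._integrals: dict[TrainingClass, np.ndarray] = {}
        self._samplers: dict = {}

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]

    def class_regions(self, cls: TrainingClass) -> list[AnnotationRegion]:
        return [r for r in self.regions if r.training_class == cls]

    def _integral(self, cls: TrainingClass) -> np.ndarray:
        if cls not in self._integrals:
            mask = rasterize(self.regions, cls, (0, 0, self.width, self.height))
            sat = np.zeros((self.height + 1, self.width + 1), dtype=np.int64)
            np.cumsum(np.cumsum(mask, axis=0, dtype=np.int64), axis=1, out=sat[1:, 1:])
            self._integrals[cls] = sat
        return self._integrals[cls]

    def _sampler(self, cls: TrainingClass, size: int):
        """Cached (cumulative areas, dilated bbox top-left ranges) per class."""
        key = (cls, size)
        if key not in self._samplers:
            regions = self.class_regions(cls)
            if not regions:
                self._samplers[key] = (None, None)
            else:
                areas = np.cumsum([r.area for r in regions])
                ranges = []
                for reg in regions:
                    minx, miny, maxx, maxy = reg.bounds
                    ranges.append((
                        max(int(np.floor(minx)) - _DILATION, 0),
                        min(int(np.ceil(maxx)) + _DILATION, self.width) - size,
                        max(int(np.floor(miny)) - _DILATION, 0),
                        min(int(np.ceil(maxy)) + _DILATION, self.height) - size,
                    ))
                self._samplers[key] = (areas, ranges)
        return self._samplers[key]

    def has_valid_window(self, cls: TrainingClass, size: int = PATCH_SIZE) -> bool:
        """True iff at least one window satisfies the class acceptance rule.

        Vectorized over every possible top-left via the summed-area table;
        cached.  Slides whose regions are too small to admit any compliant
        window are excluded from batch assembly.
        """
        cls = TrainingClass(cls)
        key = ("feasible", cls, size)
        if key not in self._samplers:
            if not self.class_regions(cls):
                self._samplers[key] = False
            elif self.height < size or self.width < size:
                self._samplers[key] = False
            else:
                sat = self._integral(cls)
                sums = (sat[size:, size:] - sat[:-size, size:]
                        - sat[size:, :-size] + sat[:-size, :-size])
                need = _MIN_OVERLAP[cls] * size * size
                self._samplers[key] = bool((sums >= need).any())
        return self._samplers[key]

    def window_overlap(self, window: Window, cls: TrainingClass) -> float:
        """Fraction of window pixel centers inside the class union (O(1))."""
        sat = self._integral(cls)
        x0, y0, s = window.x0, window.y0, window.size
        total = (sat[y0 + s, x0 + s] - sat[y0, x0 + s]
                 - sat[y0 + s, x0] + sat[y0, x0])
        return float(total) / (s * s)

    def crop(self, window: Window) -> np.ndarray:
        return self.image[window.y0:window.y0 + window.size,
                          window.x0:window.x0 + window.size]


class SlideDataset:
    """A list of slide records with convenience constructors."""

    def __init__(self, records: Sequence[SlideRecord]) -> None:
        self.records = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def with_region_filter(self, keep) -> "SlideDataset":
        """Dataset view whose annotations are filtered by ``keep(region)``.

        Used for the training-data-expansion experiment: e.g. drop
        germinal-center / epithelium annotations to emulate the initial
        annotation round.
        """
        out = []
        for rec in self.records:
            out.append(SlideRecord(rec.slide_id, rec.image,
                                   [r for r in rec.regions if keep(r)], rec.label))
        return SlideDataset(out)

    @classmethod
    def from_slides(cls, slides, ids=None) -> "SlideDataset":
        records = []
        for i, slide in enumerate(slides):
            sid = ids[i] if ids is not None else f"slide_{i:04d}"
            records.append(SlideRecord(sid, slide.image, slide.regions, slide.label))
        return cls(records)

    @classmethod
    def from_manifest(cls, manifest, split: str | None = None) -> "SlideDataset":
        """Load slides listed in a manifest CSV (or DataFrame)."""
        df = manifest if isinstance(manifest, pd.DataFrame) else pd.read_csv(manifest)
        if split is not None:
            df = df[df["split"] == split]
        records = []
        for row in df.itertuples():
            image = _read_image(row.path)
            regions = load_annotations(row.annotation_path)
            records.append(SlideRecord(row.slide_id, image, regions, row.label))
        return cls(records)


def _read_image(path) -> np.ndarray:
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        import tifffile
        return tifffile.imread(path)
    return np.asarray(Image.open(path).convert("RGB"))


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def accept_window(window: Window, label: TrainingClass,
                  annotations: Sequence[AnnotationRegion]) -> bool:
    """Acceptance rule: benign/background 100% inside, tumor >= 50% inside.

    Overlap is measured against the union of all same-class regions by the
    pixel-center rule.
    """
    frac = overlap_fraction(window, annotations, TrainingClass(label))
    return frac >= _MIN_OVERLAP[TrainingClass(label)]


_MAX_ATTEMPTS = 10_000
_DILATION = 128


def sample_window(record: SlideRecord, label: TrainingClass,
                  rng: np.random.Generator, size: int = PATCH_SIZE) -> Window:
    """Rejection-sample an accepted window for the class on this slide.

    A region is picked with probability proportional to its polygon area, a
    candidate top-left uniformly inside the region's bounding box dilated by
    128 px (clamped to the slide), and candidates are tested against the
    class rule until one is accepted.
    """
    label = TrainingClass(label)
    cum_areas, ranges = record._sampler(label, size)
    if cum_areas is None:
        raise NoRegionError(
            f"slide {record.slide_id!r} has no {label.name} region")
    sat = record._integral(label)
    need = _MIN_OVERLAP[label] * size * size
    for _ in range(_MAX_ATTEMPTS):
        i = int(np.searchsorted(cum_areas, rng.random() * cum_areas[-1], "right"))
        lo_x, hi_x, lo_y, hi_y = ranges[min(i, len(ranges) - 1)]
        if hi_x < lo_x or hi_y < lo_y:
            continue
        x0 = int(rng.integers(lo_x, hi_x + 1))
        y0 = int(rng.integers(lo_y, hi_y + 1))
        inside = (sat[y0 + size, x0 + size] - sat[y0, x0 + size]
                  - sat[y0 + size, x0] + sat[y0, x0])
        if inside >= need:
            return Window(x0, y0, size)
    raise SamplingExhaustedError(
        f"no acceptable {label.name} window on slide {record.slide_id!r} "
        f"after {_MAX_ATTEMPTS} attempts")


def sample_patch(record: SlideRecord, label: TrainingClass,
                 rng: np.random.Generator) -> Patch:
    """Sample one accepted patch (see :func:`sample_window`)."""
    window = sample_window(record, label, rng)
    return Patch(pixels=record.crop(window).copy(), slide_id=record.slide_id,
                 window=window, label=TrainingClass(label))


def balanced_patch_batch(dataset: SlideDataset, rng: np.random.Generator,
                         batch_size: int = 48) -> list[Patch]:
    """A balanced batch: batch_size/3 patches per class, slides uniform."""
    if batch_size % len(TrainingClass):
        raise CompositionError("batch size must be divisible by 3")
    per_class = batch_size // len(TrainingClass)
    by_class: dict[TrainingClass, list[SlideRecord]] = {}
    for cls in TrainingClass:
        eligible = [rec for rec in dataset if rec.has_valid_window(cls)]
        if not eligible:
            raise CompositionError(f"no slide in the dataset has a {cls.name} region")
        by_class[cls] = eligible
    batch = []
    for cls in TrainingClass:
        eligible = by_class[cls]
        for _ in range(per_class):
            rec = eligible[rng.integers(0, len(eligible))]
            batch.append(sample_patch(rec, cls, rng))
    return batch


def compliance_audit(record: SlideRecord, windows: Sequence[Window],
                     label: TrainingClass) -> np.ndarray:
    """Re-check windows against freshly rasterized masks; returns a bool array.

    Independent of the sampler's cached summed-area tables: the class union
    is rasterized anew and each window is scored by its mask mean.
    """
    label = TrainingClass(label)
    mask = rasterize(record.regions, label, (0, 0, record.width, record.height))
    out = np.empty(len(windows), dtype=bool)
    for i, wdw in enumerate(windows):
        frac = mask[wdw.y0:wdw.y0 + wdw.size, wdw.x0:wdw.x0 + wdw.size].mean()
        out[i] = frac >= _MIN_OVERLAP[label]
    return out


# ---------------------------------------------------------------------------
# the classifier
# ---------------------------------------------------------------------------


def _fast_balanced_batch(dataset: SlideDataset, rng: np.random.Generator,
                         batch_size: int) -> tuple[np.ndarray, np.ndarray]:
    """uint8 batch tensor + labels, avoiding Patch object overhead."""
    per_class = batch_size // len(TrainingClass)
    x = np.empty((batch_size, PATCH_SIZE, PATCH_SIZE, 3), dtype=np.uint8)
    y = np.empty(batch_size, dtype=np.int64)
    i = 0
    for cls in TrainingClass:
        eligible = [rec for rec in dataset if rec.has_valid_window(cls)]
        if not eligible:
            raise CompositionError(f"no slide in the dataset has a {cls.name} region")
        for _ in range(per_class):
            rec = eligible[rng.integers(0, len(eligible))]
            wdw = sample_window(rec, cls, rng)
            x[i] = rec.crop(wdw)
            y[i] = cls.value
            i += 1
    return x, y


class PatchClassifier(ClassifierMixin, BaseEstimator):
    """3-way patch classifier (tumor / benign tissue / background).

    A scikit-learn style estimator around the NumPy conv net.  ``fit``
    accepts either a :class:`SlideDataset` (patches are then sampled
    dynamically and balanced per batch) or a plain ``(X, y)`` pair of patch
    arrays.  Fitted attributes carry the trailing underscore convention:
    ``net_``, ``curves_``, ``classes_``.
    """

    def __init__(self, learning_rate: float = 0.0017, momentum: float = 0.95,
                 batch_size: int = 48, eval_interval: int = 1000,
                 plateau_factor: float = 0.1, plateau_patience: int = 5,
                 min_lr: float = 1e-6, max_steps: int = 3000,
                 arch: dict | None = None, seed: int = 0,
                 n_val_patches: int = 96) -> None:
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
        self.n_val_patches = n_val_patches

    # -- config plumbing ----------------------------------------------------

    @classmethod
    def from_config(cls, config: TrainingConfig, **kwargs) -> "PatchClassifier":
        return cls(learning_rate=config.learning_rate, momentum=config.momentum,
                   batch_size=config.batch_size, eval_interval=config.eval_interval,
                   plateau_factor=config.plateau_factor,
                   plateau_patience=config.plateau_patience, min_lr=config.min_lr,
                   max_steps=config.max_steps, seed=config.seed, **kwargs)

    def _make_net(self) -> nn.ConvNet:
        arch = self.arch or nn.default_patch_arch()
        return nn.ConvNet(arch, seed=self.seed)

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y=None, validation=None):
        """Train on a SlideDataset (y ignored) or on arrays (X, y).

        ``validation`` follows the same convention: a SlideDataset or an
        ``(X_val, y_val)`` tuple.  Without one, validation patches are drawn
        from the training source (useful for smoke runs only).
        """
        if self.batch_size % len(TrainingClass):
            raise ValueError("batch_size must be divisible by the number of classes")
        rng = np.random.default_rng(self.seed)
        if isinstance(X, SlideDataset):
            if len(X) == 0:
                raise ValueError("empty dataset")
            batch_fn = lambda: _fast_balanced_batch(X, rng, self.batch_size)
            val_source = validation if validation is not None else X
            x_val, y_val = _val_patches(val_source, rng, self.n_val_patches)
        else:
            X = np.asarray(X)
            if X.size == 0:
                raise ValueError("empty dataset")
            y = np.asarray(y)
            batch_fn = lambda: _array_balanced_batch(X, y, rng, self.batch_size)
            if validation is not None:
                x_val, y_val = validation
                x_val, y_val = np.asarray(x_val), np.asarray(y_val)
            else:
                x_val, y_val = X, y
        net = self._make_net()
        self.net_, self.curves_ = _train_loop(
            net, batch_fn, x_val, y_val,
            lr=self.learning_rate, momentum=self.momentum,
            eval_interval=self.eval_interval, plateau_factor=self.plateau_factor,
            plateau_patience=self.plateau_patience, min_lr=self.min_lr,
            max_steps=self.max_steps, positive_class=TrainingClass.NPC.value)
        self.classes_ = np.array([c.value for c in TrainingClass])
        return self

    # -- inference ----------------------------------------------------------

    def predict_proba(self, X) -> np.ndarray:
        """Class probabilities for patches, order preserved, chunked."""
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "net_")
        x = _as_patch_array(X)
        out = np.empty((len(x), len(TrainingClass)), dtype=np.float64)
        for i in range(0, len(x), 64):
            out[i:i + 64] = nn.softmax(self.net_.forward(x[i:i + 64]))
        return out

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "net_")
        self.net_.save(path)

    @classmethod
    def load(cls, path) -> "PatchClassifier":
        est = cls()
        est.net_ = nn.ConvNet.load(path)
        est.arch = est.net_.arch
        est.seed = est.net_.seed
        est.classes_ = np.array([c.value for c in TrainingClass])
        return est


def _as_patch_array(X) -> np.ndarray:
    if isinstance(X, (list, tuple)) and X and isinstance(X[0], Patch):
        return np.stack([p.pixels for p in X])
    x = np.asarray(X)
    if x.ndim == 3:
        x = x[None]
    if x.ndim != 4:
        raise ValueError(f"expected (N, H, W, C) patches, got shape {x.shape}")
    return x


def _val_patches(source, rng, n_total: int) -> tuple[np.ndarray, np.ndarray]:
    per_class = max(n_total // len(TrainingClass), 1)
    xs, ys = [], []
    for cls in TrainingClass:
        eligible = [rec for rec in source if rec.has_valid_window(cls)]
        if not eligible:
            raise CompositionError(f"validation source lacks {cls.name} regions")
        for _ in range(per_class):
            rec = eligible[rng.integers(0, len(eligible))]
            wdw = sample_window(rec, cls, rng)
            xs.append(rec.crop(wdw))
            ys.append(cls.value)
    return np.stack(xs), np.asarray(ys)


def _array_balanced_batch(X, y, rng, batch_size):
    per_class = batch_size // len(TrainingClass)
    idx = []
    for cls in TrainingClass:
        pool = np.flatnonzero(y == cls.value)
        if len(pool) == 0:
            raise CompositionError(f"no {cls.name} patches in the array dataset")
        idx.append(rng.choice(pool, size=per_class, replace=True))
    idx = np.concatenate(idx)
    return X[idx], y[idx]


def _train_loop(net, batch_fn, x_val, y_val, *, lr, momentum, eval_interval,
                plateau_factor, plateau_patience, min_lr, max_steps,
                positive_class) -> tuple[nn.ConvNet, pd.DataFrame]:
    from .evaluation import auc

    opt = nn.SGDNesterov(net, lr, momentum)
    sched = nn.ReduceLROnPlateau(opt, factor=plateau_factor,
                                 patience=plateau_patience, min_lr=min_lr)
    rows = []
    best_state, best_loss = None, np.inf
    running, n_running = 0.0, 0
    for step in range(1, max_steps + 1):
        xb, yb = batch_fn()
        logits = net.forward(xb, train=True)
        loss, dlogits = nn.cross_entropy(logits, yb)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss at step {step}: {loss}")
        net.backward(dlogits)
        opt.step()
        net.step += 1
        running += loss
        n_running += 1
        if step % eval_interval == 0 or step == max_steps:
            val_loss, val_auc = _evaluate(net, x_val, y_val, positive_class)
            rows.append({"step": step, "train_loss": running / max(n_running, 1),
                         "val_loss": val_loss, "val_auc": val_auc,
                         "lr": opt.lr})
            running, n_running = 0.0, 0
            if val_loss < best_loss:
                best_loss = val_loss
                best_state = net.state_dict()
            sched.step(val_loss)
    if best_state is not None:
        net.load_state_dict(best_state)
    return net, pd.DataFrame(rows)


def _evaluate(net, x_val, y_val, positive_class) -> tuple[float, float]:
    from .evaluation import auc

    logits = np.concatenate([net.forward(x_val[i:i + 64])
                             for i in range(0, len(x_val), 64)])
    loss, _ = nn.cross_entropy(logits, y_val)
    probs = nn.softmax(logits)
    pos = y_val == positive_class
    if pos.any() and (~pos).any():
        val_auc = auc(probs[:, positive_class], pos.astype(int))
    else:
        val_auc = np.nan
    return loss, val_auc


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def train_patch_model(dataset: SlideDataset, config: TrainingConfig,
                      validation: SlideDataset | None = None,
                      arch: dict | None = None) -> tuple[PatchClassifier, pd.DataFrame]:
    """Train a patch classifier; returns the estimator and learning curves."""
    est = PatchClassifier.from_config(config, arch=arch)
    est.fit(dataset, validation=validation)
    return est, est.curves_


def infer_patch_probs(model: PatchClassifier, patches) -> np.ndarray:
    """N x 3 class probabilities (rows sum to 1), order preserved."""
    return model.predict_proba(patches)
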