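"""ROC/AUC evaluation and the repeated-inference model comparison.

The AUC here is the probability that a positive outranks a negative (ties
counted half), identical to the trapezoidal area under the empirical ROC
curve.  Two patch models are compared by repeating the testing inference
many times: each run draws the same balanced random patch sample for both
models, the per-run AUCs are summarised by mean and standard deviation, and
the two AUC samples are compared with a two-tailed Welch t-test (an
unpaired test; a paired variant is available since both models score the
same patches in every run).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .annotations import TrainingClass

__all__ = [
    "RocResult",
    "ComparisonResult",
    "UndefinedAUCError",
    "auc",
    "roc",
    "sens_spec",
    "welch_t_two_tailed",
    "repeated_model_comparison",
    "plot_roc_with_readers",
]


class UndefinedAUCError(ValueError):
    """AUC is undefined when only one class is present."""


@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class ComparisonResult:
    """Per-run AUCs of two models plus the Welch t-test across runs."""

    auc_a: np.ndarray
    auc_b: np.ndarray
    mean_a: float = field(init=False)
    mean_b: float = field(init=False)
    std_a: float = field(init=False)
    std_b: float = field(init=False)
    t: float = field(init=False)
    df: float = field(init=False)
    p: float = field(init=False)
    paired: bool = False

    def __post_init__(self) -> None:
        self.auc_a = np.asarray(self.auc_a, dtype=np.float64)
        self.auc_b = np.asarray(self.auc_b, dtype=np.float64)
        if len(self.auc_a) != len(self.auc_b):
            raise ValueError("run counts differ between the two models")
        self.mean_a = float(self.auc_a.mean())
        self.mean_b = float(self.auc_b.mean())
        self.std_a = float(self.auc_a.std(ddof=1))
        self.std_b = float(self.auc_b.std(ddof=1))
        if self.paired:
            d = self.auc_a - self.auc_b
            if np.allclose(d.std(ddof=1), 0.0):
                self.t, self.df = 0.0, float(len(d) - 1)
                self.p = 1.0 if np.allclose(d.mean(), 0.0) else 0.0
            else:
                res = stats.ttest_rel(self.auc_a, self.auc_b)
                self.t, self.p = float(res.statistic), float(res.pvalue)
                self.df = float(len(d) - 1)
        else:
            self.t, self.df, self.p = welch_t_two_tailed(self.auc_a, self.auc_b)


def auc(scores, labels) -> float:
    """Concordance AUC: P(score_pos > score_neg) + 0.5 P(equal)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedAUCError("AUC needs both positive and negative labels")
    return float(roc_auc_score(labels, scores))


def roc(scores, labels) -> RocResult:
    """Empirical ROC curve with (0,0) and (1,1) and its trapezoidal area."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedAUCError("ROC needs both positive and negative labels")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    return RocResult(thresholds=thresholds, fpr=fpr, tpr=tpr,
                     auc=float(np.trapezoid(tpr, fpr)))


def sens_spec(scores, labels, threshold: float) -> tuple[float, float]:
    """(sensitivity, specificity) calling score >= threshold positive."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    calls = scores >= threshold
    tp = int(np.sum(calls & labels))
    fn = int(np.sum(~calls & labels))
    tn = int(np.sum(~calls & ~labels))
    fp = int(np.sum(calls & ~labels))
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return sens, spec


def welch_t_two_tailed(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t statistic, Welch-Satterthwaite df, 2-sided p.

    Degenerate convention: if both samples have zero variance the p-value is
    1 for equal means and 0 otherwise.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        same = np.isclose(a.mean(), b.mean())
        return (0.0 if same else np.inf * np.sign(a.mean() - b.mean()),
                float(len(a) + len(b) - 2), 1.0 if same else 0.0)
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / len(a), vb / len(b)
    df = (sa + sb) ** 2 / (sa ** 2 / (len(a) - 1) + sb ** 2 / (len(b) - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def repeated_model_comparison(model_a, model_b, test_dataset, runs: int = 30,
                              n_patches: int = 16_000,
                              rng: np.random.Generator | None = None,
                              paired: bool = False) -> ComparisonResult:
    """Repeat the testing inference ``runs`` times on shared patch samples.

    Each run draws ``n_patches`` patches (half tumor, half benign) from the
    test dataset once; both models score the same patches; the per-model
    AUC uses the NPC probability channel against the binary tumor label.
    """
    from .patch_pipeline import sample_window

    if runs < 2:
        raise ValueError("need at least 2 runs for a t-test")
    rng = np.random.default_rng() if rng is None else rng
    auc_a, auc_b = [], []
    npc_idx = TrainingClass.NPC.value
    for _ in range(runs):
        x, y = _balanced_test_patches(test_dataset, n_patches, rng)
        pa = _chunked_probs(model_a, x)[:, npc_idx]
        pb = _chunked_probs(model_b, x)[:, npc_idx]
        auc_a.append(auc(pa, y))
        auc_b.append(auc(pb, y))
    return ComparisonResult(np.array(auc_a), np.array(auc_b), paired=paired)


def _balanced_test_patches(dataset, n_patches, rng):
    from .patch_pipeline import CompositionError, sample_window

    half = n_patches // 2
    xs = np.empty((2 * half, 256, 256, 3), dtype=np.uint8)
    ys = np.concatenate([np.ones(half, dtype=np.int64),
                         np.zeros(half, dtype=np.int64)])
    i = 0
    for cls, count in ((TrainingClass.NPC, half), (TrainingClass.BENIGN, half)):
        eligible = [rec for rec in dataset if rec.has_valid_window(cls)]
        if not eligible:
            raise CompositionError(f"test dataset lacks {cls.name} regions")
        for _ in range(count):
            rec = eligible[rng.integers(0, len(eligible))]
            wdw = sample_window(rec, cls, rng)
            xs[i] = rec.crop(wdw)
            i += 1
    return xs, ys


def _chunked_probs(model, x, chunk: int = 64) -> np.ndarray:
    return model.predict_proba(x)


def plot_roc_with_readers(roc_result: RocResult, reader_points, out,
                          title: str = "Slide-level ROC") -> None:
    """ROC curve figure with human-reader operating points.

    ``reader_points`` is a list of (one_minus_specificity, sensitivity,
    role) tuples; roles are colored consistently (residents red, chief
    resident green, attending pathologists blue, anything else gray).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"resident": "red", "chief resident": "green",
              "attending": "blue"}
    for x, y, _role in reader_points:
        if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
            raise ValueError(f"reader point ({x}, {y}) outside the unit square")
    fig, ax = plt.subplots(figsize=(5, 5), dpi=150)
    ax.plot(roc_result.fpr, roc_result.tpr, color="black",
            label=f"model (AUC = {roc_result.auc:.4f})")
    ax.plot([0, 1], [0, 1], linestyle=":", color="0.6", linewidth=0.8)
    seen = set()
    for x, y, role in reader_points:
        color = colors.get(role, "gray")
        ax.scatter([x], [y], marker="x", s=60, color=color,
                   label=role if role not in seen else None)
        seen.add(role)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    fig.savefig(out, metadata={"Software": None})
    plt.close(fig)
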