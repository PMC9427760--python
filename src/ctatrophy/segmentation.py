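"""CSF/GM/WM segmentation of axial CT slices.

Two segmenters share one evaluation harness:

* a trainable encoder-decoder network with skip connections (2D U-Net
  family), trained slice-wise with Adam and early stopping on a
  held-out validation split;
* a deterministic intensity-threshold fallback, exact on noiseless
  phantoms, which makes the downstream feature and grading stages
  testable without any network training.

Evaluation uses the Dice similarity coefficient
``DSC = 2|X n Y| / (|X| + |Y|)`` per tissue class, with subject-level
k-fold splitting (slices of one subject never straddle train/test).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._unet import Adam, UNet, softmax_cross_entropy
from .imgio import (
    CTVolume,
    LabelVolume,
    SliceStack,
    LABEL_BACKGROUND,
    LABEL_CSF,
    LABEL_GM,
    LABEL_WM,
    TISSUE_NAMES,
)

__all__ = [
    "SegmenterConfig",
    "FoldAssignment",
    "DiceReport",
    "FittedSegmenter",
    "dice",
    "multiclass_dice",
    "make_folds",
    "threshold_segment",
    "default_thresholds",
    "train_segmenter",
    "predict_labels",
]

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Dice evaluation
# --------------------------------------------------------------------------

def dice(x_mask: np.ndarray, y_mask: np.ndarray) -> float:
    """Dice similarity coefficient 2|X n Y| / (|X| + |Y|).

    Symmetric in its arguments.  Raises on a shape mismatch or when both
    masks are empty (0/0 is left to the caller's convention).
    """
    x = np.asarray(x_mask, dtype=bool)
    y = np.asarray(y_mask, dtype=bool)
    if x.shape != y.shape:
        raise ValueError(f"mask shapes differ: {x.shape} vs {y.shape}")
    sx, sy = int(x.sum()), int(y.sum())
    if sx == 0 and sy == 0:
        raise ValueError("both masks empty: dice is 0/0; handle upstream")
    return 2.0 * int((x & y).sum()) / (sx + sy)


def multiclass_dice(pred: LabelVolume, truth: LabelVolume) -> tuple[dict[str, float], float]:
    """Per-tissue one-vs-rest Dice and their unweighted mean.

    A class absent from both volumes is excluded from the mean (logged);
    a class present in only one scores 0.
    """
    if pred.data.shape != truth.data.shape:
        raise ValueError("pred and truth geometries differ")
    per_class: dict[str, float] = {}
    included = []
    for lab, name in TISSUE_NAMES.items():
        pm = pred.data == lab
        tm = truth.data == lab
        if not pm.any() and not tm.any():
            logger.info("class %s absent from both volumes; excluded from mean", name)
            continue
        per_class[name] = dice(pm, tm)
        included.append(per_class[name])
    if not included:
        raise ValueError("no tissue class present in either volume")
    return per_class, float(np.mean(included))


@dataclass
class DiceReport:
    """Per-subject Dice scores with cohort mean and SD."""

    per_subject_dsc: dict[str, float]
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        vals = np.array(list(self.per_subject_dsc.values()), dtype=float)
        self.mean = float(vals.mean())
        self.sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0


# --------------------------------------------------------------------------
# Subject-level fold assignment
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldAssignment:
    n_subjects: int
    k: int
    fold_of_subject: dict
    seed: int

    def subjects_in_fold(self, f: int) -> list:
        return [s for s, ff in self.fold_of_subject.items() if ff == f]


def make_folds(subject_ids, k: int, seed: int = 0) -> FoldAssignment:
    """Uniform random partition of subjects into k folds.

    Fold sizes differ by at most one; assignment is by subject, never by
    slice, so no subject's slices can straddle train and test.
    """
    ids = list(subject_ids)
    if k < 1 or k > len(ids):
        raise ValueError(f"k={k} must be in [1, n_subjects={len(ids)}]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    fold_of = {}
    for pos, idx in enumerate(order):
        fold_of[ids[idx]] = pos % k
    return FoldAssignment(n_subjects=len(ids), k=k, fold_of_subject=fold_of, seed=seed)


# --------------------------------------------------------------------------
# Threshold fallback segmenter
# --------------------------------------------------------------------------

def default_thresholds(tissue_means: dict[str, float]) -> dict[str, tuple[float, float]]:
    """Contiguous HU intervals with boundaries midway between tissue means.

    CT orders CSF < WM < GM, so the intervals are
    ``CSF: (-inf, m_cw), WM: [m_cw, m_wg), GM: [m_wg, inf)``.
    """
    m_cw = 0.5 * (tissue_means["CSF"] + tissue_means["WM"])
    m_wg = 0.5 * (tissue_means["WM"] + tissue_means["GM"])
    return {
        "CSF": (-math.inf, m_cw),
        "WM": (m_cw, m_wg),
        "GM": (m_wg, math.inf),
    }


def threshold_segment(
    vol: CTVolume,
    brain_mask: np.ndarray,
    class_thresholds: dict[str, tuple[float, float]] | None = None,
) -> LabelVolume:
    """Assign each in-mask voxel the tissue class of its intensity interval.

    Intervals are half-open ``[lo, hi)`` and must not overlap; in-mask
    voxels outside every interval become background.  Out-of-mask voxels
    are background.  Deterministic; exact on noiseless phantoms whose
    intervals bracket the tissue means.
    """
    thr = class_thresholds or default_thresholds({"CSF": 8.0, "GM": 38.0, "WM": 28.0})
    if set(thr) != {"CSF", "GM", "WM"}:
        raise ValueError("class_thresholds must cover exactly CSF, WM, GM")
    intervals = sorted(thr.items(), key=lambda kv: kv[1][0])
    for name, (lo, hi) in intervals:
        if not lo < hi:
            raise ValueError(f"empty interval for {name}: [{lo}, {hi})")
    for (n1, (_, hi1)), (n2, (lo2, _)) in zip(intervals, intervals[1:]):
        if hi1 > lo2:
            raise ValueError(f"overlapping intervals: {n1} ends at {hi1}, {n2} starts at {lo2}")
    mask = np.asarray(brain_mask, dtype=bool)
    if mask.shape != vol.data.shape:
        raise ValueError("brain_mask shape must match volume")
    out = np.full(vol.data.shape, LABEL_BACKGROUND, dtype=np.int16)
    label_of = {"CSF": LABEL_CSF, "GM": LABEL_GM, "WM": LABEL_WM}
    for name, (lo, hi) in thr.items():
        sel = mask & (vol.data >= lo) & (vol.data < hi)
        out[sel] = label_of[name]
    return LabelVolume(out, voxel_size_mm=vol.voxel_size_mm)


# --------------------------------------------------------------------------
# Trainable encoder-decoder segmenter
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmenterConfig:
    """Training configuration.

    The learning-rate and batch-size defaults (1e-6, 16) are the
    published settings for fine-tuning on a full clinical cohort; small
    phantom experiments typically pass a larger learning rate.
    """

    depth: int = 3
    base_channels: int = 16
    learning_rate: float = 1e-6
    batch_size: int = 16
    max_epochs: int = 50
    early_stop_patience: int = 5
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1 (0 would silently skip training)")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")


@dataclass
class FittedSegmenter:
    """A trained network plus the config and slice shape it expects."""

    net: UNet
    config: SegmenterConfig
    slice_shape: tuple[int, int]
    best_val_loss: float
    n_epochs_run: int

    def predict_slice_labels(self, slices: np.ndarray) -> np.ndarray:
        """Per-pixel argmax class maps for a batch of slices (n, H, W)."""
        x = np.asarray(slices, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != self.slice_shape:
            raise ValueError(f"slice shape {x.shape[1:]} != training shape {self.slice_shape}")
        logits = self.net.forward(x)
        return logits.argmax(axis=1).astype(np.int16)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        cfg = json.dumps({**self.config.__dict__, "slice_shape": list(self.slice_shape),
                          "best_val_loss": self.best_val_loss,
                          "n_epochs_run": self.n_epochs_run})
        weights = {f"w{i}": w for i, w in enumerate(self.net.get_weights())}
        np.savez(path, config=np.array(cfg), **weights)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "FittedSegmenter":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["config"]))
            weights = [data[f"w{i}"] for i in range(len(data.files) - 1)]
        slice_shape = tuple(meta.pop("slice_shape"))
        best = meta.pop("best_val_loss")
        n_epochs = meta.pop("n_epochs_run")
        config = SegmenterConfig(**meta)
        net = UNet(depth=config.depth, base_channels=config.base_channels, seed=config.seed)
        net.set_weights(weights)
        return cls(net=net, config=config, slice_shape=slice_shape,
                   best_val_loss=best, n_epochs_run=n_epochs)


def _val_split(n: int, groups, fraction: float, rng: np.random.Generator):
    """Indices for train/validation; by subject group when groups given."""
    if groups is None:
        units = np.arange(n)
        unit_of = units
    else:
        groups = np.asarray(groups)
        units = np.unique(groups)
        unit_of = groups
    if len(units) == 1:
        # degenerate single-unit input: validate on the training data itself
        return np.arange(n), np.arange(n)
    n_val = max(1, int(round(fraction * len(units))))
    val_units = set(rng.permutation(units)[:n_val].tolist())
    val = np.array([i for i in range(n) if unit_of[i] in val_units])
    train = np.array([i for i in range(n) if unit_of[i] not in val_units])
    return train, val


def train_segmenter(
    ct_slices: np.ndarray,
    label_slices: np.ndarray,
    config: SegmenterConfig | None = None,
    groups=None,
) -> FittedSegmenter:
    """Train the encoder-decoder on paired (CT slice, label slice) data.

    ``ct_slices``: (n, H, W) float intensities (any consistent scale);
    ``label_slices``: (n, H, W) integer class maps; ``groups`` optionally
    assigns each slice to a subject so the validation split is by
    subject.  Training minimizes per-pixel multiclass cross-entropy with
    Adam and stops when the validation loss has not improved for
    ``early_stop_patience`` epochs, returning the best-validation
    weights.  Deterministic for a fixed seed.
    """
    config = config or SegmenterConfig()
    X = np.asarray(ct_slices, dtype=np.float64)
    Y = np.asarray(label_slices)
    if X.ndim != 3 or Y.shape != X.shape:
        raise ValueError("expected matching (n, H, W) CT and label stacks")
    if len(X) < 1:
        raise ValueError("need at least one training pair")
    h, w = X.shape[1:]
    if h % 2**config.depth or w % 2**config.depth:
        raise ValueError(
            f"slice shape ({h}, {w}) must be divisible by 2^depth = {2**config.depth}"
        )

    rng = np.random.default_rng(config.seed)
    net = UNet(depth=config.depth, base_channels=config.base_channels, seed=config.seed)
    opt = Adam(net.parameters(), lr=config.learning_rate)
    train_idx, val_idx = _val_split(len(X), groups, config.validation_fraction, rng)
    Xv, Yv = X[val_idx], Y[val_idx].astype(np.int64)

    def val_loss() -> float:
        total, npx = 0.0, 0
        for i in range(0, len(Xv), config.batch_size):
            logits = net.forward(Xv[i : i + config.batch_size])
            loss, _ = softmax_cross_entropy(logits, Yv[i : i + config.batch_size])
            total += loss * len(Xv[i : i + config.batch_size])
            npx += len(Xv[i : i + config.batch_size])
        return total / npx

    best_loss = np.inf
    best_weights = net.get_weights()
    patience_left = config.early_stop_patience
    epochs_run = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(train_idx)
        for i in range(0, len(order), config.batch_size):
            batch = order[i : i + config.batch_size]
            logits = net.forward(X[batch])
            _, grad = softmax_cross_entropy(logits, Y[batch].astype(np.int64))
            net.backward(grad)
            opt.step(net.gradients())
        epochs_run = epoch + 1
        vl = val_loss()
        if vl < best_loss - 1e-7:
            best_loss = vl
            best_weights = net.get_weights()
            patience_left = config.early_stop_patience
        else:
            patience_left -= 1
            if patience_left == 0:
                logger.info("early stop at epoch %d (best val loss %.5f)", epochs_run, best_loss)
                break
    net.set_weights(best_weights)
    return FittedSegmenter(
        net=net, config=config, slice_shape=(h, w),
        best_val_loss=float(best_loss), n_epochs_run=epochs_run,
    )


def predict_labels(
    segmenter: FittedSegmenter,
    stack: SliceStack,
    voxel_size_mm: tuple[float, float, float] = (0.5, 0.5, 3.3),
) -> LabelVolume:
    """Segment every retained slice and re-stack into a label volume.

    Slices removed during extraction are filled with background.
    """
    n_slices = stack.n_source_slices
    preds = segmenter.predict_slice_labels(stack.slices)
    out = np.full((n_slices, *preds.shape[1:]), LABEL_BACKGROUND, dtype=np.int16)
    out[stack.source_indices] = preds
    return LabelVolume(out, voxel_size_mm=voxel_size_mm)
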