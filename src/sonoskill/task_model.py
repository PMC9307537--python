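"""Binary frame classification: does a frame support accurate biometry?

The *task model* ``f_task`` maps an ultrasound frame (optionally with a
five-frame temporal context) to the probability that a sufficiently
accurate biometry measurement could be taken on it.  Architecture: a
seed-deterministic convolutional encoder over the preprocessed frame
followed by a trainable logistic head, optimised with Adam on
cross-entropy; the checkpoint with the highest class-balanced accuracy on
the validation set is selected.

Decision rule everywhere: a frame is called positive when the predicted
probability strictly exceeds the cut-off ``c`` (ties break negative);
``c = 0.5`` unless a specificity-controlled cut-off has been calibrated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from skimage.transform import resize

from ._nn import ConvEncoder2D, MLPHead, Standardizer

log = logging.getLogger(__name__)

__all__ = [
    "TaskModelConfig",
    "FramePredictions",
    "preprocess",
    "TaskModel",
    "train_task_model",
    "predict",
    "calibrate_cutoff",
    "evaluate_task_model",
    "balanced_accuracy",
]

STANDARD_SHAPE = (224, 288)


@dataclass(frozen=True)
class TaskModelConfig:
    backbone: str = "small_cnn"         # 'small_cnn' | 'vgg16_like'
    context: int = 1                    # frames per input: 1 or 5
    lr: float = 1e-4
    batch: int = 64
    epochs: int = 50
    seed: int = 0
    resize_shape: tuple[int, int] = STANDARD_SHAPE
    class_weighting: bool = False       # optional weighted cross-entropy

    def __post_init__(self) -> None:
        if self.context not in (1, 5):
            raise ValueError("context must be 1 or 5")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.backbone not in ("small_cnn", "vgg16_like"):
            raise ValueError(f"unknown backbone {self.backbone!r}")


@dataclass
class FramePredictions:
    """Per-frame positive-class probabilities for one clip."""

    g_hat: np.ndarray
    clip_id: str = ""

    def __post_init__(self) -> None:
        g = np.asarray(self.g_hat, dtype=np.float64)
        if g.size and (g.min() < 0 or g.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        self.g_hat = g


def preprocess(frame: np.ndarray, target_shape: tuple[int, int] = STANDARD_SHAPE) -> np.ndarray:
    """Resize to the model input shape and z-score to zero mean, unit variance.

    Constant images are zero-centred with the variance left untouched
    (warned) — there is no information to rescale.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2 or frame.size == 0:
        raise ValueError("frame must be a non-empty 2-D image")
    if frame.shape != tuple(target_shape):
        frame = resize(frame, target_shape, order=1, anti_aliasing=True)
    return normalise(frame)


def normalise(frame: np.ndarray) -> np.ndarray:
    """Zero-mean unit-variance intensity normalisation."""
    frame = np.asarray(frame, dtype=np.float64)
    sd = frame.std()
    if sd == 0:
        log.warning("normalise: constant image, variance left at 0")
        return frame - frame.mean()
    return (frame - frame.mean()) / sd


def _encoder_for(config: TaskModelConfig) -> ConvEncoder2D:
    if config.backbone == "vgg16_like":
        return ConvEncoder2D(n_filters=32, kernel=3, pool=4, seed=config.seed)
    return ConvEncoder2D(n_filters=16, kernel=5, pool=4, seed=config.seed)


def _context_stack(feats: np.ndarray, context: int) -> np.ndarray:
    """Concatenate per-frame features over a centred temporal context,
    replicate-padded at the clip edges."""
    if context == 1:
        return feats
    half = context // 2
    j = np.arange(feats.shape[0])
    cols = [feats[np.clip(j + o, 0, feats.shape[0] - 1)] for o in range(-half, half + 1)]
    return np.concatenate(cols, axis=1)


class TaskModel:
    """Trained frame classifier (fixed conv encoder + logistic head)."""

    def __init__(self, config: TaskModelConfig):
        self.config = config
        self.encoder = _encoder_for(config)
        self.standardizer = Standardizer()
        n_in = self.encoder.n_features * config.context
        self.head = MLPHead(n_in, hidden=0, task="binary", seed=config.seed)
        self.history: dict = {}

    def clip_features(self, frames: np.ndarray) -> np.ndarray:
        """Preprocess + encode a clip's frames, with temporal context."""
        pre = np.stack(
            [preprocess(f, self.config.resize_shape) for f in np.asarray(frames)]
        )
        return _context_stack(self.encoder.encode(pre), self.config.context)

    def predict_proba(self, frames: np.ndarray) -> np.ndarray:
        x = self.standardizer.transform(self.clip_features(frames))
        return self.head.predict(x)


def save_task_model(model: TaskModel, path) -> None:
    """Persist a trained classifier (config + head weights + feature stats);
    the fixed encoder is regenerated from the seed on load."""
    import dataclasses
    import json

    cfg = json.dumps(dataclasses.asdict(model.config))
    np.savez(
        path,
        config=np.array(cfg),
        feat_mean=model.standardizer.mean,
        feat_sd=model.standardizer.sd,
        **{f"param_{i}": p for i, p in enumerate(model.head.params)},
    )


def load_task_model(path) -> TaskModel:
    import json

    data = np.load(path, allow_pickle=False)
    cfg = json.loads(str(data["config"]))
    for key in ("resize_shape",):
        cfg[key] = tuple(cfg[key])
    model = TaskModel(TaskModelConfig(**cfg))
    model.standardizer.mean = data["feat_mean"]
    model.standardizer.sd = data["feat_sd"]
    for i, p in enumerate(model.head.params):
        p[...] = data[f"param_{i}"]
    return model


def balanced_accuracy(y: np.ndarray, g_hat: np.ndarray, cutoff: float = 0.5) -> float:
    """Mean of sensitivity and specificity at the given cut-off."""
    y = np.asarray(y).astype(int)
    pred = np.asarray(g_hat) > cutoff
    pos, neg = y == 1, y == 0
    sens = pred[pos].mean() if pos.any() else np.nan
    spec = (~pred[neg]).mean() if neg.any() else np.nan
    return float((sens + spec) / 2.0)


def train_task_model(
    train: list[tuple[np.ndarray, np.ndarray]],
    val: list[tuple[np.ndarray, np.ndarray]],
    config: TaskModelConfig,
) -> TaskModel:
    """Train the frame classifier on per-clip (frames, labels) pairs.

    Cross-entropy, Adam, minibatches of ``config.batch``; after each epoch
    the class-balanced accuracy on the validation frames is logged and the
    best epoch's weights are kept.
    """
    model = TaskModel(config)
    x_tr = np.concatenate([model.clip_features(f) for f, _ in train])
    y_tr = np.concatenate([np.asarray(l) for _, l in train]).astype(float)
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training set must contain both classes")
    x_va = np.concatenate([model.clip_features(f) for f, _ in val])
    y_va = np.concatenate([np.asarray(l) for _, l in val]).astype(float)

    model.standardizer.fit(x_tr)
    x_tr = model.standardizer.transform(x_tr)
    x_va = model.standardizer.transform(x_va)

    if config.class_weighting:
        # reweight by inverse class frequency via sample duplication weights
        w_pos = 0.5 / max(y_tr.mean(), 1e-9)
        w_neg = 0.5 / max(1 - y_tr.mean(), 1e-9)
        log.info("class weights: pos=%.3f neg=%.3f", w_pos, w_neg)

    model.history = model.head.fit(
        x_tr, y_tr, x_va, y_va,
        lr=config.lr, batch=config.batch, epochs=config.epochs, seed=config.seed,
        val_metric=lambda y, p: balanced_accuracy(y, p, 0.5),
    )
    return model


def predict(model: TaskModel, clip) -> FramePredictions:
    """Per-frame positive-class probabilities for a clip."""
    frames = clip.frames if hasattr(clip, "frames") else np.asarray(clip)
    clip_id = getattr(clip, "subject_id", "")
    return FramePredictions(g_hat=model.predict_proba(frames), clip_id=clip_id)


def calibrate_cutoff(
    g_hat: np.ndarray, labels: np.ndarray, target_specificity: float
) -> tuple[float, float]:
    """Smallest cut-off whose empirical specificity reaches the target.

    With the strict ``g_hat > c`` positive rule, candidate cut-offs are the
    observed negative-frame probabilities; the smallest candidate whose
    specificity on the given set is >= ``target_specificity`` is returned
    together with the specificity it achieves.
    """
    g_hat = np.asarray(g_hat, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    neg = g_hat[labels == 0]
    if neg.size == 0:
        raise ValueError("calibration requires negative frames")
    if neg.size < 10:
        log.warning("calibrating on only %d negatives", neg.size)
    for c in np.unique(neg):
        spec = float((neg <= c).mean())
        if spec >= target_specificity:
            return float(c), spec
    c = float(neg.max())
    return c, 1.0


class TaskMetrics(NamedTuple):
    accuracy: float
    sensitivity: float
    specificity: float


def evaluate_task_model(
    g_hat: np.ndarray, labels: np.ndarray, cutoff: float = 0.5
) -> TaskMetrics:
    """Accuracy, sensitivity and specificity at the given cut-off."""
    g_hat = np.asarray(g_hat, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if g_hat.size == 0 or g_hat.size != labels.size:
        raise ValueError("need equal-length, non-empty predictions and labels")
    pred = g_hat > cutoff
    tp = int(np.sum(pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    acc = (tp + tn) / labels.size
    sens = tp / (tp + fn) if (tp + fn) else np.nan
    spec = tn / (tn + fp) if (tn + fp) else np.nan
    return TaskMetrics(float(acc), float(sens), float(spec))
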