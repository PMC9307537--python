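"""Windowed task-performance scores — the supervision signal for skill
assessment.

Two criteria over sliding windows of ``tau`` consecutive frames (stride 1,
so a clip of J frames yields ``J - tau + 1`` windows):

* ``pos`` — expected positive task prediction: the mean predicted
  positive-class probability over the window.
* ``acc`` — expected task prediction accuracy: the fraction of window
  frames the task model classifies correctly at cut-off ``c``
  (``g_hat > c`` is called positive), against the mixed binary labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SkillScoreSeries", "score_pos", "score_acc", "sliding_scores"]

#: default window lengths mirroring the ablation grids
DEFAULT_TAU = {"pos": (1, 4, 8, 16), "acc": (15, 30, 60, 120)}


@dataclass
class SkillScoreSeries:
    scores: np.ndarray          # (J - tau + 1,) in [0, 1]
    criterion: str              # 'pos' | 'acc'
    tau: int
    cutoff: float | None = None  # acc only

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)

    @property
    def n_windows(self) -> int:
        return self.scores.size


def score_pos(g_hat: np.ndarray) -> float:
    """Mean predicted probability over one window."""
    g_hat = np.asarray(g_hat, dtype=np.float64)
    if g_hat.size == 0:
        raise ValueError("empty window")
    return float(g_hat.mean())


def score_acc(g_hat: np.ndarray, g: np.ndarray, c: float) -> float:
    """Fraction of window frames classified correctly at cut-off ``c``."""
    g_hat = np.asarray(g_hat, dtype=np.float64)
    g = np.asarray(g).astype(int)
    if g_hat.size == 0:
        raise ValueError("empty window")
    if g_hat.shape != g.shape:
        raise ValueError("prediction and label windows must align")
    pred = (g_hat > c).astype(int)
    return float((pred == g).mean())


def sliding_scores(
    g_hat: np.ndarray,
    criterion: str,
    tau: int,
    labels: np.ndarray | None = None,
    cutoff: float = 0.5,
) -> SkillScoreSeries:
    """Score every length-``tau`` window of a clip, stride 1.

    The ``acc`` criterion needs the per-frame binary labels; ``pos`` does
    not.  Raises if ``tau`` exceeds the clip length.
    """
    g_hat = np.asarray(g_hat, dtype=np.float64)
    j = g_hat.size
    if not 1 <= tau <= j:
        raise ValueError(f"tau={tau} invalid for clip of {j} frames")
    windows = np.lib.stride_tricks.sliding_window_view(g_hat, tau)
    if criterion == "pos":
        scores = windows.mean(axis=1)
        return SkillScoreSeries(scores=scores, criterion="pos", tau=tau)
    if criterion == "acc":
        if labels is None:
            raise ValueError("acc criterion requires labels")
        labels = np.asarray(labels).astype(int)
        if labels.size != j:
            raise ValueError("labels must match predictions in length")
        correct = ((g_hat > cutoff).astype(int) == labels).astype(np.float64)
        wins = np.lib.stride_tricks.sliding_window_view(correct, tau)
        return SkillScoreSeries(
            scores=wins.mean(axis=1), criterion="acc", tau=tau, cutoff=cutoff
        )
    raise ValueError(f"unknown criterion {criterion!r}")
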