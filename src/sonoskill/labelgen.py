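"""Label-efficient mixed ground-truth generation.

A frame is a *positive* example when its biometry deviates from the
diagnostic-plane biometry by no more than a precision threshold
``delta_min`` (1-4% by default).  Manual annotations exist for only a
handful of frames, so the relative error of every other frame is estimated
by a linear regression from the five image-similarity metrics to the
relative error, fitted on the manually annotated frames.  Labels then come
from thresholding: exact relative error for manual frames (manual
information takes precedence), estimated error for the rest.

The relative error is the absolute relative deviation
``delta = |f(v) - f(dp)| / f(dp)``, stored as a fraction in [0, 1]; a
``delta_min`` of 0.04 corresponds to a 4% biometry precision requirement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .similarity import METRIC_NAMES

__all__ = [
    "relative_error",
    "LinearErrorModel",
    "fit_error_model",
    "FrameLabels",
    "make_mixed_labels",
]

DEFAULT_DELTA_MIN = (0.01, 0.02, 0.03, 0.04)


def relative_error(biometry_frame: float, biometry_dp: float) -> float:
    """Relative biometry error of a frame against the diagnostic plane.

    ``|b_frame - b_dp| / b_dp`` clipped to [0, 1]; both inputs must be
    positive physical measurements.
    """
    if biometry_frame <= 0 or biometry_dp <= 0:
        raise ValueError("biometry values must be positive")
    return float(min(1.0, abs(biometry_frame - biometry_dp) / biometry_dp))


@dataclass
class LinearErrorModel:
    """OLS map from the 5-metric similarity vector to estimated relative error.

    ``coefficients`` holds the five slopes in :data:`METRIC_NAMES` order;
    predictions are clipped to [0, 1].
    """

    coefficients: np.ndarray    # (5,)
    intercept: float
    fit_mse: float              # training MSE on the [0,1] error scale
    n_train: int

    def predict(self, sims: np.ndarray) -> np.ndarray:
        """Estimated relative error for an (n, 5) block of similarity vectors."""
        sims = np.atleast_2d(np.asarray(sims, dtype=np.float64))
        if sims.shape[1] != len(METRIC_NAMES):
            raise ValueError(f"expected {len(METRIC_NAMES)} metrics per row")
        return np.clip(sims @ self.coefficients + self.intercept, 0.0, 1.0)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "metric_order": list(METRIC_NAMES),
                    "coefficients": self.coefficients.tolist(),
                    "intercept": self.intercept,
                    "fit_mse": self.fit_mse,
                    "n_train": self.n_train,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "LinearErrorModel":
        d = json.loads(Path(path).read_text())
        if tuple(d["metric_order"]) != METRIC_NAMES:
            raise ValueError("metric order mismatch in model file")
        return cls(
            coefficients=np.asarray(d["coefficients"]),
            intercept=d["intercept"],
            fit_mse=d["fit_mse"],
            n_train=d["n_train"],
        )


def fit_error_model(
    sims: np.ndarray, delta: np.ndarray, ridge: float = 0.0
) -> LinearErrorModel:
    """Ordinary least squares from similarity vectors to relative error.

    Parameters
    ----------
    sims : (n, 5) array
        Similarity vectors in :data:`METRIC_NAMES` order.
    delta : (n,) array
        Observed relative errors in [0, 1].
    ridge : float
        Optional L2 penalty on the slopes for collinear metrics; 0 keeps
        plain OLS.

    A rank-deficient design (after centring; the constant-target case is
    fine) raises an error naming the collinear columns unless ``ridge > 0``.
    """
    sims = np.asarray(sims, dtype=np.float64)
    delta = np.asarray(delta, dtype=np.float64).ravel()
    if sims.ndim != 2 or sims.shape[1] != len(METRIC_NAMES):
        raise ValueError(f"sims must be (n, {len(METRIC_NAMES)})")
    n = sims.shape[0]
    if n < sims.shape[1] + 2 or n != delta.size:
        raise ValueError("need more rows than parameters and matching delta length")

    design = np.column_stack([sims, np.ones(n)])
    if ridge > 0:
        penalty = ridge * np.eye(design.shape[1])
        penalty[-1, -1] = 0.0
        beta = np.linalg.solve(design.T @ design + penalty, design.T @ delta)
    else:
        centred = sims - sims.mean(axis=0)
        rank = np.linalg.matrix_rank(centred, tol=1e-9 * max(1.0, np.abs(centred).max()))
        if 0 < rank < sims.shape[1]:
            # name the offending columns via QR column pivoting
            from scipy.linalg import qr

            _, r, piv = qr(centred, pivoting=True)
            bad = sorted(METRIC_NAMES[i] for i in piv[rank:])
            raise np.linalg.LinAlgError(
                f"rank-deficient design: collinear columns {bad}; "
                "use ridge > 0 to proceed"
            )
        beta, *_ = np.linalg.lstsq(design, delta, rcond=None)
    pred = np.clip(design @ beta, 0.0, 1.0)
    return LinearErrorModel(
        coefficients=beta[:-1],
        intercept=float(beta[-1]),
        fit_mse=float(np.mean((pred - delta) ** 2)),
        n_train=n,
    )


@dataclass
class FrameLabels:
    """Per-frame binary labels with provenance and estimated error."""

    g: np.ndarray               # (J,) int, 0/1
    provenance: np.ndarray      # (J,) str, 'manual' | 'surrogate'
    delta_hat: np.ndarray       # (J,) float; NaN for manual frames
    delta_min: float

    @property
    def n_frames(self) -> int:
        return self.g.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "g": self.g,
                "provenance": self.provenance,
                "delta_hat": self.delta_hat,
            }
        )


def make_mixed_labels(
    clip,
    sims: np.ndarray,
    model: LinearErrorModel,
    manual: pd.DataFrame | None,
    delta_min: float,
) -> FrameLabels:
    """Mixed manual/surrogate binary labels for one clip.

    Frames in the ``manual`` table (columns ``frame, biometry``) are
    labelled by thresholding their exact relative error against the
    diagnostic-plane biometry; all other frames by thresholding the linear
    model's estimate from their similarity vector.  ``g = 1`` iff the
    (exact or estimated) error is at most ``delta_min``.
    """
    if delta_min <= 0:
        raise ValueError("delta_min must be positive")
    j_total = clip.n_frames
    sims = np.asarray(sims, dtype=np.float64)
    if sims.shape[0] != j_total:
        raise ValueError("one similarity vector per frame required")

    delta_hat = model.predict(sims)
    g = (delta_hat <= delta_min).astype(int)
    provenance = np.full(j_total, "surrogate", dtype=object)
    out_delta = delta_hat.copy()

    if manual is not None and len(manual):
        frames = manual["frame"].to_numpy()
        if frames.min() < 0 or frames.max() >= j_total:
            raise ValueError("manual annotation references a frame absent from the clip")
        dp_rows = manual[manual["frame"] == clip.dp_index]
        if len(dp_rows):
            b_dp = float(dp_rows["biometry"].iloc[0])
        else:
            raise ValueError("manual table must include the diagnostic-plane frame")
        for _, row in manual.iterrows():
            fr = int(row["frame"])
            d = relative_error(float(row["biometry"]), b_dp)
            g[fr] = int(d <= delta_min)
            provenance[fr] = "manual"
            out_delta[fr] = np.nan
    return FrameLabels(
        g=g, provenance=provenance.astype(str), delta_hat=out_delta, delta_min=delta_min
    )
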