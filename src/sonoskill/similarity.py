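"""Image-similarity metrics between a frame and its clip's diagnostic plane.

Five metrics are computed per frame, in a fixed order that downstream linear
models rely on:

1. ``cosine_feat`` — cosine similarity of feature-space embeddings;
2. ``mse``        — mean squared intensity error (a *dissimilarity*);
3. ``cross_corr`` — Pearson correlation of flattened intensities;
4. ``mutual_info``— mutual information of the joint intensity histogram (nats);
5. ``ssim``       — structural similarity index.

Metric orientation is deliberately not harmonised (mse grows with
dissimilarity while the others shrink); the downstream linear error model
absorbs signs, and each metric keeps its textbook definition exact.

The feature embedder is a pluggable component.  The default is a fixed-seed
random projection of the 4x-downsampled image: deterministic, training-free,
and easily replaced by any user-supplied extractor exposing the same
``embed`` signature (e.g. a pretrained ultrasound CNN).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

log = logging.getLogger(__name__)

#: canonical metric order; feeds the linear error model and every CSV header
METRIC_NAMES = ("cosine_feat", "mse", "cross_corr", "mutual_info", "ssim")

MI_BINS = 32


@dataclass(frozen=True)
class SimilarityVector:
    cosine_feat: float
    mse: float
    cross_corr: float
    mutual_info: float
    ssim: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, m) for m in METRIC_NAMES])


class FeatureEmbedder:
    """Deterministic random-projection image embedder.

    The image is average-pooled by ``downsample`` in each axis, flattened,
    and projected by a fixed Gaussian matrix drawn once from ``seed``.
    Projections are cached per input shape, so the same embedder instance
    maps equal images to bit-identical vectors.
    """

    def __init__(self, embed_dim: int = 512, downsample: int = 4, seed: int = 0):
        if embed_dim < 1:
            raise ValueError("embed_dim must be >= 1")
        self.embed_dim = embed_dim
        self.downsample = downsample
        self.seed = seed
        self._projections: dict[tuple[int, int], np.ndarray] = {}

    def _projection(self, n_in: int) -> np.ndarray:
        key = (n_in, self.embed_dim)
        if key not in self._projections:
            rng = np.random.default_rng(self.seed)
            self._projections[key] = rng.standard_normal((n_in, self.embed_dim)) / np.sqrt(n_in)
        return self._projections[key]

    def embed(self, frame: np.ndarray) -> np.ndarray:
        if frame.ndim != 2:
            raise ValueError("frame must be 2-D")
        d = self.downsample
        h, w = frame.shape
        hc, wc = (h // d) * d, (w // d) * d
        pooled = frame[:hc, :wc].reshape(hc // d, d, wc // d, d).mean(axis=(1, 3))
        return pooled.ravel() @ self._projection(pooled.size)


def embed(frame: np.ndarray, embedder: FeatureEmbedder) -> np.ndarray:
    """Feature-space embedding of a single frame (deterministic)."""
    return embedder.embed(frame)


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def mean_squared_error(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean((x.astype(np.float64) - y.astype(np.float64)) ** 2))


def cross_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of flattened intensities.

    For constant images the correlation is undefined; the documented
    sentinel is 1.0 if both are constant and equal, else 0.0 (warned).
    """
    xf = x.ravel().astype(np.float64)
    yf = y.ravel().astype(np.float64)
    sx, sy = xf.std(), yf.std()
    if sx == 0 or sy == 0:
        log.warning("cross_correlation: constant image, returning sentinel")
        return 1.0 if (sx == 0 and sy == 0 and np.array_equal(xf, yf)) else 0.0
    return float(np.clip(np.corrcoef(xf, yf)[0, 1], -1.0, 1.0))


def mutual_information(x: np.ndarray, y: np.ndarray, bins: int = MI_BINS) -> float:
    """Mutual information in nats from a ``bins`` x ``bins`` equal-width
    joint histogram over each image's observed intensity range."""
    joint, _, _ = np.histogram2d(x.ravel(), y.ravel(), bins=bins)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])))


def ssim_index(x: np.ndarray, y: np.ndarray) -> float:
    """SSIM with a 7x7 Gaussian-weighted window, K1=0.01, K2=0.03; the
    dynamic range is taken from the pair's joint observed range."""
    rng_x = x.max() - x.min()
    rng_y = y.max() - y.min()
    data_range = max(rng_x, rng_y)
    if data_range == 0:
        log.warning("ssim: constant images, returning sentinel")
        return 1.0 if np.array_equal(x, y) else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        val = structural_similarity(
            x.astype(np.float64),
            y.astype(np.float64),
            win_size=7,
            gaussian_weights=True,
            sigma=1.5,
            K1=0.01,
            K2=0.03,
            data_range=data_range,
        )
    return float(np.clip(val, -1.0, 1.0))


def similarity_vector(
    frame: np.ndarray, reference: np.ndarray, embedder: FeatureEmbedder
) -> SimilarityVector:
    """All five similarity metrics between ``frame`` and ``reference``.

    Both images must share one shape and should already be preprocessed
    (zero-mean, unit-variance).  mse, cross_corr, mutual_info and ssim are
    symmetric in their arguments; cosine_feat is symmetric too because the
    embedding is linear.
    """
    if frame.shape != reference.shape:
        raise ValueError(f"shape mismatch: {frame.shape} vs {reference.shape}")
    return SimilarityVector(
        cosine_feat=_cosine(embedder.embed(frame), embedder.embed(reference)),
        mse=mean_squared_error(frame, reference),
        cross_corr=cross_correlation(frame, reference),
        mutual_info=mutual_information(frame, reference),
        ssim=ssim_index(frame, reference),
    )


def clip_similarity_table(clip, embedder: FeatureEmbedder | None = None):
    """Per-frame similarity vectors of a clip against its diagnostic plane.

    Returns a DataFrame with columns ``frame`` + :data:`METRIC_NAMES`.
    Frames are z-scored before comparison (the preprocessing every
    downstream model assumes).
    """
    import pandas as pd

    from .task_model import normalise

    if embedder is None:
        embedder = FeatureEmbedder()
    ref = normalise(clip.frames[clip.dp_index])
    rows = []
    for j in range(clip.n_frames):
        sv = similarity_vector(normalise(clip.frames[j]), ref, embedder)
        rows.append({"frame": j, **{m: getattr(sv, m) for m in METRIC_NAMES}})
    return pd.DataFrame(rows)
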