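"""Synthetic freehand-ultrasound scan generator.

Emulates the statistical structure of a biometry scanning session so the
whole skill-assessment pipeline can be exercised without clinical data:

* one clip per subject, nominally 30 Hz and 6-12 s long, with a designated
  diagnostic-plane frame where the operator would take the measurement;
* a latent 1-D probe *pose offset* path ``p(j)`` with ``p = 0`` exactly at
  the diagnostic plane; image appearance degrades and the rendered anatomy
  deforms as ``|p|`` grows, so image similarity to the diagnostic plane
  decays with pose offset;
* per-frame true biometry whose relative error grows linearly with ``|p|``;
* a synchronized 3-axis angular-velocity trace derived kinematically from
  the pose path, with sensor noise whose variance shrinks as the latent
  operator skill rises.

The anatomy is an elliptical bright ring on a textured background, so the
biometry (ring circumference) is known in closed form and the relative
error is exact and auditable.  Speckle is multiplicative gamma noise.

The pose path is an Ornstein-Uhlenbeck mean-reverting walk toward 0: a
skilled operator reverts faster and wanders less, hence dwells longer near
the diagnostic plane, which makes the fraction of low-error frames monotone
in the latent skill by construction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SyntheticScanConfig",
    "ScanClip",
    "MotionTrace",
    "FrameTruth",
    "generate_dataset",
    "annotate_subset",
    "write_dataset",
]

# Gain mapping |pose offset| -> relative biometry error; chosen so that a
# typical clip spans delta in [0, ~0.3] and skilled clips dwell below 0.04.
DELTA_GAIN = 0.5

# Out-of-plane defocus: anatomy is blurred with sigma = BLUR_GAIN * |pose|
# pixels, mimicking the loss of focus as the probe leaves the imaging plane.
BLUR_GAIN = 3.0


@dataclass(frozen=True)
class SyntheticScanConfig:
    """Configuration of one synthetic scanning session.

    Parameters
    ----------
    n_operators, clips_per_operator : int
        Dataset size; each clip belongs to a distinct subject.
    fps : float
        Frame rate in frames per second (clinical video is 30 Hz).
    duration_range : (float, float)
        Clip duration bounds in seconds.
    image_shape : (int, int)
        Frame height and width in pixels.
    skill_range : (float, float)
        Range of the latent per-operator skill parameter in [0, 1].
    noise_sd : float
        Relative standard deviation of the multiplicative speckle noise.
    video_informative, motion_informative : bool
        Ablation switches.  When False the corresponding modality carries
        no information about the pose offset (frames rendered at pose 0,
        or motion replaced by skill-independent white noise).
    seed : int
        Master seed; identical seeds give bit-identical datasets.
    """

    n_operators: int = 8
    clips_per_operator: int = 5
    fps: float = 30.0
    duration_range: tuple[float, float] = (6.0, 12.0)
    image_shape: tuple[int, int] = (224, 288)
    skill_range: tuple[float, float] = (0.1, 0.9)
    noise_sd: float = 0.1
    video_informative: bool = True
    motion_informative: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_operators < 1 or self.clips_per_operator < 1:
            raise ValueError("counts must be >= 1")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        lo, hi = self.duration_range
        if not (0 < lo <= hi):
            raise ValueError("invalid duration_range")
        if min(self.image_shape) < 8:
            raise ValueError("image_shape too small")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class ScanClip:
    """One subject's frame sequence."""

    frames: np.ndarray          # (J, H, W) float32 intensities in [0, ~2]
    fps: float
    subject_id: str
    operator_id: str
    dp_index: int               # diagnostic-plane frame index
    zoom: float = 1.0

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (J, H, W) array")
        if not (0 <= self.dp_index < self.n_frames):
            raise ValueError("dp_index out of range")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class MotionTrace:
    """Synchronized 3-channel angular-velocity signal (rad/s)."""

    omega: np.ndarray           # (3, J)
    fps: float

    def __post_init__(self) -> None:
        if self.omega.shape[0] != 3:
            raise ValueError("omega must have 3 channels")
        if not np.all(np.isfinite(self.omega)):
            raise ValueError("omega must be finite")


@dataclass
class FrameTruth:
    """Closed-form per-frame ground truth for one clip."""

    biometry: np.ndarray        # (J,) positive, ring circumference (px)
    delta_true: np.ndarray      # (J,) relative error in [0, 1]
    skill_latent: float         # per-clip operator skill in [0, 1]
    pose: np.ndarray = field(default=None)  # (J,) latent pose offset path


def _ou_pose_path(
    rng: np.random.Generator, n: int, fps: float, skill: float
) -> tuple[np.ndarray, int]:
    """Mean-reverting pose-offset walk; reversion speed and volatility set by skill."""
    theta = 1.0 + 4.0 * skill            # reversion rate, 1/s
    sigma = 0.45 - 0.35 * skill          # volatility, pose units / sqrt(s)
    dt = 1.0 / fps
    x = np.empty(n)
    # start away from the plane: the operator approaches it
    x[0] = rng.uniform(0.3, 0.6) * rng.choice([-1.0, 1.0])
    eps = rng.standard_normal(n - 1)
    for j in range(1, n):
        x[j] = x[j - 1] - theta * x[j - 1] * dt + sigma * np.sqrt(dt) * eps[j - 1]
    # anchor the diagnostic plane exactly at pose 0
    dp = int(np.argmin(np.abs(x[n // 4:]))) + n // 4
    return x - x[dp], dp


def _render_frames(
    rng: np.random.Generator,
    pose: np.ndarray,
    shape: tuple[int, int],
    base_scale: float,
    noise_sd: float,
    informative: bool,
) -> np.ndarray:
    """Render the elliptical ring anatomy for each pose offset.

    Off-plane frames (larger |pose|) have a dimmer ring and scaled axes, so
    their appearance drifts away from the diagnostic-plane frame.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry0 = base_scale * h / 2.0
    rx0 = base_scale * w / 2.0
    ring_w = 0.08
    # fixed per-subject background texture (smooth random field)
    from scipy.ndimage import gaussian_filter

    background = gaussian_filter(rng.standard_normal((h, w)), sigma=max(2, h // 16))
    background = 0.15 * background / (np.abs(background).max() + 1e-12) + 0.2

    p = pose if informative else np.zeros_like(pose)
    frames = np.empty((len(pose), h, w), dtype=np.float32)
    for j, pj in enumerate(p):
        scale = 1.0 + 0.5 * pj
        q = np.sqrt((yy - cy) ** 2 / (ry0 * scale) ** 2 + (xx - cx) ** 2 / (rx0 * scale) ** 2)
        brightness = 1.0 / (1.0 + 2.0 * abs(pj))
        ring = brightness * np.exp(-((q - 1.0) ** 2) / (2.0 * ring_w**2))
        img = background + ring
        if abs(pj) > 1e-6:
            img = gaussian_filter(img, sigma=BLUR_GAIN * abs(pj))
        if noise_sd > 0:
            k = 1.0 / noise_sd**2
            img = img * rng.gamma(k, 1.0 / k, size=img.shape)
        frames[j] = img.astype(np.float32)
    return frames


def _motion_from_pose(
    rng: np.random.Generator, pose: np.ndarray, fps: float, skill: float, informative: bool
) -> np.ndarray:
    """Three-axis angular velocity: derivatives of smooth functions of pose plus noise."""
    if informative:
        chans = np.stack([pose, 0.5 * pose**2, np.sin(pose)])
        omega = np.gradient(chans, axis=1) * fps
        noise_scale = 0.3 * (1.1 - skill)
    else:
        omega = np.zeros((3, len(pose)))
        noise_scale = 0.3
    omega = omega + noise_scale * rng.standard_normal(omega.shape)
    return omega


def generate_dataset(
    config: SyntheticScanConfig,
) -> list[tuple[ScanClip, MotionTrace, FrameTruth]]:
    """Generate a full synthetic dataset of (clip, motion, truth) triples.

    Operators are assigned evenly spaced latent skills across
    ``config.skill_range``; every clip belongs to a distinct subject.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.skill_range
    if config.n_operators == 1:
        skills = np.array([(lo + hi) / 2.0])
    else:
        skills = np.linspace(lo, hi, config.n_operators)

    dataset = []
    subject = 0
    for op in range(config.n_operators):
        skill = float(skills[op])
        for _ in range(config.clips_per_operator):
            duration = rng.uniform(*config.duration_range)
            n = int(round(duration * config.fps))
            pose, dp = _ou_pose_path(rng, n, config.fps, skill)
            delta = np.minimum(1.0, DELTA_GAIN * np.abs(pose))
            base_circ = rng.uniform(300.0, 500.0)
            biometry = base_circ * (1.0 + np.sign(pose) * delta)
            frames = _render_frames(
                rng, pose, config.image_shape, base_scale=0.6,
                noise_sd=config.noise_sd, informative=config.video_informative,
            )
            omega = _motion_from_pose(rng, pose, config.fps, skill, config.motion_informative)
            clip = ScanClip(
                frames=frames, fps=config.fps,
                subject_id=f"S{subject:03d}", operator_id=f"O{op:02d}",
                dp_index=dp,
            )
            motion = MotionTrace(omega=omega, fps=config.fps)
            truth = FrameTruth(
                biometry=biometry, delta_true=delta, skill_latent=skill, pose=pose
            )
            dataset.append((clip, motion, truth))
            subject += 1
    return dataset


def annotate_subset(
    dataset: list[tuple[ScanClip, MotionTrace, FrameTruth]],
    n_clips: int,
    frames_per_clip: int,
    seed: int = 0,
):
    """Sample sparse manual biometry annotations, as an expert would provide.

    Returns a DataFrame with columns ``clip, frame, biometry, provenance``;
    the diagnostic-plane frame of each sampled clip is always included
    (operators always annotate the plane they measured on).
    """
    import pandas as pd

    if n_clips > len(dataset):
        raise ValueError(f"requested {n_clips} clips but dataset has {len(dataset)}")
    rng = np.random.default_rng(seed)
    rows = []
    if n_clips > 0:
        chosen = rng.choice(len(dataset), size=n_clips, replace=False)
        for ci in sorted(chosen):
            clip, _, truth = dataset[ci]
            if frames_per_clip > clip.n_frames:
                raise ValueError(
                    f"clip {ci} has {clip.n_frames} frames, cannot annotate {frames_per_clip}"
                )
            others = np.setdiff1d(np.arange(clip.n_frames), [clip.dp_index])
            extra = rng.choice(others, size=frames_per_clip - 1, replace=False)
            for fr in sorted([clip.dp_index, *extra.tolist()]):
                rows.append(
                    {
                        "clip": ci,
                        "frame": int(fr),
                        "biometry": float(truth.biometry[fr]),
                        "provenance": "manual",
                    }
                )
    return pd.DataFrame(rows, columns=["clip", "frame", "biometry", "provenance"])


def write_dataset(
    dataset: list[tuple[ScanClip, MotionTrace, FrameTruth]],
    out_dir: str | Path,
    image_format: str = "npz",
) -> Path:
    """Write a dataset to disk: one directory per clip, manifest as JSON.

    ``image_format='png'`` stores frames as zero-padded 8-bit PNGs for
    inspectability; ``'npz'`` stores a single compressed array (faster).
    Motion goes to ``motion.csv`` (header ``frame,wx,wy,wz``), truth to
    ``truth.csv``.
    """
    import imageio.v3 as iio
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for ci, (clip, motion, truth) in enumerate(dataset):
        cdir = out / f"clip{ci:04d}"
        cdir.mkdir(exist_ok=True)
        if image_format == "png":
            lo, hi = clip.frames.min(), clip.frames.max()
            scaled = (255 * (clip.frames - lo) / max(hi - lo, 1e-12)).astype(np.uint8)
            for j in range(clip.n_frames):
                iio.imwrite(cdir / f"frame{j:05d}.png", scaled[j])
        elif image_format == "npz":
            np.savez_compressed(cdir / "frames.npz", frames=clip.frames)
        else:
            raise ValueError(f"unknown image_format {image_format!r}")
        pd.DataFrame(
            {
                "frame": np.arange(clip.n_frames),
                "wx": motion.omega[0],
                "wy": motion.omega[1],
                "wz": motion.omega[2],
            }
        ).to_csv(cdir / "motion.csv", index=False)
        pd.DataFrame(
            {
                "frame": np.arange(clip.n_frames),
                "biometry": truth.biometry,
                "delta_true": truth.delta_true,
            }
        ).to_csv(cdir / "truth.csv", index=False)
        manifest.append(
            {
                "clip": ci,
                "dir": cdir.name,
                "operator_id": clip.operator_id,
                "subject_id": clip.subject_id,
                "dp_index": clip.dp_index,
                "fps": clip.fps,
                "n_frames": clip.n_frames,
                "skill_latent": truth.skill_latent,
                "image_format": image_format,
            }
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def read_dataset(root: str | Path) -> list[tuple[ScanClip, MotionTrace, FrameTruth]]:
    """Read back a dataset written by :func:`write_dataset`."""
    import imageio.v3 as iio
    import pandas as pd

    root = Path(root)
    manifest = json.loads((root / "manifest.json").read_text())
    dataset = []
    for entry in manifest:
        cdir = root / entry["dir"]
        if entry.get("image_format", "npz") == "png":
            files = sorted(cdir.glob("frame*.png"))
            frames = np.stack([iio.imread(f) for f in files]).astype(np.float32) / 255.0
        else:
            frames = np.load(cdir / "frames.npz")["frames"]
        mot = pd.read_csv(cdir / "motion.csv")
        tru = pd.read_csv(cdir / "truth.csv")
        clip = ScanClip(
            frames=frames, fps=entry["fps"],
            subject_id=entry["subject_id"], operator_id=entry["operator_id"],
            dp_index=entry["dp_index"],
        )
        motion = MotionTrace(
            omega=mot[["wx", "wy", "wz"]].to_numpy().T, fps=entry["fps"]
        )
        truth = FrameTruth(
            biometry=tru["biometry"].to_numpy(),
            delta_true=tru["delta_true"].to_numpy(),
            skill_latent=entry["skill_latent"],
        )
        dataset.append((clip, motion, truth))
    return dataset
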