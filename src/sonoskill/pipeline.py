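"""End-to-end pipeline stages shared by the ablation driver and the CLI.

Each helper runs one stage of the framework on an in-memory dataset:
similarity tables -> linear error model -> labels -> task model ->
windowed scores -> skill predictor.  Desk-scale defaults (small input
resize, larger head learning rate, fewer epochs) keep a full run on one
CPU in minutes; every stage is deterministic given its seed.
"""

from __future__ import annotations

import logging

import numpy as np

from . import evaluation, labelgen, skill_predictor, skill_scores, task_model
from .similarity import FeatureEmbedder, METRIC_NAMES, clip_similarity_table
from .synthetic_data import annotate_subset

log = logging.getLogger(__name__)

#: desk-scale model defaults; the dataclass defaults keep the full-scale values
DESK_TASK = dict(lr=1e-2, epochs=30, resize_shape=(56, 72))
DESK_PREDICTOR = dict(lr=1e-2, epochs=300, patience=25)


def oracle_frame_predictions(dataset, delta_min: float = 0.04):
    """Idealised task-model output from the generator's closed-form truth:
    probability 1 for frames within the precision threshold, else 0.
    Useful for experiments that need score series carrying a known signal
    without the variance of a trained classifier."""
    return [(truth.delta_true <= delta_min).astype(float) for _, _, truth in dataset]


def compute_similarities(dataset, embedder: FeatureEmbedder | None = None):
    """Per-clip (J, 5) similarity matrices against each diagnostic plane."""
    if embedder is None:
        embedder = FeatureEmbedder()
    sims = []
    for clip, _, _ in dataset:
        table = clip_similarity_table(clip, embedder)
        sims.append(table[list(METRIC_NAMES)].to_numpy())
    return sims


def fit_label_model_from_dataset(
    dataset,
    n_clips: int | None = None,
    frames_per_clip: int = 16,
    seed: int = 0,
    sims: list | None = None,
):
    """Annotate a sparse subset and fit the similarity -> error linear model.

    Returns ``(sims, model)`` where ``sims`` is the per-clip similarity
    matrix list (computed here unless supplied).
    """
    if sims is None:
        sims = compute_similarities(dataset)
    if n_clips is None:
        n_clips = max(2, int(round(0.15 * len(dataset))))
    ann = annotate_subset(dataset, n_clips=n_clips, frames_per_clip=frames_per_clip, seed=seed)

    rows, deltas = [], []
    for ci, group in ann.groupby("clip"):
        clip = dataset[ci][0]
        dp_row = group[group["frame"] == clip.dp_index]
        b_dp = float(dp_row["biometry"].iloc[0])
        for _, r in group.iterrows():
            fr = int(r["frame"])
            rows.append(sims[ci][fr])
            deltas.append(labelgen.relative_error(float(r["biometry"]), b_dp))
    # on zero-mean unit-variance images mse == 2 - 2*cross_corr exactly, so
    # the five-metric design is perfectly collinear; a tiny ridge resolves it
    model = labelgen.fit_error_model(np.array(rows), np.array(deltas), ridge=1e-6)
    log.info("label model fitted on %d frames, training MSE %.2e", model.n_train, model.fit_mse)
    return sims, model


def label_dataset(dataset, sims, model, delta_min: float):
    """Surrogate labels for every clip (the at-scale label source)."""
    return [
        labelgen.make_mixed_labels(clip, sims[ci], model, manual=None, delta_min=delta_min)
        for ci, (clip, _, _) in enumerate(dataset)
    ]


def task_model_dataset(dataset, labels, split, config=None, seed: int = 0):
    """Train the frame classifier on the development split; predict all clips."""
    if config is None:
        config = task_model.TaskModelConfig(seed=seed, **DESK_TASK)
    train_idx = split.dev_train or split.development
    val_idx = split.dev_val or train_idx
    train = [(dataset[i][0].frames, labels[i].g) for i in train_idx]
    val = [(dataset[i][0].frames, labels[i].g) for i in val_idx]
    model = task_model.train_task_model(train, val, config)
    preds = [model.predict_proba(clip.frames) for clip, _, _ in dataset]
    return model, preds


def score_dataset(
    dataset,
    labels,
    preds,
    split,
    *,
    tau: int,
    criterion: str = "pos",
    cutoff: float = 0.5,
    modality: str = "both",
    predictor_config=None,
    seed: int = 0,
):
    """Train the skill predictor on development clips, evaluate on test clips.

    Returns per-test-clip aggregated metrics: RMSE and PCC mean/SD between
    predicted and task-model-generated score series, plus the RMSE of the
    predict-the-training-mean baseline.
    """
    if predictor_config is None:
        predictor_config = skill_predictor.PredictorConfig(
            modality=modality, tau=tau, seed=seed, **DESK_PREDICTOR
        )

    def series_for(idx):
        return [
            skill_scores.sliding_scores(
                preds[i], criterion, tau, labels=labels[i].g, cutoff=cutoff
            )
            for i in idx
        ]

    def samples_for(idx, series):
        clips = [dataset[i][0] for i in idx]
        motions = [dataset[i][1] for i in idx]
        return skill_predictor.build_training_set(clips, motions, series, tau)

    tr_idx = split.dev_train or split.development
    va_idx = split.dev_val or tr_idx
    train_samples = samples_for(tr_idx, series_for(tr_idx))
    val_samples = samples_for(va_idx, series_for(va_idx))
    model = skill_predictor.train_predictor(train_samples, predictor_config, val_samples)

    train_mean = float(np.mean([s.target for s in train_samples]))
    rmses, pccs, base_rmses = [], [], []
    for i in split.test:
        true = skill_scores.sliding_scores(
            preds[i], criterion, tau, labels=labels[i].g, cutoff=cutoff
        )
        pred = skill_predictor.predict_scores(
            model, dataset[i][0], dataset[i][1], tau
        )
        rmses.append(evaluation.rmse(true.scores, pred.scores))
        base_rmses.append(
            evaluation.rmse(true.scores, np.full_like(true.scores, train_mean))
        )
        pccs.append(evaluation.pcc(true.scores, pred.scores))
    pccs_ok = [p for p in pccs if np.isfinite(p)]
    return {
        "rmse_mean": float(np.mean(rmses)),
        "rmse_sd": float(np.std(rmses)),
        "pcc_mean": float(np.mean(pccs_ok)) if pccs_ok else float("nan"),
        "pcc_sd": float(np.std(pccs_ok)) if pccs_ok else float("nan"),
        "baseline_rmse_mean": float(np.mean(base_rmses)),
        "model": model,
    }
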