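"""Operator/subject-disjoint splitting, metric suite and ablation driver.

Clips are partitioned into a development and a holdout test set at the
*operator* level, so no operator (and, since subjects are scanned by a
single operator here, no subject) appears on both sides.  The development
set is further split 85:15 by clip into training and validation sets.

Metrics: RMSE and Pearson correlation between predicted and task-model-
generated score series, plus the frame-classification confusion metrics in
:mod:`sonoskill.task_model`.  Tables aggregate per test clip and report
mean +/- SD across clips.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = ["SplitSpec", "make_split", "rmse", "pcc", "paired_ttest", "run_ablation"]


@dataclass
class SplitSpec:
    """Clip-index partition with the disjointness invariant."""

    development: list[int]
    test: list[int]
    dev_train: list[int]
    dev_val: list[int]
    seed: int

    def validate(self, dataset) -> None:
        dev_ops = {dataset[i][0].operator_id for i in self.development}
        test_ops = {dataset[i][0].operator_id for i in self.test}
        dev_sub = {dataset[i][0].subject_id for i in self.development}
        test_sub = {dataset[i][0].subject_id for i in self.test}
        if dev_ops & test_ops or dev_sub & test_sub:
            raise AssertionError("development/test sets share an operator or subject")


def make_split(dataset, test_fraction: float = 0.2, seed: int = 0) -> SplitSpec:
    """Greedy operator-level partition into development and test sets.

    Operators are shuffled by ``seed`` and assigned to the test side until
    at least ``test_fraction`` of the clips are there; the rest form the
    development set, which is split 85:15 by clip into train and val.
    """
    rng = np.random.default_rng(seed)
    by_op: dict[str, list[int]] = {}
    for i, (clip, *_rest) in enumerate(dataset):
        by_op.setdefault(clip.operator_id, []).append(i)
    if len(by_op) < 2:
        raise ValueError("operator-disjoint split requires >= 2 operators")

    ops = sorted(by_op)
    rng.shuffle(ops)
    n_total = len(dataset)
    test: list[int] = []
    k = 0
    while len(test) < test_fraction * n_total and k < len(ops) - 1:
        test.extend(by_op[ops[k]])
        k += 1
    development = [i for op in ops[k:] for i in by_op[op]]

    dev = np.array(development)
    rng.shuffle(dev)
    n_val = int(round(0.15 * len(dev)))
    spec = SplitSpec(
        development=sorted(development),
        test=sorted(test),
        dev_train=sorted(dev[n_val:].tolist()),
        dev_val=sorted(dev[:n_val].tolist()),
        seed=seed,
    )
    spec.validate(dataset)
    return spec


def rmse(true: np.ndarray, pred: np.ndarray) -> float:
    """Root-mean-square error between two aligned score series."""
    true = np.asarray(true, dtype=np.float64)
    pred = np.asarray(pred, dtype=np.float64)
    if true.shape != pred.shape or true.size == 0:
        raise ValueError("series must be non-empty and equal length")
    return float(np.sqrt(np.mean((true - pred) ** 2)))


def pcc(true: np.ndarray, pred: np.ndarray) -> float:
    """Pearson correlation; NaN (with a log message) if a series is constant."""
    true = np.asarray(true, dtype=np.float64)
    pred = np.asarray(pred, dtype=np.float64)
    if true.shape != pred.shape or true.size < 2:
        raise ValueError("series must be equal length, >= 2 points")
    if true.std() == 0 or pred.std() == 0:
        log.warning("pcc undefined for a constant series; returning NaN")
        return float("nan")
    return float(stats.pearsonr(true, pred).statistic)


def paired_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Paired t test helper (statistic, p value) for configuration contrasts."""
    res = stats.ttest_rel(np.asarray(a, dtype=float), np.asarray(b, dtype=float))
    return float(res.statistic), float(res.pvalue)


def run_ablation(
    dataset,
    grid: dict,
    *,
    annotate_clips: int | None = None,
    frames_per_clip: int = 16,
    seed: int = 0,
    task_config=None,
    predictor_config=None,
) -> pd.DataFrame:
    """Run the full pipeline once per grid configuration.

    ``grid`` maps the axes ``delta_min``, ``tau``, ``modality``,
    ``cutoff_target`` (each a sequence; ``cutoff_target`` entries may be
    None for the default 0.5 cut-off) to their values.  Returns one row per
    configuration with the task-model metrics on the held-out test clips
    and the skill-predictor RMSE/PCC aggregated per test clip (mean, SD).
    """
    from itertools import product

    from . import task_model
    from .pipeline import (
        fit_label_model_from_dataset,
        label_dataset,
        score_dataset,
        task_model_dataset,
    )

    axes = {
        "delta_min": list(grid.get("delta_min", [0.04])),
        "tau": list(grid.get("tau", [16])),
        "modality": list(grid.get("modality", ["both"])),
        "cutoff_target": list(grid.get("cutoff_target", [None])),
        "criterion": list(grid.get("criterion", ["pos"])),
    }
    if any(len(v) == 0 for v in axes.values()):
        raise ValueError("empty ablation grid")

    split = make_split(dataset, seed=seed)
    sims, model_err = fit_label_model_from_dataset(
        dataset, n_clips=annotate_clips, frames_per_clip=frames_per_clip, seed=seed
    )

    rows = []
    for dmin, tau, modality, ctarget, criterion in product(*axes.values()):
        labels = label_dataset(dataset, sims, model_err, dmin)
        tm, preds = task_model_dataset(dataset, labels, split, task_config, seed=seed)

        test_g = np.concatenate([preds[i] for i in split.test])
        test_y = np.concatenate([labels[i].g for i in split.test])
        if ctarget is None:
            cutoff = 0.5
        else:
            cal_g = np.concatenate([preds[i] for i in split.dev_val or split.development])
            cal_y = np.concatenate(
                [labels[i].g for i in (split.dev_val or split.development)]
            )
            cutoff, _ = task_model.calibrate_cutoff(cal_g, cal_y, ctarget)
        acc, sens, spec = task_model.evaluate_task_model(test_g, test_y, cutoff)

        results = score_dataset(
            dataset, labels, preds, split, tau=tau, criterion=criterion,
            cutoff=cutoff, modality=modality,
            predictor_config=predictor_config, seed=seed,
        )
        results.pop("model", None)
        rows.append(
            {
                "split_seed": seed,
                "delta_min": dmin,
                "tau": tau,
                "modality": modality,
                "criterion": criterion,
                "cutoff_target": np.nan if ctarget is None else ctarget,
                "cutoff": cutoff,
                "acc": acc,
                "sens": sens,
                "spec": spec,
                "pos_label_count": int(sum(labels[i].g.sum() for i in range(len(labels)))),
                **results,
            }
        )
    return pd.DataFrame(rows)
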