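"""Metrics, cross-validation harnesses, and focus-channel localization.

The classification metrics are the clinical five — accuracy,
sensitivity, specificity, positive and negative predictive value —
computed from the confusion counts with the focal class as positive.
A metric whose denominator is empty (e.g. sensitivity with no positive
ground truth) is reported as missing (NaN) rather than forced to zero.

Localization treats each multi-channel recording as a bank of
single-channel segments: the fine-tuned model scores every channel
with its focal-class probability and the channel with the highest
probability is declared the focus.  Ties break to the earlier channel
in recording order, with a warning.
"""

from __future__ import annotations

import json
import math
import os
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .synthetic import FOCAL, LabeledSegment


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with the focal class as positive."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.tn + self.fp + self.fn < 1:
            raise ValueError("confusion counts sum to zero")

    @classmethod
    def from_predictions(cls, y_true: np.ndarray,
                         y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(bool)
        y_pred = np.asarray(y_pred).astype(bool)
        return cls(tp=int(np.sum(y_true & y_pred)),
                   tn=int(np.sum(~y_true & ~y_pred)),
                   fp=int(np.sum(~y_true & y_pred)),
                   fn=int(np.sum(y_true & ~y_pred)))


@dataclass(frozen=True)
class MetricSet:
    """ACC / SN / SP / PPV / NPV as fractions; NaN marks undefined."""

    acc: float
    sn: float
    sp: float
    ppv: float
    npv: float

    def as_dict(self) -> dict:
        return {"acc": self.acc, "sn": self.sn, "sp": self.sp,
                "ppv": self.ppv, "npv": self.npv}


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def metrics(c: ConfusionCounts) -> MetricSet:
    """The five clinical metrics from confusion counts.

    acc = (TP+TN)/(TP+TN+FP+FN), sn = TP/(TP+FN), sp = TN/(TN+FP),
    ppv = TP/(TP+FP), npv = TN/(TN+FN).
    """
    total = c.tp + c.tn + c.fp + c.fn
    return MetricSet(acc=_ratio(c.tp + c.tn, total),
                     sn=_ratio(c.tp, c.tp + c.fn),
                     sp=_ratio(c.tn, c.tn + c.fp),
                     ppv=_ratio(c.tp, c.tp + c.fp),
                     npv=_ratio(c.tn, c.tn + c.fn))


# ----------------------------------------------------------------------
# split harnesses
def kfold_split(n: int, k: int = 10,
                seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled k-fold partition of ``range(n)``.

    Returns ``k`` (train_idx, test_idx) pairs; test folds are disjoint,
    cover every index once, and differ in size by at most one.
    """
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    out = []
    for i in range(k):
        test = np.sort(folds[i])
        train = np.sort(np.concatenate([folds[j] for j in range(k) if j != i]))
        out.append((train, test))
    return out


def kfold_split_by_patient(patient_ids: Sequence[str], k: int = 10,
                           seed: int = 0
                           ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Patient-stratified k-fold: whole patients are assigned to folds,
    so no identity leaks between train and test.  Requires at least
    ``k`` distinct patients."""
    ids = np.asarray(patient_ids)
    patients = np.array(sorted(set(ids.tolist())))
    if k > len(patients):
        raise ValueError(f"cannot make {k} patient folds from "
                         f"{len(patients)} patients")
    rng = np.random.default_rng(seed)
    pfolds = np.array_split(rng.permutation(patients), k)
    out = []
    for i in range(k):
        mask = np.isin(ids, pfolds[i])
        out.append((np.flatnonzero(~mask), np.flatnonzero(mask)))
    return out


def loocv_by_patient(patient_ids: Sequence[str]
                     ) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Leave-one-patient-out splits.

    Returns one ``(patient, train_idx, test_idx)`` triple per distinct
    patient; the test set holds exactly that patient's rows.
    """
    ids = np.asarray(patient_ids)
    patients = sorted(set(ids.tolist()))
    if len(patients) < 2:
        raise ValueError("leave-one-patient-out needs at least 2 patients")
    out = []
    for p in patients:
        mask = ids == p
        out.append((p, np.flatnonzero(~mask), np.flatnonzero(mask)))
    return out


# ----------------------------------------------------------------------
# localization
@dataclass
class LocalizationResult:
    """Per-channel focal probabilities and the argmax decision."""

    probabilities: dict[str, float]
    predicted_channel: str
    true_channel: Optional[str] = None

    @property
    def correct(self) -> Optional[bool]:
        if self.true_channel is None:
            return None
        return self.predicted_channel == self.true_channel


def localize(recording: Sequence[LabeledSegment], model,
             channel_order: Optional[Sequence[str]] = None
             ) -> LocalizationResult:
    """Pick the focus channel of one recording by argmax probability.

    Each channel may contribute several segments; its score is the
    mean focal-class probability over them.  ``model`` is any object
    with ``predict_proba((N, W)) -> (N, 2)`` (class 1 = focal).  Exact
    ties resolve to the channel appearing first, with a warning.
    """
    by_channel: dict[str, list[np.ndarray]] = {}
    true_channel = None
    for seg in recording:
        by_channel.setdefault(seg.channel_name, []).append(seg.samples)
        if seg.class_label == FOCAL:
            true_channel = seg.channel_name
    if channel_order is not None:
        missing = set(channel_order) ^ set(by_channel)
        if missing:
            raise ValueError(
                f"recording channels do not match the manifest: {sorted(missing)}")
        names = list(channel_order)
    else:
        names = list(by_channel)
    probs = {}
    for name in names:
        segs = np.stack(by_channel[name])
        p = model.predict_proba(segs)[:, 1]
        probs[name] = float(p.mean())
    values = np.array([probs[n] for n in names])
    best = int(np.argmax(values))
    if np.sum(values == values[best]) > 1:
        warnings.warn("tie in channel probabilities; choosing the first "
                      "channel in recording order", stacklevel=2)
    return LocalizationResult(probabilities=probs,
                              predicted_channel=names[best],
                              true_channel=true_channel)


def localization_accuracy(results: Sequence[LocalizationResult]) -> float:
    """Fraction of recordings whose argmax channel is the true focus."""
    flags = [r.correct for r in results if r.correct is not None]
    if not flags:
        raise ValueError("no recording carries a true focus label")
    return float(np.mean(flags))


# ----------------------------------------------------------------------
# end-to-end harnesses
def run_kfold(data, k: int = 10, train_cfg=None, loss_weights=None,
              model_cfg=None, by_patient: bool = False,
              seed: int = 0) -> dict:
    """k-fold cross-validation of the pre-training phase.

    Trains a fresh model on each train fold and scores the test fold.
    Default splitting is at segment level; ``by_patient=True`` keeps
    whole patients together (no identity leakage, needs >= k patients).
    Returns per-fold metric sets and their mean accuracy.
    """
    from .network import ModelConfig
    from .training import (LossWeights, TrainConfig, TrainingData,
                           pretrain)
    train_cfg = train_cfg or TrainConfig()
    loss_weights = loss_weights or LossWeights()
    model_cfg = model_cfg or ModelConfig()
    if by_patient:
        ids = [data.patients[i] for i in data.d]
        splits = kfold_split_by_patient(ids, k=k, seed=seed)
    else:
        splits = kfold_split(len(data), k=k, seed=seed)
    fold_metrics = []
    for train_idx, test_idx in splits:
        sub = TrainingData(data.X[train_idx], data.y[train_idx],
                           data.d[train_idx], data.patients)
        state = pretrain(sub, train_cfg, loss_weights, model_cfg)
        probs = state.model.predict_proba(data.X[test_idx])
        pred = probs[:, 1] > 0.5
        counts = ConfusionCounts.from_predictions(data.y[test_idx], pred)
        fold_metrics.append(metrics(counts))
    return {"folds": fold_metrics,
            "mean_accuracy": float(np.mean([m.acc for m in fold_metrics]))}


def run_loocv_localization(pretrained, recordings_by_patient: dict,
                           train_cfg=None, weighted: bool = True) -> dict:
    """Leave-one-patient-out transfer evaluation on recordings.

    For each patient: fine-tune the pretrained model's classifier on
    every other patient's recordings, then localize the held-out
    patient's recordings.  Reports per-patient localization accuracy
    and their mean (the averaging convention used for multi-patient
    test results).
    """
    import copy

    from .training import TrainingData, finetune
    patients = sorted(recordings_by_patient)
    if len(patients) < 2:
        raise ValueError("leave-one-patient-out needs at least 2 patients")
    per_patient = {}
    results = []
    for held in patients:
        train_segs = [s for p in patients if p != held
                      for rec in recordings_by_patient[p] for s in rec]
        data = TrainingData.from_segments(train_segs)
        state = copy.deepcopy(pretrained)
        state = finetune(state, data, train_cfg, weighted=weighted)
        res = [localize(rec, state.model)
               for rec in recordings_by_patient[held]]
        per_patient[held] = localization_accuracy(res)
        results.extend((held, r) for r in res)
    return {"per_patient_accuracy": per_patient,
            "mean_accuracy": float(np.mean(list(per_patient.values()))),
            "results": results}


# ----------------------------------------------------------------------
# export
def export_results(results: Sequence[tuple[str, LocalizationResult]],
                   out_dir: str,
                   metric_set: Optional[MetricSet] = None) -> dict:
    """Write per-channel probabilities (CSV) and a JSON summary.

    ``results`` is a list of (patient_id, LocalizationResult).  The CSV
    has one row per (patient, channel); the summary holds per-patient
    localization accuracy and their mean.  Returns the summary dict.
    """
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    per_patient: dict[str, list[bool]] = {}
    for patient, res in results:
        for ch, p in res.probabilities.items():
            rows.append({"patient": patient, "channel": ch,
                         "probability": p,
                         "predicted_flag": int(ch == res.predicted_channel),
                         "true_flag": int(ch == res.true_channel)})
        if res.correct is not None:
            per_patient.setdefault(patient, []).append(res.correct)
    frame = pd.DataFrame(rows, columns=["patient", "channel", "probability",
                                        "predicted_flag", "true_flag"])
    frame.to_csv(os.path.join(out_dir, "channel_probabilities.csv"),
                 index=False)
    acc = {p: float(np.mean(v)) for p, v in sorted(per_patient.items())}
    summary = {
        "per_patient_accuracy": acc,
        "mean_accuracy": float(np.mean(list(acc.values()))) if acc else None,
        "n_recordings": len(results),
    }
    if metric_set is not None:
        summary["metrics"] = metric_set.as_dict()
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary
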