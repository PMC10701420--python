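"""Shared fixtures: the synthetic study conditions and trained models.

Heavy artefacts (the 20-epoch pre-trained model, the fine-tuned pair,
the zero-effect null model) are session-scoped so the classification,
transfer and localization tests all reuse one training run each.
"""

from __future__ import annotations

import numpy as np
import pytest

from focusloc import (LossWeights, SyntheticConfig, TrainConfig,
                      TrainingData, finetune, generate_dataset,
                      generate_multichannel_recording, preprocess_segments,
                      pretrain)

#: focus channel per patient in the 16-channel cohort (mirrors a
#: clinical table where each patient has their own focus electrode)
COHORT_FOCUS = [3, 2, 1, 12, 0, 6]


def make_split(cfg: SyntheticConfig, holdout_frac: float = 0.25,
               split_seed: int = 0):
    """Generate, preprocess and split a single-channel ensemble."""
    data = TrainingData.from_segments(
        preprocess_segments(generate_dataset(cfg)))
    rng = np.random.default_rng(split_seed)
    n = len(data)
    test = np.zeros(n, bool)
    test[rng.choice(n, int(n * holdout_frac), replace=False)] = True
    train = TrainingData(data.X[~test], data.y[~test], data.d[~test],
                         data.patients)
    held = TrainingData(data.X[test], data.y[test], data.d[test],
                        data.patients)
    return train, held


@pytest.fixture(scope="session")
def study_cfg() -> SyntheticConfig:
    """5 patients, 4 s segments at 256 Hz, 60 segments/class/patient,
    class effect 1.0 (doubled θ+α band power), style confound on."""
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def study_split(study_cfg):
    return make_split(study_cfg)


@pytest.fixture(scope="session")
def pretrained(study_split):
    """Reduced 20-epoch adversarial pre-training run."""
    train, _ = study_split
    return pretrain(train, TrainConfig(epochs=20, batch_size=100, seed=1),
                    LossWeights())


@pytest.fixture(scope="session")
def null_split():
    """Zero class effect: focal and non-focal identically distributed."""
    cfg = SyntheticConfig(class_effect=0.0, n_segments_per_class=30, seed=7)
    return make_split(cfg)


@pytest.fixture(scope="session")
def null_pretrained(null_split):
    train, _ = null_split
    return pretrain(train, TrainConfig(epochs=12, batch_size=100, seed=1),
                    LossWeights())


@pytest.fixture(scope="session")
def cohort16():
    """Six new patients with 16-channel recordings (1 focal : 15
    non-focal per recording): 10 fine-tuning and up to 4 held-out
    recordings per patient."""
    cfg = SyntheticConfig(n_patients=6, n_channels=16, seed=21,
                          focus_channel_index=COHORT_FOCUS)
    train_recs = [preprocess_segments(
        generate_multichannel_recording(cfg, p, recording_index=r))
        for p in range(cfg.n_patients) for r in range(10)]
    test_recs = [preprocess_segments(
        generate_multichannel_recording(cfg, p, recording_index=100 + r))
        for p in range(cfg.n_patients) for r in range(4)][:20]
    return cfg, train_recs, test_recs


@pytest.fixture(scope="session")
def finetuned_pair(pretrained, cohort16):
    """Weighted- and plain-CE fine-tunes from the same pre-trained
    model, same seed — the controlled comparison for the imbalance
    loss."""
    import copy
    _, train_recs, _ = cohort16
    data = TrainingData.from_segments([s for r in train_recs for s in r])
    cfg = TrainConfig(epochs=30, batch_size=100, seed=2)
    weighted = finetune(copy.deepcopy(pretrained), data, cfg, weighted=True)
    plain = finetune(copy.deepcopy(pretrained), data, cfg, weighted=False)
    return weighted, plain


@pytest.fixture()
def tiny_cfg():
    """Small, fast conditions for training-mechanics tests."""
    return SyntheticConfig(segment_seconds=1.0, n_segments_per_class=10,
                           seed=3)
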