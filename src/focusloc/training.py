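"""Losses and the two training phases.

Pre-training jointly optimises three objectives on multi-patient data:

* ``L_cls`` — cross-entropy of the category classifier on both the
  clean path and the style-randomized path,
* ``L_mse`` — mean squared difference between the classifier's output
  probabilities on the two paths (consistency under style removal),
* ``L_pd`` — cross-entropy of the patient discriminator.

The combined objective is ``L_sum = L_cls + λ1·L_mse − λ2·L_pd`` with
λ1 = λ2 = 0.01: the feature extractor and classifier minimise it while
the discriminator maximises it.  The minimax is realised with a single
Adam pass by routing the discriminator loss through a gradient
reversal layer — the discriminator head receives the plain gradient
(so it keeps getting better at identifying patients) while the feature
extractor receives the negated gradient (so it learns
patient-invariant features).

Fine-tuning freezes every parameter upstream of the category
classifier and retrains only the classifier with the class-weighted
cross-entropy ``L_weight = −Σ_c w_c y_c log p_c``, ``w_c = (N−N_c)/N``,
countering the one-focus-channel-in-sixteen imbalance of multi-channel
recordings.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .network import FocusNet, ModelConfig
from .nn import Adam
from .synthetic import CLASS_LABELS, LabeledSegment


@dataclass(frozen=True)
class LossWeights:
    """λ1 weighs the consistency (MSE) term, λ2 the adversarial term."""

    lambda1: float = 0.01
    lambda2: float = 0.01

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 100
    learning_rate: float = 5e-4
    clip_norm: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (SR permutes "
                             "statistics within the batch)")


@dataclass
class TrainingData:
    """Dense arrays ready for the network, plus label vocabularies."""

    X: np.ndarray              # (N, W) preprocessed segments
    y: np.ndarray              # (N,) 0 = non-focal, 1 = focal
    d: np.ndarray              # (N,) patient index into ``patients``
    patients: list[str]

    @classmethod
    def from_segments(cls, segments: Sequence[LabeledSegment],
                      patients: Optional[list[str]] = None
                      ) -> "TrainingData":
        widths = {len(s.samples) for s in segments}
        if len(widths) != 1:
            raise ValueError(f"segments have varying lengths {sorted(widths)}")
        if patients is None:
            patients = sorted({s.patient_id for s in segments})
        index = {p: i for i, p in enumerate(patients)}
        unknown = {s.patient_id for s in segments} - set(index)
        if unknown:
            raise ValueError(f"patients {sorted(unknown)} not in the "
                             "training vocabulary")
        X = np.stack([s.samples for s in segments])
        y = np.array([CLASS_LABELS.index(s.class_label) for s in segments])
        d = np.array([index[s.patient_id] for s in segments])
        return cls(X=X, y=y, d=d, patients=list(patients))

    def __len__(self):
        return len(self.X)

    @property
    def width(self) -> int:
        return self.X.shape[1]


@dataclass
class TrainState:
    """A trained (or in-training) model plus its provenance."""

    model: FocusNet
    patients: list[str]
    model_cfg: ModelConfig
    loss_weights: LossWeights
    train_cfg: TrainConfig
    history: list[dict] = field(default_factory=list)

    def save(self, path: str) -> None:
        """Serialise parameters + buffers + config to ``path`` (.npz)
        with a JSON sidecar of the configuration (format version 1)."""
        arrays = self.model.state_dict()
        meta = {
            "format_version": 1,
            "width": self.model.width,
            "patients": self.patients,
            "model_cfg": asdict(self.model_cfg),
            "loss_weights": asdict(self.loss_weights),
            "train_cfg": asdict(self.train_cfg),
            "history": self.history,
        }
        np.savez(path, **arrays)
        with open(_meta_path(path), "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "TrainState":
        with open(_meta_path(path)) as fh:
            meta = json.load(fh)
        if meta.get("format_version") != 1:
            raise ValueError("unsupported checkpoint format")
        mc = dict(meta["model_cfg"])
        mc["classifier_hidden"] = tuple(mc["classifier_hidden"])
        model_cfg = ModelConfig(**mc)
        model = FocusNet(np.random.default_rng(0), width=meta["width"],
                         n_patients=len(meta["patients"]), cfg=model_cfg)
        with np.load(path if path.endswith(".npz") else path + ".npz") as z:
            model.load_state_dict({k: z[k] for k in z.files})
        return cls(model=model, patients=list(meta["patients"]),
                   model_cfg=model_cfg,
                   loss_weights=LossWeights(**meta["loss_weights"]),
                   train_cfg=TrainConfig(**meta["train_cfg"]),
                   history=list(meta["history"]))


def _meta_path(path: str) -> str:
    base = path[:-4] if path.endswith(".npz") else path
    return base + ".json"


# ----------------------------------------------------------------------
# losses
def _batch_losses(model: FocusNet, X: np.ndarray, y: np.ndarray,
                  d: np.ndarray, perm: np.ndarray,
                  use_discriminator: bool = True):
    """One shared forward of the clean and SR paths; returns the three
    component losses as graph nodes."""
    xt = Tensor(X)
    eb = model.embedding(xt)
    eb_sr = model.sr(eb, rng=None, perm=perm)
    f_clean = model.extractor(eb)
    f_sr = model.extractor(eb_sr)
    logits_clean = model.classifier(f_clean)
    logits_sr = model.classifier(f_sr)
    l_cls = (ad.cross_entropy_logits(logits_clean, y)
             + ad.cross_entropy_logits(logits_sr, y))
    diff = ad.softmax(logits_clean) - ad.softmax(logits_sr)
    l_mse = (diff * diff).sum() * (1.0 / len(y))
    if use_discriminator:
        d_logits = model.discriminator(f_clean)  # clean path feeds G_pd
        l_pd = ad.cross_entropy_logits(d_logits, d)
    else:
        l_pd = Tensor(0.0)
    return l_cls, l_mse, l_pd


def loss_cls(model: FocusNet, X: np.ndarray, y: np.ndarray,
             perm: np.ndarray) -> Tensor:
    """Eq-style classification loss: CE on the clean path plus CE on
    the style-randomized path, averaged over the batch."""
    l_cls, _, _ = _batch_losses(model, X, y, np.zeros(len(y), int), perm,
                                use_discriminator=False)
    return l_cls

def loss_mse(model: FocusNet, X: np.ndarray, perm: np.ndarray) -> Tensor:
    """Consistency loss: batch-mean squared difference between the
    classifier's probability outputs on the clean and SR paths."""
    y0 = np.zeros(len(X), int)
    _, l_mse, _ = _batch_losses(model, X, y0, y0, perm,
                                use_discriminator=False)
    return l_mse


def loss_pd(model: FocusNet, X: np.ndarray, d: np.ndarray,
            reverse: bool = False) -> Tensor:
    """Patient-discrimination loss: mean CE of G_pd(G_f(x)) against the
    patient labels.  Warns when the batch holds a single patient (the
    adversarial term is then inert)."""
    d = np.asarray(d)
    if d.max(initial=0) >= model.discriminator.n_patients:
        raise ValueError("patient label outside the training vocabulary")
    if len(np.unique(d)) < 2:
        warnings.warn("single-patient data: the adversarial term is inert",
                      stacklevel=2)
    f = model.extractor(model.embedding(Tensor(X)))
    logits = model.discriminator(f, reverse=reverse)
    return ad.cross_entropy_logits(logits, d)


def evaluate_losses(model: FocusNet, X: np.ndarray, y: np.ndarray,
                    d: np.ndarray, perm: np.ndarray,
                    weights: LossWeights = LossWeights()) -> dict:
    """Component losses and their combination on one batch.

    ``L_sum = L_cls + λ1·L_mse − λ2·L_pd`` is the reporting convention
    (the discriminator maximises it); ``objective`` is the quantity the
    single Adam pass descends, where the sign flip on the adversarial
    term is realised by the gradient reversal layer instead.
    """
    l_cls, l_mse, l_pd = _batch_losses(model, X, y, d, perm)
    return {
        "L_cls": l_cls.item(), "L_mse": l_mse.item(), "L_pd": l_pd.item(),
        "L_sum": (l_cls.item() + weights.lambda1 * l_mse.item()
                  - weights.lambda2 * l_pd.item()),
        "objective": (l_cls.item() + weights.lambda1 * l_mse.item()
                      + weights.lambda2 * l_pd.item()),
    }


def class_weights(counts: Sequence[int]) -> np.ndarray:
    """Imbalance weights w_c = (N - N_c) / N from per-class counts."""
    counts = np.asarray(counts, dtype=np.float64)
    if np.any(counts < 1):
        raise ValueError("every class needs at least one sample")
    n = counts.sum()
    return (n - counts) / n


def weighted_ce(probs: np.ndarray, labels: np.ndarray,
                weights: np.ndarray) -> float:
    """Class-weighted cross-entropy on probabilities:
    mean over the batch of ``-w_y log p_y``."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.intp)
    weights = np.asarray(weights, dtype=np.float64)
    p_true = probs[np.arange(len(labels)), labels]
    if np.any(p_true <= 0):
        warnings.warn("zero probability on a true class; clamping at 1e-12",
                      stacklevel=2)
        p_true = np.maximum(p_true, 1e-12)
    return float(np.mean(-weights[labels] * np.log(p_true)))


# ----------------------------------------------------------------------
# training phases
def pretrain(data: TrainingData, train_cfg: TrainConfig = TrainConfig(),
             loss_weights: LossWeights = LossWeights(),
             model_cfg: ModelConfig = ModelConfig(),
             model: Optional[FocusNet] = None) -> TrainState:
    """Joint adversarial pre-training on multi-patient data.

    A single Adam optimiser (lr from ``train_cfg``) descends
    ``L_cls + λ1·L_mse + λ2·CE_pd`` where the discriminator CE reaches
    the feature extractor through the gradient reversal layer — which
    realises the minimax: (θ_f, θ_c) minimise L_sum while θ_pd
    maximises it.  Returns the final state with a per-epoch history of
    L_cls, L_mse, L_pd and L_sum.
    """
    if len(np.unique(data.y)) < 2:
        raise ValueError("pre-training needs both classes present")
    rng = np.random.default_rng(train_cfg.seed)
    if model is None:
        model = FocusNet(rng, width=data.width,
                         n_patients=len(data.patients), cfg=model_cfg)
    model.train()
    opt = Adam(model.parameters(), lr=train_cfg.learning_rate,
               clip_norm=train_cfg.clip_norm)
    l1, l2 = loss_weights.lambda1, loss_weights.lambda2
    state = TrainState(model=model, patients=data.patients,
                       model_cfg=model_cfg, loss_weights=loss_weights,
                       train_cfg=train_cfg)
    n = len(data)
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        sums = np.zeros(4)
        n_batches = 0
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start: start + train_cfg.batch_size]
            if len(idx) < 2:
                continue  # SR needs at least two samples to permute
            perm = rng.permutation(len(idx))
            l_cls, l_mse, l_pd = _batch_losses(
                model, data.X[idx], data.y[idx], data.d[idx], perm)
            objective = l_cls + l1 * l_mse + l2 * l_pd
            if not np.isfinite(objective.item()):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: "
                    f"L_cls={l_cls.item():.4g} L_mse={l_mse.item():.4g} "
                    f"L_pd={l_pd.item():.4g}")
            opt.zero_grad()
            objective.backward()
            opt.step()
            l_sum = l_cls.item() + l1 * l_mse.item() - l2 * l_pd.item()
            sums += (l_cls.item(), l_mse.item(), l_pd.item(), l_sum)
            n_batches += 1
        avg = sums / max(n_batches, 1)
        state.history.append({"phase": "pretrain", "epoch": epoch,
                              "L_cls": avg[0], "L_mse": avg[1],
                              "L_pd": avg[2], "L_sum": avg[3]})
    return state


def finetune(state: TrainState, data: TrainingData,
             train_cfg: Optional[TrainConfig] = None,
             weighted: bool = True) -> TrainState:
    """Frozen-extractor fine-tuning of the category classifier.

    Everything upstream of the classifier (embedding block, feature
    extractor, SE attention) is frozen bit-for-bit; SR and the
    discriminator are inactive; batch norm uses its running moments.
    The loss is the class-weighted cross-entropy (``weighted=False``
    switches to plain CE, for controlled comparisons).
    Returns a new TrainState sharing θ_f with the input.
    """
    if train_cfg is None:
        train_cfg = state.train_cfg
    if len(np.unique(data.y)) < 2:
        raise ValueError("fine-tuning data must contain both classes")
    model = state.model
    model.eval()  # frozen extractor: BN running stats, SR off
    counts = np.bincount(data.y, minlength=2)
    w = class_weights(counts) if weighted else None
    rng = np.random.default_rng(train_cfg.seed)
    opt = Adam(model.classifier_parameters(), lr=train_cfg.learning_rate,
               clip_norm=train_cfg.clip_norm)
    new_state = TrainState(model=model, patients=state.patients,
                           model_cfg=state.model_cfg,
                           loss_weights=state.loss_weights,
                           train_cfg=train_cfg,
                           history=list(state.history))
    n = len(data)
    # the extractor is frozen, so features are fixed: compute them once
    feats_all = []
    with ad.no_grad():
        for start in range(0, n, train_cfg.batch_size):
            xt = Tensor(data.X[start: start + train_cfg.batch_size])
            feats_all.append(model.extractor(model.embedding(xt)).data)
    feats_all = np.concatenate(feats_all, axis=0)
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        total, n_batches = 0.0, 0
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start: start + train_cfg.batch_size]
            if len(idx) == 0:
                continue
            logits = model.classifier(Tensor(feats_all[idx]))
            loss = ad.cross_entropy_logits(logits, data.y[idx],
                                           class_weights=w)
            if not np.isfinite(loss.item()):
                raise RuntimeError(f"fine-tuning diverged at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += loss.item()
            n_batches += 1
        new_state.history.append({"phase": "finetune", "epoch": epoch,
                                  "L_weight": total / max(n_batches, 1)})
    return new_state


def parameter_checksum(params: Sequence[Tensor]) -> float:
    """Order-dependent checksum of a parameter group, for freeze checks."""
    total = 0.0
    for i, p in enumerate(params, start=1):
        total += float(np.sum(p.data * np.cos(np.arange(p.data.size)
                                              .reshape(p.data.shape) + i)))
    return total
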