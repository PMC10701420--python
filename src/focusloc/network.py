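"""The feature path and heads of the focus-classification network.

Architecture (single-channel EEG segments, 256 Hz working rate):

1. **Embedding block** — two temporal convolutions with batch norm
   produce ``n_embed`` adaptive sub-band channels which are stacked
   with the raw signal, giving a sub-band tensor of C = 1 + n_embed
   channels (laid out N×C×1×W; the height axis is a formal spatial
   axis, EEG segments being one-dimensional).
2. **Style-feature randomization (SR)** — per-(sample, sub-band) mean
   μ and standard deviation σ are computed over the spatial axes and
   randomly reassigned within the training batch; each sub-band is
   then normalised with the reassigned moments.  This strips
   patient-specific amplitude/scale style while preserving waveform
   shape, and is active only during pre-training.
3. **Spectral branch** — cascaded Daubechies-4 conv-DWT yielding one
   coefficient map per physiological band (δ … high-γ).
4. **Temporal branch** — six conv → BN → ELU branches with kernel
   sizes {k, k, k/2, k/4, k/8, k/16}, k = 64, spanning coarse-to-fine
   receptive fields.
5. **Fusion** — band-matched concatenation: [f_δ‖f_t1] … [f_high-γ‖f_t6].
6. **Squeeze-and-excitation** — per-level channel gating, then
   flattening into the feature vector consumed by the heads.

Heads: a 3-layer fully connected category classifier (focal vs
non-focal) and a patient discriminator behind a gradient reversal
layer for adversarial patient-invariance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import BatchNorm1d, Conv1d, Linear, Module
from .wavelets import WaveletFilterPair, daubechies4, multilevel_spectral

#: temporal-branch kernel sizes {k, k, k/2, k/4, k/8, k/16} for k = 2^6,
#: ordered to pair with the bands δ, θ, α, β, γ, high-γ
TEMPORAL_KERNELS = (64, 64, 32, 16, 8, 4)
#: matching strides so each branch's output length tracks the paired
#: dyadic band map (W/32 ... W/2)
TEMPORAL_STRIDES = (32, 32, 16, 8, 4, 2)


# ----------------------------------------------------------------------
# sub-band statistics and style randomization
@dataclass
class SubBandStats:
    """Per-(sample, sub-band) spatial moments; σ includes the ε floor."""

    mu: object      # (N, C) array or Tensor
    sigma: object   # (N, C) array or Tensor
    eps: float


def subband_stats(x, eps: float = 1e-5) -> SubBandStats:
    """Spatial mean and ε-floored standard deviation per (n, c).

    ``x`` is (N, C, W) or (N, C, H, W); moments are taken over all
    spatial axes, independently per sample and sub-band channel:
    μ_nc = mean(x_nc), σ_nc = sqrt(var(x_nc) + ε) ≥ sqrt(ε).
    """
    axes = tuple(range(2, x.ndim))
    if isinstance(x, Tensor):
        mu = x.mean(axis=axes, keepdims=False)
        centred = x - x.mean(axis=axes, keepdims=True)
        var = (centred * centred).mean(axis=axes, keepdims=False)
        sigma = (var + eps) ** 0.5
    else:
        x = np.asarray(x, dtype=np.float64)
        mu = x.mean(axis=axes)
        sigma = np.sqrt(x.var(axis=axes) + eps)
    return SubBandStats(mu=mu, sigma=sigma, eps=eps)


def _check_perm(perm: np.ndarray, n: int) -> np.ndarray:
    perm = np.asarray(perm, dtype=np.intp)
    if perm.shape != (n,) or not np.array_equal(np.sort(perm), np.arange(n)):
        raise ValueError(f"perm is not a permutation of {n} batch indices")
    return perm


def style_randomize(x, stats: SubBandStats, perm: Sequence[int],
                    mix_weight: Optional[np.ndarray] = None):
    """Normalise each sub-band with moments drawn from another sample.

    ``x'[n, c] = (x[n, c] - μ[perm(n), c]) / σ[perm(n), c]``.  With the
    identity permutation this is plain per-sub-band standardisation.
    If ``mix_weight`` (per-sample in [0, 1]) is given, the assigned
    moments are the convex mix ``λ·own + (1-λ)·permuted`` (MixStyle-like
    variant).
    """
    n = x.shape[0]
    perm = _check_perm(perm, n)
    mu, sigma = stats.mu, stats.sigma
    tensor = isinstance(x, Tensor)
    mu_p = mu[perm]
    sig_p = sigma[perm]
    if mix_weight is not None:
        lam = np.asarray(mix_weight, dtype=np.float64).reshape(n, 1)
        lam_t = Tensor(lam) if tensor else lam
        mu_p = lam_t * mu + (1.0 - lam_t) * mu_p
        sig_p = lam_t * sigma + (1.0 - lam_t) * sig_p
    extra = (1,) * (x.ndim - 2)
    shape = (n,) + (x.shape[1],) + extra
    mu_b = mu_p.reshape(shape)
    sig_b = sig_p.reshape(shape)
    return (x - mu_b) / sig_b


class StyleRandomization(Module):
    """SR as a network stage: draws a fresh batch permutation per call."""

    def __init__(self, eps: float = 1e-5, mode: str = "permute"):
        super().__init__()
        if mode not in ("permute", "mix"):
            raise ValueError("sr mode must be 'permute' or 'mix'")
        self.eps = eps
        self.mode = mode

    def forward(self, x, rng: np.random.Generator,
                perm: Optional[np.ndarray] = None):
        n = x.shape[0]
        if perm is None:
            perm = rng.permutation(n)
        stats = subband_stats(x, self.eps)
        mix = rng.uniform(size=n) if self.mode == "mix" else None
        return style_randomize(x, stats, perm, mix_weight=mix)


# ----------------------------------------------------------------------
# network stages
class EmbeddingBlock(Module):
    """Two temporal conv+BN stages; output stacked with the raw signal.

    Input (N, W) or (N, 1, W); output (N, 1 + n_embed, 1, W) with the
    raw signal unchanged as channel 0.
    """

    def __init__(self, rng: np.random.Generator, n_embed: int = 7,
                 kernel: int = 64, use_bn: bool = True):
        super().__init__()
        self.n_embed = n_embed
        pad = ((kernel - 1) // 2 + (kernel - 1) % 2, (kernel - 1) // 2)
        self.conv1 = Conv1d(1, n_embed, kernel, rng, padding=pad)
        self.conv2 = Conv1d(n_embed, n_embed, kernel, rng, padding=pad)
        self.use_bn = use_bn
        if use_bn:
            self.bn1 = BatchNorm1d(n_embed)
            self.bn2 = BatchNorm1d(n_embed)

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.ndim == 2:
            x = x.reshape((x.shape[0], 1, x.shape[1]))
        if x.ndim != 3 or x.shape[1] != 1:
            raise ValueError("embedding block expects (N, W) or (N, 1, W)")
        h = self.conv1(x)
        if self.use_bn:
            h = self.bn1(h)
        h = ad.elu(h)
        h = self.conv2(h)
        if self.use_bn:
            h = self.bn2(h)
        h = ad.elu(h)
        out = ad.concatenate([x, h], axis=1)  # raw as channel 0
        n, c, w = out.shape
        return out.reshape((n, c, 1, w))


class TemporalBranch(Module):
    """Six multi-scale conv → BN → ELU branches over the sub-band tensor."""

    def __init__(self, rng: np.random.Generator, n_ch: int, k: int = 64):
        super().__init__()
        if k != 64:
            # kernel set scales with k while keeping six branches
            kernels = (k, k, k // 2, k // 4, k // 8, k // 16)
        else:
            kernels = TEMPORAL_KERNELS
        self.kernels = kernels
        self.convs = [Conv1d(n_ch, n_ch, ks, rng, stride=st)
                      for ks, st in zip(kernels, TEMPORAL_STRIDES)]
        self.bns = [BatchNorm1d(n_ch) for _ in kernels]

    def forward(self, x) -> list:
        # x: (N, C, W) after squeezing the height axis
        if x.shape[-1] < max(self.kernels):
            raise ValueError(
                f"segment width {x.shape[-1]} shorter than the largest "
                f"temporal kernel {max(self.kernels)}")
        maps = []
        for conv, bn in zip(self.convs, self.bns):
            maps.append(ad.elu(bn(conv(x))))
        return maps


@dataclass
class FeatureBundle:
    """Six temporal maps, six spectral maps, and their fusion."""

    temporal: list
    spectral: list
    fused: list


def fuse_features(temporal: list, spectral: list) -> FeatureBundle:
    """Band-matched concatenation along the feature (width) axis:
    fused[j] = [spectral_j ‖ temporal_j] for the pairs
    (δ,t1), (θ,t2), (α,t3), (β,t4), (γ,t5), (high-γ,t6)."""
    if len(temporal) != len(spectral):
        raise ValueError("need equally many temporal and spectral maps")
    fused = []
    for j, (sp, tm) in enumerate(zip(spectral, temporal)):
        if sp.shape[:-1] != tm.shape[:-1]:
            raise ValueError(
                f"fusion pair {j}: incompatible shapes "
                f"{sp.shape} vs {tm.shape}")
        if isinstance(sp, Tensor) or isinstance(tm, Tensor):
            fused.append(ad.concatenate(
                [sp if isinstance(sp, Tensor) else Tensor(sp),
                 tm if isinstance(tm, Tensor) else Tensor(tm)], axis=-1))
        else:
            fused.append(np.concatenate([sp, tm], axis=-1))
    return FeatureBundle(temporal=list(temporal), spectral=list(spectral),
                         fused=fused)


class SEAttention(Module):
    """Per-level squeeze-and-excitation gating, then flattening.

    For each fused level: global average over the feature axis →
    two-layer bottleneck (reduction ratio r) → sigmoid gates in [0, 1]
    → channel-wise rescale.  The gated levels are flattened and
    concatenated into the final feature vector.
    """

    def __init__(self, rng: np.random.Generator, n_ch: int,
                 n_levels: int = 6, reduction: int = 8,
                 gate_bias_init: float = 0.0, pooling: str = "flatten"):
        super().__init__()
        if n_ch % reduction != 0:
            raise ValueError(
                f"reduction {reduction} must divide channel width {n_ch}")
        if pooling not in ("flatten", "moments"):
            raise ValueError("pooling must be 'flatten' or 'moments'")
        self.pooling = pooling
        hidden = max(n_ch // reduction, 1)
        self.fc1 = [Linear(n_ch, hidden, rng) for _ in range(n_levels)]
        self.fc2 = [Linear(hidden, n_ch, rng) for _ in range(n_levels)]
        for fc in self.fc2:
            fc.bias.data[...] = gate_bias_init

    def gates(self, fused: list) -> list:
        out = []
        for j, f in enumerate(fused):
            s = f.mean(axis=-1)  # (N, C)
            z = self.fc2[j](ad.elu(self.fc1[j](s)))
            out.append(ad.sigmoid(z))
        return out

    def forward(self, bundle: FeatureBundle) -> Tensor:
        pieces = []
        for f, g in zip(bundle.fused, self.gates(bundle.fused)):
            n, c = f.shape[0], f.shape[1]
            gated = f * g.reshape((n, c, 1))
            if self.pooling == "flatten":
                pieces.append(gated.reshape((n, c * gated.shape[-1])))
            else:
                # phase-robust per-(channel, level) summary: the mean
                # reads the (signed) temporal activations, the RMS the
                # wavelet-coefficient energy.  Raw coefficients have
                # sample-specific phase, so flattening them invites
                # memorisation at small sample sizes.
                mean = gated.mean(axis=-1)
                rms = ((gated * gated).mean(axis=-1) + 1e-12) ** 0.5
                pieces.extend([mean, rms])
        return ad.concatenate(pieces, axis=-1)


class FeatureExtractor(Module):
    """G_f: spectral + temporal branches, fusion, SE attention."""

    def __init__(self, rng: np.random.Generator, n_ch: int, k: int = 64,
                 wavelet: Optional[WaveletFilterPair] = None,
                 n_bands: int = 6, se_reduction: int = 8,
                 pooling: str = "moments"):
        super().__init__()
        self.wavelet = wavelet or daubechies4()
        self.n_bands = n_bands
        self.temporal = TemporalBranch(rng, n_ch, k=k)
        self.se = SEAttention(rng, n_ch, n_levels=n_bands,
                              reduction=se_reduction, pooling=pooling)

    def forward(self, x) -> Tensor:
        # accept (N, C, 1, W) sub-band tensors or (N, C, W)
        if x.ndim == 4:
            n, c, h, w = x.shape
            x = x.reshape((n, c * h, w))
        spectral = multilevel_spectral(x, self.wavelet, n_bands=self.n_bands)
        temporal = self.temporal(x)
        bundle = fuse_features(temporal, spectral)
        return self.se(bundle)


class Classifier(Module):
    """G_c: 3-layer fully connected category classifier → 2 logits."""

    def __init__(self, rng: np.random.Generator, n_features: int,
                 hidden=(128, 64), n_classes: int = 2):
        super().__init__()
        self.fc1 = Linear(n_features, hidden[0], rng)
        self.fc2 = Linear(hidden[0], hidden[1], rng)
        self.fc3 = Linear(hidden[1], n_classes, rng)

    def forward(self, f: Tensor) -> Tensor:
        return self.fc3(ad.elu(self.fc2(ad.elu(self.fc1(f)))))


class PatientDiscriminator(Module):
    """G_pd: adversarial patient-identity head behind a GRL."""

    def __init__(self, rng: np.random.Generator, n_features: int,
                 n_patients: int, hidden: int = 128,
                 grl_lambda: float = 1.0):
        super().__init__()
        self.grl_lambda = grl_lambda
        self.n_patients = n_patients
        self.fc1 = Linear(n_features, hidden, rng)
        self.fc2 = Linear(hidden, n_patients, rng)

    def forward(self, f: Tensor, reverse: bool = True) -> Tensor:
        if reverse:
            f = ad.grad_reverse(f, self.grl_lambda)
        return self.fc2(ad.elu(self.fc1(f)))


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters of the full network."""

    n_embed: int = 7
    embed_kernel: int = 64
    k: int = 64
    sr_eps: float = 1e-5
    sr_mode: str = "permute"
    se_reduction: int = 8
    #: classifier input: 'moments' pools each gated map to per-channel
    #: mean and RMS; 'flatten' keeps every gated coefficient
    pooling: str = "moments"
    n_bands: int = 6
    grl_lambda: float = 1.0
    classifier_hidden: tuple = (128, 64)

    @property
    def n_ch(self) -> int:
        return 1 + self.n_embed


def feature_dim(width: int, cfg: ModelConfig) -> int:
    """Length of the feature vector produced for input width ``width``."""
    if cfg.pooling == "moments":
        return cfg.n_ch * 2 * cfg.n_bands
    spec_lens = []
    w = width
    for _ in range(cfg.n_bands - 1):
        w = w // 2
        spec_lens.append(w)
    spec_lens = [w] + spec_lens[::-1]
    kernels = (cfg.k, cfg.k, cfg.k // 2, cfg.k // 4, cfg.k // 8, cfg.k // 16)
    temp_lens = [(width - ks) // st + 1
                 for ks, st in zip(kernels, TEMPORAL_STRIDES)]
    return cfg.n_ch * sum(s + t for s, t in zip(spec_lens, temp_lens))


class FocusNet(Module):
    """The complete pre-training network: EB, SR, G_f, G_c, G_pd."""

    def __init__(self, rng: np.random.Generator, width: int,
                 n_patients: int, cfg: ModelConfig = ModelConfig()):
        super().__init__()
        self.cfg = cfg
        self.width = width
        self.embedding = EmbeddingBlock(rng, n_embed=cfg.n_embed,
                                        kernel=cfg.embed_kernel)
        self.sr = StyleRandomization(eps=cfg.sr_eps, mode=cfg.sr_mode)
        self.extractor = FeatureExtractor(rng, cfg.n_ch, k=cfg.k,
                                          n_bands=cfg.n_bands,
                                          se_reduction=cfg.se_reduction,
                                          pooling=cfg.pooling)
        nf = feature_dim(width, cfg)
        self.classifier = Classifier(rng, nf, hidden=cfg.classifier_hidden)
        self.discriminator = PatientDiscriminator(
            rng, nf, n_patients, grl_lambda=cfg.grl_lambda)

    # parameter groups -------------------------------------------------
    def feature_parameters(self) -> list[Tensor]:
        """θ_f: embedding block + feature extractor (incl. SE)."""
        return self.embedding.parameters() + self.extractor.parameters()

    def classifier_parameters(self) -> list[Tensor]:
        return self.classifier.parameters()

    def discriminator_parameters(self) -> list[Tensor]:
        return self.discriminator.parameters()

    # forward paths ----------------------------------------------------
    def features(self, x, rng: Optional[np.random.Generator] = None,
                 use_sr: bool = False,
                 perm: Optional[np.ndarray] = None) -> Tensor:
        eb = self.embedding(x)
        if use_sr:
            if rng is None and perm is None:
                raise ValueError("SR path needs an rng or explicit perm")
            eb = self.sr(eb, rng=rng, perm=perm)
        return self.extractor(eb)

    def logits(self, x, **kw) -> Tensor:
        return self.classifier(self.features(x, **kw))

    def predict_proba(self, x, batch_size: int = 128) -> np.ndarray:
        """Class probabilities (N, 2) in eval mode, no gradient tape."""
        was_training = self.training
        self.eval()
        try:
            with ad.no_grad():
                out = []
                for i in range(0, x.shape[0], batch_size):
                    logits = self.logits(Tensor(x[i: i + batch_size]))
                    out.append(ad.softmax(logits).data)
            return np.concatenate(out, axis=0)
        finally:
            self.train(was_training)
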