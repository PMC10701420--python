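"""Synthetic multi-patient, multi-channel EEG generator.

Real focal/non-focal EEG corpora are clinical and cannot be bundled,
so this module generates surrogate recordings carrying exactly the two
statistical structures the localization method exploits:

* a **class effect** — focal segments carry elevated power in a
  configurable band (θ+α, 4–16 Hz, by default), with the band-power
  ratio focal/non-focal equal to ``1 + class_effect`` in expectation;
* a **patient style** — a per-patient multiplicative amplitude scale
  and an additive spectral-tilt component, shared by every segment and
  channel of that patient.  This is the confound the adversarial
  patient discriminator is meant to remove.

Each segment is 1/f-shaped Gaussian noise plus one random-phase
sinusoid per physiological band.  The focal boost is applied to the
full band-limited content (oscillation and noise background alike) via
an FFT mask, so the band-power ratio is exact rather than approximate.

Everything is a pure function of the configuration and the seed:
segment ``i`` of patient ``p`` is reproducible in isolation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

FOCAL = "focal"
NON_FOCAL = "non-focal"
CLASS_LABELS = (NON_FOCAL, FOCAL)

#: 16-channel scalp montage used for multi-channel recordings.
DEFAULT_CHANNELS = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "C3", "C4",
    "T3", "T4", "P3", "P4", "O1", "O2", "Fz", "Cz",
)

_STYLE_TAG = 101        # spawn-key tags keeping rng substreams disjoint
_SEGMENT_TAG = 202
_RECORDING_TAG = 303


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic EEG ensemble."""

    n_patients: int = 5
    n_channels: int = 16
    #: focus channel per patient; an int applies to every patient, a
    #: sequence gives one index per patient, None cycles p % n_channels
    focus_channel_index: Union[int, Sequence[int], None] = None
    fs: float = 256.0
    segment_seconds: float = 4.0
    n_segments_per_class: int = 60
    #: relative sub-band power shift between classes (ratio - 1)
    class_effect: float = 1.0
    #: band carrying the focal signature, Hz
    focal_band: tuple = (4.0, 16.0)
    style_scale_range: tuple = (0.5, 2.0)
    style_shift_range: tuple = (-0.5, 0.5)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.class_effect < 0:
            raise ValueError("class_effect must be >= 0")
        for p in range(self.n_patients):
            idx = self.focus_channel(p)
            if not 0 <= idx < self.n_channels:
                raise ValueError(
                    f"focus channel {idx} out of range for "
                    f"{self.n_channels} channels")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.segment_seconds))

    def focus_channel(self, patient: int) -> int:
        if self.focus_channel_index is None:
            return patient % self.n_channels
        if isinstance(self.focus_channel_index, int):
            return self.focus_channel_index
        return int(self.focus_channel_index[patient])

    def channel_names(self) -> list[str]:
        base = list(DEFAULT_CHANNELS)
        if self.n_channels <= len(base):
            return base[: self.n_channels]
        return base + [f"X{i}" for i in range(len(base), self.n_channels)]


@dataclass
class LabeledSegment:
    """One channel's samples with its provenance labels."""

    samples: np.ndarray
    fs: float
    patient_id: str
    channel_name: str
    class_label: str

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.class_label not in CLASS_LABELS:
            raise ValueError(
                f"class_label must be one of {CLASS_LABELS}, "
                f"got {self.class_label!r}")
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")


def _patient_style(cfg: SyntheticConfig, patient: int):
    """Patient-level style draws: amplitude scale, spectral tilt, and
    the patient's characteristic rhythm frequency per band (real EEG
    rhythms sit at stable individual peak frequencies, e.g. the
    individual alpha frequency, rather than wandering over the band)."""
    rng = np.random.default_rng(
        np.random.SeedSequence(cfg.seed, spawn_key=(_STYLE_TAG, patient)))
    scale = rng.uniform(*cfg.style_scale_range)
    tilt = rng.uniform(*cfg.style_shift_range)
    band_freqs = []
    for lo, hi in _BANDS_HZ:
        width = hi - lo
        band_freqs.append(rng.uniform(lo + 0.2 * width, hi - 0.2 * width))
    return scale, tilt, band_freqs


# relative sinusoid amplitudes per band, lowest first; roughly mimics
# the decreasing-power-with-frequency shape of resting EEG
_BAND_AMP = (1.0, 0.9, 0.8, 0.5, 0.3, 0.15)
_BANDS_HZ = ((0.5, 4.0), (4.0, 8.0), (8.0, 16.0),
             (16.0, 32.0), (32.0, 64.0), (64.0, 128.0))


def _base_signal(cfg: SyntheticConfig, rng: np.random.Generator,
                 band_freqs: Sequence[float]) -> np.ndarray:
    n = cfg.n_samples
    freqs = np.fft.rfftfreq(n, d=1.0 / cfg.fs)
    # 1/f-shaped background: white noise spectrally weighted by f^-1/2
    spec = np.fft.rfft(rng.standard_normal(n))
    weight = np.zeros_like(freqs)
    nz = freqs > 0
    weight[nz] = freqs[nz] ** -0.5
    noise = np.fft.irfft(spec * weight, n=n)
    sd = noise.std()
    if sd > 0:
        noise *= cfg.noise_sd / sd
    t = np.arange(n) / cfg.fs
    x = noise
    nyq = cfg.fs / 2.0
    for (lo, hi), amp, f0 in zip(_BANDS_HZ, _BAND_AMP, band_freqs):
        if lo >= nyq:
            continue
        # small per-segment jitter around the patient's peak frequency,
        # mild amplitude variability, random phase
        f = min(f0 * rng.uniform(0.98, 1.02), 0.98 * nyq)
        a = amp * cfg.noise_sd * rng.uniform(0.9, 1.1)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        x = x + a * np.sin(2.0 * np.pi * f * t + phase)
    return x


def _boost_band(x: np.ndarray, fs: float, band: tuple,
                gain_power: float) -> np.ndarray:
    """Scale the power of ``band`` by ``gain_power`` via an FFT mask."""
    n = len(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = np.fft.rfft(x)
    mask = (freqs >= band[0]) & (freqs < band[1])
    in_band = np.fft.irfft(spec * mask, n=n)
    return (x - in_band) + np.sqrt(gain_power) * in_band


def _apply_style(x: np.ndarray, scale: float, tilt: float) -> np.ndarray:
    # tilt adds a first-difference (high-frequency-emphasised) component,
    # shifting the spectral slope; both classes of a patient get the
    # same linear colouring, so within-patient class contrasts survive
    diff = np.diff(x, prepend=x[:1])
    return scale * (x + tilt * diff)


def generate_segment(cfg: SyntheticConfig, patient: int, klass: str,
                     segment_index: int = 0,
                     rng: Optional[np.random.Generator] = None) -> LabeledSegment:
    """Generate one labelled single-channel segment.

    Deterministic given ``(cfg.seed, patient, klass, segment_index)``
    unless an explicit ``rng`` is supplied.
    """
    if klass not in CLASS_LABELS:
        raise ValueError(
            f"invalid class label {klass!r}; expected one of {CLASS_LABELS}")
    if not 0 <= patient < cfg.n_patients:
        raise ValueError(f"patient index {patient} out of range")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(
            cfg.seed,
            spawn_key=(_SEGMENT_TAG, patient,
                       CLASS_LABELS.index(klass), segment_index)))
    scale, tilt, band_freqs = _patient_style(cfg, patient)
    x = _base_signal(cfg, rng, band_freqs)
    if klass == FOCAL and cfg.class_effect > 0:
        x = _boost_band(x, cfg.fs, cfg.focal_band, 1.0 + cfg.class_effect)
    x = _apply_style(x, scale, tilt)
    return LabeledSegment(samples=x, fs=cfg.fs,
                          patient_id=f"P{patient:02d}",
                          channel_name="ch0", class_label=klass)


def generate_multichannel_recording(cfg: SyntheticConfig, patient: int,
                                    recording_index: int = 0,
                                    rng: Optional[np.random.Generator] = None
                                    ) -> list[LabeledSegment]:
    """One recording: ``n_channels`` segments, exactly one focal.

    The focal signature sits on ``cfg.focus_channel(patient)``; every
    channel shares the patient's style.
    """
    if not 0 <= patient < cfg.n_patients:
        raise ValueError(f"patient index {patient} out of range")
    focus = cfg.focus_channel(patient)
    names = cfg.channel_names()
    segments = []
    for ch in range(cfg.n_channels):
        ch_rng = rng
        if ch_rng is None:
            ch_rng = np.random.default_rng(np.random.SeedSequence(
                cfg.seed,
                spawn_key=(_RECORDING_TAG, patient, recording_index, ch)))
        klass = FOCAL if ch == focus else NON_FOCAL
        seg = generate_segment(cfg, patient, klass,
                               segment_index=recording_index, rng=ch_rng)
        seg.channel_name = names[ch]
        segments.append(seg)
    return segments


def generate_dataset(cfg: SyntheticConfig) -> list[LabeledSegment]:
    """Balanced single-channel ensemble: every patient contributes
    ``n_segments_per_class`` focal and as many non-focal segments."""
    out = []
    for p in range(cfg.n_patients):
        for klass in CLASS_LABELS:
            for i in range(cfg.n_segments_per_class):
                out.append(generate_segment(cfg, p, klass, segment_index=i))
    return out


def write_manifest(segments: Sequence[LabeledSegment], out_dir: str,
                   manifest_name: str = "manifest.csv") -> str:
    """Store segments as one-value-per-line text files plus a CSV manifest.

    Manifest columns: ``file, patient_id, channel_name, class_label, fs``.
    Returns the manifest path.  An empty segment list yields a valid
    manifest with a header and no rows.
    """
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i, seg in enumerate(segments):
        fname = f"seg_{i:05d}.txt"
        np.savetxt(os.path.join(out_dir, fname), seg.samples, fmt="%.8e")
        rows.append({"file": fname, "patient_id": seg.patient_id,
                     "channel_name": seg.channel_name,
                     "class_label": seg.class_label, "fs": seg.fs})
    manifest = pd.DataFrame(
        rows, columns=["file", "patient_id", "channel_name",
                       "class_label", "fs"])
    path = os.path.join(out_dir, manifest_name)
    manifest.to_csv(path, index=False)
    return path
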