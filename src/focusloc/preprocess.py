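"""Reading, filtering and windowing of EEG segment files.

Covers the standard front end of the pipeline: plain-text segment
files indexed by a CSV manifest, zero-phase Butterworth band-pass
filtering, per-segment z-scoring, resampling to the 256 Hz working
rate, and the 90 %-overlap window expansion used to enlarge the
fine-tuning sample.

The working rate matters: the spectral branch maps dyadic DWT levels
onto the physiological bands (δ up to high-γ at 128 Hz), which line up
exactly only at fs = 256 Hz, so 512 Hz material is decimated and
173.61 Hz material upsampled before entering the network.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from scipy import signal

from .synthetic import LabeledSegment

#: dyadic working rate for the spectral branch
TARGET_FS = 256.0


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass design parameters."""

    order: int = 4
    low_hz: float = 0.5
    high_hz: float = 150.0
    fs: float = 512.0

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")
        if self.high_hz >= self.fs / 2:
            raise ValueError(
                f"high cutoff {self.high_hz} Hz violates the Nyquist "
                f"limit {self.fs / 2} Hz")

    def sos(self) -> np.ndarray:
        return signal.butter(self.order, [self.low_hz, self.high_hz],
                             btype="bandpass", fs=self.fs, output="sos")


def read_segment(path: str, fs: float | None = None) -> np.ndarray:
    """Read a plain-text segment: one value per line or delimited rows.

    Returns the samples in file order as a float vector.  Non-numeric
    content raises with the offending 1-based line number.
    """
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip().replace(",", " ")
            if not line:
                continue
            for tok in line.split():
                try:
                    values.append(float(tok))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric value {tok!r} at line "
                        f"{lineno}") from None
    if not values:
        raise ValueError(f"{path}: file contains no samples")
    arr = np.asarray(values, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{path}: non-finite sample values")
    return arr


def bandpass(x: np.ndarray, spec: FilterSpec,
             zero_phase: bool = True) -> np.ndarray:
    """Band-pass filter a segment with the given Butterworth design.

    Zero-phase (forward-backward) by default, which leaves waveform
    morphology undistorted; set ``zero_phase=False`` for a causal
    single pass.
    """
    x = np.asarray(x, dtype=np.float64)
    if len(x) <= 3 * spec.order:
        raise ValueError(
            f"segment of {len(x)} samples too short for order "
            f"{spec.order} filtering")
    sos = spec.sos()
    if zero_phase:
        return signal.sosfiltfilt(sos, x)
    return signal.sosfilt(sos, x)


def zscore(x: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Per-segment standardisation to zero mean, unit variance."""
    x = np.asarray(x, dtype=np.float64)
    return (x - x.mean()) / (x.std() + eps)


def resample_to(x: np.ndarray, fs_in: float,
                fs_out: float = TARGET_FS) -> np.ndarray:
    """Polyphase resampling to ``fs_out`` (rational approximation of
    the rate ratio; exact for 512 → 256)."""
    if fs_in == fs_out:
        return np.asarray(x, dtype=np.float64)
    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    return signal.resample_poly(np.asarray(x, dtype=np.float64),
                                frac.numerator, frac.denominator)


def expand_overlap(x: np.ndarray, fs: float, window_s: float,
                   overlap_frac: float = 0.9) -> list[np.ndarray]:
    """Slice a record into overlapping windows.

    Windows have ``round(window_s * fs)`` samples and start every
    ``round(window_s * (1 - overlap_frac) * fs)`` samples; the count is
    ``floor((L - W) / stride) + 1``.  Used with a 20 s window and 90 %
    overlap to expand scarce fine-tuning records.
    """
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must lie in [0, 1)")
    x = np.asarray(x, dtype=np.float64)
    w = int(round(window_s * fs))
    stride = int(round(window_s * (1 - overlap_frac) * fs))
    stride = max(stride, 1)
    if len(x) < w:
        raise ValueError(
            f"record of {len(x)} samples shorter than one "
            f"{w}-sample window")
    count = (len(x) - w) // stride + 1
    return [x[i * stride: i * stride + w] for i in range(count)]


class DatasetManifest:
    """A table of segment files with patient/channel/class labels."""

    COLUMNS = ["file", "patient_id", "channel_name", "class_label", "fs"]

    def __init__(self, table: pd.DataFrame, root: str = "."):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"manifest missing columns {missing}")
        if len(table) and table["patient_id"].astype(str).eq("").any():
            raise ValueError("manifest has rows with empty patient_id")
        if len(table) and table["fs"].nunique() > 1:
            raise ValueError("manifest mixes sampling rates")
        self.table = table.reset_index(drop=True)
        self.root = root

    @classmethod
    def load(cls, path: str) -> "DatasetManifest":
        table = pd.read_csv(path)
        return cls(table, root=os.path.dirname(os.path.abspath(path)))

    def __len__(self) -> int:
        return len(self.table)

    @property
    def fs(self) -> float:
        if not len(self.table):
            raise ValueError("empty manifest has no sampling rate")
        return float(self.table["fs"].iloc[0])

    def patients(self) -> list[str]:
        return sorted(self.table["patient_id"].astype(str).unique())

    def segments(self) -> Iterator[LabeledSegment]:
        for _, row in self.table.iterrows():
            samples = read_segment(os.path.join(self.root, row["file"]))
            yield LabeledSegment(samples=samples, fs=float(row["fs"]),
                                 patient_id=str(row["patient_id"]),
                                 channel_name=str(row["channel_name"]),
                                 class_label=str(row["class_label"]))


def preprocess_segments(segments: Iterable[LabeledSegment],
                        filter_spec: FilterSpec | None = None,
                        do_zscore: bool = True,
                        resample: float | None = TARGET_FS
                        ) -> list[LabeledSegment]:
    """Standard front end: band-pass, resample to the working rate,
    z-score.  Pass ``filter_spec=None`` to skip filtering (synthetic
    segments are already band-limited)."""
    out = []
    for seg in segments:
        x = seg.samples
        if filter_spec is not None:
            x = bandpass(x, filter_spec)
        fs = seg.fs
        if resample is not None and fs != resample:
            x = resample_to(x, fs, resample)
            fs = resample
        if do_zscore:
            x = zscore(x)
        out.append(LabeledSegment(samples=x, fs=fs,
                                  patient_id=seg.patient_id,
                                  channel_name=seg.channel_name,
                                  class_label=seg.class_label))
    return out
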