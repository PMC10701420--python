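"""Multi-level discrete wavelet decomposition as strided convolution.

The spectral branch of the feature extractor computes a pyramid DWT
with Daubechies-4 filters, expressed as strided convolutions so the
whole network is one computational graph.  The boundary is handled by
wrapping the head and tail of each signal with samples from the
opposite end::

    xp = x(N-R/2+1) ... x(N-1) | x(0) ... x(N-1) | x(0) ... x(R/2-2)

which makes the strided convolution exactly equivalent to a periodized
pyramid DWT (length N/2 per level, no boundary distortion from zero
padding).

At a working rate of 256 Hz the dyadic levels land on the standard
physiological sub-bands: detail levels 1..5 cover high-γ (64–128 Hz),
γ (32–64), β (16–32), α (8–16) and θ (4–8), and the level-5
approximation is δ (0–4 Hz).

Functions accept either plain numpy arrays or autodiff Tensors; the
Tensor path participates in backpropagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

ArrayLike = Union[np.ndarray, Tensor]

# Orthonormal Daubechies-4 decomposition low-pass filter, in the order
# used by the convolution y(i) = sum_r xp(s*i - r) g(r).
_DB4_G = np.array([
    -0.010597401785069032, 0.0328830116668852,
    0.030841381835560764, -0.18703481171909309,
    -0.027983769416859854, 0.6308807679298589,
    0.7148465705529157, 0.2303778133088965,
])

#: Names of the six physiological sub-bands, lowest first.
BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma", "high_gamma")

#: Band edges in Hz at the 256 Hz working rate.
BAND_EDGES_HZ = ((0, 4), (4, 8), (8, 16), (16, 32), (32, 64), (64, 128))


@dataclass(frozen=True)
class WaveletFilterPair:
    """A quadrature-mirror pair of scaling (g) and wavelet (h) filters."""

    g: np.ndarray
    h: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        g = np.asarray(self.g, dtype=np.float64)
        object.__setattr__(self, "g", g)
        k = np.arange(len(g))
        # quadrature-mirror construction h[k] = (-1)^(k+1) g[R-1-k]; the
        # sign convention matches the common periodized-DWT reference
        # implementations (either overall sign gives a valid wavelet
        # filter, so a supplied h may use either)
        qmf = ((-1.0) ** (k + 1)) * g[::-1]
        if self.h is None:
            object.__setattr__(self, "h", qmf)
        else:
            h = np.asarray(self.h, dtype=np.float64)
            object.__setattr__(self, "h", h)
            if len(h) != len(g):
                raise ValueError("g and h must have equal length")
            if not (np.allclose(h, qmf, atol=1e-12)
                    or np.allclose(h, -qmf, atol=1e-12)):
                raise ValueError("h is not the quadrature mirror of g")

    @property
    def R(self) -> int:
        """Tap count (convolution kernel size)."""
        return len(self.g)


def daubechies4() -> WaveletFilterPair:
    """The 8-tap orthonormal Daubechies-4 filter pair."""
    return WaveletFilterPair(_DB4_G)


def pad_boundary(x: ArrayLike, R: int) -> ArrayLike:
    """Wrap-pad the last axis of ``x`` for an R-tap strided convolution.

    The head receives the final ``R/2 - 1`` samples and the tail the
    first ``R/2 - 1`` samples, so the convolution sees the signal as
    periodic.  ``R`` must be even; for ``R == 2`` the padding is empty
    and the input is returned unchanged.
    """
    if R % 2 != 0:
        raise ValueError(f"kernel size R must be even, got {R}")
    half = R // 2
    n = x.shape[-1]
    if n < half:
        raise ValueError(f"signal length {n} shorter than R/2 = {half}")
    if half == 1:
        return x
    head = x[..., n - half + 1:]
    tail = x[..., : half - 1]
    if isinstance(x, Tensor):
        return ad.concatenate([head, x, tail], axis=-1)
    return np.concatenate([head, x, tail], axis=-1)


def dwt_level(xp: ArrayLike, filt: WaveletFilterPair, s: int = 2):
    """One analysis level: approximation and detail coefficients.

    ``xp`` must already be wrap-padded via :func:`pad_boundary` with
    ``R = filt.R``.  Computes ``yA(i) = sum_r xp(s*i - r) g(r)`` and
    ``yD(i) = sum_r xp(s*i - r) h(r)`` over the valid range — i.e. a
    stride-``s`` convolution with the filter pair.
    """
    arr = not isinstance(xp, Tensor)
    t = Tensor(xp) if arr else xp
    lead = t.shape[:-1]
    wp = t.shape[-1]
    batch = int(np.prod(lead)) if lead else 1
    flat = t.reshape((batch, 1, wp))
    # conv1d computes a cross-correlation, so reverse the taps to get
    # the true convolution of the definition above
    w = Tensor(np.stack([filt.g[::-1], filt.h[::-1]])[:, None, :])
    out = ad.conv1d(flat, w, stride=s)  # (B, 2, L)
    L = out.shape[-1]
    yA = out[:, 0, :].reshape(lead + (L,))
    yD = out[:, 1, :].reshape(lead + (L,))
    if arr:
        return yA.data, yD.data
    return yA, yD


def multilevel_spectral(x: ArrayLike, filt: WaveletFilterPair = None,
                        n_bands: int = 6):
    """Cascaded DWT yielding one coefficient map per physiological band.

    Runs ``n_bands - 1`` analysis levels on the last axis of ``x``.
    Returns a list ordered from the lowest band upward: the final
    approximation (δ at 256 Hz), then detail levels deepest-first
    (θ, α, β, γ, high-γ).
    """
    if filt is None:
        filt = daubechies4()
    levels = n_bands - 1
    if x.shape[-1] < 2 ** n_bands:
        raise ValueError(
            f"signal length {x.shape[-1]} too short for {n_bands} bands "
            f"(needs at least {2 ** n_bands} samples)")
    details = []
    cur = x
    for _ in range(levels):
        xp = pad_boundary(cur, filt.R)
        cur, yD = dwt_level(xp, filt, s=2)
        details.append(yD)
    return [cur] + details[::-1]
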