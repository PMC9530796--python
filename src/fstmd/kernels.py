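"""Discrete spatial and temporal filter kernels.

The temporal kernels are causal Gamma kernels

    Gamma_{n,tau}(t) = (n t)^n exp(-n t / tau) / ((n-1)! tau^(n+1)),   t >= 0

which have unit integral and a single mode at t = tau.  The spatial
kernels are 2-D Gaussians and the center-surround (difference of
Gaussians) lateral-inhibition kernel that confers size selectivity.

Time constants are interpreted in sample units (frames): at a 1,000 Hz
sampling rate one frame is one millisecond, so the model's standard
parameter table applies verbatim.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from scipy.special import gammaln

__all__ = [
    "TemporalKernel",
    "SpatialKernel",
    "gamma_kernel",
    "bandpass_kernel",
    "gaussian_kernel",
    "inhibition_kernel",
    "convolve_temporal",
    "convolve_spatial",
]


@dataclass(frozen=True)
class TemporalKernel:
    """Causal FIR filter taps; ``taps[0]`` weights the current sample.

    The kernel never reads future samples: output at frame t is
    ``sum_k taps[k] * x[t - k]`` with implicit zero history before
    frame 0.
    """

    taps: np.ndarray
    fs: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        taps = np.asarray(self.taps, dtype=np.float64)
        if taps.ndim != 1 or taps.size < 1:
            raise ValueError("taps must be a non-empty 1-D sequence")
        object.__setattr__(self, "taps", taps)

    def __len__(self) -> int:
        return self.taps.size

    @property
    def mass(self) -> float:
        """Tap sum (discrete analogue of the kernel integral)."""
        return float(self.taps.sum())

    def convolve(self, other: "TemporalKernel") -> "TemporalKernel":
        """Discrete convolution of two kernels (composite filter)."""
        return TemporalKernel(
            np.convolve(self.taps, other.taps),
            fs=self.fs,
            meta={"composite_of": (self.meta, other.meta)},
        )


@dataclass(frozen=True)
class SpatialKernel:
    """Square 2-D filter grid of odd side; ``center`` is the (0,0) tap."""

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 2 or w.shape[0] != w.shape[1] or w.shape[0] % 2 == 0:
            raise ValueError("weights must be a square grid of odd side")
        object.__setattr__(self, "weights", w)

    @property
    def radius(self) -> int:
        return self.weights.shape[0] // 2

    @property
    def center(self) -> float:
        r = self.radius
        return float(self.weights[r, r])


def _gamma_pdf(n: int, tau: float, t: np.ndarray) -> np.ndarray:
    """Evaluate Gamma_{n,tau} at sample times t >= 0 (log-domain for safety)."""
    out = np.zeros_like(t, dtype=np.float64)
    pos = t > 0
    tp = t[pos]
    log_v = (
        n * (np.log(n) + np.log(tp))
        - n * tp / tau
        - gammaln(n)
        - (n + 1) * np.log(tau)
    )
    out[pos] = np.exp(log_v)
    if n == 0:  # not reachable through public API (n >= 1 enforced)
        out[t == 0] = 1.0 / tau
    return out


def gamma_kernel(
    n: int,
    tau: float,
    fs: float = 1.0,
    mass_tol: float = 1e-4,
    length: int | None = None,
) -> TemporalKernel:
    """Discretize the order-n Gamma kernel with time constant tau (samples).

    Samples the continuous kernel at t = 0, 1, 2, ... frames, truncates
    once the cumulative mass reaches ``1 - mass_tol`` (hard cap at
    ``10 (n+1) tau`` samples) and renormalizes to tap-sum exactly 1,
    preserving the analytic unit-integral property discretely.  The tap
    argmax sits at t = tau for integer tau, matching the continuous mode.

    ``length`` forces a fixed support length instead of mass-based
    truncation (used to place two kernels on a common support).
    """
    if not (isinstance(n, (int, np.integer)) and n >= 1):
        raise ValueError(f"Gamma order n must be a positive integer, got {n!r}")
    if tau <= 0:
        raise ValueError(f"Gamma time constant tau must be > 0, got {tau!r}")
    if fs <= 0:
        raise ValueError(f"sampling rate fs must be > 0, got {fs!r}")
    if not (0 < mass_tol < 1):
        raise ValueError(f"mass_tol must lie in (0, 1), got {mass_tol!r}")

    if length is not None:
        if length < 1:
            raise ValueError("length must be >= 1")
        cap = int(length)
    else:
        cap = int(np.ceil(10 * (n + 1) * tau)) + 1
    t = np.arange(cap, dtype=np.float64)
    vals = _gamma_pdf(int(n), float(tau), t)
    if length is None:
        cum = np.cumsum(vals)
        reached = np.nonzero(cum >= 1.0 - mass_tol)[0]
        if reached.size:
            vals = vals[: reached[0] + 1]
    total = vals.sum()
    if total <= 0:
        raise ValueError(
            f"degenerate Gamma kernel for n={n}, tau={tau}: no positive mass"
        )
    taps = vals / total
    return TemporalKernel(taps, fs=fs, meta={"n": int(n), "tau": float(tau)})


def bandpass_kernel(
    n1: int, tau1: float, n2: int, tau2: float, fs: float = 1.0,
    mass_tol: float = 1e-4,
) -> TemporalKernel:
    """Temporal band-pass filter H = Gamma_{n1,tau1} - Gamma_{n2,tau2}.

    The difference of two unit-mass Gamma kernels has zero tap-sum, so a
    temporally constant signal produces zero response (zero-DC).  With
    the standard parameters (2, 3, 6, 9) the taps form a positive early
    lobe followed by a negative late lobe: a biphasic change detector.
    """
    k1 = gamma_kernel(n1, tau1, fs=fs, mass_tol=mass_tol)
    k2 = gamma_kernel(n2, tau2, fs=fs, mass_tol=mass_tol)
    # resample both on a common support so neither lobe is clipped early,
    # which would leave a spurious tail of the other sign
    length = max(len(k1), len(k2))
    k1 = gamma_kernel(n1, tau1, fs=fs, length=length)
    k2 = gamma_kernel(n2, tau2, fs=fs, length=length)
    return TemporalKernel(
        k1.taps - k2.taps,
        fs=fs,
        meta={"n1": int(n1), "tau1": float(tau1),
              "n2": int(n2), "tau2": float(tau2)},
    )


def gaussian_kernel(sigma: float, radius: int | None = None) -> SpatialKernel:
    """Unit-sum 2-D Gaussian on the integer grid; default radius ceil(3 sigma)."""
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma!r}")
    if radius is None:
        radius = int(np.ceil(3 * sigma))
    if radius < 1:
        radius = 1
    ax = np.arange(-radius, radius + 1, dtype=np.float64)
    xx, yy = np.meshgrid(ax, ax)
    w = np.exp(-(xx**2 + yy**2) / (2 * sigma**2))
    return SpatialKernel(w / w.sum())


def _gaussian_unnormalized(sigma: float, xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
    return np.exp(-(xx**2 + yy**2) / (2 * sigma**2)) / (2 * np.pi * sigma**2)


def inhibition_kernel(
    sigma2: float = 1.5,
    sigma3: float = 3.0,
    e: float = 1.0,
    rho: float = 0.0,
    A: float = 1.0,
    B: float = 3.0,
    radius: int | None = None,
) -> SpatialKernel:
    """Center-surround lateral inhibition kernel for size selectivity.

    g = G_{sigma2} - e G_{sigma3} - rho on the grid, with the Gaussians
    carrying their analytic 1/(2 pi sigma^2) amplitude (no unit-sum
    renormalization), then W = A [g]^+ + B [g]^-.  The positive center
    passes compact activity; the amplified negative surround (B > A)
    suppresses spatially extended activity.
    """
    if sigma2 <= 0 or sigma3 <= 0:
        raise ValueError("sigma2 and sigma3 must be > 0")
    if sigma3 <= sigma2:
        warnings.warn(
            "sigma3 <= sigma2: inhibition kernel has no center-surround "
            "structure",
            stacklevel=2,
        )
    if radius is None:
        radius = int(np.ceil(3 * max(sigma2, sigma3)))
    ax = np.arange(-radius, radius + 1, dtype=np.float64)
    xx, yy = np.meshgrid(ax, ax)
    g = (
        _gaussian_unnormalized(sigma2, xx, yy)
        - e * _gaussian_unnormalized(sigma3, xx, yy)
        - rho
    )
    w = A * np.maximum(g, 0.0) + B * np.minimum(g, 0.0)
    return SpatialKernel(w)


def convolve_temporal(sig: np.ndarray, kernel: TemporalKernel) -> np.ndarray:
    """Causal temporal convolution along axis 0 with implicit zero history.

    Output at frame t uses frames <= t only.  Accepts a 1-D time series
    or a T x H x W volume (any trailing shape).
    """
    x = np.asarray(sig, dtype=np.float64)
    if x.shape[0] < 1:
        raise ValueError("signal must contain at least one sample")
    taps = kernel.taps
    shape = (len(taps),) + (1,) * (x.ndim - 1)
    full = signal.fftconvolve(x, taps.reshape(shape), mode="full", axes=0)
    return full[: x.shape[0]]


def convolve_spatial(frame: np.ndarray, kernel: SpatialKernel) -> np.ndarray:
    """Same-size 2-D convolution with replicate-edge padding.

    Replicate padding avoids the spurious dark border a zero pad would
    introduce, which the model would otherwise mistake for dark targets.
    Accepts a single H x W frame or a T x H x W volume (per-frame).
    """
    x = np.asarray(frame, dtype=np.float64)
    w = kernel.weights
    if x.ndim == 2:
        if w.shape[0] > x.shape[0] or w.shape[1] > x.shape[1]:
            raise ValueError("kernel larger than frame")
        return ndimage.convolve(x, w, mode="nearest")
    if x.ndim == 3:
        if w.shape[0] > x.shape[1] or w.shape[1] > x.shape[2]:
            raise ValueError("kernel larger than frame")
        return ndimage.convolve(x, w[None, :, :], mode="nearest")
    raise ValueError("expected a 2-D frame or 3-D volume")
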