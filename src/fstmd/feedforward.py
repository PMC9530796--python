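"""The four feed-forward neural layers of the detector.

Retina: each ommatidium spatially low-passes the luminance signal with a
Gaussian.  Lamina: large monopolar cells (LMCs) band-pass the signal in
time — positive output signals a luminance increase, negative a
decrease.  Medulla: the Tm3 (ON) channel half-wave rectifies the
positive part of the LMC output; the Tm1 (OFF) channel carries the
magnitude of the negative part, delayed and spread by a Gamma kernel.
Lobula: a small-target motion detector (STMD) multiplies the ON signal
with the delayed OFF signal, so a dark target that darkens then
re-brightens a pixel with transit time near the OFF delay produces a
strong coincidence response.  A final center-surround lateral inhibition
suppresses spatially extended responses (size selectivity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ModelConfig
from .kernels import (
    SpatialKernel,
    TemporalKernel,
    bandpass_kernel,
    convolve_spatial,
    convolve_temporal,
    gamma_kernel,
    gaussian_kernel,
    inhibition_kernel,
)

__all__ = [
    "ImageSequence",
    "LayerOutputs",
    "KernelBank",
    "build_kernels",
    "retina",
    "lamina",
    "medulla_on",
    "medulla_off",
    "lobula",
    "lateral_inhibition",
    "feedforward_pass",
]


@dataclass(frozen=True)
class ImageSequence:
    """T x H x W luminance volume in [0, 1] sampled at ``fs`` Hz.

    Coordinate convention: x = column, y = row, both 0-based; frame t
    samples time t / fs.
    """

    frames: np.ndarray
    fs: float

    def __post_init__(self):
        f = np.asarray(self.frames, dtype=np.float64)
        if f.ndim != 3 or f.shape[0] < 1:
            raise ValueError("frames must be a T x H x W volume with T >= 1")
        if self.fs <= 0:
            raise ValueError("sampling rate fs must be > 0")
        if f.min() < -1e-9 or f.max() > 1 + 1e-9:
            raise ValueError("luminance values must lie in [0, 1]")
        object.__setattr__(self, "frames", np.clip(f, 0.0, 1.0))

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape


@dataclass
class LayerOutputs:
    """Per-layer response volumes, all aligned with the input sequence.

    P: retina output; P_TF: retina plus feedback signal (equals P when
    feedback is off); L: lamina band-pass output; S_ON / S_OFF: medulla
    half-wave channels (non-negative); D: lobula STMD correlation
    (non-negative); D_F: the time-delay feedback signal; D_w: STMD
    output after lateral inhibition (non-negative) — the detection map.
    """

    P: np.ndarray
    P_TF: np.ndarray
    L: np.ndarray
    S_ON: np.ndarray
    S_OFF: np.ndarray
    D: np.ndarray
    D_F: np.ndarray
    D_w: np.ndarray
    warm_up_frames: int = 0


@dataclass(frozen=True)
class KernelBank:
    """All discrete kernels the model needs, built once from a config."""

    G1: SpatialKernel          # retina Gaussian
    H: TemporalKernel          # lamina band-pass
    gamma3: TemporalKernel     # OFF-channel delay
    gamma4: TemporalKernel     # feedback delay
    W: SpatialKernel           # lateral inhibition
    warm_up_frames: int = field(init=False)

    def __post_init__(self):
        object.__setattr__(
            self,
            "warm_up_frames",
            len(self.H) + len(self.gamma3) + len(self.gamma4),
        )


def build_kernels(config: ModelConfig, fs: float) -> KernelBank:
    mt = config.mass_tol
    return KernelBank(
        G1=gaussian_kernel(config.sigma1),
        H=bandpass_kernel(
            config.n1, config.tau1, config.n2, config.tau2, fs=fs, mass_tol=mt
        ),
        gamma3=gamma_kernel(config.n3, config.tau3, fs=fs, mass_tol=mt),
        gamma4=gamma_kernel(config.n4, config.tau4, fs=fs, mass_tol=mt),
        W=inhibition_kernel(
            config.sigma2, config.sigma3, config.e, config.rho,
            config.A, config.B,
        ),
    )


def retina(
    seq: ImageSequence, sigma1: float = 1.0, luminance_scale: float = 1.0
) -> np.ndarray:
    """Ommatidium layer: per-frame Gaussian smoothing of the luminance.

    ``luminance_scale`` converts the [0, 1] input to the model's
    internal luminance unit (255 in the composed passes, i.e. 8-bit
    grayscale levels).
    """
    return luminance_scale * convolve_spatial(seq.frames, gaussian_kernel(sigma1))


def lamina(P_TF: np.ndarray, H: TemporalKernel) -> np.ndarray:
    """LMC layer: per-pixel causal temporal band-pass (luminance change).

    The filter has zero tap-sum, so any temporally constant input maps
    to zero — after the start-up transient of one kernel length, during
    which the implicit zero history makes the input look like a step.
    """
    return convolve_temporal(P_TF, H)


def medulla_on(L: np.ndarray) -> np.ndarray:
    """Tm3 (ON) channel: positive part of the LMC output."""
    return np.maximum(L, 0.0)


def medulla_off(L: np.ndarray, gamma3: TemporalKernel) -> np.ndarray:
    """Tm1 (OFF) channel: magnitude of the negative LMC part, delayed.

    Uses the f^- = (|f| - f)/2 >= 0 convention for the negative part, so
    the OFF response is non-negative and peaks ~tau3 frames after a
    darkening event.
    """
    neg = np.maximum(-L, 0.0)
    # non-negative signal through a non-negative kernel is analytically
    # non-negative; the clamp removes FFT round-off at the 1e-16 level
    return np.maximum(convolve_temporal(neg, gamma3), 0.0)


def lobula(S_ON: np.ndarray, S_OFF: np.ndarray) -> np.ndarray:
    """STMD correlation: elementwise product of ON and delayed OFF."""
    if S_ON.shape != S_OFF.shape:
        raise ValueError(
            f"shape mismatch: S_ON {S_ON.shape} vs S_OFF {S_OFF.shape}"
        )
    return S_ON * S_OFF


def lateral_inhibition(D: np.ndarray, W: SpatialKernel) -> np.ndarray:
    """Per-frame center-surround convolution, positively rectified."""
    return np.maximum(convolve_spatial(D, W), 0.0)


def _stmd_core(P_TF: np.ndarray, bank: KernelBank) -> tuple:
    """lamina -> medulla -> lobula chain on a given LMC input volume."""
    L = lamina(P_TF, bank.H)
    S_ON = medulla_on(L)
    S_OFF = medulla_off(L, bank.gamma3)
    D = lobula(S_ON, S_OFF)
    return L, S_ON, S_OFF, D


def feedforward_pass(
    seq: ImageSequence,
    config: ModelConfig | None = None,
    feedback_signal: np.ndarray | None = None,
    bank: KernelBank | None = None,
) -> LayerOutputs:
    """Run the full open-loop chain, optionally with a frozen feedback volume.

    retina -> (+ feedback signal, if provided) -> lamina -> medulla ->
    lobula -> lateral inhibition.  All intermediate volumes are
    returned; detections within the first ``warm_up_frames`` frames sit
    inside the causal-filter start-up transient and should be treated
    with caution (they are flagged, not dropped).
    """
    config = config or ModelConfig()
    bank = bank or build_kernels(config, seq.fs)
    P = config.luminance_scale * convolve_spatial(seq.frames, bank.G1)
    if feedback_signal is None:
        D_F = np.zeros_like(P)
        P_TF = P
    else:
        if feedback_signal.shape != P.shape:
            raise ValueError(
                f"feedback volume shape {feedback_signal.shape} does not "
                f"match sequence shape {P.shape}"
            )
        D_F = feedback_signal
        P_TF = P + D_F
    L, S_ON, S_OFF, D = _stmd_core(P_TF, bank)
    D_w = lateral_inhibition(D, bank.W)
    return LayerOutputs(
        P=P, P_TF=P_TF, L=L, S_ON=S_ON, S_OFF=S_OFF, D=D, D_F=D_F, D_w=D_w,
        warm_up_frames=bank.warm_up_frames,
    )
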