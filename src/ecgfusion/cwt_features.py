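"""Complex Morlet CWT, scalograms, phasograms and their image rendering.

The continuous wavelet transform of a discrete beat x[t] is evaluated as
the Riemann sum

    W(tau, a) = (1/a) * sum_t x[t] * conj(Psi((t - tau) / a)),

with the L1 (1/a) normalization and the complex Morlet mother wavelet

    Psi(t) = (2*pi*sigma^2)^(-1/2) * exp(-t^2 / (2 sigma^2)) * exp(i w0 t),

where sigma = n / w0 and n is the number of wavelet cycles (default 6).
The sum is computed per scale as a convolution with the conjugated,
time-reversed scaled wavelet, truncated at +-6*sigma*a samples (the
Gaussian envelope is ~1.5e-8 of its peak there, keeping the convolution
within 1e-6 of the untruncated sum), with zero-padded (or optionally
circular) edges.  The scalogram is |W|^2, the
phasogram the wrapped phase angle of W.

A scale ``a`` corresponds to the pseudo-frequency f = w0 * fs / (2 pi a);
the default grid is 180 log-spaced scales spanning 1 Hz to 0.45 * fs, so
the pre-resize matrix of a 180-sample beat is square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

IMAGE_SIZE = 224


@dataclass(frozen=True)
class MorletParams:
    """Complex Morlet parameters; sigma is derived as n_cycles/omega0."""

    omega0: float = 6.0     # carrier, rad/sample
    n_cycles: float = 6.0   # n; sets sigma = n/omega0

    def __post_init__(self):
        if self.omega0 <= 0 or self.n_cycles <= 0:
            raise ValueError("omega0 and n_cycles must be positive")

    @property
    def sigma(self) -> float:
        return self.n_cycles / self.omega0


def morlet_mother(t, params: MorletParams = MorletParams()):
    """Mother wavelet value(s) at time t (samples)."""
    t = np.asarray(t, dtype=float)
    s2 = params.sigma ** 2
    return (1.0 / np.sqrt(2 * np.pi * s2)
            * np.exp(-t * t / (2 * s2))
            * np.exp(1j * params.omega0 * t))


@dataclass
class CWTResult:
    """Complex coefficients W(scale, time) over a strictly increasing
    scale grid."""

    coefficients: np.ndarray  # (n_scales, n_times) complex
    scales: np.ndarray
    fs: float

    def __post_init__(self):
        self.scales = np.asarray(self.scales, dtype=float)
        if np.any(np.diff(self.scales) <= 0):
            raise ValueError("scales must be strictly increasing")
        if self.coefficients.shape[0] != len(self.scales):
            raise ValueError("coefficient/scale shape mismatch")


def default_scales(fs, n_scales=180, params: MorletParams = MorletParams(),
                   f_min=1.0, f_max_frac=0.9):
    """Log-spaced scales whose pseudo-frequencies span
    [f_min, f_max_frac * fs/2]."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    if n_scales < 2:
        raise ValueError("need at least 2 scales")
    f_hi = f_max_frac * fs / 2.0
    a_min = params.omega0 * fs / (2 * np.pi * f_hi)
    a_max = params.omega0 * fs / (2 * np.pi * f_min)
    return np.geomspace(a_min, a_max, n_scales)


def pseudo_frequency(scales, fs, params: MorletParams = MorletParams()):
    """Morlet pseudo-frequency (Hz) of each scale."""
    return params.omega0 * fs / (2 * np.pi * np.asarray(scales, dtype=float))


def cwt(x, scales, params: MorletParams = MorletParams(), fs=250.0,
        mode="zero", truncation_sigmas=6.0) -> CWTResult:
    """CWT via per-scale convolution with the scaled, conjugated wavelet.

    ``mode`` is "zero" (zero-padded edges, default) or "circular"
    (periodic extension; makes the transform exactly shift-covariant).
    ``truncation_sigmas`` sets the kernel support half-width in units of
    the scaled Gaussian envelope width.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    if x.size < 8:
        raise ValueError("signal too short for CWT")
    scales = np.asarray(scales, dtype=float)
    if np.any(scales <= 0):
        raise ValueError("scales must be positive")
    n = x.size
    coeffs = np.empty((len(scales), n), dtype=complex)
    for i, a in enumerate(scales):
        half = int(np.ceil(truncation_sigmas * params.sigma * a))
        u = np.arange(-half, half + 1)
        # y[tau] = (1/a) sum_t x[t] conj(Psi((t-tau)/a)) = (x * h)[tau]
        # with kernel h[k] = (1/a) conj(Psi(-k/a))
        kernel = np.conj(morlet_mother(-u / a, params)) / a
        if mode == "circular":
            m = len(kernel)
            if m >= n:
                wrapped = np.zeros(n, dtype=complex)
                for j, v in enumerate(kernel):
                    wrapped[(j - half) % n] += v
            else:
                wrapped = np.zeros(n, dtype=complex)
                idx = (u % n)
                np.add.at(wrapped, idx, kernel)
            coeffs[i] = np.fft.ifft(np.fft.fft(x) * np.fft.fft(wrapped))
        elif mode == "zero":
            coeffs[i] = sps.fftconvolve(x, kernel, mode="same")
        else:
            raise ValueError(f"unknown edge mode {mode!r}")
    return CWTResult(coefficients=coeffs, scales=scales, fs=fs)


def cwt_direct(x, scales, params: MorletParams = MorletParams(), fs=250.0):
    """Direct O(N^2 * n_scales) Riemann-sum evaluation (oracle-grade
    reference; no truncation of the wavelet support)."""
    x = np.asarray(x, dtype=float)
    scales = np.asarray(scales, dtype=float)
    n = x.size
    t = np.arange(n)
    coeffs = np.empty((len(scales), n), dtype=complex)
    for i, a in enumerate(scales):
        arg = (t[None, :] - t[:, None]) / a  # rows tau, cols t
        coeffs[i] = (np.conj(morlet_mother(arg, params)) @ x) / a
    return CWTResult(coefficients=coeffs, scales=scales, fs=fs)


def scalogram(result: CWTResult) -> np.ndarray:
    """S(tau, a) = |W(tau, a)|^2."""
    return np.abs(result.coefficients) ** 2


def phasogram(result: CWTResult) -> np.ndarray:
    """Wrapped phase in (-pi, pi]; exact-zero coefficients get phase 0.

    ``np.angle`` returns values in [-pi, pi]; -pi is remapped to +pi so
    the range convention holds.
    """
    w = result.coefficients
    p = np.angle(w)
    p[p == -np.pi] = np.pi
    p[w == 0] = 0.0
    return p


def to_image(matrix, modality, size=IMAGE_SIZE) -> np.ndarray:
    """Render a scalogram/phasogram matrix as an 8-bit grayscale image.

    Scalograms are log-compressed (log(1+v)) then min–max mapped per
    image to [0, 255]; a constant matrix maps to all zeros.  Phasograms
    use the fixed linear map (-pi, pi] -> [0, 255] so phase values are
    comparable across beats.  The result is bilinearly resized to
    ``size`` x ``size`` and rounded half-to-even.
    """
    from skimage.transform import resize

    m = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix must be finite")
    if modality == "scalogram":
        v = np.log1p(np.maximum(m, 0.0))
        lo, hi = v.min(), v.max()
        scaled = np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo) * 255.0
    elif modality == "phasogram":
        scaled = (m + np.pi) / (2 * np.pi) * 255.0
    else:
        raise ValueError(f"unknown modality {modality!r}")
    out = resize(scaled, (size, size), order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    return np.rint(np.clip(out, 0, 255)).astype(np.uint8)


def beat_to_images(beat_samples, params: MorletParams = MorletParams(),
                   fs=250.0, n_scales=180, size=IMAGE_SIZE, mode="zero"):
    """Convenience: beat -> (scalogram image, phasogram image)."""
    scales = default_scales(fs, n_scales=n_scales, params=params)
    res = cwt(beat_samples, scales, params=params, fs=fs, mode=mode)
    return (to_image(scalogram(res), "scalogram", size=size),
            to_image(phasogram(res), "phasogram", size=size))
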