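"""Beat-level ECG preprocessing.

The chain mirrors standard MIT-BIH practice: zero-phase 5–20 Hz
band-pass denoising, resampling to 250 Hz, QRS detection, segmentation
into 180-sample windows centered on the detected R peaks, and per-beat
min–max normalization to [0, 1].

The QRS detector is a transparent Pan–Tompkins-style implementation
(differentiate, square, 150 ms moving-window integration, adaptive
threshold at half the running median of recent peak heights, 200 ms
refractory period), with the final R location snapped to the local
maximum of the filtered signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .ecg_io import ECGRecord, map_symbol_to_aami

logger = logging.getLogger(__name__)

BEAT_LEN = 180


@dataclass
class Beat:
    """A 180-sample [0,1]-normalized heartbeat window."""

    samples: np.ndarray
    class_label: str | None = None
    source: tuple = ("synth", -1)  # (record id, peak index)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (BEAT_LEN,):
            raise ValueError(f"beat must have {BEAT_LEN} samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("beat samples must be finite")


def bandpass_filter(x, fs, low=5.0, high=20.0, order=3):
    """Zero-phase Butterworth band-pass (forward-backward)."""
    x = np.asarray(x, dtype=float)
    if fs <= 2 * high:
        raise ValueError(f"fs={fs} too low for a {high} Hz passband edge")
    pad = 3 * (2 * order + 1)
    if len(x) <= 3 * pad:
        raise ValueError("signal too short for edge padding")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs,
                     output="sos")
    return sps.sosfiltfilt(sos, x)


def resample_signal(x, fs_in, fs_out=250.0):
    """Polyphase resampling with anti-aliasing; output length is
    round(len * fs_out / fs_in)."""
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        raise ValueError("empty signal")
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    if fs_in == fs_out:
        return x.copy()
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    y = sps.resample_poly(x, frac.numerator, frac.denominator)
    n_out = int(round(len(x) * fs_out / fs_in))
    if len(y) > n_out:
        y = y[:n_out]
    elif len(y) < n_out:
        y = np.pad(y, (0, n_out - len(y)), mode="edge")
    return y


def detect_r_peaks(x, fs):
    """Pan–Tompkins-style R-peak detection on a band-passed signal.

    Returns sorted peak indices; empty array for flat/short input.
    """
    x = np.asarray(x, dtype=float)
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz for QRS detection")
    if len(x) < int(0.4 * fs) or np.ptp(x) == 0:
        return np.array([], dtype=int)

    deriv = np.gradient(x)
    sq = deriv * deriv
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    refractory = int(round(0.200 * fs))
    cand, _ = sps.find_peaks(mwi, distance=refractory)
    if len(cand) == 0:
        return np.array([], dtype=int)

    # adaptive threshold: half the running median of recent peak heights,
    # applied on the amplitude (sqrt-energy) scale so wide-QRS ectopic
    # beats, whose squared-derivative energy is ~4x lower, are retained
    heights = np.sqrt(mwi[cand])
    kept = []
    recent = [np.median(heights[:max(3, len(heights) // 10)])]
    for c, h in zip(cand, heights):
        thr = 0.5 * np.median(recent[-8:])
        if h >= thr:
            kept.append(c)
            recent.append(h)
    if not kept:
        return np.array([], dtype=int)

    # snap each detection to the local maximum of the input signal
    half = int(round(0.100 * fs))
    peaks = []
    for c in kept:
        lo = max(0, c - half)
        hi = min(len(x), c + half + 1)
        peaks.append(lo + int(np.argmax(x[lo:hi])))
    peaks = np.unique(np.asarray(peaks, dtype=int))

    # local-dominance rule: a snapped peak must be the maximum of the
    # signal within its own refractory neighborhood, which removes
    # secondary MWI maxima on a QRS plateau that snap onto P/T waves
    peaks = np.asarray(
        [p for p in peaks
         if x[p] >= x[max(0, p - refractory):p + refractory + 1].max()],
        dtype=int)

    # enforce the refractory rule on the snapped locations: keep the larger
    out = []
    for p in peaks:
        if out and p - out[-1] < refractory:
            if x[p] > x[out[-1]]:
                out[-1] = p
        else:
            out.append(p)
    return np.asarray(out, dtype=int)


def segment_beats(x, peak_indices, width=BEAT_LEN):
    """Windows ``x[p - width//2, p + width - width//2)`` per peak.

    Peaks whose window crosses a record boundary are discarded; the
    number discarded is logged.  Returns (windows, kept_peaks).
    """
    x = np.asarray(x, dtype=float)
    before = width // 2
    after = width - before
    windows, kept = [], []
    dropped = 0
    for p in np.sort(np.asarray(peak_indices, dtype=int)):
        lo, hi = p - before, p + after
        if lo < 0 or hi > len(x):
            dropped += 1
            continue
        windows.append(x[lo:hi])
        kept.append(p)
    if dropped:
        logger.info("segment_beats: discarded %d boundary peaks", dropped)
    return windows, np.asarray(kept, dtype=int)


def normalize_beat(window):
    """Min–max normalization to [0, 1]; raises on constant windows."""
    w = np.asarray(window, dtype=float)
    if w.shape != (BEAT_LEN,):
        raise ValueError(f"window must have {BEAT_LEN} samples")
    lo, hi = w.min(), w.max()
    if hi == lo:
        raise ValueError("degenerate (constant) beat window")
    return (w - lo) / (hi - lo)


def extract_beats(record: ECGRecord, fs_out=250.0, low=5.0, high=20.0,
                  label_tolerance_s=0.075):
    """Full chain: filter -> resample -> detect -> segment -> normalize.

    Detected beats are labeled by the nearest annotation within
    ``label_tolerance_s``; unmatched detections are dropped.  Returns a
    list of :class:`Beat`.
    """
    filtered = bandpass_filter(record.samples, record.fs, low=low, high=high)
    resampled = resample_signal(filtered, record.fs, fs_out)
    scale = fs_out / record.fs
    ann_idx = np.asarray(
        [int(round(i * scale)) for i, _ in record.annotations], dtype=int)
    ann_cls = [map_symbol_to_aami(s) for _, s in record.annotations]

    peaks = detect_r_peaks(resampled, fs_out)
    windows, kept = segment_beats(resampled, peaks)

    tol = int(round(label_tolerance_s * fs_out))
    beats = []
    skipped_degenerate = 0
    for win, p in zip(windows, kept):
        label = None
        if len(ann_idx):
            j = int(np.argmin(np.abs(ann_idx - p)))
            if abs(int(ann_idx[j]) - int(p)) <= tol:
                label = ann_cls[j]
        if label is None:
            continue  # unmatched or non-beat annotation
        try:
            norm = normalize_beat(win)
        except ValueError:
            skipped_degenerate += 1
            continue
        beats.append(Beat(samples=norm, class_label=label,
                          source=(record.record_id, int(p))))
    if skipped_degenerate:
        logger.warning("skipped %d degenerate beats", skipped_degenerate)
    return beats
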